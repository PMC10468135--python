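"""Hull volumes, null models, lumpiness, and the permutation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metatrait.hypervolume import (
    HypervolumeNull,
    LumpinessParams,
    NullModelSpec,
    draw_null,
    hull_volume,
    hypervolume_report,
    null_test,
    occupancy_lumpiness,
)


# ------------------------------------------------------------------ hull_volume
def _cube_corners(n):
    from itertools import product

    return np.array(list(product([0.0, 1.0], repeat=n)))


def test_unit_square_volume():
    assert hull_volume(_cube_corners(2)) == pytest.approx(1.0, abs=1e-9)


def test_simplex_volume_is_one_over_factorial():
    corners = np.vstack([np.zeros(3), np.eye(3)])
    assert hull_volume(corners) == pytest.approx(1 / 6, abs=1e-12)


def test_translation_and_row_permutation_invariance(rng):
    pts = rng.standard_normal((30, 3))
    v = hull_volume(pts)
    assert hull_volume(pts + 7.5) == pytest.approx(v, rel=1e-10)
    assert hull_volume(pts[rng.permutation(30)]) == pytest.approx(v, rel=1e-10)


def test_volume_scales_with_determinant(rng):
    pts = rng.standard_normal((25, 3))
    diag = np.array([2.0, 0.5, 3.0])
    assert hull_volume(pts * diag) == pytest.approx(hull_volume(pts) * diag.prod(), rel=1e-9)


def test_interior_duplicate_point_changes_nothing(rng):
    pts = rng.standard_normal((20, 3))
    centroid = pts.mean(axis=0, keepdims=True)
    assert hull_volume(np.vstack([pts, centroid])) == pytest.approx(hull_volume(pts), rel=1e-12)


def test_rank_deficient_points_raise(rng):
    flat = rng.standard_normal((10, 2))
    pts = np.column_stack([flat, flat.sum(axis=1)])  # third dim dependent
    with pytest.raises(ValueError, match="zero-volume"):
        hull_volume(pts)


def test_too_few_points_raise(rng):
    with pytest.raises(ValueError, match="at least"):
        hull_volume(rng.standard_normal((3, 3)))


# -------------------------------------------------------------------- draw_null
@pytest.fixture(scope="module")
def observed_traits():
    rng = np.random.default_rng(77)
    cov = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.5], [0.3, 0.5, 1.0]])
    X = rng.multivariate_normal(np.array([5.0, 0.0, -2.0]), cov, size=120)
    return pd.DataFrame(X, columns=["t1", "t2", "t3"])


def test_permute_preserves_marginal_multisets(observed_traits):
    sims = draw_null(observed_traits, NullModelSpec("permute_indep", n_sim=19, seed=1))
    X = observed_traits.to_numpy()
    for sim in sims:
        for j in range(X.shape[1]):
            assert np.array_equal(np.sort(sim[:, j]), np.sort(X[:, j]))


def test_uniform_within_observed_range(observed_traits):
    sims = draw_null(observed_traits, NullModelSpec("uniform_indep", n_sim=19, seed=2))
    lo, hi = observed_traits.min().to_numpy(), observed_traits.max().to_numpy()
    for sim in sims:
        assert (sim >= lo).all() and (sim <= hi).all()


def test_normal_matches_observed_moments(observed_traits):
    sims = np.concatenate(
        draw_null(observed_traits, NullModelSpec("normal_indep", n_sim=199, seed=3))
    )
    assert np.allclose(sims.mean(axis=0), observed_traits.mean(), atol=0.05)
    assert np.allclose(sims.std(axis=0, ddof=1), observed_traits.std(ddof=1), atol=0.05)


def test_mvnormal_recovers_covariance(observed_traits):
    sims = draw_null(observed_traits, NullModelSpec("mvnormal", n_sim=19, seed=4))
    big = np.concatenate(sims)
    target = np.cov(observed_traits.to_numpy(), rowvar=False)
    sample = np.cov(big, rowvar=False)
    assert np.linalg.norm(sample - target) / np.linalg.norm(target) < 0.05


def test_draws_deterministic(observed_traits):
    spec = NullModelSpec("mvnormal", n_sim=19, seed=5)
    a = draw_null(observed_traits, spec)
    b = draw_null(observed_traits, spec)
    for x, y in zip(a, b):
        assert np.array_equal(x, y)


def test_singular_covariance_raises(rng):
    x = rng.standard_normal(50)
    frame = pd.DataFrame({"a": x, "b": 2 * x})
    with pytest.raises(ValueError, match="singular"):
        draw_null(frame, NullModelSpec("mvnormal", n_sim=19, seed=0))


def test_unknown_model_and_small_nsim_rejected():
    with pytest.raises(ValueError):
        NullModelSpec("bootstrap")
    with pytest.raises(ValueError):
        NullModelSpec("mvnormal", n_sim=10)


# --------------------------------------------------------- occupancy_lumpiness
def test_lumpiness_hand_fixture_concentrated():
    # 12 species stacked in one spot, 8 spread out alone; 10% of 20 -> 2 species
    pts = np.vstack([np.full((12, 2), 0.05), np.column_stack([np.linspace(0.15, 0.95, 8)] * 2)])
    res = occupancy_lumpiness(pts, LumpinessParams(bins_per_dim=10, capture_fraction=0.10))
    assert res.min_cells == 1
    assert sum(res.cell_counts.values()) == 20


def test_lumpiness_all_singletons():
    # 20 species, one per cell: a 10 x 2 grid arrangement
    pts = np.column_stack([np.arange(20.0) % 10, np.arange(20.0) // 10])
    res = occupancy_lumpiness(pts, LumpinessParams(10, 0.10))
    assert res.occupied_cells == 20
    assert res.min_cells == 2  # threshold = ceil(2) and every cell holds one


def test_lumpiness_single_point():
    res = occupancy_lumpiness(np.array([[0.3, 0.4]]), LumpinessParams(10, 0.10), ranges=([0, 0], [1, 1]))
    assert res.min_cells == 1


def test_lumpiness_maxima_fall_in_last_bin():
    pts = np.array([[0.0], [1.0]])
    res = occupancy_lumpiness(pts, LumpinessParams(10, 0.5))
    assert res.occupied_cells == 2
    assert (9,) in res.cell_counts


def test_lumpiness_zero_range_dimension_raises():
    pts = np.column_stack([np.arange(5.0), np.ones(5)])
    with pytest.raises(ValueError, match="zero-range"):
        occupancy_lumpiness(pts)


def test_min_cells_monotone_in_capture_fraction(rng):
    pts = rng.standard_normal((100, 2))
    prev = None
    for frac in (0.05, 0.10, 0.20, 0.40):
        m = occupancy_lumpiness(pts, LumpinessParams(10, frac)).min_cells
        if prev is not None:
            assert m >= prev
        prev = m


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=60), st.integers(min_value=0, max_value=10_000))
def test_cell_counts_always_sum_to_n(n, seed):
    rng = np.random.default_rng(seed)
    # two fixed corners guarantee nonzero range in both dimensions
    pts = np.vstack([rng.random((n, 2)), [[0.0, 0.0], [1.0, 1.0]]])
    res = occupancy_lumpiness(pts, LumpinessParams(10, 0.10))
    assert sum(res.cell_counts.values()) == len(pts)
    assert 1 <= res.min_cells <= res.occupied_cells


# -------------------------------------------------------------------- null_test
def test_strong_covariance_shrinks_volume(rng):
    cov = np.full((4, 4), 0.95)
    np.fill_diagonal(cov, 1.0)
    X = rng.multivariate_normal(np.zeros(4), cov, size=150)
    res = null_test(
        pd.DataFrame(X), "volume", NullModelSpec("permute_indep", n_sim=99, seed=0)
    )
    assert res.observed < res.null_values.min()
    assert res.p_value == pytest.approx(1 / 100)
    assert res.percent_change < 0
    assert res.direction == -1


def test_null_draw_as_observed_is_typical(rng):
    # observed data drawn from the permutation null family itself
    X = rng.standard_normal((80, 3))
    ps = []
    for seed in range(20):
        res = null_test(
            pd.DataFrame(rng.standard_normal((80, 3))),
            "volume",
            NullModelSpec("permute_indep", n_sim=99, seed=seed),
        )
        ps.append(res.p_value)
    assert np.mean(np.array(ps) > 0.1) >= 0.7


def test_mvnormal_null_accepts_mvnormal_data(rng):
    cov = np.array([[1.0, 0.7], [0.7, 1.0]])
    hits = 0
    for seed in range(20):
        X = np.random.default_rng(seed).multivariate_normal(np.zeros(2), cov, size=200)
        res = null_test(
            pd.DataFrame(X), "volume", NullModelSpec("mvnormal", n_sim=99, seed=seed)
        )
        hits += res.p_value > 0.05
    assert hits >= 16


def test_lumpiness_statistic_runs_with_observed_binning(rng):
    X = pd.DataFrame(rng.standard_normal((100, 3)))
    res = null_test(
        X,
        "lumpiness",
        NullModelSpec("permute_indep", n_sim=19, seed=0),
        params=LumpinessParams(10, 0.10),
        bin_range="observed",
    )
    assert res.observed >= 1
    assert len(res.null_values) == 19


def test_incomplete_traits_rejected():
    frame = pd.DataFrame({"a": [1.0, np.nan, 2.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]})
    with pytest.raises(ValueError, match="complete"):
        HypervolumeNull(frame, "volume", NullModelSpec("permute_indep", n_sim=19))


def test_summary_mentions_direction(rng):
    cov = np.full((3, 3), 0.9)
    np.fill_diagonal(cov, 1.0)
    X = rng.multivariate_normal(np.zeros(3), cov, size=100)
    res = null_test(pd.DataFrame(X), "volume", NullModelSpec("permute_indep", n_sim=49, seed=1))
    assert "smaller" in res.summary()


# ------------------------------------------------------------ hypervolume_report
def test_report_covers_full_grid(rng):
    X = pd.DataFrame(rng.standard_normal((60, 3)), columns=["a", "b", "c"])
    report = hypervolume_report(X, n_sim=19, seed=0)
    assert len(report) == 8
    assert set(report["model"]) == {"uniform_indep", "normal_indep", "permute_indep", "mvnormal"}
    assert set(report["statistic"]) == {"volume", "lumpiness"}
    assert report["p_value"].between(0, 1).all()


def test_report_volume_shrinks_under_independence_nulls(rng):
    cov = np.full((3, 3), 0.9)
    np.fill_diagonal(cov, 1.0)
    X = pd.DataFrame(rng.multivariate_normal(np.zeros(3), cov, size=200))
    report = hypervolume_report(X, n_sim=49, seed=3)
    vol = report[report["statistic"] == "volume"].set_index("model")
    for model in ("uniform_indep", "normal_indep", "permute_indep"):
        assert vol.loc[model, "percent_change"] < 0
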