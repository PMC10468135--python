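"""Constraints on multidimensional trait space.

Species are points in n-dimensional trait space (n = number of traits, used
on their analysis scale). Two occupancy statistics are compared against
randomized counterparts of the observed trait table:

* volume — the n-dimensional convex-hull volume of the species cloud; an
  observed volume far below the null indicates trait interdependence
  (few viable trait combinations);
* lumpiness — the minimum number of equal-width grid cells (10 bins per
  dimension by default) needed to capture a fixed fraction (10%) of species;
  fewer cells = more aggregated = lumpier.

Four null models break chosen structure: (i) ``uniform_indep`` — traits vary
independently with uniform marginals over the observed range; (ii)
``normal_indep`` — independent normal marginals (selection against extremes);
(iii) ``permute_indep`` — independent column permutations, marginals exactly
as observed; (iv) ``mvnormal`` — multivariate normal with the observed mean
and covariance (covariance kept, extremes penalized). Significance comes from
a two-sided permutation test around the null mean, and effect size is the
percent change of the observed statistic relative to the null mean
(positive = observed > simulated).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .traits import TraitTable, _trait_frame

__all__ = [
    "NullModelSpec",
    "LumpinessParams",
    "LumpinessResult",
    "HypervolumeResult",
    "HypervolumeNull",
    "NULL_MODELS",
    "hull_volume",
    "draw_null",
    "occupancy_lumpiness",
    "null_test",
    "hypervolume_report",
]

NULL_MODELS = ("uniform_indep", "normal_indep", "permute_indep", "mvnormal")


@dataclass
class NullModelSpec:
    """One null model and its simulation settings."""

    model: str
    n_sim: int = 999
    seed: int | None = None

    def __post_init__(self):
        if self.model not in NULL_MODELS:
            raise ValueError(f"unknown null model {self.model!r}; choose from {NULL_MODELS}")
        if self.n_sim < 19:
            raise ValueError("n_sim must be >= 19")


@dataclass
class LumpinessParams:
    bins_per_dim: int = 10
    capture_fraction: float = 0.10

    def __post_init__(self):
        if self.bins_per_dim < 2:
            raise ValueError("bins_per_dim must be >= 2")
        if not 0 < self.capture_fraction < 1:
            raise ValueError("capture_fraction must be in (0, 1)")


@dataclass
class LumpinessResult:
    min_cells: int
    occupied_cells: int
    cell_counts: dict


def _as_points(points) -> np.ndarray:
    pts = np.asarray(_trait_frame(points) if isinstance(points, TraitTable) else points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    return pts


def hull_volume(points) -> float:
    """Volume of the convex hull of an (observations x dimensions) point set."""
    pts = _as_points(points)
    n, d = pts.shape
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} points in {d} dimensions, got {n}")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered) < d:
        raise ValueError("zero-volume hull: points are affinely rank-deficient")
    try:
        return float(ConvexHull(pts).volume)
    except QhullError as err:  # pragma: no cover - rank check catches most cases
        raise ValueError(f"zero-volume hull: {err}") from None


def draw_null(traits, spec: NullModelSpec) -> list[np.ndarray]:
    """Simulate ``spec.n_sim`` null trait matrices with the observed shape."""
    frame = _trait_frame(traits)
    if frame.isna().any().any():
        raise ValueError("trait table must be complete")
    X = frame.to_numpy(dtype=float)
    n, d = X.shape
    rng = np.random.default_rng(spec.seed)
    if spec.model == "uniform_indep":
        lo, hi = X.min(axis=0), X.max(axis=0)
        return [rng.uniform(lo, hi, size=(n, d)) for _ in range(spec.n_sim)]
    if spec.model == "normal_indep":
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
        return [rng.normal(mu, sd, size=(n, d)) for _ in range(spec.n_sim)]
    if spec.model == "permute_indep":
        out = []
        for _ in range(spec.n_sim):
            sim = np.column_stack([rng.permutation(X[:, j]) for j in range(d)])
            out.append(sim)
        return out
    # mvnormal
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError(
            "singular trait covariance for mvnormal null; jitter the traits or drop a redundant trait"
        ) from None
    return [mu + rng.standard_normal((n, d)) @ chol.T for _ in range(spec.n_sim)]


def occupancy_lumpiness(
    points, params: LumpinessParams | None = None, ranges=None
) -> LumpinessResult:
    """Grid-occupancy lumpiness of a point cloud.

    Each dimension is cut into ``bins_per_dim`` equal-width intervals over the
    point set's own [min, max] (or over ``ranges = (mins, maxs)`` when given;
    out-of-range points then fall in the end bins); maxima go to the last bin.
    Only occupied cells are stored. The statistic is the smallest number of
    cells, taken in decreasing-count order (ties broken by cell index), whose
    counts sum to at least ``ceil(capture_fraction * n_points)``.
    """
    params = params or LumpinessParams()
    pts = _as_points(points)
    n, d = pts.shape
    if n < 1:
        raise ValueError("need at least one point")
    if ranges is None:
        mins, maxs = pts.min(axis=0), pts.max(axis=0)
    else:
        mins, maxs = (np.asarray(r, dtype=float) for r in ranges)
    span = maxs - mins
    zero = np.nonzero(span == 0)[0]
    if len(zero):
        raise ValueError(f"zero-range dimension(s) at index {zero.tolist()}")
    b = params.bins_per_dim
    idx = np.floor((pts - mins) / span * b).astype(int)
    idx = np.clip(idx, 0, b - 1)
    counts: dict[tuple, int] = {}
    for row in map(tuple, idx):
        counts[row] = counts.get(row, 0) + 1
    threshold = math.ceil(params.capture_fraction * n)
    total, min_cells = 0, 0
    for cell, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        total += c
        min_cells += 1
        if total >= threshold:
            break
    return LumpinessResult(min_cells=min_cells, occupied_cells=len(counts), cell_counts=counts)


@dataclass
class HypervolumeResult:
    """Observed statistic vs. its null distribution under one null model.

    ``percent_change = 100 * (observed - mean(null)) / mean(null)`` (positive
    = observed > simulated); ``p_value`` is two-sided around the null mean
    with the +1 permutation correction.
    """

    statistic: str
    model: str
    observed: float
    null_values: np.ndarray
    p_value: float
    percent_change: float
    direction: int
    n_sim: int
    seed: int | None = None

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    def summary(self) -> str:
        word = {
            ("volume", 1): "larger",
            ("volume", -1): "smaller",
            ("lumpiness", 1): "less lumpy",
            ("lumpiness", -1): "lumpier",
        }.get((self.statistic, self.direction), "unchanged")
        return (
            f"Trait-space {self.statistic} vs null model '{self.model}' "
            f"({self.n_sim} simulations)\n"
            f"  observed = {self.observed:.6g}, null mean = {self.null_mean:.6g}\n"
            f"  percent change = {self.percent_change:+.1f}% "
            f"(observed {word} than simulated), P = {self.p_value:.4g}"
        )


class HypervolumeNull:
    """Null-model test of trait-space occupancy (model object).

    Parameters
    ----------
    traits : TraitTable or DataFrame
        Complete species x trait table on its analysis scale.
    statistic : {"volume", "lumpiness"}
    spec : NullModelSpec
    params : LumpinessParams, optional
    bin_range : {"self", "observed"}
        Whether each simulated cloud is binned on its own ranges or on the
        observed ranges (lumpiness only).
    standardize : {"none", "zscore"}
        Optional z-scoring of the observed traits before everything.
    """

    def __init__(
        self,
        traits,
        statistic: str,
        spec: NullModelSpec,
        params: LumpinessParams | None = None,
        bin_range: str = "self",
        standardize: str = "none",
    ):
        if statistic not in ("volume", "lumpiness"):
            raise ValueError(f"unknown statistic {statistic!r}")
        if bin_range not in ("self", "observed"):
            raise ValueError(f"unknown bin_range {bin_range!r}")
        if standardize not in ("none", "zscore"):
            raise ValueError(f"unknown standardize {standardize!r}")
        frame = _trait_frame(traits)
        if frame.isna().any().any():
            raise ValueError("trait table must be complete")
        if standardize == "zscore":
            frame = (frame - frame.mean()) / frame.std(ddof=1)
        self.traits = frame
        self.statistic = statistic
        self.spec = spec
        self.params = params or LumpinessParams()
        self.bin_range = bin_range

    def _evaluate(self, pts: np.ndarray, observed_ranges) -> float:
        if self.statistic == "volume":
            return hull_volume(pts)
        ranges = observed_ranges if self.bin_range == "observed" else None
        return float(occupancy_lumpiness(pts, self.params, ranges=ranges).min_cells)

    def fit(self) -> HypervolumeResult:
        X = self.traits.to_numpy(dtype=float)
        ranges = (X.min(axis=0), X.max(axis=0))
        observed = self._evaluate(X, ranges)
        nulls = np.empty(self.spec.n_sim)
        for i, sim in enumerate(draw_null(self.traits, self.spec)):
            try:
                nulls[i] = self._evaluate(sim, ranges)
            except ValueError:
                warnings.warn(
                    f"degenerate hull in null draw {i}; counted as volume 0",
                    RuntimeWarning,
                    stacklevel=2,
                )
                nulls[i] = 0.0
        mean = nulls.mean()
        p = (np.sum(np.abs(nulls - mean) >= abs(observed - mean)) + 1) / (self.spec.n_sim + 1)
        pct = 100.0 * (observed - mean) / mean
        return HypervolumeResult(
            statistic=self.statistic,
            model=self.spec.model,
            observed=float(observed),
            null_values=nulls,
            p_value=float(p),
            percent_change=float(pct),
            direction=int(np.sign(pct)),
            n_sim=self.spec.n_sim,
            seed=self.spec.seed,
        )


def null_test(
    traits,
    statistic: str,
    spec: NullModelSpec,
    params: LumpinessParams | None = None,
    **kwargs,
) -> HypervolumeResult:
    """Fit a :class:`HypervolumeNull` model and return its result."""
    return HypervolumeNull(traits, statistic, spec, params=params, **kwargs).fit()


def hypervolume_report(
    traits,
    n_sim: int = 999,
    seed=None,
    params: LumpinessParams | None = None,
    models=NULL_MODELS,
    statistics=("volume", "lumpiness"),
    **kwargs,
) -> pd.DataFrame:
    """Run every (null model x statistic) test; one row each.

    Seeds for the individual tests are spawned deterministically from
    ``seed`` so the 8 cells are mutually independent but reproducible.
    """
    children = np.random.SeedSequence(seed).spawn(len(models) * len(statistics))
    rows = []
    i = 0
    for statistic in statistics:
        for model in models:
            child_seed = int(children[i].generate_state(1)[0] % (2**31))
            i += 1
            res = null_test(
                traits,
                statistic,
                NullModelSpec(model=model, n_sim=n_sim, seed=child_seed),
                params=params,
                **kwargs,
            )
            rows.append(
                {
                    "statistic": statistic,
                    "model": model,
                    "observed": res.observed,
                    "null_mean": res.null_mean,
                    "percent_change": res.percent_change,
                    "p_value": res.p_value,
                    "n_sim": n_sim,
                    "seed": child_seed,
                }
            )
    return pd.DataFrame(rows)
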