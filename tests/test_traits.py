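"""Trait tables: presence collapse, metabolic traits, cleaning, gap-filling."""

import numpy as np
import pandas as pd
import pytest

from metatrait.chemspace import PropertyTable
from metatrait.synthetic import gen_classical_traits
from metatrait.traits import (
    Taxonomy,
    TraitTable,
    clean_classical,
    collapse_to_presence,
    gapfill_two_step,
    genus_fallback,
    metabolic_traits,
    transform_traits,
)


# -------------------------------------------------------- collapse_to_presence
def test_collapse_sums_features_per_consensus():
    features = pd.DataFrame(
        {"f1": [0.0, 1.0, 0.0], "f2": [5.0, 0.0, 0.0], "f3": [0.0, 2.0, 0.0], "f4": [1.0, 0.0, 0.0]},
        index=["s1", "s2", "s3"],
    )
    cmap = {"f1": "c1", "f2": "c1", "f3": "c2", "f4": "c2"}
    presence = collapse_to_presence(features, cmap)
    expected = pd.DataFrame(
        {"c1": [1, 1, 0], "c2": [1, 1, 0]}, index=["s1", "s2", "s3"], dtype=np.int8
    )
    pd.testing.assert_frame_equal(presence, expected, check_names=False)
    # the all-zero species row survives (flagged downstream, not dropped here)
    assert (presence.loc["s3"] == 0).all()


def test_collapse_negative_peak_raises():
    features = pd.DataFrame({"f1": [-1.0]}, index=["s1"])
    with pytest.raises(ValueError, match="negative"):
        collapse_to_presence(features, {"f1": "c1"})


def test_collapse_unmapped_feature_raises():
    features = pd.DataFrame({"f1": [1.0]}, index=["s1"])
    with pytest.raises(KeyError):
        collapse_to_presence(features, {"other": "c1"})


# ------------------------------------------------------------ metabolic_traits
def _toy_properties():
    data = pd.DataFrame(
        {
            "molecular_weight": [180.2, 300.0, 120.0, 250.0],
            "aromatic_atom_count": [6.0, 12.0, 0.0, 5.0],
        },
        index=pd.Index(["m1", "m2", "m3", "m4"], name="metabolite_id"),
    )
    return PropertyTable(data)


def test_single_metabolite_species_mean_is_its_value():
    presence = pd.DataFrame(
        [[1, 0, 0, 0]], index=["sp1"], columns=["m1", "m2", "m3", "m4"]
    )
    traits = metabolic_traits(presence, _toy_properties(), ["molecular_weight"])
    assert traits.data.loc["sp1", "molecular_weight"] == pytest.approx(180.2)


def test_two_metabolite_mean():
    presence = pd.DataFrame(
        [[1, 1, 0, 0]], index=["sp1"], columns=["m1", "m2", "m3", "m4"]
    )
    traits = metabolic_traits(presence, _toy_properties(), ["aromatic_atom_count"])
    assert traits.data.loc["sp1", "aromatic_atom_count"] == pytest.approx(9.0)


def test_metabolic_traits_match_bruteforce(rng):
    ids = [f"m{i}" for i in range(8)]
    prop = PropertyTable(
        pd.DataFrame(
            rng.standard_normal((8, 3)), index=pd.Index(ids, name="metabolite_id"),
            columns=["a", "b", "c"],
        )
    )
    presence = pd.DataFrame(
        (rng.random((5, 8)) < 0.6).astype(int), index=[f"s{i}" for i in range(5)], columns=ids
    )
    presence.iloc[presence.sum(axis=1) == 0, 0] = 1
    traits = metabolic_traits(presence, prop, ["a", "b", "c"])
    for s in presence.index:
        present = presence.columns[presence.loc[s] == 1]
        for t in ("a", "b", "c"):
            assert traits.data.loc[s, t] == pytest.approx(prop.data.loc[present, t].mean())


def test_zero_presence_species_listed():
    presence = pd.DataFrame(
        [[0, 0, 0, 0], [1, 0, 0, 0]], index=["empty", "ok"], columns=["m1", "m2", "m3", "m4"]
    )
    with pytest.raises(ValueError, match="empty"):
        metabolic_traits(presence, _toy_properties(), ["molecular_weight"])


def test_species_reordering_commutes(rng):
    ids = [f"m{i}" for i in range(6)]
    prop = PropertyTable(
        pd.DataFrame(rng.standard_normal((6, 2)), index=pd.Index(ids), columns=["a", "b"])
    )
    presence = pd.DataFrame(
        (rng.random((4, 6)) < 0.7).astype(int), index=list("wxyz"), columns=ids
    )
    presence[presence.sum(axis=1) == 0] = 1
    t1 = metabolic_traits(presence, prop, ["a", "b"])
    t2 = metabolic_traits(presence.iloc[::-1], prop, ["a", "b"])
    pd.testing.assert_frame_equal(t1.data.sort_index(), t2.data.sort_index())


def test_absent_everywhere_metabolite_changes_nothing(rng):
    ids = [f"m{i}" for i in range(5)]
    prop = PropertyTable(
        pd.DataFrame(rng.standard_normal((5, 2)), index=pd.Index(ids), columns=["a", "b"])
    )
    presence = pd.DataFrame([[1, 1, 0, 1, 0]], index=["s"], columns=ids)
    base = metabolic_traits(presence[ids[:4]], PropertyTable(prop.data.iloc[:4]), ["a", "b"])
    extended = metabolic_traits(presence, prop, ["a", "b"])
    pd.testing.assert_frame_equal(base.data, extended.data)


# ------------------------------------------------------------- clean_classical
def _records():
    return pd.DataFrame(
        {
            "species": ["s1"] * 6,
            "trait": ["h"] * 6,
            "value": [1.0, 2.0, 3.0, 4.0, 100.0, -5.0],
            "error_risk": [0.0, 3.9, 4.0, 0.0, 0.0, 0.0],
        }
    )


def test_error_risk_boundary_semantics():
    table, report = clean_classical(_records(), limits={"h": (0.0, 50.0)})
    # risk 4.0 dropped, 3.9 kept; 100 and -5 outside limits dropped
    assert table.data.loc["s1", "h"] == pytest.approx(np.mean([1.0, 2.0, 4.0]))
    row = report.set_index("trait").loc["h"]
    assert row["dropped_error_risk"] == 1
    assert row["dropped_limits"] == 2
    assert row["kept"] == 3
    assert row["kept"] + row["dropped_error_risk"] + row["dropped_limits"] == 6


def test_limit_bounds_are_inclusive():
    records = pd.DataFrame(
        {"species": ["s1", "s1"], "trait": ["h", "h"], "value": [0.0, 50.0], "error_risk": [0, 0]}
    )
    table, report = clean_classical(records, limits={"h": (0.0, 50.0)})
    assert report.set_index("trait").loc["h", "kept"] == 2


def test_inverted_limits_raise():
    with pytest.raises(ValueError, match="min"):
        clean_classical(_records(), limits={"h": (10.0, 1.0)})


# ------------------------------------------------------------ gapfill_two_step
def _tax(species, genera=None, families=None):
    n = len(species)
    genera = genera or ["g1"] * n
    families = families or ["f1"] * n
    return Taxonomy(pd.DataFrame({"genus": genera, "family": families}, index=species))


def test_complete_table_returned_unchanged():
    frame = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]}, index=["s1", "s2"])
    out, prov = gapfill_two_step(TraitTable(frame), _tax(["s1", "s2"]), n_runs=2, seed=0)
    pd.testing.assert_frame_equal(out.data, frame)
    assert (prov == "observed").all().all()


def test_noiseless_genus_mean_fill():
    frame = pd.DataFrame(
        {"a": [6.0, 8.0, np.nan]}, index=["s1", "s2", "s3"]
    )
    tax = _tax(["s1", "s2", "s3"])

    def noiseless(f, taxonomy, rng):
        out = f.copy()
        out.loc["s3", "a"] = 7.0  # genus mean of 6 and 8
        return out

    out, prov = gapfill_two_step(TraitTable(frame), tax, n_runs=2, seed=0, imputer=noiseless)
    assert out.data.loc["s3", "a"] == pytest.approx(7.0)
    assert prov.loc["s3", "a"] == "imputed_step1"
    # observed cells untouched
    assert out.data.loc["s1", "a"] == 6.0


def _scripted_imputer(values):
    """Imputer stub filling every missing cell with the next scripted value."""
    state = {"i": 0}

    def impute(frame, taxonomy, rng):
        out = frame.copy()
        v = values[state["i"] % len(values)]
        state["i"] += 1
        return out.fillna(v)

    return impute


def test_extreme_filter_is_strictly_greater():
    # max observed = 10; a run at exactly 15 (= 1.5 x max) must be KEPT
    frame = pd.DataFrame({"a": [10.0, 2.0, np.nan]}, index=["s1", "s2", "s3"])
    out, prov = gapfill_two_step(
        TraitTable(frame), _tax(["s1", "s2", "s3"]), n_runs=2, seed=0,
        imputer=_scripted_imputer([15.0, 15.0]),
    )
    assert prov.loc["s3", "a"] == "imputed_step1"
    assert out.data.loc["s3", "a"] == pytest.approx(15.0)


def test_extreme_filter_reblanks_above_threshold():
    frame = pd.DataFrame({"a": [10.0, 2.0, np.nan], "b": [1.0, 2.0, 3.0]}, index=["s1", "s2", "s3"])
    out, prov = gapfill_two_step(
        TraitTable(frame), _tax(["s1", "s2", "s3"]), n_runs=2, seed=0,
        imputer=_scripted_imputer([15.01, 15.01]),
    )
    # one run above 1.5 x max -> cell re-blanked, then filled by step 2
    assert prov.loc["s3", "a"] == "imputed_step2"
    assert out.complete


def test_cv_filter_boundary_kept_and_exceeded_reblanked():
    # scripted runs (2 - sqrt(2), 2 + sqrt(2)): mean 2, sd 2 -> CV exactly 1 -> kept
    frame = pd.DataFrame({"a": [10.0, 2.0, np.nan], "b": [1.0, 2.0, 3.0]}, index=["s1", "s2", "s3"])
    r2 = np.sqrt(2.0)
    out, prov = gapfill_two_step(
        TraitTable(frame), _tax(["s1", "s2", "s3"]), n_runs=2, seed=0,
        imputer=_scripted_imputer([2 - r2, 2 + r2]),
    )
    assert prov.loc["s3", "a"] == "imputed_step1"
    assert out.data.loc["s3", "a"] == pytest.approx(2.0)
    # now CV just above 1 -> re-blanked and resolved in step 2
    out2, prov2 = gapfill_two_step(
        TraitTable(frame), _tax(["s1", "s2", "s3"]), n_runs=2, seed=0,
        imputer=_scripted_imputer([2 - 1.01 * r2, 2 + 1.01 * r2]),
    )
    assert prov2.loc["s3", "a"] == "imputed_step2"
    assert out2.complete


def test_all_missing_trait_raises():
    frame = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]}, index=["s1", "s2"])
    with pytest.raises(ValueError, match="zero observed"):
        gapfill_two_step(TraitTable(frame), _tax(["s1", "s2"]), n_runs=2, seed=0)


def test_gapfill_never_alters_observed_and_completes():
    table, tax = gen_classical_traits(120, taxonomy_spec=(20, 6), missing_frac=0.25, seed=4)
    out, prov = gapfill_two_step(table, tax, n_runs=10, seed=9)
    assert out.complete
    observed = table.data.notna()
    before = table.data.to_numpy()[observed.to_numpy()]
    after = out.data.to_numpy()[observed.to_numpy()]
    assert np.array_equal(before, after)
    assert (prov.to_numpy()[observed.to_numpy()] == "observed").all()


def test_gapfill_beats_grand_mean_baseline():
    full, tax = gen_classical_traits(300, missing_frac=0.0, seed=3)
    masked, _ = gen_classical_traits(300, missing_frac=0.2, seed=3)  # same values, masked
    out, _ = gapfill_two_step(masked, tax, n_runs=20, seed=5)
    mask = masked.data.isna().to_numpy()
    truth = full.data.to_numpy()[mask]
    rmse = np.sqrt(np.mean((out.data.to_numpy()[mask] - truth) ** 2))
    grand = np.broadcast_to(masked.data.mean().to_numpy(), masked.data.shape)[mask]
    rmse_baseline = np.sqrt(np.mean((grand - truth) ** 2))
    assert rmse < rmse_baseline


# -------------------------------------------------------------- genus_fallback
def test_genus_fallback_hand_means():
    frame = pd.DataFrame({"h": [2.0, 4.0, 10.0]}, index=["s1", "s2", "s3"])
    tax = _tax(
        ["s1", "s2", "s3", "s4", "s5", "s6"],
        genera=["g1", "g1", "g2", "g1", "g2", "g2"],
    )
    out, prov = genus_fallback(TraitTable(frame), tax, ["s4", "s5", "s6"])
    assert out.data.loc["s4", "h"] == pytest.approx(3.0)
    assert out.data.loc["s5", "h"] == pytest.approx(10.0)
    assert out.data.loc["s6", "h"] == pytest.approx(10.0)
    assert prov.loc["s4", "h"] == "genus"
    assert prov.loc["s1", "h"] == "species"
    # species with own data untouched
    assert out.data.loc["s1", "h"] == 2.0


def test_genus_fallback_orphan_raises():
    frame = pd.DataFrame({"h": [2.0]}, index=["s1"])
    tax = _tax(["s1", "s2"], genera=["g1", "g9"])
    with pytest.raises(ValueError, match="s2"):
        genus_fallback(TraitTable(frame), tax, ["s2"])


# ------------------------------------------------------------ transform_traits
def test_log10_transforms():
    frame = pd.DataFrame(
        {"height": [10.0, 1.0], "seed_mass": [1.0, 100.0], "other": [5.0, 6.0]},
        index=["s1", "s2"],
    )
    out = transform_traits(TraitTable(frame), ["height", "seed_mass"])
    assert out.data.loc["s1", "height"] == pytest.approx(1.0)
    assert list(out.data["seed_mass"]) == pytest.approx([0.0, 2.0])
    assert out.transforms["height"] == "log10"
    assert out.transforms["other"] == "none"
    # input not mutated
    assert frame.loc["s1", "height"] == 10.0


def test_log10_nonpositive_raises():
    frame = pd.DataFrame({"height": [0.0]}, index=["s1"])
    with pytest.raises(ValueError, match="height"):
        transform_traits(TraitTable(frame), ["height"])
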