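"""Species-level trait tables.

Two kinds of traits are built here. Metabolic functional traits summarize a
species' leaf metabolome: for each selected chemical property, the trait is
the unweighted mean of that property over all metabolites present in the
species (presence/absence only — abundance is deliberately ignored).
Classical functional traits (plant height, seed mass, SLA, leaf N, ...) come
as noisy long-format records that are cleaned by error-risk and documented
trait limits, averaged per species, gap-filled in two stages with extreme-
value and coefficient-of-variation filters, and log10-transformed where
their distributions require it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemspace import PropertyTable

__all__ = [
    "TraitTable",
    "Taxonomy",
    "collapse_to_presence",
    "validate_presence",
    "metabolic_traits",
    "clean_classical",
    "gapfill_two_step",
    "genus_fallback",
    "transform_traits",
    "taxonomic_shrinkage_imputer",
]


@dataclass
class TraitTable:
    """Species x trait numeric table with per-trait units and transforms.

    ``transforms[trait]`` is ``"none"`` or ``"log10"``; log10-flagged traits
    were strictly positive before transformation.
    """

    data: pd.DataFrame
    units: dict = field(default_factory=dict)
    transforms: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = pd.DataFrame(self.data)
        for t in self.data.columns:
            self.transforms.setdefault(t, "none")

    @property
    def species(self) -> pd.Index:
        return self.data.index

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def complete(self) -> bool:
        return not self.data.isna().any().any()

    def require_complete(self):
        if not self.complete:
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"trait table has missing values in: {bad}")
        return self

    def copy(self) -> "TraitTable":
        return TraitTable(self.data.copy(), dict(self.units), dict(self.transforms))

    def __len__(self) -> int:
        return len(self.data)


class Taxonomy:
    """Total species -> (genus, family) mapping."""

    def __init__(self, table: pd.DataFrame):
        table = pd.DataFrame(table)
        if not {"genus", "family"}.issubset(table.columns):
            raise ValueError("taxonomy needs 'genus' and 'family' columns")
        if table.index.duplicated().any():
            raise ValueError("duplicate species in taxonomy")
        self.table = table[["genus", "family"]]

    def genus_of(self, species) -> pd.Series:
        return self.table.loc[species, "genus"]

    def require_covers(self, species_ids):
        missing = [s for s in species_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"species missing from taxonomy: {missing[:10]}")

    @property
    def species(self) -> pd.Index:
        return self.table.index


def _trait_frame(traits) -> pd.DataFrame:
    return traits.data if isinstance(traits, TraitTable) else pd.DataFrame(traits)


def validate_presence(presence: pd.DataFrame) -> pd.DataFrame:
    values = presence.to_numpy()
    if not np.isin(values, (0, 1)).all():
        bad = np.argwhere(~np.isin(values, (0, 1)))[0]
        raise ValueError(
            "presence matrix is not binary at "
            f"({presence.index[bad[0]]!r}, {presence.columns[bad[1]]!r})"
        )
    return presence


def collapse_to_presence(
    feature_table: pd.DataFrame, consensus_map: pd.Series | dict
) -> pd.DataFrame:
    """Collapse a species x feature peak table to species x consensus presence.

    Peak heights/areas of features mapping to the same consensus metabolite
    are summed per species; a consensus metabolite is present (1) when the sum
    is positive. Species rows that end up all-zero are kept (flagged for
    downstream exclusion by the caller).
    """
    feature_table = pd.DataFrame(feature_table)
    if (feature_table.to_numpy() < 0).any():
        raise ValueError("negative peak value in feature table")
    cmap = pd.Series(consensus_map)
    unmapped = [f for f in feature_table.columns if f not in cmap.index]
    if unmapped:
        raise KeyError(f"features without consensus mapping: {unmapped[:10]}")
    sums = feature_table.T.groupby(cmap.reindex(feature_table.columns)).sum().T
    presence = (sums > 0).astype(np.int8)
    presence.index.name = feature_table.index.name
    return presence


def metabolic_traits(
    presence: pd.DataFrame, properties: PropertyTable, selected: list[str]
) -> TraitTable:
    """Per-species mean of each selected chemical property over present metabolites.

    Unweighted: presence only, never abundance. Raises if any species has no
    present metabolite with property data (callers must exclude those first).
    """
    presence = validate_presence(pd.DataFrame(presence))
    prop = properties.data if isinstance(properties, PropertyTable) else pd.DataFrame(properties)
    missing_props = [p for p in selected if p not in prop.columns]
    if missing_props:
        raise KeyError(f"selected properties not in property table: {missing_props}")
    missing_mets = presence.columns.difference(prop.index)
    if len(missing_mets):
        raise KeyError(
            f"metabolites in presence matrix without property data: {list(missing_mets[:10])}"
        )
    P = presence.to_numpy(dtype=float)
    counts = P.sum(axis=1)
    empty = presence.index[counts == 0].tolist()
    if empty:
        raise ValueError(f"species with zero present metabolites: {empty[:10]}")
    V = prop.loc[presence.columns, list(selected)].to_numpy(dtype=float)
    means = (P @ V) / counts[:, None]
    data = pd.DataFrame(means, index=presence.index, columns=list(selected))
    return TraitTable(data)


def clean_classical(
    raw: pd.DataFrame,
    limits: dict,
    error_risk_max: float = 4.0,
) -> tuple[TraitTable, pd.DataFrame]:
    """Clean long-format trait records and average per species.

    Records with reported error risk >= ``error_risk_max`` are dropped, as are
    values falling outside the documented [min, max] limits for their trait
    (limits are inclusive). Returns the species x trait mean table and a
    per-trait report of kept/dropped record counts.

    ``raw`` columns: species, trait, value, error_risk (error_risk optional).
    """
    raw = pd.DataFrame(raw)
    needed = {"species", "trait", "value"}
    if not needed.issubset(raw.columns):
        raise ValueError(f"raw records need columns {sorted(needed)}")
    for trait, (lo, hi) in limits.items():
        if lo > hi:
            raise ValueError(f"limits for {trait!r}: min {lo} > max {hi}")
    records = raw.copy()
    if "error_risk" not in records.columns:
        records["error_risk"] = 0.0
    risk_drop = records["error_risk"].fillna(0) >= error_risk_max
    lo = records["trait"].map(lambda t: limits.get(t, (-np.inf, np.inf))[0])
    hi = records["trait"].map(lambda t: limits.get(t, (-np.inf, np.inf))[1])
    limit_drop = (~risk_drop) & ((records["value"] < lo) | (records["value"] > hi))
    kept = records[~risk_drop & ~limit_drop]
    report = (
        pd.DataFrame(
            {
                "trait": records["trait"],
                "dropped_error_risk": risk_drop.astype(int),
                "dropped_limits": limit_drop.astype(int),
                "kept": (~risk_drop & ~limit_drop).astype(int),
            }
        )
        .groupby("trait")
        .sum()
        .reset_index()
    )
    means = kept.pivot_table(index="species", columns="trait", values="value", aggfunc="mean")
    means.columns.name = None
    return TraitTable(means), report


def taxonomic_shrinkage_imputer(
    frame: pd.DataFrame, taxonomy: Taxonomy, rng: np.random.Generator
) -> pd.DataFrame:
    """One stochastic taxonomic-shrinkage imputation of a trait table.

    A missing cell gets the genus mean when >= 2 congeneric observations
    exist, else the family mean, else the trait grand mean — plus Gaussian
    noise with the trait's pooled within-genus residual standard deviation,
    so repeated runs differ and an across-run coefficient of variation is
    meaningful.
    """
    tax = taxonomy.table.loc[frame.index]
    genus = tax["genus"]
    family = tax["family"]
    out = frame.copy()
    for trait in frame.columns:
        col = frame[trait]
        obs = col.dropna()
        if obs.empty:
            raise ValueError(f"trait {trait!r} has zero observed values")
        g_mean = obs.groupby(genus.loc[obs.index]).mean()
        g_count = obs.groupby(genus.loc[obs.index]).size()
        f_mean = obs.groupby(family.loc[obs.index]).mean()
        grand = obs.mean()
        # pooled within-genus residual sd (fallback: overall sd)
        resid = obs - genus.loc[obs.index].map(g_mean)
        n_groups = (g_count >= 1).sum()
        dof = len(obs) - n_groups
        sd = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else float(obs.std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            sd = max(float(obs.std(ddof=1)), 1e-9)
        miss = col.index[col.isna()]
        if not len(miss):
            continue
        fills = pd.Series(index=miss, dtype=float)
        g_ok = g_count[g_count >= 2].index
        use_genus = genus.loc[miss].isin(g_ok)
        fills[use_genus] = genus.loc[miss[use_genus]].map(g_mean).to_numpy()
        rest = miss[~use_genus]
        fam_fill = family.loc[rest].map(f_mean)
        fills[rest] = fam_fill.fillna(grand).to_numpy()
        out.loc[miss, trait] = fills + rng.normal(0.0, sd, size=len(miss))
    return out


def _chained_equations(
    frame: pd.DataFrame,
    missing_mask: pd.DataFrame,
    rng: np.random.Generator,
    n_sweeps: int = 5,
) -> pd.DataFrame:
    """One stochastic-regression chained-equations imputation run."""
    work = frame.copy()
    traits = list(frame.columns)
    # initialize missing cells by sampling observed values of the same trait
    for trait in traits:
        miss = missing_mask[trait]
        if miss.any():
            obs = frame.loc[~miss, trait].to_numpy()
            work.loc[miss, trait] = rng.choice(obs, size=int(miss.sum()), replace=True)
    if len(traits) == 1:
        return work
    for _ in range(n_sweeps):
        for trait in traits:
            miss = missing_mask[trait]
            if not miss.any():
                continue
            others = [t for t in traits if t != trait]
            X = work[others].to_numpy()
            X = np.column_stack([np.ones(len(X)), X])
            y = work[trait].to_numpy()
            fit_rows = (~miss).to_numpy()
            beta, *_ = np.linalg.lstsq(X[fit_rows], y[fit_rows], rcond=None)
            resid = y[fit_rows] - X[fit_rows] @ beta
            dof = max(fit_rows.sum() - len(beta), 1)
            sd = float(np.sqrt((resid**2).sum() / dof))
            pred = X[miss.to_numpy()] @ beta
            work.loc[miss, trait] = pred + rng.normal(0.0, sd, size=len(pred))
    return work


def gapfill_two_step(
    traits: TraitTable,
    taxonomy: Taxonomy,
    n_runs: int = 90,
    cv_max: float = 1.0,
    extreme_factor: float = 1.5,
    n_chain_iters: int = 5,
    seed=None,
    imputer=None,
) -> tuple[TraitTable, pd.DataFrame]:
    """Two-step gap-filling with extreme-value and uncertainty filters.

    Step 1 repeats a pluggable stochastic imputer ``n_runs`` times (default:
    :func:`taxonomic_shrinkage_imputer`). Per missing cell, across the runs:
    if any run's value exceeds ``extreme_factor`` x the maximum observed value
    of that trait (strictly), or the across-run coefficient of variation
    exceeds ``cv_max`` (strictly), the cell is set back to missing; otherwise
    it is filled with the across-run mean. Step 2 fills the remaining cells
    with ``n_chain_iters`` independent chained-equations imputations
    (stochastic per-trait linear regression on all other traits, 5 sweeps
    each), averaged. Observed cells are never altered; the output is complete.

    Returns the complete table and a species x trait provenance frame with
    values in {"observed", "imputed_step1", "imputed_step2"}.
    """
    table = traits if isinstance(traits, TraitTable) else TraitTable(traits)
    frame = table.data.copy()
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 (the CV filter needs repeats)")
    all_missing = frame.columns[frame.notna().sum() == 0].tolist()
    if all_missing:
        raise ValueError(f"trait(s) with zero observed values: {all_missing}")
    taxonomy.require_covers(frame.index)
    impute = imputer if imputer is not None else taxonomic_shrinkage_imputer
    provenance = pd.DataFrame("observed", index=frame.index, columns=frame.columns)
    missing = frame.isna()
    if not missing.any().any():
        return table.copy(), provenance
    rng = np.random.default_rng(seed)
    cells = np.argwhere(missing.to_numpy())
    draws = np.empty((len(cells), n_runs))
    for r in range(n_runs):
        filled = impute(frame, taxonomy, rng)
        draws[:, r] = filled.to_numpy()[cells[:, 0], cells[:, 1]]
    max_obs = frame.max()  # per-trait max over observed values
    cell_max = max_obs.to_numpy()[cells[:, 1]]
    extreme = (draws > extreme_factor * cell_max[:, None]).any(axis=1)
    means = draws.mean(axis=1)
    sds = draws.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means != 0, sds / np.abs(means), np.where(sds > 0, np.inf, 0.0))
    rejected = extreme | (cv > cv_max)
    out = frame.copy()
    vals = out.to_numpy()
    keep = ~rejected
    vals[cells[keep, 0], cells[keep, 1]] = means[keep]
    out = pd.DataFrame(vals, index=frame.index, columns=frame.columns)
    prov = provenance.to_numpy(dtype=object)
    prov[cells[keep, 0], cells[keep, 1]] = "imputed_step1"
    still_missing = out.isna()
    if still_missing.any().any():
        runs = [
            _chained_equations(out, still_missing, rng) for _ in range(n_chain_iters)
        ]
        stacked = np.stack([r.to_numpy() for r in runs])
        chained_mean = stacked.mean(axis=0)
        vals = out.to_numpy()
        mm = still_missing.to_numpy()
        vals[mm] = chained_mean[mm]
        out = pd.DataFrame(vals, index=frame.index, columns=frame.columns)
        prov[mm] = "imputed_step2"
    result = TraitTable(out, dict(table.units), dict(table.transforms))
    result.require_complete()
    provenance = pd.DataFrame(prov, index=frame.index, columns=frame.columns)
    return result, provenance


def genus_fallback(
    traits: TraitTable, taxonomy: Taxonomy, target_species: list
) -> tuple[TraitTable, pd.DataFrame]:
    """Extend a trait table to target species using genus-level means.

    Species already in the table keep their values (provenance "species");
    absent species receive per-trait genus means over congeners present in
    the table (provenance "genus"). Raises, listing species, when a target has
    no congeneric data at all.
    """
    table = traits if isinstance(traits, TraitTable) else TraitTable(traits)
    frame = table.data
    taxonomy.require_covers(list(frame.index) + list(target_species))
    genus = taxonomy.table["genus"]
    genus_means = frame.groupby(genus.loc[frame.index]).mean()
    new_species = [s for s in target_species if s not in frame.index]
    orphans = [s for s in new_species if genus.loc[s] not in genus_means.index]
    if orphans:
        raise ValueError(f"no congeneric trait data for species: {orphans[:10]}")
    fills = genus_means.loc[genus.loc[new_species]].set_axis(pd.Index(new_species))
    out = pd.concat([frame, fills])
    provenance = pd.DataFrame("species", index=out.index, columns=out.columns)
    provenance.loc[new_species, :] = "genus"
    return TraitTable(out, dict(table.units), dict(table.transforms)), provenance


def transform_traits(traits: TraitTable, log10_traits: list[str]) -> TraitTable:
    """log10-transform the listed traits (which must be strictly positive)."""
    table = traits if isinstance(traits, TraitTable) else TraitTable(traits)
    out = table.copy()
    for trait in log10_traits:
        if trait not in out.data.columns:
            raise KeyError(f"trait {trait!r} not in table")
        col = out.data[trait]
        bad = col[col <= 0]
        if len(bad):
            cell = (bad.index[0], trait)
            raise ValueError(f"nonpositive value {bad.iloc[0]!r} at {cell}; cannot log10")
        out.data[trait] = np.log10(col)
        out.transforms[trait] = "log10"
    return out
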