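"""Axes of metabolic specialization and their relation to classical traits.

Varimax-rotated PCAs summarize species-level trait variation: a 2-axis PCA of
the five metabolic traits gives the axes of leaf metabolic specialization; a
joint PCA of metabolic plus classical traits (13 by default, 4 retained axes)
tests whether those axes are orthogonal to, or colinear with, classical
life-history axes. Each retained axis is anchored back to individual traits
by Pearson correlation, and a per-axis purity index quantifies how exclusively
an axis belongs to one trait block.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .chemspace import ClusterResult, cluster_properties, corr_matrix
from .pca import RotatedPCAResults, fit_rotated_pca
from .traits import TraitTable, _trait_frame

__all__ = [
    "metabolic_axes",
    "combined_axes",
    "axis_anchor",
    "orthogonality_index",
    "trait_clustering",
]


def metabolic_axes(metabolic, n_axes: int = 2, rotate: bool = True) -> RotatedPCAResults:
    """Varimax-rotated PCA of the metabolic functional traits."""
    frame = _trait_frame(metabolic)
    if frame.isna().any().any():
        raise ValueError("metabolic trait table must be complete")
    return fit_rotated_pca(frame, n_axes=n_axes, rotate=rotate)


def axis_anchor(scores: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation (and p) between each trait and each axis score.

    Long format: one row per (trait, axis).
    """
    rows = []
    for trait in traits.columns:
        x = traits[trait].to_numpy(dtype=float)
        for axis in scores.columns:
            r, p = stats.pearsonr(x, scores[axis].to_numpy())
            rows.append({"trait": trait, "axis": axis, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def combined_axes(
    metabolic, classical, n_axes: int = 4, rotate: bool = True
) -> tuple[RotatedPCAResults, pd.DataFrame]:
    """Joint varimax-rotated PCA of metabolic + classical traits with anchoring.

    Both tables must cover the same species. Returns the fitted PCA and the
    trait x axis anchor table (one row per trait per retained axis).
    """
    met = _trait_frame(metabolic)
    cls = _trait_frame(classical)
    if met.isna().any().any() or cls.isna().any().any():
        raise ValueError("both trait tables must be complete")
    only_met = met.index.difference(cls.index).tolist()
    only_cls = cls.index.difference(met.index).tolist()
    if only_met or only_cls:
        raise ValueError(
            f"species mismatch: only in metabolic {only_met[:5]}, only in classical {only_cls[:5]}"
        )
    overlap = met.columns.intersection(cls.columns)
    if len(overlap):
        raise ValueError(f"duplicate trait names across blocks: {list(overlap)}")
    joint = pd.concat([met, cls.loc[met.index]], axis=1)
    res = fit_rotated_pca(joint, n_axes=n_axes, rotate=rotate)
    anchor = axis_anchor(res.scores, joint)
    return res, anchor


def orthogonality_index(anchor: pd.DataFrame, block_labels: dict) -> pd.DataFrame:
    """Per-axis block purity of the trait anchoring.

    For each axis, purity = (sum of r^2 over the dominant block) / (sum of
    r^2 over all traits); 1.0 means the axis correlates with one block only.
    Purity is invariant to axis sign flips (it uses r^2).
    """
    anchor = pd.DataFrame(anchor)
    missing = [t for t in anchor["trait"].unique() if t not in block_labels]
    if missing:
        raise KeyError(f"traits without block label: {missing}")
    work = anchor.assign(
        block=anchor["trait"].map(block_labels), r2=anchor["r"] ** 2
    )
    rows = []
    for axis, grp in work.groupby("axis", sort=False):
        by_block = grp.groupby("block")["r2"].sum()
        total = by_block.sum()
        dominant = by_block.idxmax()
        rows.append(
            {
                "axis": axis,
                "dominant_block": dominant,
                "purity": float(by_block.max() / total) if total > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def trait_clustering(
    traits, k_range: tuple[int, int] = (2, 8), distance_rule: str = "one_minus_r"
) -> ClusterResult:
    """Ward clustering of the trait correlation matrix with silhouette K."""
    frame = _trait_frame(traits)
    corr = corr_matrix(frame)
    return cluster_properties(corr, k_range=k_range, distance_rule=distance_rule)
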