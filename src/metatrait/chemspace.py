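"""Structure of metabolite chemical space.

A metabolite chemistry table (one row per annotated metabolite, one column
per numeric chemical property such as molecular weight or H-bond acceptor
count) is analysed in four steps: pairwise Pearson correlations between
properties, Ward clustering of the correlation structure with the cluster
count chosen by maximal mean silhouette width, selection of one
representative property per cluster, and a varimax-rotated PCA on the
representative subset. Whether the subset PCA is equivalent to a PCA on the
full property set is tested with score correlations and a Procrustes
rotation test, optionally over every subset combination that covers all
clusters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .pca import RotatedPCAResults, fit_rotated_pca

__all__ = [
    "PropertyTable",
    "ClusterResult",
    "ProcrustesResult",
    "DEFAULT_SUBSET",
    "corr_matrix",
    "cluster_properties",
    "select_subset",
    "procrustes_test",
    "equivalence_scan",
    "fit_rotated_pca",
]

#: The five canonical representative properties, one per cluster of leaf
#: metabolite chemistry: size/complexity, polar intermolecular forces,
#: bond conjugation/reactivity, lipophilicity, carbon-bond saturation.
DEFAULT_SUBSET = (
    "molecular_weight",
    "h_bond_acceptor_count",
    "aromatic_atom_count",
    "xlogp",
    "c_hybridization_ratio",
)


@dataclass
class PropertyTable:
    """Metabolite x chemical-property matrix with optional metadata.

    Parameters
    ----------
    data : DataFrame
        Numeric property values, indexed by metabolite id.
    smiles : Series, optional
        SMILES string per metabolite (may be empty).
    family : Series, optional
        Chemical-family label per metabolite.
    clusters : Series, optional
        Ground-truth property-cluster label per property column (synthetic
        tables only; used by recovery tests).
    """

    data: pd.DataFrame
    smiles: pd.Series | None = None
    family: pd.Series | None = None
    clusters: pd.Series | None = None

    def __post_init__(self):
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate metabolite ids: {dup[:5]}")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing property values in column(s): {bad}")
        nunique = self.data.nunique()
        flat = nunique[nunique <= 1].index.tolist()
        if flat:
            raise ValueError(f"property column(s) with <= 1 distinct value: {flat}")

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.data.index

    @property
    def property_names(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, PropertyTable):
        return table.data
    return pd.DataFrame(table)


def corr_matrix(table, variables: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix between columns.

    Raises if fewer than 3 rows or if any requested column has zero variance.
    """
    frame = _as_frame(table)
    if variables is not None:
        missing = [v for v in variables if v not in frame.columns]
        if missing:
            raise KeyError(f"variables not in table: {missing}")
        frame = frame[list(variables)]
    if len(frame) < 3:
        raise ValueError("need at least 3 observations for correlations")
    sd = frame.std(ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance column(s): {flat}")
    corr = frame.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class ClusterResult:
    """Ward clustering of variables with silhouette-selected K.

    ``labels`` maps every variable to a cluster id in 1..K; ``merge_tree`` is
    the scipy linkage matrix; ``silhouette_by_K`` has one row per scanned K.
    """

    labels: pd.Series
    K: int
    silhouette_by_K: pd.DataFrame
    merge_tree: np.ndarray
    distance_rule: str = "one_minus_r"

    def members(self, cluster_id: int) -> list[str]:
        return self.labels.index[self.labels == cluster_id].tolist()

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(self.labels.unique())


def cluster_properties(
    corr: pd.DataFrame,
    k_range: tuple[int, int] = (2, 8),
    distance_rule: str = "one_minus_r",
) -> ClusterResult:
    """Ward-cluster variables on a correlation-derived distance.

    The distance is ``1 - r`` (``one_minus_r``; anticorrelated variables are
    far apart) or ``1 - |r|`` (``one_minus_abs_r``; any strong relationship,
    signed or not, is close). For each K in the inclusive ``k_range`` the tree
    is cut and the mean silhouette width computed on the same distance; the K
    with maximal mean silhouette wins, ties broken toward smaller K.
    """
    corr = pd.DataFrame(corr)
    n = corr.shape[0]
    if corr.shape[0] != corr.shape[1]:
        raise ValueError("corr must be square")
    lo, hi = int(k_range[0]), int(k_range[1])
    if lo < 2 or hi > n - 1 or lo > hi:
        raise ValueError(f"k_range {k_range} must lie within [2, {n - 1}]")
    if distance_rule == "one_minus_r":
        dist = 1.0 - corr.to_numpy()
    elif distance_rule == "one_minus_abs_r":
        dist = 1.0 - np.abs(corr.to_numpy())
    else:
        raise ValueError(f"unknown distance_rule: {distance_rule!r}")
    dist = np.clip(dist, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0]):
        raise ValueError("no cluster structure: all pairwise distances identical")
    tree = linkage(condensed, method="ward")
    rows = []
    labels_by_k = {}
    for k in range(lo, hi + 1):
        labels = fcluster(tree, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            rows.append({"K": k, "mean_silhouette": np.nan})
            continue
        sil = silhouette_score(dist, labels, metric="precomputed")
        labels_by_k[k] = labels
        rows.append({"K": k, "mean_silhouette": float(sil)})
    table = pd.DataFrame(rows)
    if table["mean_silhouette"].isna().all():
        raise ValueError("no cluster structure: silhouette undefined for all K")
    best = int(table.loc[table["mean_silhouette"].idxmax(), "K"])  # idxmax -> first max = smaller K
    return ClusterResult(
        labels=pd.Series(labels_by_k[best], index=corr.index, name="cluster"),
        K=best,
        silhouette_by_K=table,
        merge_tree=tree,
        distance_rule=distance_rule,
    )


def select_subset(cluster_result: ClusterResult, choice="default") -> list[str]:
    """Validate a choice of exactly one representative variable per cluster.

    ``choice`` may be ``"default"`` (the five canonical property names, which
    must all exist in the clustered table), or an explicit list of names.
    """
    labels = cluster_result.labels
    if isinstance(choice, str) and choice == "default":
        missing = [p for p in DEFAULT_SUBSET if p not in labels.index]
        if missing:
            raise KeyError(f"default subset properties missing from table: {missing}")
        chosen = list(DEFAULT_SUBSET)
    else:
        chosen = list(choice)
        missing = [p for p in chosen if p not in labels.index]
        if missing:
            raise KeyError(f"chosen properties missing from table: {missing}")
    seen: dict[int, str] = {}
    for name in chosen:
        cid = int(labels[name])
        if cid in seen:
            raise ValueError(
                f"properties {seen[cid]!r} and {name!r} both come from cluster {cid}"
            )
        seen[cid] = name
    uncovered = sorted(set(cluster_result.cluster_ids) - set(seen))
    if uncovered:
        raise ValueError(f"cluster(s) {uncovered} not covered by the choice")
    return chosen


@dataclass
class ProcrustesResult:
    """Symmetric Procrustes comparison of two point configurations.

    ``m12`` is the residual statistic in [0, 1] with 0 = identical shapes
    (m12^2 = 1 - (sum of singular values)^2 after both configurations are
    centered and scaled to unit total sum of squares); ``r2 = 1 - m12^2``.
    ``p_value`` is the permutation probability of an equally close or closer
    association under random row permutation.
    """

    m12: float
    r2: float
    p_value: float
    n_perm: int

    def summary(self) -> str:
        return (
            f"Procrustes rotation test ({self.n_perm} permutations)\n"
            f"  m12 = {self.m12:.4f}, r2 = {self.r2:.4f}, P = {self.p_value:.4g}"
        )


def _procrustes_m12(a: np.ndarray, b: np.ndarray) -> float:
    # m12^2 = 1 - (sum of singular values)^2, but evaluated as the residual
    # sum of squares of the optimally rotated and scaled configurations —
    # algebraically identical and numerically exact when the shapes coincide
    u, sv, vt = np.linalg.svd(a.T @ b)
    rot = vt.T @ u.T  # optimal rotation taking b onto a
    scale = sv.sum()
    resid = a - scale * (b @ rot)
    return float(np.sqrt((resid**2).sum()))


def _center_scale(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    x = x - x.mean(axis=0)
    norm = np.linalg.norm(x)
    if norm == 0:
        raise ValueError("configuration with zero total sum of squares")
    return x / norm


def procrustes_test(
    scores_a, scores_b, n_perm: int = 999, seed=None
) -> ProcrustesResult:
    """Procrustes rotation test between two configurations with shared rows.

    Both configurations are column-centered and scaled to unit total sum of
    squares; the optimal orthogonal rotation comes from the SVD of the
    cross-product. The permutation null permutes the rows of the second
    configuration; smaller m12 means closer association, so
    ``p = (#{m12_perm <= m12_obs} + 1) / (n_perm + 1)``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"row-count mismatch: {a.shape[0]} vs {b.shape[0]}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    za, zb = _center_scale(a), _center_scale(b)
    m12 = _procrustes_m12(za, zb)
    rng = np.random.default_rng(seed)
    n = za.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        # re-center after permutation is a no-op (rows reordered), scale unchanged
        if _procrustes_m12(za, zb[perm]) <= m12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return ProcrustesResult(m12=m12, r2=1.0 - m12**2, p_value=p, n_perm=n_perm)


def _match_axes(scores_full: np.ndarray, scores_sub: np.ndarray) -> list[float]:
    """Greedy matching of subset axes to full axes by max |Pearson r|."""
    k = scores_full.shape[1]
    r = np.corrcoef(scores_full, scores_sub, rowvar=False)[:k, k:]
    r = np.abs(r)
    out = [np.nan] * k
    free_full = set(range(k))
    free_sub = set(range(scores_sub.shape[1]))
    while free_full and free_sub:
        i, j = max(
            ((i, j) for i in free_full for j in free_sub), key=lambda ij: r[ij[0], ij[1]]
        )
        out[i] = float(r[i, j])
        free_full.discard(i)
        free_sub.discard(j)
    return out


def equivalence_scan(
    table,
    cluster_result: ClusterResult,
    n_axes: int = 3,
    n_perm: int = 999,
    seed=None,
    max_combinations: int = 5000,
) -> pd.DataFrame:
    """Compare the full-table PCA with every cluster-covering subset PCA.

    Enumerates the Cartesian product of cluster memberships (one property per
    cluster), fits a varimax-rotated PCA per combination, and reports per-axis
    |score correlation| against the greedily matched full-PCA axes plus the
    Procrustes m12 and permutation p on the first ``n_axes`` scores.
    """
    frame = _as_frame(table)
    clusters = [cluster_result.members(c) for c in cluster_result.cluster_ids]
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters to scan combinations")
    n_comb = int(np.prod([len(c) for c in clusters]))
    if n_comb > max_combinations:
        raise ValueError(
            f"{n_comb} combinations exceed cap {max_combinations}; "
            "raise max_combinations or sample combinations instead"
        )
    full = fit_rotated_pca(frame[cluster_result.labels.index], n_axes=n_axes)
    full_scores = full.scores.to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for combo in itertools.product(*clusters):
        sub = fit_rotated_pca(frame[list(combo)], n_axes=min(n_axes, len(combo)))
        sub_scores = sub.scores.to_numpy()
        rs = _match_axes(full_scores, sub_scores)
        pro = procrustes_test(
            full_scores, sub_scores, n_perm=n_perm, seed=rng.integers(2**31)
        )
        row = {"combination": "+".join(combo)}
        row.update({f"abs_r_axis{i + 1}": rs[i] for i in range(n_axes)})
        row["m12"] = pro.m12
        row["p_value"] = pro.p_value
        rows.append(row)
    return pd.DataFrame(rows)
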