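"""Synthetic study generator.

Emulates the statistical structure the downstream analysis assumes, so every
stage is testable without any external download:

* a metabolite x chemical-property table whose 21 properties fall into 5
  correlated clusters (each property = cluster latent factor x loading +
  noise), mirroring the five facets of leaf metabolite chemistry
  (size/complexity, conjugation/reactivity, polar forces, lipophilicity,
  carbon saturation);
* species metabolomes (presence/absence) whose composition varies along a
  small number of latent species axes: a metabolite's inclusion log-odds in
  a species is the species' latent position dotted with the metabolite's
  position on the leading principal axes of chemical space;
* classical trait tables with block covariance, genus/family structure,
  missing values, and (optionally) injected outliers, to exercise the
  cleaning and gap-filling rules.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .chemspace import PropertyTable
from .traits import Taxonomy, TraitTable

__all__ = [
    "ClusterSpec",
    "AxisSpec",
    "ClassicalSpec",
    "SyntheticConfig",
    "StudyBundle",
    "gen_property_table",
    "gen_metabolomes",
    "gen_classical_traits",
    "gen_study",
    "default_classical_cov",
]

# Property names per cluster: the first entry of each cluster is the canonical
# representative used by the default subset.
_CLUSTER_PROPERTY_NAMES = (
    (
        "molecular_weight",
        "atom_count",
        "bond_count",
        "mlogp",
        "wiener_index",
        "eccentric_connectivity",
        "heavy_atom_count",
        "ring_count",
    ),
    (
        "aromatic_atom_count",
        "aromatic_bond_count",
        "pi_system_size",
        "fmf_complexity",
        "conjugated_fraction",
    ),
    (
        "h_bond_acceptor_count",
        "h_bond_donor_count",
        "polar_surface_area",
        "relative_psa",
    ),
    ("xlogp", "alogp"),
    ("c_hybridization_ratio", "sp3_fraction"),
)


@dataclass
class ClusterSpec:
    """Planted cluster structure of the chemical-property table."""

    n_clusters: int = 5
    props_per_cluster: tuple = (8, 5, 4, 2, 2)
    within_loading: float = 0.9
    noise_sd: float = 0.3

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if len(self.props_per_cluster) != self.n_clusters:
            raise ValueError("props_per_cluster must have n_clusters entries")
        if not 0 <= self.within_loading <= 1:
            raise ValueError("within_loading must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.within_loading == 0 and self.noise_sd == 0:
            raise ValueError("degenerate property: loading and noise both zero")

    @property
    def n_properties(self) -> int:
        return int(sum(self.props_per_cluster))


@dataclass
class AxisSpec:
    """Planted latent axes of species metabolome composition."""

    n_axes: int = 2
    species_sd: float = 1.0
    slope: float = 1.5
    baseline_logit: float = -2.0

    def __post_init__(self):
        if self.n_axes < 1:
            raise ValueError("n_axes must be >= 1")
        if self.species_sd < 0:
            raise ValueError("species_sd must be >= 0")


def _property_names(spec: ClusterSpec) -> tuple[list[str], list[int]]:
    names, clusters = [], []
    for c, size in enumerate(spec.props_per_cluster):
        canonical = _CLUSTER_PROPERTY_NAMES[c] if c < len(_CLUSTER_PROPERTY_NAMES) else ()
        for j in range(size):
            if j < len(canonical):
                names.append(canonical[j])
            else:
                names.append(f"prop_c{c + 1}_{j + 1}")
            clusters.append(c + 1)
    return names, clusters


def gen_property_table(n_metabolites: int, spec: ClusterSpec | None = None, seed=None) -> PropertyTable:
    """Generate a metabolite x property table with planted property clusters.

    Property p in cluster c is ``within_loading * F_c + noise_sd * eps`` with
    F_c a per-metabolite standard-normal cluster factor and eps independent
    standard normal. Ground-truth cluster labels ride along on the table.
    """
    spec = spec or ClusterSpec()
    if n_metabolites < 10 * spec.n_properties:
        raise ValueError(
            f"n_metabolites must be >= 10 x n_properties = {10 * spec.n_properties}"
        )
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n_metabolites, spec.n_clusters))
    names, clusters = _property_names(spec)
    cols = np.empty((n_metabolites, spec.n_properties))
    for j, c in enumerate(clusters):
        cols[:, j] = spec.within_loading * factors[:, c - 1] + spec.noise_sd * rng.standard_normal(
            n_metabolites
        )
    ids = pd.Index([f"met{i + 1:05d}" for i in range(n_metabolites)], name="metabolite_id")
    data = pd.DataFrame(cols, index=ids, columns=names)
    smiles = pd.Series("", index=ids, name="smiles")
    return PropertyTable(
        data=data,
        smiles=smiles,
        clusters=pd.Series(clusters, index=names, name="cluster"),
    )


def gen_metabolomes(
    property_table: PropertyTable,
    n_species: int = 300,
    spec: AxisSpec | None = None,
    seed=None,
    max_redraws: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate species metabolomes structured along latent species axes.

    Metabolite j gets a chemistry score z_j: its coordinates on the first
    ``n_axes`` principal axes of the standardized property table, each axis
    re-standardized to unit variance. Species i draws a latent position
    u_i ~ N(0, species_sd^2 I); metabolite j is present with probability
    ``logistic(baseline_logit + slope * <u_i, z_j>)``. Species drawn with an
    empty metabolome are redrawn so n_species is exact. Returns the binary
    presence matrix and the ground-truth latent positions.
    """
    spec = spec or AxisSpec()
    frame = property_table.data if isinstance(property_table, PropertyTable) else pd.DataFrame(property_table)
    if frame.shape[1] < 2:
        raise ValueError("property table needs at least 2 properties")
    rng = np.random.default_rng(seed)
    Z = ((frame - frame.mean()) / frame.std(ddof=1)).to_numpy()
    # principal axes of chemical space via SVD of the standardized table
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    z = Z @ vt[: spec.n_axes].T
    z = z / z.std(axis=0, ddof=1)
    n_met = z.shape[0]
    species_ids = pd.Index([f"sp{i + 1:04d}" for i in range(n_species)], name="species_id")
    presence = np.zeros((n_species, n_met), dtype=np.int8)
    latent = np.zeros((n_species, spec.n_axes))
    for i in range(n_species):
        for attempt in range(max_redraws + 1):
            u = rng.normal(0.0, spec.species_sd, size=spec.n_axes)
            prob = expit(spec.baseline_logit + spec.slope * (z @ u))
            if prob.max() < 1e-12:
                raise ValueError(
                    "impossible prevalence: inclusion probabilities are numerically zero"
                )
            row = (rng.random(n_met) < prob).astype(np.int8)
            if row.sum() >= 1:
                presence[i] = row
                latent[i] = u
                break
        else:
            raise ValueError(
                f"could not draw a non-empty metabolome for species {i} "
                f"after {max_redraws} redraws; raise baseline_logit"
            )
    presence_df = pd.DataFrame(presence, index=species_ids, columns=frame.index)
    latent_df = pd.DataFrame(
        latent, index=species_ids, columns=[f"axis{a + 1}" for a in range(spec.n_axes)]
    )
    return presence_df, latent_df


DEFAULT_CLASSICAL_TRAITS = (
    "plant_height",
    "seed_mass",
    "leaf_area",
    "stem_density",
    "sla",
    "leaf_n",
    "leaf_p",
    "leaf_c",
)

DEFAULT_CLASSICAL_UNITS = {
    "plant_height": "m",
    "seed_mass": "mg",
    "leaf_area": "mm^2",
    "stem_density": "mg mm^-3",
    "sla": "mm^2 mg^-1",
    "leaf_n": "mg g^-1",
    "leaf_p": "mg g^-1",
    "leaf_c": "mg g^-1",
}


def default_classical_cov(
    n_traits: int = 8, block_sizes=(4, 4), within_r: float = 0.7
) -> np.ndarray:
    """Block covariance: unit variances, ``within_r`` within blocks, 0 across."""
    if sum(block_sizes) != n_traits:
        raise ValueError("block sizes must sum to n_traits")
    cov = np.zeros((n_traits, n_traits))
    start = 0
    for size in block_sizes:
        cov[start : start + size, start : start + size] = within_r
        start += size
    np.fill_diagonal(cov, 1.0)
    return cov


@dataclass
class ClassicalSpec:
    """Settings for the classical-trait generator (defaults: two 4-trait blocks)."""

    n_traits: int = 8
    cov: np.ndarray | None = None
    means: np.ndarray | None = None
    trait_names: tuple = DEFAULT_CLASSICAL_TRAITS
    n_genera: int = 50
    species_per_genus: int = 6
    genera_per_family: int = 5
    missing_frac: float = 0.2
    outlier_frac: float = 0.0
    genus_share: float = 0.5


def gen_classical_traits(
    n_species: int,
    cov: np.ndarray | None = None,
    taxonomy_spec: tuple[int, int] | None = None,
    missing_frac: float = 0.2,
    outlier_frac: float = 0.0,
    seed=None,
    means: np.ndarray | None = None,
    trait_names=None,
    genus_share: float = 0.5,
    genera_per_family: int = 5,
) -> tuple[TraitTable, Taxonomy]:
    """Generate classical traits with taxonomic structure, gaps, and outliers.

    Species values are genus effect + species effect, multivariate normal
    with covariances ``genus_share * cov`` and ``(1 - genus_share) * cov``, so
    the marginal trait covariance matches ``cov`` while congeners resemble
    each other. A ``missing_frac`` of entries is masked completely at random;
    an ``outlier_frac`` of the remaining observed entries is replaced by
    values above 1.5x the column maximum (to exercise outlier filters).
    """
    cov = default_classical_cov() if cov is None else np.asarray(cov, dtype=float)
    d = cov.shape[0]
    if cov.shape != (d, d) or not np.allclose(cov, cov.T):
        raise ValueError("cov must be square symmetric")
    evals = np.linalg.eigvalsh(cov)
    if evals.min() < -1e-10 * max(1.0, evals.max()):
        raise ValueError("cov is not positive semi-definite")
    if not (0 <= missing_frac < 1 and 0 <= outlier_frac < 1):
        raise ValueError("missing_frac and outlier_frac must be in [0, 1)")
    if taxonomy_spec is None:
        n_genera = max(1, int(np.ceil(n_species / 6)))
        taxonomy_spec = (n_genera, 6)
    n_genera, per_genus = taxonomy_spec
    if n_genera * per_genus < n_species:
        raise ValueError("taxonomy_spec too small for n_species")
    if trait_names is None:
        trait_names = (
            DEFAULT_CLASSICAL_TRAITS if d == len(DEFAULT_CLASSICAL_TRAITS) else tuple(f"trait{i + 1}" for i in range(d))
        )
    if means is None:
        means = np.full(d, 10.0)
    means = np.asarray(means, dtype=float)
    rng = np.random.default_rng(seed)
    # jitter the PSD covariance only through its eigen square root (exact for PSD)
    w, V = np.linalg.eigh(cov)
    root = V @ np.diag(np.sqrt(np.clip(w, 0, None))) @ V.T
    species_ids = pd.Index([f"sp{i + 1:04d}" for i in range(n_species)], name="species_id")
    genus_idx = np.arange(n_species) // per_genus
    genus_names = np.array([f"genus{g + 1:03d}" for g in range(n_genera)])
    family_names = np.array(
        [f"family{(g // genera_per_family) + 1:02d}" for g in range(n_genera)]
    )
    tax = Taxonomy(
        pd.DataFrame(
            {"genus": genus_names[genus_idx], "family": family_names[genus_idx]},
            index=species_ids,
        )
    )
    g_eff = rng.standard_normal((n_genera, d)) @ (np.sqrt(genus_share) * root).T
    s_eff = rng.standard_normal((n_species, d)) @ (np.sqrt(1.0 - genus_share) * root).T
    values = means + g_eff[genus_idx] + s_eff
    data = pd.DataFrame(values, index=species_ids, columns=list(trait_names))
    if missing_frac > 0:
        mask = rng.random(values.shape) < missing_frac
        # keep at least one observation per trait
        for j in range(d):
            if mask[:, j].all():
                mask[rng.integers(n_species), j] = False
        data = data.mask(mask)
    if outlier_frac > 0:
        observed = np.argwhere(data.notna().to_numpy())
        n_out = int(round(outlier_frac * len(observed)))
        if n_out:
            pick = observed[rng.choice(len(observed), size=n_out, replace=False)]
            col_max = data.max().to_numpy()
            vals = data.to_numpy()
            factors = rng.uniform(1.6, 3.0, size=n_out)
            vals[pick[:, 0], pick[:, 1]] = factors * col_max[pick[:, 1]]
            data = pd.DataFrame(vals, index=data.index, columns=data.columns)
    units = {t: DEFAULT_CLASSICAL_UNITS.get(t, "") for t in trait_names}
    return TraitTable(data, units=units), tax


@dataclass
class SyntheticConfig:
    """Study-scale configuration for :func:`gen_study`."""

    n_metabolites: int = 3000
    n_species: int = 300
    cluster_spec: ClusterSpec = field(default_factory=ClusterSpec)
    axis_spec: AxisSpec = field(default_factory=AxisSpec)
    classical: ClassicalSpec = field(default_factory=ClassicalSpec)


@dataclass
class StudyBundle:
    """A complete synthetic study with its ground truth."""

    property_table: PropertyTable
    presence: pd.DataFrame
    classical: TraitTable
    taxonomy: Taxonomy
    latent_species_axes: pd.DataFrame
    seed: int | None
    config: SyntheticConfig

    def validate(self):
        from .traits import validate_presence

        validate_presence(self.presence)
        if not self.presence.columns.equals(self.property_table.metabolite_ids):
            raise ValueError("presence columns do not match property-table metabolites")
        if not self.presence.index.equals(self.classical.species):
            raise ValueError("presence and classical trait species differ")
        if not self.presence.index.equals(self.latent_species_axes.index):
            raise ValueError("latent axes species differ from presence species")
        self.taxonomy.require_covers(self.presence.index)
        if (self.presence.sum(axis=1) < 1).any():
            raise ValueError("species with empty metabolome in bundle")
        return self

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for frame in (
            self.property_table.data,
            self.presence,
            self.classical.data,
            self.taxonomy.table,
            self.latent_species_axes,
        ):
            h.update(pd.util.hash_pandas_object(frame, index=True).to_numpy().tobytes())
        return h.hexdigest()


def gen_study(config: SyntheticConfig | None = None, seed=None) -> StudyBundle:
    """Compose the three generators into one consistent study bundle."""
    config = config or SyntheticConfig()
    ss = np.random.SeedSequence(seed)
    s_prop, s_met, s_cls = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    prop = gen_property_table(config.n_metabolites, config.cluster_spec, seed=s_prop)
    presence, latent = gen_metabolomes(
        prop, n_species=config.n_species, spec=config.axis_spec, seed=s_met
    )
    c = config.classical
    cov = c.cov if c.cov is not None else default_classical_cov(c.n_traits)
    classical, taxonomy = gen_classical_traits(
        config.n_species,
        cov=cov,
        taxonomy_spec=(c.n_genera, c.species_per_genus),
        missing_frac=c.missing_frac,
        outlier_frac=c.outlier_frac,
        seed=s_cls,
        means=c.means,
        trait_names=c.trait_names,
        genus_share=c.genus_share,
        genera_per_family=c.genera_per_family,
    )
    bundle = StudyBundle(
        property_table=prop,
        presence=presence,
        classical=classical,
        taxonomy=taxonomy,
        latent_species_axes=latent,
        seed=seed,
        config=config,
    )
    return bundle.validate()
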