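"""End-to-end pipeline: chemspace -> traits -> hypervolume -> specialization.

A single YAML config drives the whole run. Every stage writes TSVs into the
run directory and the run ends with a manifest recording the config hash, the
seed, the package version, and per-stage status and wall time. Any stage
error halts the run, leaves partial outputs in place, and drops a FAILED
marker naming the stage.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from ._version import __version__
from .chemspace import cluster_properties, corr_matrix, equivalence_scan, procrustes_test, select_subset
from .hypervolume import LumpinessParams, hypervolume_report
from .pca import fit_rotated_pca
from .specialization import combined_axes, metabolic_axes, orthogonality_index, trait_clustering
from .traits import gapfill_two_step, metabolic_traits, transform_traits, validate_presence

__all__ = ["PipelineConfig", "StageError", "run_all", "validate_inputs"]

_DEFAULTS = {
    "subset": "default",
    "k_range": [2, 8],
    "distance_rule": "one_minus_r",
    "scan": {"enabled": False, "n_axes": 3, "n_perm": 199, "max_combinations": 5000},
    "procrustes": {"n_axes": 3, "n_perm": 999},
    "gapfill": {"n_runs": 90, "cv_max": 1.0, "extreme_factor": 1.5, "n_chain_iters": 5},
    "log10_traits": [],
    "null_models": {"n_sim": 999},
    "lumpiness": {"bins_per_dim": 10, "capture_fraction": 0.10},
    "axes": {"metabolic": 2, "combined": 4},
    "seed": 0,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``_DEFAULTS`` for knobs)."""

    inputs: dict
    output: str
    options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        inputs = raw.pop("inputs", {})
        output = raw.pop("output", "metatrait_run")
        return cls(inputs=inputs, output=output, options=raw).validate()

    def validate(self) -> "PipelineConfig":
        needed = {"properties", "presence", "classical", "taxonomy"}
        missing = needed - set(self.inputs)
        if missing:
            raise ValueError(f"config missing input path(s): {sorted(missing)}")
        absent = [p for p in self.inputs.values() if not Path(p).exists()]
        if absent:
            raise FileNotFoundError(f"input path(s) do not exist: {absent}")
        opts = self.resolved()
        lo, hi = opts["k_range"]
        if not (2 <= lo <= hi):
            raise ValueError(f"invalid k_range {opts['k_range']}")
        gf = opts["gapfill"]
        if gf["n_runs"] < 2 or gf["cv_max"] <= 0 or gf["extreme_factor"] <= 0:
            raise ValueError("gapfill parameters out of range")
        if opts["null_models"]["n_sim"] < 19:
            raise ValueError("null_models.n_sim must be >= 19")
        lp = opts["lumpiness"]
        LumpinessParams(lp["bins_per_dim"], lp["capture_fraction"])
        return self

    def resolved(self) -> dict:
        out = {}
        for key, default in _DEFAULTS.items():
            value = self.options.get(key, default)
            if isinstance(default, dict):
                merged = dict(default)
                merged.update(value or {})
                value = merged
            out[key] = value
        return out

    def content_hash(self) -> str:
        blob = yaml.safe_dump(
            {"inputs": self.inputs, "output": str(self.output), "options": self.options},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()


def validate_inputs(config: PipelineConfig) -> pd.DataFrame:
    """Schema and cross-reference checks; one row per check, never raises."""
    checks = []

    def check(name, fn):
        try:
            detail = fn()
            checks.append({"check": name, "passed": True, "detail": detail or ""})
        except Exception as err:  # noqa: BLE001 - report, don't raise
            checks.append({"check": name, "passed": False, "detail": str(err)})

    tables = {}

    def load(kind, reader):
        def _do():
            tables[kind] = reader(config.inputs[kind])
            return f"{kind} loaded"

        return _do

    check("properties_readable", load("properties", mio.read_property_table))
    check("presence_readable", load("presence", mio.read_presence))
    check("classical_readable", load("classical", mio.read_trait_table))
    check("taxonomy_readable", load("taxonomy", mio.read_taxonomy))

    if "presence" in tables:
        check("presence_binary", lambda: (validate_presence(tables["presence"]), "binary")[1])
        if "properties" in tables:

            def _ids():
                missing = tables["presence"].columns.difference(
                    tables["properties"].metabolite_ids
                )
                if len(missing):
                    raise ValueError(f"metabolites without properties: {list(missing[:5])}")
                return "all presence metabolites have properties"

            check("presence_metabolites_in_properties", _ids)
        if "taxonomy" in tables:

            def _tax():
                missing = tables["presence"].index.difference(tables["taxonomy"].species)
                if len(missing):
                    raise ValueError(f"species missing from taxonomy: {list(missing[:5])}")
                return "taxonomy covers presence species"

            check("presence_species_in_taxonomy", _tax)
        if "classical" in tables:

            def _cls():
                missing = tables["presence"].index.difference(tables["classical"].species)
                if len(missing):
                    raise ValueError(f"species without classical traits: {list(missing[:5])}")
                return "classical table covers presence species"

            check("presence_species_in_classical", _cls)
    return pd.DataFrame(checks)


def run_all(config: PipelineConfig, seed=None) -> Path:
    """Execute every stage; returns the run directory."""
    config.validate()
    opts = config.resolved()
    seed = opts["seed"] if seed is None else seed
    out = Path(config.output)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.content_hash(),
        "seed": int(seed),
        "version": __version__,
        "stages": [],
    }
    ss = np.random.SeedSequence(seed)
    seeds = {
        name: int(c.generate_state(1)[0] % (2**31))
        for name, c in zip(
            ("procrustes", "scan", "gapfill", "hv_metabolic", "hv_classical"), ss.spawn(5)
        )
    }
    state: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as err:
            (out / "FAILED").write_text(f"stage: {name}\nerror: {err}\n")
            manifest["stages"].append({"name": name, "status": "failed"})
            with open(out / "manifest.yaml", "w") as fh:
                yaml.safe_dump(manifest, fh, sort_keys=False)
            raise StageError(name, err) from err
        manifest["stages"].append(
            {"name": name, "status": "ok", "seconds": round(time.perf_counter() - t0, 3)}
        )

    def _chemspace():
        prop = mio.read_property_table(config.inputs["properties"])
        state["properties"] = prop
        corr = corr_matrix(prop)
        mio.write_tsv(corr, out / "property_corr.tsv", index_label="property")
        clusters = cluster_properties(
            corr, k_range=tuple(opts["k_range"]), distance_rule=opts["distance_rule"]
        )
        state["clusters"] = clusters
        mio.write_tsv(clusters.labels.to_frame(), out / "property_clusters.tsv", index_label="property")
        mio.write_tsv(
            clusters.silhouette_by_K.set_index("K"), out / "silhouette_by_k.tsv", index_label="K"
        )
        subset = select_subset(clusters, opts["subset"])
        state["subset"] = subset
        (out / "subset.txt").write_text("\n".join(subset) + "\n")
        pr = opts["procrustes"]
        n_axes = min(pr["n_axes"], len(subset))
        full = fit_rotated_pca(prop.data, n_axes=n_axes)
        sub = fit_rotated_pca(prop.data[subset], n_axes=n_axes)
        mio.write_tsv(sub.loadings, out / "subset_pca_loadings.tsv", index_label="property")
        mio.write_tsv(sub.scores, out / "subset_pca_scores.tsv", index_label="metabolite_id")
        pro = procrustes_test(
            full.scores, sub.scores, n_perm=pr["n_perm"], seed=seeds["procrustes"]
        )
        mio.write_tsv(
            pd.DataFrame(
                [{"m12": pro.m12, "r2": pro.r2, "p_value": pro.p_value, "n_perm": pro.n_perm}]
            ).set_index(pd.Index([0], name="row")),
            out / "procrustes_full_vs_subset.tsv",
        )
        if opts["scan"]["enabled"]:
            scan = equivalence_scan(
                prop,
                clusters,
                n_axes=opts["scan"]["n_axes"],
                n_perm=opts["scan"]["n_perm"],
                seed=seeds["scan"],
                max_combinations=opts["scan"]["max_combinations"],
            )
            mio.write_tsv(scan.set_index("combination"), out / "equivalence_scan.tsv")

    def _traits():
        presence = mio.read_presence(config.inputs["presence"])
        taxonomy = mio.read_taxonomy(config.inputs["taxonomy"])
        empty = presence.index[presence.sum(axis=1) == 0]
        if len(empty):
            pd.Series(empty, name="species_id").to_csv(
                out / "excluded_species.tsv", sep="\t", index=False
            )
            presence = presence.drop(index=empty)
        metab = metabolic_traits(presence, state["properties"], state["subset"])
        state["metabolic"] = metab
        mio.write_trait_table(metab, out / "metabolic_traits.tsv")
        classical = mio.read_trait_table(config.inputs["classical"])
        gf = opts["gapfill"]
        if not classical.complete:
            classical, provenance = gapfill_two_step(
                classical,
                taxonomy,
                n_runs=gf["n_runs"],
                cv_max=gf["cv_max"],
                extreme_factor=gf["extreme_factor"],
                n_chain_iters=gf["n_chain_iters"],
                seed=seeds["gapfill"],
            )
            mio.write_tsv(provenance, out / "classical_provenance.tsv", index_label="species_id")
        if opts["log10_traits"]:
            classical = transform_traits(classical, opts["log10_traits"])
        classical.data = classical.data.loc[presence.index]
        state["classical"] = classical
        mio.write_trait_table(classical, out / "classical_traits.tsv")

    def _hypervolume():
        lp = LumpinessParams(**opts["lumpiness"])
        n_sim = opts["null_models"]["n_sim"]
        for label, table, hv_seed in (
            ("metabolic", state["metabolic"], seeds["hv_metabolic"]),
            ("classical", state["classical"], seeds["hv_classical"]),
        ):
            report = hypervolume_report(table, n_sim=n_sim, seed=hv_seed, params=lp)
            mio.write_tsv(report.set_index("model"), out / f"hypervolume_{label}.tsv")

    def _specialization():
        ax = opts["axes"]
        met_pca = metabolic_axes(state["metabolic"], n_axes=ax["metabolic"])
        mio.write_tsv(met_pca.loadings, out / "metabolic_axes_loadings.tsv", index_label="trait")
        mio.write_tsv(met_pca.scores, out / "metabolic_axes_scores.tsv", index_label="species_id")
        res, anchor = combined_axes(state["metabolic"], state["classical"], n_axes=ax["combined"])
        mio.write_tsv(res.loadings, out / "combined_axes_loadings.tsv", index_label="trait")
        mio.write_tsv(res.scores, out / "combined_axes_scores.tsv", index_label="species_id")
        mio.write_tsv(anchor.set_index(["trait", "axis"]), out / "axis_anchor.tsv")
        blocks = {t: "metabolic" for t in state["metabolic"].trait_names}
        blocks.update({t: "classical" for t in state["classical"].trait_names})
        purity = orthogonality_index(anchor, blocks)
        mio.write_tsv(purity.set_index("axis"), out / "axis_purity.tsv")
        joint = pd.concat([state["metabolic"].data, state["classical"].data], axis=1)
        n_traits = joint.shape[1]
        lo, hi = opts["k_range"]
        clusters = trait_clustering(
            joint, k_range=(min(lo, n_traits - 1), min(hi, n_traits - 1)),
            distance_rule=opts["distance_rule"],
        )
        mio.write_tsv(clusters.labels.to_frame(), out / "trait_clusters.tsv", index_label="trait")

    stage("chemspace", _chemspace)
    stage("traits", _traits)
    stage("hypervolume", _hypervolume)
    stage("specialization", _specialization)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out
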