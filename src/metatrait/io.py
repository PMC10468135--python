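"""TSV / YAML input and output.

All tables travel as tab-separated text with a header row; the bundle
manifest is YAML recording the seed and generator parameters.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chemspace import PropertyTable
from .synthetic import StudyBundle, SyntheticConfig
from .traits import Taxonomy, TraitTable

__all__ = [
    "write_tsv",
    "read_tsv",
    "read_property_table",
    "write_property_table",
    "read_presence",
    "read_trait_table",
    "write_trait_table",
    "read_taxonomy",
    "write_bundle",
    "read_bundle",
]

_META_COLS = ("smiles", "family", "cluster")


def write_tsv(frame: pd.DataFrame, path, index_label=None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index_label=index_label or frame.index.name)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_property_table(table: PropertyTable, path):
    out = table.data.copy()
    if table.smiles is not None:
        out.insert(0, "smiles", table.smiles)
    if table.family is not None:
        out.insert(0, "family", table.family)
    write_tsv(out, path, index_label="metabolite_id")


def read_property_table(path) -> PropertyTable:
    raw = read_tsv(path)
    smiles = raw.pop("smiles") if "smiles" in raw.columns else None
    family = raw.pop("family") if "family" in raw.columns else None
    if smiles is not None:
        smiles = smiles.fillna("").astype(str)
    return PropertyTable(data=raw.astype(float), smiles=smiles, family=family)


def read_presence(path) -> pd.DataFrame:
    frame = read_tsv(path)
    return frame.astype(np.int8)


def write_trait_table(table: TraitTable, path):
    write_tsv(table.data, path, index_label="species_id")
    meta = pd.DataFrame(
        {
            "trait": list(table.data.columns),
            "unit": [table.units.get(t, "") for t in table.data.columns],
            "transform": [table.transforms.get(t, "none") for t in table.data.columns],
        }
    )
    meta_path = Path(path).with_suffix(".meta.tsv")
    meta.to_csv(meta_path, sep="\t", index=False)


def read_trait_table(path) -> TraitTable:
    data = read_tsv(path)
    meta_path = Path(path).with_suffix(".meta.tsv")
    units, transforms = {}, {}
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t")
        units = dict(zip(meta["trait"], meta["unit"].fillna("")))
        transforms = dict(zip(meta["trait"], meta["transform"].fillna("none")))
    return TraitTable(data, units=units, transforms=transforms)


def read_taxonomy(path) -> Taxonomy:
    return Taxonomy(read_tsv(path))


def _config_to_dict(config: SyntheticConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return convert(config)


def write_bundle(bundle: StudyBundle, out_dir) -> Path:
    """Write a study bundle as TSVs plus a YAML manifest; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_property_table(bundle.property_table, out / "properties.tsv")
    write_tsv(bundle.presence, out / "presence.tsv", index_label="species_id")
    write_trait_table(bundle.classical, out / "classical.tsv")
    write_tsv(bundle.taxonomy.table, out / "taxonomy.tsv", index_label="species_id")
    write_tsv(bundle.latent_species_axes, out / "latent_axes.tsv", index_label="species_id")
    if bundle.property_table.clusters is not None:
        write_tsv(
            bundle.property_table.clusters.to_frame(),
            out / "property_clusters.tsv",
            index_label="property",
        )
    manifest = {
        "seed": bundle.seed,
        "content_hash": bundle.content_hash(),
        "config": _config_to_dict(bundle.config),
        "files": [
            "properties.tsv",
            "presence.tsv",
            "classical.tsv",
            "taxonomy.tsv",
            "latent_axes.tsv",
        ],
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out


def read_bundle(bundle_dir) -> dict:
    """Read the on-disk pieces of a bundle back into memory (plain dict)."""
    d = Path(bundle_dir)
    out = {
        "property_table": read_property_table(d / "properties.tsv"),
        "presence": read_presence(d / "presence.tsv"),
        "classical": read_trait_table(d / "classical.tsv"),
        "taxonomy": read_taxonomy(d / "taxonomy.tsv"),
    }
    latent = d / "latent_axes.tsv"
    if latent.exists():
        out["latent_species_axes"] = read_tsv(latent)
    clusters = d / "property_clusters.tsv"
    if clusters.exists():
        out["property_table"].clusters = read_tsv(clusters)["cluster"]
    manifest = d / "manifest.yaml"
    if manifest.exists():
        with open(manifest) as fh:
            out["manifest"] = yaml.safe_load(fh)
    return out
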