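"""Readers/writers for the plain-text interchange formats and run config."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, fields
from pathlib import Path

import pandas as pd
import yaml

from .model import ExperimentConfig


def read_table(path) -> pd.DataFrame:
    """Read a CSV or TSV measurement table (delimiter by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def write_table(df: pd.DataFrame, path, float_format: str = "%.10g"):
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df.to_csv(path, sep=sep, index=False, float_format=float_format)


def read_config(path) -> ExperimentConfig:
    """Experiment config from YAML; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ExperimentConfig(**raw)


def write_config(config: ExperimentConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


def config_hash(config) -> str:
    """Stable short hash of a dataclass config, recorded in every output."""
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_otu_table(path):
    """OTU TSV: rows are OTUs, a ``taxonomy`` column carries the 7-rank
    semicolon lineage, remaining columns are samples. Returns (counts with
    samples as rows, taxonomy Series)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "taxonomy" not in df.columns:
        raise ValueError("OTU table needs a 'taxonomy' column")
    taxonomy = df["taxonomy"]
    counts = df.drop(columns=["taxonomy"]).T
    return counts.astype(int), taxonomy


def write_otu_table(counts: pd.DataFrame, taxonomy: pd.Series, path):
    out = counts.T.copy()
    out["taxonomy"] = taxonomy.loc[out.index]
    out.to_csv(path, sep="\t", index_label="otu_id")
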