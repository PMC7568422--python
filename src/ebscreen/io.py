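"""Plain-text I/O: tab-delimited matrices and YAML configuration.

All pipeline stages exchange tab-delimited text so each stage is
independently inspectable and testable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "read_counts",
    "write_matrix",
    "read_condition_map",
    "read_phenotype",
    "read_annotations",
    "write_manifest",
]


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene x sample integer counts; first column is the gene ID."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"empty count matrix: {path}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)


def read_condition_map(path: str | Path) -> dict[str, str]:
    """sample -> condition mapping from YAML ({sample: condition}) or 2-col TSV."""
    p = Path(path)
    if p.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(p.read_text())
        if not isinstance(data, Mapping):
            raise ValueError("condition map YAML must be a sample: condition mapping")
        return {str(k): str(v) for k, v in data.items()}
    df = pd.read_csv(p, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("condition map TSV needs sample and condition columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_phenotype(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("donor", "condition"):
        if col not in df.columns:
            raise ValueError(f"phenotype table lacks column {col!r}")
    return df


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "symbol" not in df.columns:
        raise ValueError("annotation table lacks a 'symbol' column")
    for col in df.columns:
        if df[col].dtype == object and set(df[col].dropna().unique()) <= {
            "true", "false", "True", "False", "TRUE", "FALSE",
        }:
            df[col] = df[col].str.lower() == "true"
    return df


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
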