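"""Readers and writers for the tab-separated interchange formats.

All files are UTF-8, Unix line endings, tab-separated:

- expression matrix: header row of sample ids, first column feature ids,
  normal samples as the leading columns; missing values as empty fields or
  ``NA``;
- outlier tables: feature_id, outlier_samples (comma-joined), percentile pair
  and counts;
- annotation: two columns, probe id -> gene symbol;
- subtype labels: two columns, sample id -> subtype;
- run configuration: flat YAML mapping.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Tuple

import pandas as pd
import yaml

from .matrix import ExpressionMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "probes_to_genes",
    "read_labels",
    "read_outlier_table",
    "write_outlier_table",
    "read_config",
    "write_config",
]

logger = logging.getLogger(__name__)

_NA_VALUES = ["", "NA"]


def read_matrix(path, n_normal: int) -> ExpressionMatrix:
    """Parse a tab-separated expression matrix with the group split at n_normal."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=_NA_VALUES,
        keep_default_na=False, header=0,
    )
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression values ({exc})") from None
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least two sample columns")
    return ExpressionMatrix(df, n_normal)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_annotation(path) -> dict:
    """Two-column probe -> gene TSV; duplicate probe ids are rejected."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError("annotation file needs two columns: probe_id, gene")
    probes = df.iloc[:, 0]
    if probes.duplicated().any():
        dups = probes[probes.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe ids in annotation: {dups[:5]}")
    return dict(zip(probes, df.iloc[:, 1]))


def probes_to_genes(features, annotation: dict) -> Tuple[list, list]:
    """Map probe ids to gene symbols.

    Returns (genes, unmapped): de-duplicated gene symbols in first-seen
    order, and the probes without a (non-empty) annotation entry.
    """
    genes, seen, unmapped = [], set(), []
    for probe in features:
        gene = annotation.get(probe, "")
        if not gene:
            unmapped.append(probe)
            continue
        if gene not in seen:
            seen.add(gene)
            genes.append(gene)
    return genes, unmapped


def read_labels(path) -> pd.Series:
    """Two-column sample -> subtype TSV as a Series indexed by sample id."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: sample_id, subtype")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="subtype")
    if s.index.has_duplicates:
        raise ValueError("duplicate sample ids in label file")
    s.index.name = "sample_id"
    return s


def write_outlier_table(table: pd.DataFrame, path, direction: str) -> None:
    """Serialise a filter output table; sample lists are comma-joined."""
    p = "pu" if direction == "up" else "pl"
    out = pd.DataFrame(
        {
            "outlier_sample_ids": table["outlier_samples"].map(",".join),
            f"{p}_t": table["p_t"],
            f"{p}_n": table["p_n"],
            "n_tumour_outliers": table["n_tumour_outliers"],
        },
        index=table.index,
    )
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_outlier_table(path) -> pd.DataFrame:
    """Inverse of :func:`write_outlier_table` (back to list-valued samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    samples = [
        s.split(",") if s else [] for s in df["outlier_sample_ids"].astype(str)
    ]
    p_t_col = "pu_t" if "pu_t" in df.columns else "pl_t"
    p_n_col = "pu_n" if "pu_n" in df.columns else "pl_n"
    out = pd.DataFrame(
        {
            "outlier_samples": samples,
            "n_tumour_outliers": df["n_tumour_outliers"].astype(int),
            "p_t": df[p_t_col].astype(float),
            "p_n": df[p_n_col].astype(float),
        },
        index=df.index,
    )
    out.index.name = "feature_id"
    return out


def read_config(path) -> dict:
    """Flat key/value configuration (YAML subset)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a flat key/value mapping")
    return cfg


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
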