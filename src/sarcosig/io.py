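"""Plain-text readers and writers for the pipeline's tabular formats.

All formats are tab-separated text: expression matrices (rows = genes,
first column the gene ID, header = sample IDs), sample metadata
(sample_id, subtype), score tables, long-format qPCR Ct tables and FISH
per-cell count tables.  GMT handling lives in :mod:`sarcosig.signatures`.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .scoring import validate_matrix

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_scores_tsv",
    "write_scores_tsv",
    "read_ct_tsv",
    "write_ct_tsv",
    "read_fish_tsv",
    "write_fish_tsv",
]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    x = pd.read_csv(path, sep="\t", index_col=0)
    x.index = x.index.astype(str)
    x.columns = x.columns.astype(str)
    x.index.name = "gene_id"
    validate_matrix(x)
    return x


def write_expression_tsv(x: pd.DataFrame, path: str | Path) -> None:
    x.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "subtype"}
    if not required <= set(df.columns):
        raise ValueError(f"metadata TSV needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample IDs in metadata")
    return df.set_index("sample_id")["subtype"]


def write_annotation_tsv(annotation: pd.Series, path: str | Path) -> None:
    annotation.rename("subtype").to_csv(path, sep="\t", index_label="sample_id")


def read_scores_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index = df.index.astype(str)
    return df


def write_scores_tsv(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index_label="sample_id")


def read_ct_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"well": str, "sample_id": str, "assay": str,
                               "role": str}, keep_default_na=True,
    )
    needed = {"assay", "role", "ct"}
    if not needed <= set(df.columns):
        raise ValueError(f"Ct TSV needs columns {sorted(needed)}")
    df["sample_id"] = df.get("sample_id", pd.Series("", index=df.index)).fillna("")
    return df


def write_ct_tsv(ct: pd.DataFrame, path: str | Path) -> None:
    ct.to_csv(path, sep="\t", index=False)


def read_fish_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    needed = {"cell_id", "met_count", "cen7_count"}
    if not needed <= set(df.columns):
        raise ValueError(f"FISH TSV needs columns {sorted(needed)}")
    return df


def write_fish_tsv(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, sep="\t", index=False)
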