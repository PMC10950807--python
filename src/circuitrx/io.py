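"""Reading and writing the tabular artifacts.

Labeled matrices (samples x features) travel as TSV / TSV.GZ — tab
delimiter, header row of feature identifiers, first column of sample
identifiers, UTF-8 — or optionally as Feather when pyarrow is available.
The in-memory container is a plain :class:`pandas.DataFrame` with unique
string index (samples) and columns (features): Entrez gene identifiers for
expression matrices, circuit names/identifiers for activity matrices.

Missing cells are an empty field or the literal ``NA`` on read and an empty
field on write; every other non-numeric cell is a format error.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

_NA_VALUES = ["", "NA"]


def _check_unique(index: pd.Index, what: str, path: Path) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise FormatError(f"{path}: duplicate {what} identifiers: {dups}")


def validate_labeled_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Check the labeled-matrix invariants (unique ids, numeric cells)."""
    if df.index.has_duplicates:
        raise FormatError("duplicate row identifiers")
    if df.columns.has_duplicates:
        raise FormatError("duplicate column identifiers")
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise FormatError("non-numeric data column")
    return df


def feather_available() -> bool:
    try:
        import pyarrow  # noqa: F401
    except ImportError:
        return False
    return True


def read_labeled_matrix(path: str | Path) -> pd.DataFrame:
    """Read a samples-x-features matrix, preserving file row/column order.

    Accepts ``.tsv``, ``.tsv.gz`` and (when pyarrow is installed)
    ``.feather``; for Feather the first column is taken as the index.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"matrix file not found: {path}")
    if path.suffix == ".feather":
        if not feather_available():
            raise FormatError("Feather support requires pyarrow, which is not installed")
        df = pd.read_feather(path)
        df = df.set_index(df.columns[0])
    else:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=_NA_VALUES,
            keep_default_na=False,
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "sample", path)
    _check_unique(df.columns, "feature", path)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise FormatError(
                f"{path}: non-numeric cell(s) in column {col!r}: {bad.head(3).tolist()}"
            )
    return df.astype(float)


def write_labeled_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled matrix as round-trippable TSV (or TSV.GZ / Feather)."""
    path = Path(path)
    validate_labeled_matrix(df)
    if path.suffix == ".feather":
        if not feather_available():
            raise FormatError("Feather support requires pyarrow, which is not installed")
        df.reset_index().to_feather(path)
        return
    df.to_csv(path, sep="\t", na_rep="", index=True, lineterminator="\n")


def load_gene_table(path: str | Path, genes_column: str = "drugbank_approved_targets") -> pd.DataFrame:
    """Load the three-column gene metadata table.

    Columns: ``entrez_id`` (unique int), ``symbol_id`` (HUGO symbol) and a
    boolean KDT flag named by *genes_column*.  The known-drug-target set is
    ``table.loc[table[genes_column], "entrez_id"]``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("entrez_id", "symbol_id", genes_column):
        if col not in df.columns:
            raise FormatError(f"{path}: gene table missing required column {col!r}")
    if df["entrez_id"].duplicated().any():
        dups = df.loc[df["entrez_id"].duplicated(), "entrez_id"].tolist()[:5]
        raise FormatError(f"{path}: duplicate entrez_id values: {dups}")
    df["entrez_id"] = df["entrez_id"].astype(int)
    df[genes_column] = df[genes_column].astype(bool)
    return df


def kdt_genes(gene_table: pd.DataFrame, genes_column: str = "drugbank_approved_targets") -> list[int]:
    """Entrez identifiers flagged as known drug targets, in table order."""
    return gene_table.loc[gene_table[genes_column], "entrez_id"].astype(int).tolist()


def load_drug_table(path: str | Path) -> pd.DataFrame:
    """Load the drug→target table.

    Long format: one row per (drug, target) pair with columns ``drug_id``,
    ``drug_name``, ``target_entrez`` and the pharmacological ``action``
    (e.g. inhibitor / activator / other).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("drug_id", "drug_name", "target_entrez", "action"):
        if col not in df.columns:
            raise FormatError(f"{path}: drug table missing required column {col!r}")
    if df.duplicated(subset=["drug_id", "target_entrez"]).any():
        raise FormatError(f"{path}: duplicate (drug_id, target_entrez) pairs")
    df["target_entrez"] = df["target_entrez"].astype(int)
    return df
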