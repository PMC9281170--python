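"""Readers and writers for expression matrices, labels, truth sets, tables.

Supported matrix inputs: a Matrix Market triplet directory
(``matrix.mtx`` plus ``genes.tsv``/``features.tsv`` and ``barcodes.tsv``
sidecars, 10x-style) or a dense CSV/TSV with genes as rows and cells as
columns.  Orientation is auto-detected from the sidecar lengths (MTX) or
from known cell identifiers when provided (dense).  All outputs are
plain UTF-8 CSV with six-significant-digit floats for stable regression
comparison.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio

from maxmarker.core import ExpressionMatrix, InvalidInputError, ThresholdResult

__all__ = [
    "FormatError",
    "read_expression",
    "read_labels",
    "read_truth",
    "write_marker_table",
    "read_marker_table",
]

MARKER_TABLE_COLUMNS = [
    "rank", "gene", "direction", "alpha", "gene_split", "tpr", "tnr", "fc",
    "ranking_score", "db_source", "evidence", "antibody_registry_id", "vendor_link",
]


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


def _dedup_symbols(symbols: Sequence[str]) -> list[str]:
    """Disambiguate duplicate symbols with numeric suffixes (.1, .2, ...)."""
    counts: dict[str, int] = {}
    out = []
    dups = 0
    for s in symbols:
        if s in counts:
            counts[s] += 1
            out.append(f"{s}.{counts[s]}")
            dups += 1
        else:
            counts[s] = 0
            out.append(s)
    if dups:
        warnings.warn(f"{dups} duplicate gene symbols disambiguated with numeric suffixes")
    return out


def _read_sidecar(path: Path) -> list[str]:
    # 10x features files may have multiple tab-separated columns; symbol first
    lines = path.read_text(encoding="utf-8").splitlines()
    return [ln.split("\t")[0].strip() for ln in lines if ln.strip()]


def _read_mtx_dir(directory: Path) -> ExpressionMatrix:
    mtx_path = directory / "matrix.mtx"
    if not mtx_path.exists():
        raise FormatError(f"{directory}: no matrix.mtx found")
    gene_path = next(
        (directory / n for n in ("genes.tsv", "features.tsv") if (directory / n).exists()),
        None,
    )
    barcode_path = directory / "barcodes.tsv"
    if gene_path is None or not barcode_path.exists():
        raise FormatError(f"{directory}: missing genes/features or barcodes sidecar")
    try:
        mat = spio.mmread(str(mtx_path))
    except ValueError as exc:
        raise FormatError(f"{mtx_path}: malformed Matrix Market file: {exc}") from None
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    genes = _dedup_symbols(_read_sidecar(gene_path))
    cells = _read_sidecar(barcode_path)
    if dense.shape == (len(genes), len(cells)):
        dense = dense.T  # genes-as-rows on disk -> cells x genes in memory
    elif dense.shape != (len(cells), len(genes)):
        raise FormatError(
            f"{mtx_path}: shape {dense.shape} matches neither "
            f"(genes={len(genes)}, cells={len(cells)}) orientation"
        )
    if np.any(dense < 0):
        raise FormatError(f"{mtx_path}: negative expression values")
    return ExpressionMatrix(dense, tuple(cells), tuple(genes))


def read_expression(
    path: str | Path, known_cell_ids: Iterable[str] | None = None
) -> ExpressionMatrix:
    """Read an expression matrix from an MTX directory or dense CSV/TSV.

    Dense files are assumed to have genes as rows (gene ids in the first
    column, cell ids in the header); if ``known_cell_ids`` is given and
    matches the row index better than the columns, the matrix is
    transposed automatically.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file or directory")
    if path.is_dir():
        return _read_mtx_dir(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise FormatError(f"{path}: empty matrix file")
    if known_cell_ids is not None:
        known = set(map(str, known_cell_ids))
        row_hits = sum(str(i) in known for i in df.index)
        col_hits = sum(str(c) in known for c in df.columns)
        genes_as_rows = col_hits >= row_hits
    else:
        genes_as_rows = True
    if genes_as_rows:
        df = df.T  # rows were genes -> cells x genes
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise FormatError(f"{path}: negative expression values")
    genes = _dedup_symbols([str(g) for g in df.columns])
    return ExpressionMatrix(values, tuple(str(c) for c in df.index), tuple(genes))


def read_labels(path: str | Path, matrix: ExpressionMatrix | None = None) -> dict[str, str]:
    """Read a cell_id -> cluster label table (CSV/TSV, first two columns).

    When ``matrix`` is given, every matrix cell must be labelled (error
    listing the first 10 offenders); labels for cells absent from the
    matrix are dropped with a warning.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected at least two columns (cell_id, label)")
    labels = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    if matrix is not None:
        missing = [c for c in matrix.cell_ids if c not in labels]
        if missing:
            raise InvalidInputError(
                f"{len(missing)} matrix cells have no label (first 10: {missing[:10]})"
            )
        extra = set(labels) - set(matrix.cell_ids)
        if extra:
            warnings.warn(f"{len(extra)} labelled cells absent from the matrix; ignored")
            labels = {c: labels[c] for c in matrix.cell_ids}
    return labels


def read_truth(path: str | Path) -> dict[str, list[str]]:
    """Read a truth set CSV with columns cell_type,gene_symbol."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "cell_type" not in cols or "gene_symbol" not in cols:
        raise FormatError(f"{path}: expected columns cell_type,gene_symbol")
    truth: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        truth.setdefault(str(row[cols["cell_type"]]), []).append(str(row[cols["gene_symbol"]]))
    return truth


def _fmt(value) -> str:
    if isinstance(value, (float, np.floating)):
        return f"{value:.6g}"
    return str(value)


def write_marker_table(annotated: pd.DataFrame, path: str | Path) -> None:
    """Write an annotated marker table as RFC-4180 CSV.

    Floats are formatted to six significant digits so repeated runs with
    identical inputs produce byte-identical files.
    """
    path = Path(path)
    out = annotated.copy()
    for col in MARKER_TABLE_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    out = out[MARKER_TABLE_COLUMNS]
    out = out.map(_fmt)
    out.to_csv(path, index=False, lineterminator="\n")


def read_marker_table(path: str | Path) -> pd.DataFrame:
    """Read back a written marker table with numeric columns restored."""
    df = pd.read_csv(path, keep_default_na=False)
    for col in ("rank",):
        if col in df.columns and len(df):
            df[col] = df[col].astype(int)
    for col in ("alpha", "gene_split", "tpr", "tnr", "fc", "ranking_score"):
        if col in df.columns and len(df):
            df[col] = df[col].astype(float)
    return df
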