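"""Antibody marker databases: loading, gene-space restriction, annotation.

A database is a CSV with columns
``gene_symbol,category,species,evidence,source,antibody_registry_id,vendor_link``
listing genes whose protein products have antibodies validated for a
downstream application (flow cytometry, IHC, ICC, or user-provided).
Restricting candidate genes to a database guarantees that every reported
marker is experimentally actionable; annotation attaches provenance
(source atlas or vendor, evidence level, antibody registry RRID) to a
ranked marker table without altering its order.

Symbol matching is case-insensitive so that mouse-style symbols ("Cd19")
match human-style database entries ("CD19"); output always preserves the
spelling used by the expression matrix.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("ICC", "IHC", "Flow", "ICC_Mouse", "IHC_Mouse", "Flow_Mouse", "User")
EVIDENCE_LEVELS = ("validated", "homology", "user")
DB_COLUMNS = (
    "gene_symbol",
    "category",
    "species",
    "evidence",
    "source",
    "antibody_registry_id",
    "vendor_link",
)

__all__ = [
    "AntibodyRecord",
    "AntibodyDB",
    "CATEGORIES",
    "DB_COLUMNS",
    "SchemaError",
    "load_db",
    "write_db",
    "bundled_db",
    "restrict_genes",
    "annotate_results",
]


class SchemaError(ValueError):
    """Raised when a database file violates the CSV schema."""


@dataclass(frozen=True)
class AntibodyRecord:
    gene_symbol: str
    category: str
    species: str = ""
    evidence: str = ""
    source: str = ""
    antibody_registry_id: str = ""
    vendor_link: str = ""

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise SchemaError("gene_symbol must be non-empty")
        if self.category not in CATEGORIES:
            raise SchemaError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        if self.evidence and self.evidence not in EVIDENCE_LEVELS:
            raise SchemaError(
                f"unknown evidence {self.evidence!r}; expected one of {EVIDENCE_LEVELS}"
            )


@dataclass(frozen=True)
class AntibodyDB:
    """Validated antibody records with a case-insensitive symbol index."""

    records: tuple[AntibodyRecord, ...]
    index: Mapping[str, tuple[AntibodyRecord, ...]] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        idx: dict[str, list[AntibodyRecord]] = {}
        for rec in self.records:
            idx.setdefault(rec.gene_symbol.casefold(), []).append(rec)
        object.__setattr__(
            self, "index", {k: tuple(v) for k, v in idx.items()}
        )

    def __len__(self) -> int:
        return len(self.records)

    def lookup(self, gene_symbol: str) -> tuple[AntibodyRecord, ...]:
        return self.index.get(gene_symbol.casefold(), ())

    def __contains__(self, gene_symbol: str) -> bool:
        return gene_symbol.casefold() in self.index

    def merge(self, other: "AntibodyDB") -> "AntibodyDB":
        """Union of two databases; duplicate (gene, category) pairs collapse."""
        return AntibodyDB(_dedup(list(self.records) + list(other.records)))


def _dedup(records: Sequence[AntibodyRecord]) -> list[AntibodyRecord]:
    seen: dict[tuple[str, str], AntibodyRecord] = {}
    dropped = 0
    for rec in records:
        key = (rec.gene_symbol.casefold(), rec.category)
        if key in seen:
            dropped += 1
        else:
            seen[key] = rec
    if dropped:
        warnings.warn(
            f"collapsed {dropped} duplicate (gene, category) database rows",
            stacklevel=3,
        )
    return list(seen.values())


def load_db(path: str | Path) -> AntibodyDB:
    """Load and validate a marker database CSV.

    The header must contain at least ``gene_symbol`` and ``category``;
    the remaining schema columns are optional and default to empty.  Rows
    with a category outside the fixed vocabulary raise a SchemaError that
    names the offending row; duplicated (gene, category) rows are
    collapsed with a warning.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty database file")
        missing = {"gene_symbol", "category"} - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
        records = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    AntibodyRecord(
                        gene_symbol=(row.get("gene_symbol") or "").strip(),
                        category=(row.get("category") or "").strip(),
                        species=(row.get("species") or "").strip(),
                        evidence=(row.get("evidence") or "").strip(),
                        source=(row.get("source") or "").strip(),
                        antibody_registry_id=(row.get("antibody_registry_id") or "").strip(),
                        vendor_link=(row.get("vendor_link") or "").strip(),
                    )
                )
            except SchemaError as exc:
                raise SchemaError(f"{path}: row {lineno}: {exc}") from None
    if not records:
        raise SchemaError(f"{path}: database contains no records")
    return AntibodyDB(_dedup(records))


def write_db(db: AntibodyDB, path: str | Path) -> None:
    """Write a database back to the CSV schema (round-trips with load_db)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DB_COLUMNS)
        for rec in db.records:
            writer.writerow([getattr(rec, c) for c in DB_COLUMNS])


def bundled_db() -> AntibodyDB:
    """The small curated database shipped with the package.

    Covers well-known flow cytometry markers of major immune cell types
    plus mouse stromal-cell markers; intended as a worked example and
    fixture, not a replacement for a full atlas-derived database.
    """
    ref = resources.files("maxmarker").joinpath("data/antibody_db.csv")
    with resources.as_file(ref) as path:
        return load_db(path)


def restrict_genes(
    gene_ids: Iterable[str],
    db: AntibodyDB,
    categories: Iterable[str] | None = None,
) -> list[str]:
    """Whitelist of ``gene_ids`` with a database record in ``categories``.

    Matching is case-insensitive; the returned symbols keep the input
    spelling and order.  ``categories=None`` means all categories.
    """
    if categories is None:
        cats = set(CATEGORIES)
    else:
        cats = set(categories)
        unknown = cats - set(CATEGORIES)
        if unknown:
            raise SchemaError(f"unknown categories {sorted(unknown)}")
        if not cats:
            raise SchemaError("categories must be non-empty")
    out = []
    for g in gene_ids:
        if any(rec.category in cats for rec in db.lookup(g)):
            out.append(g)
    return out


def annotate_results(ranked: pd.DataFrame, db: AntibodyDB | None) -> pd.DataFrame:
    """Attach database provenance columns to a ranked marker table.

    Adds ``db_source``, ``evidence``, ``antibody_registry_id`` and
    ``vendor_link``; genes with several records get their annotations
    joined with ';' in the fixed category order.  Row order and scores are
    never modified.
    """
    out = ranked.copy()
    annot_cols = {
        "db_source": "source",
        "evidence": "evidence",
        "antibody_registry_id": "antibody_registry_id",
        "vendor_link": "vendor_link",
    }

    def _annotate(gene: str, attr: str) -> str:
        if db is None:
            return ""
        recs = sorted(db.lookup(gene), key=lambda r: CATEGORIES.index(r.category))
        return ";".join(getattr(r, attr) for r in recs)

    genes = out["gene"] if "gene" in out.columns else pd.Series([], dtype=str)
    for col, attr in annot_cols.items():
        out[col] = [_annotate(g, attr) for g in genes]
    return out
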