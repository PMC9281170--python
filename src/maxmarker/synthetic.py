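"""Desk-scale synthetic clustered scRNA-seq data with planted markers.

The generator emulates log-normalized droplet scRNA-seq expression:
background counts follow a zero-inflated negative binomial (a Bernoulli
detection mask times a shifted NB), then ``log1p``.  Each cell type gets
a set of planted positive markers — detected in a high fraction of its
cells and shifted upward on the log scale — and optionally negative
markers, which are expressed across the other cell types but silenced in
the target type.  Ground truth (which genes were planted for which type)
is returned alongside the matrix so ranking methods can be benchmarked
without external data.

A zero ``marker_mean_shift`` means a null dataset: no planting occurs at
all, so every gene is exchangeable with the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from maxmarker.core import ExpressionMatrix, InvalidInputError

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "write_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic dataset.

    Defaults give 4 cell types x 100 cells x 200 genes with 3 planted
    positive markers per type, an e^2 (~7.4-fold) marker effect on the
    log scale, 90% marker detection in the target type, and 10%
    background detection — a well-separated but sparse regime typical of
    sorted immune populations.
    """

    n_cell_types: int = 4
    cells_per_type: int = 100
    n_genes: int = 200
    markers_per_type: int = 3
    marker_mean_shift: float = 2.0
    target_detection: float = 0.9
    background_detection: float = 0.1
    negative_markers_per_type: int = 0
    dispersion: float = 0.5
    background_mean: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 2 or self.cells_per_type < 2 or self.n_genes < 1:
            raise InvalidInputError("need >= 2 cell types, >= 2 cells/type, >= 1 gene")
        needed = (self.markers_per_type + self.negative_markers_per_type) * self.n_cell_types
        if needed > self.n_genes:
            raise InvalidInputError(
                f"{needed} planted genes requested but only {self.n_genes} genes available"
            )
        if not (0.0 < self.target_detection <= 1.0):
            raise InvalidInputError("target_detection must be in (0, 1]")
        if not (0.0 <= self.background_detection < 1.0):
            raise InvalidInputError("background_detection must be in [0, 1)")
        if self.marker_mean_shift > 0 and self.target_detection <= self.background_detection:
            raise InvalidInputError("target_detection must exceed background_detection")
        if self.marker_mean_shift < 0 or self.dispersion <= 0 or self.background_mean <= 0:
            raise InvalidInputError("shift must be >= 0; dispersion and mean positive")


@dataclass(frozen=True)
class SyntheticDataset:
    matrix: ExpressionMatrix
    labels: Mapping[str, str]
    truth: Mapping[str, list[str]]
    negative_truth: Mapping[str, list[str]]
    spec: SyntheticSpec


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    # NB parametrized by mean and dispersion (variance = mean + dispersion * mean^2)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def generate(spec: SyntheticSpec | None = None, **overrides) -> SyntheticDataset:
    """Generate a clustered expression matrix with planted markers.

    Deterministic given ``spec`` (including its seed).  Keyword overrides
    are applied on top of the default spec for convenience.
    """
    if spec is None:
        spec = SyntheticSpec(**overrides)
    elif overrides:
        spec = SyntheticSpec(**{**asdict(spec), **overrides})
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cell_types * spec.cells_per_type
    m = spec.n_genes

    # background: detection mask * (1 + NB), then log1p
    detected = rng.random((n, m)) < spec.background_detection
    counts = detected * (1 + _nb_counts(rng, spec.background_mean, spec.dispersion, (n, m)))
    X = np.log1p(counts.astype(float))

    types = [f"type{t}" for t in range(spec.n_cell_types)]
    cell_ids = [f"cell{idx:04d}" for idx in range(n)]
    gene_ids = [f"G{j:04d}" for j in range(m)]
    labels = {
        cell_ids[i]: types[i // spec.cells_per_type] for i in range(n)
    }

    truth: dict[str, list[str]] = {t: [] for t in types}
    negative_truth: dict[str, list[str]] = {t: [] for t in types}

    if spec.marker_mean_shift > 0:
        gene_cursor = 0
        for t_idx, t in enumerate(types):
            rows = slice(t_idx * spec.cells_per_type, (t_idx + 1) * spec.cells_per_type)
            for _ in range(spec.markers_per_type):
                j = gene_cursor
                gene_cursor += 1
                truth[t].append(gene_ids[j])
                expressed = rng.random(spec.cells_per_type) < spec.target_detection
                base = 1 + _nb_counts(
                    rng, spec.background_mean, spec.dispersion, spec.cells_per_type
                )
                col = np.where(expressed, np.log1p(base) + spec.marker_mean_shift, 0.0)
                X[rows, j] = col
            for _ in range(spec.negative_markers_per_type):
                j = gene_cursor
                gene_cursor += 1
                negative_truth[t].append(gene_ids[j])
                # expressed everywhere else, silenced in the target type
                base = 1 + _nb_counts(rng, spec.background_mean, spec.dispersion, n)
                expressed = rng.random(n) < spec.target_detection
                col = np.where(expressed, np.log1p(base) + spec.marker_mean_shift, 0.0)
                col[rows] = 0.0
                X[:, j] = col

        for t, genes in truth.items():
            t_rows = [i for i, c in enumerate(cell_ids) if labels[c] == t]
            for g in genes:
                det = np.mean(X[t_rows, gene_ids.index(g)] > 0)
                if det < 0.8 * spec.target_detection:
                    raise InvalidInputError(
                        f"planted marker {g} under-detected ({det:.2f}) in {t}"
                    )

    matrix = ExpressionMatrix(X, tuple(cell_ids), tuple(gene_ids))
    return SyntheticDataset(matrix, labels, truth, negative_truth, spec)


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write a dataset as an MTX triplet plus labels/truth/DB sidecars.

    Emits ``matrix.mtx`` (genes as rows, cells as columns, the common 10x
    orientation), ``genes.tsv``, ``barcodes.tsv``, ``labels.csv``,
    ``truth.csv`` and a fixture antibody database ``db.csv`` containing
    every planted marker (category ``User``) plus all remaining genes as
    decoys — so database-restriction keeps the full candidate space
    unless a caller narrows it deliberately.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = dataset.matrix
    paths = {
        "matrix": directory / "matrix.mtx",
        "genes": directory / "genes.tsv",
        "barcodes": directory / "barcodes.tsv",
        "labels": directory / "labels.csv",
        "truth": directory / "truth.csv",
        "db": directory / "db.csv",
    }
    spio.mmwrite(str(paths["matrix"]), sparse.csr_matrix(mat.values.T))
    paths["genes"].write_text("\n".join(mat.gene_ids) + "\n", encoding="utf-8")
    paths["barcodes"].write_text("\n".join(mat.cell_ids) + "\n", encoding="utf-8")
    pd.DataFrame(
        {"cell_id": list(mat.cell_ids), "label": [dataset.labels[c] for c in mat.cell_ids]}
    ).to_csv(paths["labels"], index=False)
    truth_rows = [
        {"cell_type": t, "gene_symbol": g}
        for t, genes in dataset.truth.items()
        for g in genes
    ]
    pd.DataFrame(truth_rows, columns=["cell_type", "gene_symbol"]).to_csv(
        paths["truth"], index=False
    )
    planted = {g for genes in dataset.truth.values() for g in genes} | {
        g for genes in dataset.negative_truth.values() for g in genes
    }
    decoys = [g for g in mat.gene_ids if g not in planted][:: max(1, len(mat.gene_ids) // 50)]
    db_rows = [
        {
            "gene_symbol": g,
            "category": "User",
            "species": "human",
            "evidence": "user",
            "source": "synthetic fixture",
            "antibody_registry_id": "",
            "vendor_link": "",
        }
        for g in mat.gene_ids
        if g in planted or g in set(decoys)
    ]
    pd.DataFrame(db_rows).to_csv(paths["db"], index=False)
    return paths
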