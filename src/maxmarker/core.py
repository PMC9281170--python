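"""Maximum-margin threshold search and composite marker ranking.

Every gene is treated as a univariate threshold classifier for a target
cell type (one-vs-rest).  Expression is min-max scaled per gene to [0, 1];
a grid search over thresholds ``alpha`` maximizes the *GeneSplit* margin
score, which rewards large distances of true positives and true negatives
to the threshold and penalizes false positives.  Genes are then ranked by

    ranking_score = GeneSplit(alpha) * TPR * TNR * FC**2

where TPR/TNR are the sensitivity/specificity of the threshold classifier
at the optimal ``alpha`` and FC is a pseudo-counted ratio of the mean
scaled expression in the target versus the remaining cells.  Negative
markers (genes whose *absence* marks the target type) are scored by
inverting the scaled column (``1 - x``) and running the identical
positive-marker pipeline.

Low-quality candidates are filtered out: genes detected (raw expression
> 0) in fewer than ``min_detection`` of the relevant cluster's cells, and
genes whose TNR at the optimum falls below ``min_tnr``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ScaledMatrix",
    "CellLabelVector",
    "ConfusionPartition",
    "ThresholdResult",
    "ScoringConfig",
    "min_max_scale",
    "partition_at_threshold",
    "gene_split_score",
    "find_optimal_threshold",
    "fold_change",
    "gene_ranking_score",
    "detection_rate",
    "apply_filters",
    "score_gene",
    "rank_markers",
]


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized expression, cells x genes, with unique identifiers.

    ``values[i, j]`` is the (library-size normalized, typically
    log-transformed) expression of gene ``gene_ids[j]`` in cell
    ``cell_ids[i]``.  Values must be finite and non-negative.
    """

    values: np.ndarray
    cell_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        if values.ndim != 2:
            raise InvalidInputError("expression matrix must be 2-dimensional")
        n, m = values.shape
        if n < 2 or m < 1:
            raise InvalidInputError(f"matrix too small: {n} cells x {m} genes (need n >= 2, m >= 1)")
        if len(self.cell_ids) != n or len(self.gene_ids) != m:
            raise InvalidInputError("identifier lengths do not match matrix shape")
        if len(set(self.cell_ids)) != n:
            raise InvalidInputError("cell identifiers are not unique")
        if len(set(self.gene_ids)) != m:
            raise InvalidInputError("gene identifiers are not unique")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("matrix contains non-finite entries")
        if np.any(values < 0):
            raise InvalidInputError("matrix contains negative entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not found in matrix") from None

    def gene_column(self, gene_id: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.cell_ids), columns=list(self.gene_ids))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a cells-x-genes DataFrame (index = cells, columns = genes)."""
        return cls(df.to_numpy(dtype=float), tuple(df.index.astype(str)), tuple(df.columns.astype(str)))


@dataclass(frozen=True)
class ScaledMatrix(ExpressionMatrix):
    """Per-gene min-max scaled expression; every entry lies in [0, 1].

    Constant gene columns are mapped to all-zero: such genes carry no
    class signal and are later removed by the detection/TNR filters.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values > 1.0):
            raise InvalidInputError("scaled matrix contains entries above 1")


@dataclass(frozen=True)
class CellLabelVector:
    """Cluster label per cell and the target cluster used for one-vs-rest.

    ``class_vector`` maps the labels to the signed classes used by the
    margin score: +1 for cells of the target type, -1 for every other cell.
    """

    labels: Mapping[str, str]
    target: str

    def __post_init__(self) -> None:
        labels = {str(k): str(v) for k, v in dict(self.labels).items()}
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "target", str(self.target))
        values = set(labels.values())
        if self.target not in values:
            raise InvalidInputError(f"target label {self.target!r} not present among cell labels")
        if values == {self.target}:
            raise InvalidInputError("no non-target cells: one-vs-rest comparison is undefined")

    def aligned_mask(self, cell_ids: Sequence[str]) -> np.ndarray:
        """Boolean target-membership mask in the order of ``cell_ids``."""
        missing = [c for c in cell_ids if c not in self.labels]
        if missing:
            raise InvalidInputError(
                f"{len(missing)} cells missing labels (first: {missing[:10]})"
            )
        return np.array([self.labels[c] == self.target for c in cell_ids], dtype=bool)

    def class_vector(self, cell_ids: Sequence[str]) -> np.ndarray:
        """Signed class vector: +1 target, -1 rest, aligned to ``cell_ids``."""
        mask = self.aligned_mask(cell_ids)
        return np.where(mask, 1, -1)


@dataclass(frozen=True)
class ConfusionPartition:
    """The four cell sets induced by a threshold on one scaled gene column.

    With target cells labelled +1 and all others -1, and membership based on
    strict comparison with ``alpha``:

    * A: target cells with value > alpha (true positives)
    * B: target cells with value <= alpha (false negatives)
    * C: non-target cells with value > alpha (false positives)
    * D: non-target cells with value <= alpha (true negatives)
    """

    values: np.ndarray
    is_target: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        is_target = np.asarray(self.is_target, dtype=bool)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "is_target", is_target)
        if values.ndim != 1 or is_target.shape != values.shape:
            raise InvalidInputError("values and labels must be aligned 1-d arrays")
        if np.any(values < -1e-12) or np.any(values > 1 + 1e-12):
            raise InvalidInputError("partition requires scaled values in [0, 1]")

    def _above(self) -> np.ndarray:
        return self.values > self.alpha

    @property
    def A(self) -> np.ndarray:
        return np.flatnonzero(self.is_target & self._above())

    @property
    def B(self) -> np.ndarray:
        return np.flatnonzero(self.is_target & ~self._above())

    @property
    def C(self) -> np.ndarray:
        return np.flatnonzero(~self.is_target & self._above())

    @property
    def D(self) -> np.ndarray:
        return np.flatnonzero(~self.is_target & ~self._above())

    @property
    def counts(self) -> tuple[int, int, int, int]:
        """(|A|, |B|, |C|, |D|)."""
        return (len(self.A), len(self.B), len(self.C), len(self.D))

    @property
    def tpr(self) -> float:
        a, b, _, _ = self.counts
        return a / (a + b) if a + b else 0.0

    @property
    def tnr(self) -> float:
        _, _, c, d = self.counts
        return d / (c + d) if c + d else 0.0


@dataclass(frozen=True)
class ThresholdResult:
    """Per-gene optimum of the threshold search plus ranking components."""

    gene_id: str
    alpha: float
    gene_split: float
    tpr: float
    tnr: float
    fc: float
    ranking_score: float
    detection_rate_in_target: float
    passed_filters: bool
    direction: str = "positive"


@dataclass(frozen=True)
class ScoringConfig:
    """Tunable parameters of the threshold search, ranking, and filters.

    grid_start/grid_end/grid_step
        inclusive threshold grid on the scaled [0, 1] axis; the default
        grid is {0, 0.01, ..., 1.00}.
    pseudo_count
        additive constant in both numerator and denominator of the fold
        change, guarding against zero denominators in sparse data.
    min_detection
        minimum fraction of relevant-cluster cells with raw expression > 0.
    min_tnr
        minimum true negative rate at the optimal threshold.
    log_fc
        report/use log2 of the pseudo-counted ratio instead of the ratio.
    """

    grid_start: float = 0.0
    grid_end: float = 1.0
    grid_step: float = 0.01
    pseudo_count: float = 0.01
    min_detection: float = 0.15
    min_tnr: float = 0.65
    log_fc: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.grid_start < self.grid_end <= 1.0):
            raise InvalidInputError("grid must satisfy 0 <= start < end <= 1")
        if self.grid_step <= 0:
            raise InvalidInputError("grid_step must be positive")
        if self.pseudo_count <= 0:
            raise InvalidInputError("pseudo_count must be positive")
        if not (0.0 <= self.min_detection <= 1.0 and 0.0 <= self.min_tnr <= 1.0):
            raise InvalidInputError("filter thresholds must lie in [0, 1]")

    def grid(self) -> np.ndarray:
        """Inclusive threshold grid, generated by integer index to avoid
        floating-point accumulation (k * step, not repeated addition)."""
        n_steps = int(round((self.grid_end - self.grid_start) / self.grid_step))
        alphas = self.grid_start + np.arange(n_steps + 1) * self.grid_step
        # guarantee the end point is included exactly even if step does not divide
        if alphas[-1] < self.grid_end - 1e-12:
            alphas = np.append(alphas, self.grid_end)
        else:
            alphas[-1] = self.grid_end
        return alphas


def min_max_scale(matrix: ExpressionMatrix) -> ScaledMatrix:
    """Scale each gene column to [0, 1] via (x - min) / (max - min).

    Constant columns (max == min) become all-zero.  Identifiers and shape
    are preserved.
    """
    values = matrix.values
    mins = values.min(axis=0)
    ptp = values.max(axis=0) - mins
    safe = np.where(ptp > 0, ptp, 1.0)
    scaled = (values - mins) / safe
    scaled[:, ptp == 0] = 0.0
    return ScaledMatrix(scaled, matrix.cell_ids, matrix.gene_ids)


def partition_at_threshold(
    gene_values: np.ndarray, is_target: np.ndarray, alpha: float
) -> ConfusionPartition:
    """Partition cells into TP/FN/FP/TN sets at threshold ``alpha``.

    Membership uses strict ``>`` for the above-threshold sets (A, C) and
    ``<=`` for the rest (B, D); a value exactly equal to ``alpha`` is
    classified negative.
    """
    gene_values = np.asarray(gene_values, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    if gene_values.shape != is_target.shape:
        raise InvalidInputError("gene values and labels have different lengths")
    return ConfusionPartition(gene_values, is_target, float(alpha))


def gene_split_score(partition: ConfusionPartition) -> float:
    """Weighted-margin score of a threshold.

    With y = +1 on target cells and -1 otherwise::

        |D| * sum_{A} y (x - alpha)   # TP margins, weighted by #TN
      + |A| * sum_{D} y (x - alpha)   # TN margins, weighted by #TP
      + |B| * sum_{C} y (x - alpha)   # FP penalty, weighted by #FN

    The false-negative set B contributes no sum of its own; sparsity-driven
    dropouts are deliberately not penalized.  Note the FP penalty vanishes
    whenever B is empty, which is the score as defined, not a bug.
    """
    v, t, a = partition.values, partition.is_target, partition.alpha
    above = v > a
    A = t & above
    B = t & ~above
    C = ~t & above
    D = ~t & ~above
    # y = +1 on A, y = -1 on D and C
    term_tp = D.sum() * np.sum(v[A] - a)
    term_tn = A.sum() * np.sum(a - v[D])
    term_fp = B.sum() * -np.sum(v[C] - a)
    return float(term_tp + term_tn + term_fp)


def _grid_scores(values: np.ndarray, is_target: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """GeneSplit at every grid point, vectorized over the grid."""
    v = values[None, :]
    a = alphas[:, None]
    above = v > a
    t = is_target[None, :]
    A = above & t
    B = ~above & t
    C = above & ~t
    D = ~above & ~t
    sum_A = np.sum(np.where(A, v - a, 0.0), axis=1)
    sum_D = np.sum(np.where(D, a - v, 0.0), axis=1)
    sum_C = np.sum(np.where(C, v - a, 0.0), axis=1)
    return (
        D.sum(axis=1) * sum_A + A.sum(axis=1) * sum_D - B.sum(axis=1) * sum_C
    )


def find_optimal_threshold(
    gene_values: np.ndarray,
    is_target: np.ndarray,
    config: ScoringConfig | None = None,
) -> tuple[float, float]:
    """Grid search for the threshold maximizing the GeneSplit score.

    Evaluates every grid point (inclusive endpoints) and returns
    ``(alpha, score)``.  Ties are broken toward the smallest alpha so the
    result is deterministic.
    """
    config = config or ScoringConfig()
    gene_values = np.asarray(gene_values, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    if gene_values.shape != is_target.shape:
        raise InvalidInputError("gene values and labels have different lengths")
    if not is_target.any() or is_target.all():
        raise InvalidInputError("both target and non-target cells are required")
    alphas = config.grid()
    scores = _grid_scores(gene_values, is_target, alphas)
    # ties (within 1e-9, absorbing float summation noise) break toward the
    # smallest alpha so the result is deterministic
    best = int(np.flatnonzero(scores >= scores.max() - 1e-9)[0])
    return float(alphas[best]), float(scores[best])


def fold_change(partition: ConfusionPartition, sigma: float = 0.01, log: bool = False) -> float:
    """Pseudo-counted ratio of mean scaled expression, target over rest.

    ``(mean(target) + sigma) / (mean(rest) + sigma)``; with ``log=True``
    the base-2 logarithm of that ratio is returned instead.
    """
    t = partition.is_target
    if not t.any() or t.all():
        raise InvalidInputError("both classes must be non-empty for fold change")
    ratio = (partition.values[t].mean() + sigma) / (partition.values[~t].mean() + sigma)
    return float(np.log2(ratio)) if log else float(ratio)


def gene_ranking_score(gene_split: float, tpr: float, tnr: float, fc: float) -> float:
    """Composite ranking score: ``gene_split * tpr * tnr * fc**2``."""
    return float(gene_split * tpr * tnr * fc * fc)


def detection_rate(raw_values: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of cells in ``mask`` with raw expression strictly above 0."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    return float(np.mean(np.asarray(raw_values)[mask] > 0))


def apply_filters(result: ThresholdResult, config: ScoringConfig | None = None) -> ThresholdResult:
    """Set ``passed_filters`` from the detection and TNR criteria."""
    config = config or ScoringConfig()
    passed = (
        result.detection_rate_in_target >= config.min_detection
        and result.tnr >= config.min_tnr
    )
    return replace(result, passed_filters=passed)


def score_gene(
    gene_id: str,
    scaled: ScaledMatrix,
    raw: ExpressionMatrix,
    labels: CellLabelVector,
    config: ScoringConfig | None = None,
    direction: str = "positive",
) -> ThresholdResult:
    """Score one gene end-to-end: threshold search, FC, ranking, filters.

    ``direction='negative'`` replaces the scaled column x by 1 - x and runs
    the identical positive pipeline; the detection filter is then evaluated
    on the *non-target* cells, since a negative marker must be detectable
    in the cells where it is present.
    """
    if direction not in ("positive", "negative"):
        raise InvalidInputError(f"unknown direction {direction!r}")
    config = config or ScoringConfig()
    values = scaled.gene_column(gene_id).copy()
    raw_values = raw.gene_column(gene_id)
    is_target = labels.aligned_mask(scaled.cell_ids)
    if direction == "negative":
        values = 1.0 - values
        det = detection_rate(raw_values, ~is_target)
    else:
        det = detection_rate(raw_values, is_target)
    alpha, split = find_optimal_threshold(values, is_target, config)
    part = partition_at_threshold(values, is_target, alpha)
    fc = fold_change(part, sigma=config.pseudo_count, log=config.log_fc)
    score = gene_ranking_score(split, part.tpr, part.tnr, fc)
    result = ThresholdResult(
        gene_id=gene_id,
        alpha=alpha,
        gene_split=split,
        tpr=part.tpr,
        tnr=part.tnr,
        fc=fc,
        ranking_score=score,
        detection_rate_in_target=det,
        passed_filters=False,
        direction=direction,
    )
    return apply_filters(result, config)


def rank_markers(
    matrix: ExpressionMatrix,
    labels: Mapping[str, str] | CellLabelVector,
    target: str | None = None,
    config: ScoringConfig | None = None,
    direction: str = "positive",
    gene_whitelist: Iterable[str] | None = None,
) -> list[ThresholdResult]:
    """Rank candidate markers of a target cell type, best first.

    Scores every gene (optionally restricted to ``gene_whitelist``), keeps
    only genes passing the detection/TNR filters, and sorts by
    ranking_score descending with ties broken by fold change descending
    and then gene identifier.  ``direction`` may be ``'positive'``,
    ``'negative'`` or ``'both'`` (both directions ranked together).
    """
    if isinstance(labels, CellLabelVector):
        label_vec = labels
    else:
        if target is None:
            raise InvalidInputError("target cell type is required")
        label_vec = CellLabelVector(labels, target)
    config = config or ScoringConfig()
    if direction == "both":
        directions = ("positive", "negative")
    elif direction in ("positive", "negative"):
        directions = (direction,)
    else:
        raise InvalidInputError(f"unknown direction {direction!r}")

    genes: Sequence[str] = matrix.gene_ids
    if gene_whitelist is not None:
        allowed = set(gene_whitelist)
        genes = [g for g in matrix.gene_ids if g in allowed]
        if not genes:
            logger.info(
                "whitelist removed every candidate gene for target %s", label_vec.target
            )
            return []
    scaled = min_max_scale(matrix)
    results = [
        score_gene(g, scaled, matrix, label_vec, config, d)
        for d in directions
        for g in genes
    ]
    # a non-positive margin score means the gene never separates the target
    # class; such genes are not markers even when they pass the filters
    kept = [r for r in results if r.passed_filters and r.ranking_score > 0]
    kept.sort(key=lambda r: (-r.ranking_score, -r.fc, r.gene_id))
    return kept


def results_to_frame(results: Sequence[ThresholdResult]) -> pd.DataFrame:
    """Tabulate ThresholdResults with a 1-based ``rank`` column."""
    rows = [
        {
            "rank": i + 1,
            "gene": r.gene_id,
            "direction": r.direction,
            "alpha": r.alpha,
            "gene_split": r.gene_split,
            "tpr": r.tpr,
            "tnr": r.tnr,
            "fc": r.fc,
            "ranking_score": r.ranking_score,
        }
        for i, r in enumerate(results)
    ]
    columns = [
        "rank", "gene", "direction", "alpha", "gene_split",
        "tpr", "tnr", "fc", "ranking_score",
    ]
    return pd.DataFrame(rows, columns=columns)
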