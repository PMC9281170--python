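"""Comparison rankers under a common scorer interface.

Each scorer ranks genes by their power to distinguish a target cluster
from the pooled remaining cells (one-vs-rest):

* ``roc`` — classification power ``|AUC - 0.5| * 2`` of the single-gene
  classifier (AUC via the rank-sum identity, midrank tie handling), so
  both directions of discrimination score highly.
* ``hypergate_f1`` — the best F1 = 2PR/(P+R) over the threshold grid,
  with precision/recall from the same strict-> confusion partition used
  by the margin scorer.
* ``fc`` — pseudo-counted mean-expression ratio, target over rest.
* ``wilcoxon`` / ``ttest`` — two-sided rank-sum and Welch t-test
  p-values, ranked lower-better.
* ``maxmargin`` — this package's own margin-based ranking, exposed under
  the same interface so benchmarks treat it like any other method.

Scorers are registered by name in ``SCORERS``; ``ranked_genes`` turns any
of them into an ordered best-first gene list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
from scipy import stats

from maxmarker.core import (
    CellLabelVector,
    ExpressionMatrix,
    InvalidInputError,
    ScoringConfig,
    min_max_scale,
    rank_markers,
)

__all__ = [
    "BaselineScore",
    "SCORERS",
    "roc_power",
    "hypergate_f1",
    "fc_score",
    "wilcoxon_score",
    "ttest_score",
    "score_all",
    "ranked_genes",
]


@dataclass(frozen=True)
class BaselineScore:
    gene_id: str
    method: str
    score: float
    rank_basis: str  # "higher-better" | "lower-better"


def _check_two_classes(is_target: np.ndarray) -> None:
    if not is_target.any() or is_target.all():
        raise InvalidInputError("both target and non-target cells are required")


def roc_power(gene_values: np.ndarray, is_target: np.ndarray) -> float:
    """Classification power ``|AUC - 0.5| * 2`` of a single-gene classifier.

    AUC is computed through the Mann-Whitney rank-sum identity with
    midranks for ties, equivalent to integrating TPR over 1 - TNR across
    all thresholds.  Power is 0 for an uninformative gene and 1 for
    perfect separation in either direction.
    """
    gene_values = np.asarray(gene_values, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    _check_two_classes(is_target)
    n_pos = int(is_target.sum())
    n_neg = is_target.size - n_pos
    ranks = stats.rankdata(gene_values)
    u = ranks[is_target].sum() - n_pos * (n_pos + 1) / 2
    auc = u / (n_pos * n_neg)
    return float(abs(auc - 0.5) * 2)


def hypergate_f1(
    gene_values: np.ndarray,
    is_target: np.ndarray,
    alpha: float | None = None,
    config: ScoringConfig | None = None,
) -> float:
    """Best F1 of the threshold classifier over the grid (or at ``alpha``).

    Precision = TP/(TP+FP) and recall = TP/(TP+FN) use the strict->
    partition; F1 is defined as 0 whenever precision + recall is 0.
    """
    config = config or ScoringConfig()
    gene_values = np.asarray(gene_values, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    _check_two_classes(is_target)
    alphas = np.array([alpha]) if alpha is not None else config.grid()
    above = gene_values[None, :] > alphas[:, None]
    tp = (above & is_target[None, :]).sum(axis=1)
    fp = (above & ~is_target[None, :]).sum(axis=1)
    fn = (~above & is_target[None, :]).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    return float(f1.max())


def fc_score(
    gene_values: np.ndarray, is_target: np.ndarray, sigma: float = 0.01
) -> float:
    """Pseudo-counted mean ratio (target + sigma) / (rest + sigma)."""
    gene_values = np.asarray(gene_values, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    _check_two_classes(is_target)
    return float(
        (gene_values[is_target].mean() + sigma)
        / (gene_values[~is_target].mean() + sigma)
    )


def _safe_p(p: float) -> float:
    # degenerate inputs (zero variance) yield NaN; map to the worst rank
    return 1.0 if not np.isfinite(p) else float(p)


def wilcoxon_score(gene_values: np.ndarray, is_target: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value, target vs rest (lower-better)."""
    gene_values = np.asarray(gene_values, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    _check_two_classes(is_target)
    pos, neg = gene_values[is_target], gene_values[~is_target]
    if np.ptp(gene_values) == 0:
        return 1.0
    return _safe_p(stats.mannwhitneyu(pos, neg, alternative="two-sided").pvalue)


def ttest_score(gene_values: np.ndarray, is_target: np.ndarray) -> float:
    """Two-sided Welch t-test p-value, target vs rest (lower-better)."""
    gene_values = np.asarray(gene_values, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    _check_two_classes(is_target)
    pos, neg = gene_values[is_target], gene_values[~is_target]
    return _safe_p(stats.ttest_ind(pos, neg, equal_var=False).pvalue)


def _score_matrix(
    matrix: ExpressionMatrix,
    labels: CellLabelVector,
    config: ScoringConfig,
    per_gene: Callable[[np.ndarray, np.ndarray], float],
    method: str,
    rank_basis: str,
    use_scaled: bool,
    whitelist: Iterable[str] | None,
) -> list[BaselineScore]:
    values = min_max_scale(matrix).values if use_scaled else matrix.values
    is_target = labels.aligned_mask(matrix.cell_ids)
    genes = matrix.gene_ids
    if whitelist is not None:
        allowed = set(whitelist)
        genes = [g for g in genes if g in allowed]
    out = []
    for g in genes:
        col = values[:, matrix.gene_index(g)]
        out.append(BaselineScore(g, method, per_gene(col, is_target), rank_basis))
    return out


def _scorer(per_gene, method, rank_basis, use_scaled):
    def scorer(matrix, labels, target=None, config=None, whitelist=None):
        if not isinstance(labels, CellLabelVector):
            labels = CellLabelVector(labels, target)
        config = config or ScoringConfig()
        return _score_matrix(
            matrix, labels, config, per_gene, method, rank_basis, use_scaled, whitelist
        )
    scorer.__name__ = f"score_{method}"
    return scorer


def _maxmargin_scorer(matrix, labels, target=None, config=None, whitelist=None):
    results = rank_markers(matrix, labels, target, config, gene_whitelist=whitelist)
    return [
        BaselineScore(r.gene_id, "maxmargin", r.ranking_score, "higher-better")
        for r in results
    ]


#: Scorer registry: name -> (matrix, labels, target, config, whitelist) -> list[BaselineScore]
SCORERS: Mapping[str, Callable[..., list[BaselineScore]]] = {
    "maxmargin": _maxmargin_scorer,
    "roc": _scorer(roc_power, "roc", "higher-better", use_scaled=True),
    "hypergate_f1": _scorer(
        lambda v, t: hypergate_f1(v, t), "hypergate_f1", "higher-better", use_scaled=True
    ),
    "fc": _scorer(fc_score, "fc", "higher-better", use_scaled=True),
    "wilcoxon": _scorer(wilcoxon_score, "wilcoxon", "lower-better", use_scaled=False),
    "ttest": _scorer(ttest_score, "ttest", "lower-better", use_scaled=False),
}


def score_all(
    matrix: ExpressionMatrix,
    labels,
    target: str | None = None,
    method: str = "maxmargin",
    config: ScoringConfig | None = None,
    whitelist: Iterable[str] | None = None,
) -> list[BaselineScore]:
    """Score every candidate gene with the named method."""
    try:
        scorer = SCORERS[method]
    except KeyError:
        raise InvalidInputError(
            f"unknown method {method!r}; available: {sorted(SCORERS)}"
        ) from None
    return scorer(matrix, labels, target, config, whitelist)


def ranked_genes(
    matrix: ExpressionMatrix,
    labels,
    target: str | None = None,
    method: str = "maxmargin",
    config: ScoringConfig | None = None,
    whitelist: Iterable[str] | None = None,
) -> list[str]:
    """Ordered best-first gene list for the named method.

    Higher-better scores sort descending, p-values ascending; ties break
    on the gene identifier for determinism.  The ``maxmargin`` method
    returns only genes passing its own filters, mirroring its marker
    table; the other methods rank every candidate gene.
    """
    scores = score_all(matrix, labels, target, method, config, whitelist)
    if not scores:
        return []
    if scores[0].rank_basis == "lower-better":
        scores.sort(key=lambda s: (s.score, s.gene_id))
    elif method == "maxmargin":
        pass  # already ordered by the full ranking-score/fc/gene key
    else:
        scores.sort(key=lambda s: (-s.score, s.gene_id))
    return [s.gene_id for s in scores]
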