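"""Unit and property tests for the margin scorer and marker ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maxmarker.core import (
    CellLabelVector,
    ExpressionMatrix,
    InvalidInputError,
    ScoringConfig,
    apply_filters,
    find_optimal_threshold,
    fold_change,
    gene_ranking_score,
    gene_split_score,
    min_max_scale,
    partition_at_threshold,
    rank_markers,
    score_gene,
    ThresholdResult,
)

TOL = 1e-9


def brute_force_threshold(values, is_target, config=None):
    """Independent oracle: evaluate the margin score cell by cell at every
    grid point and return (alpha, score) with smallest-alpha tie-break."""
    config = config or ScoringConfig()
    best_alpha, best_score = None, -np.inf
    n_steps = int(round((config.grid_end - config.grid_start) / config.grid_step))
    for k in range(n_steps + 1):
        alpha = config.grid_start + k * config.grid_step
        A = [v for v, t in zip(values, is_target) if t and v > alpha]
        B = [v for v, t in zip(values, is_target) if t and v <= alpha]
        C = [v for v, t in zip(values, is_target) if not t and v > alpha]
        D = [v for v, t in zip(values, is_target) if not t and v <= alpha]
        score = (
            len(D) * sum(v - alpha for v in A)
            + len(A) * sum(-(v - alpha) for v in D)
            + len(B) * sum(-(v - alpha) for v in C)
        )
        if score > best_score + TOL:
            best_alpha, best_score = alpha, score
    return best_alpha, best_score


class TestMinMaxScale:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ([2.0, 4.0, 6.0], [0.0, 0.5, 1.0]),
            ([5.0, 5.0, 5.0], [0.0, 0.0, 0.0]),
            ([0.0, 1.0, 3.0, 4.0], [0.0, 0.25, 0.75, 1.0]),
        ],
    )
    def test_column_scaling(self, column, expected):
        n = len(column)
        mat = ExpressionMatrix(
            np.array(column).reshape(-1, 1),
            tuple(f"c{i}" for i in range(n)),
            ("g",),
        )
        assert np.allclose(min_max_scale(mat).values[:, 0], expected, atol=TOL)

    def test_nonconstant_columns_attain_bounds(self):
        rng = np.random.default_rng(0)
        mat = ExpressionMatrix(
            rng.random((10, 5)) * 7, tuple(f"c{i}" for i in range(10)), tuple(f"g{j}" for j in range(5))
        )
        scaled = min_max_scale(mat).values
        assert np.allclose(scaled.min(axis=0), 0) and np.allclose(scaled.max(axis=0), 1)

    def test_rejects_negative_values(self):
        with pytest.raises(InvalidInputError):
            ExpressionMatrix(np.array([[-1.0], [1.0]]), ("a", "b"), ("g",))


class TestPartition:
    def test_perfect_separation(self):
        p = partition_at_threshold(
            np.array([0.9, 0.8, 0.1, 0.2]), np.array([True, True, False, False]), 0.5
        )
        assert p.counts == (2, 0, 0, 2)

    def test_mixed_partition(self):
        p = partition_at_threshold(
            np.array([0.9, 0.3, 0.6, 0.2]), np.array([True, True, False, False]), 0.5
        )
        assert p.counts == (1, 1, 1, 1)

    def test_boundary_value_is_classified_negative(self):
        p = partition_at_threshold(np.array([1.0, 0.0]), np.array([True, False]), 1.0)
        assert list(p.B) == [0]  # value == alpha goes below the threshold

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(InvalidInputError):
            partition_at_threshold(np.array([0.1, 0.2]), np.array([True]), 0.5)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=30),
        st.floats(0, 1),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_partition_conserves_cells(self, values, alpha, seed):
        rng = np.random.default_rng(seed)
        is_target = rng.random(len(values)) < 0.5
        p = partition_at_threshold(np.array(values), is_target, alpha)
        assert sum(p.counts) == len(values)


class TestGeneSplit:
    def test_separated_toy(self):
        p = partition_at_threshold(
            np.array([1.0, 1.0, 0.0, 0.0, 0.0]),
            np.array([True, True, False, False, False]),
            0.5,
        )
        assert gene_split_score(p) == pytest.approx(6.0, abs=TOL)

    def test_all_cells_below_threshold_scores_zero(self):
        p = partition_at_threshold(
            np.array([0.1, 0.2, 0.3]), np.array([True, False, True]), 0.9
        )
        assert gene_split_score(p) == pytest.approx(0.0, abs=TOL)

    def test_fp_penalty_zeroed_without_false_negatives(self):
        # |B| weights the FP sum, so with B empty the FP term vanishes
        p = partition_at_threshold(
            np.array([0.9, 0.6, 0.1]), np.array([True, False, False]), 0.5
        )
        assert gene_split_score(p) == pytest.approx(0.8, abs=TOL)


class TestFindOptimalThreshold:
    def test_separable_toy_tie_breaks_to_smallest_alpha(self):
        v = np.array([1.0, 1.0, 0.0, 0.0, 0.0])
        t = np.array([True, True, False, False, False])
        alpha, score = find_optimal_threshold(v, t)
        assert alpha == pytest.approx(0.0) and score == pytest.approx(6.0, abs=TOL)

    def test_constant_zero_gene_scores_zero(self):
        v = np.zeros(6)
        t = np.array([True, True, False, False, False, False])
        _, score = find_optimal_threshold(v, t)
        assert score == pytest.approx(0.0, abs=TOL)

    def test_inverted_toy_peaks_at_one(self):
        v = np.array([0.0, 0.0, 1.0, 1.0, 1.0])
        t = np.array([True, True, False, False, False])
        alpha, score = find_optimal_threshold(v, t)
        assert alpha == pytest.approx(1.0) and score == pytest.approx(0.0, abs=TOL)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            find_optimal_threshold(np.array([0.1, 0.9]), np.array([True, True]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 21)
        values = np.round(rng.random(n), 3)
        is_target = rng.random(n) < 0.5
        if not is_target.any() or is_target.all():
            is_target[0], is_target[-1] = True, False
        alpha, score = find_optimal_threshold(values, is_target)
        oracle_alpha, oracle_score = brute_force_threshold(values, is_target)
        assert alpha == pytest.approx(oracle_alpha, abs=TOL)
        assert score == pytest.approx(oracle_score, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_grid_refinement_never_decreases_maximum(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.random(15)
        is_target = np.arange(15) < 5
        _, coarse = find_optimal_threshold(values, is_target, ScoringConfig(grid_step=0.02))
        _, fine = find_optimal_threshold(values, is_target, ScoringConfig(grid_step=0.01))
        assert fine >= coarse - TOL


class TestFoldChange:
    def test_perfect_marker_fc(self):
        p = partition_at_threshold(
            np.array([1.0, 1.0, 0.0, 0.0]), np.array([True, True, False, False]), 0.5
        )
        assert fold_change(p, sigma=0.01) == pytest.approx(101.0, abs=1e-9)

    @pytest.mark.parametrize("mean", [0.2, 0.5, 1.0])
    def test_equal_means_give_unity(self, mean):
        p = partition_at_threshold(
            np.full(4, mean), np.array([True, True, False, False]), 0.5
        )
        assert fold_change(p, sigma=0.01) == pytest.approx(1.0, abs=TOL)

    def test_inverted_marker_fc(self):
        p = partition_at_threshold(
            np.array([0.0, 0.0, 1.0, 1.0]), np.array([True, True, False, False]), 0.5
        )
        assert fold_change(p, sigma=0.01) == pytest.approx(0.01 / 1.01, abs=1e-9)

    def test_log_variant_is_log2_of_ratio(self):
        p = partition_at_threshold(
            np.array([1.0, 1.0, 0.0, 0.0]), np.array([True, True, False, False]), 0.5
        )
        assert fold_change(p, sigma=0.01, log=True) == pytest.approx(np.log2(101.0))


class TestRankingScore:
    @pytest.mark.parametrize(
        "split,tpr,tnr,fc,expected",
        [
            (6.0, 1.0, 1.0, 101.0, 61206.0),
            (5.0, 0.0, 1.0, 10.0, 0.0),
            (0.8, 1.0, 0.5, 2.0, 1.6),
        ],
    )
    def test_hand_computed_scores(self, split, tpr, tnr, fc, expected):
        assert gene_ranking_score(split, tpr, tnr, fc) == pytest.approx(expected, abs=TOL)


class TestFilters:
    def _result(self, detection, tnr):
        return ThresholdResult(
            gene_id="g", alpha=0.5, gene_split=1.0, tpr=1.0, tnr=tnr, fc=2.0,
            ranking_score=1.0, detection_rate_in_target=detection,
            passed_filters=False,
        )

    @pytest.mark.parametrize(
        "detection,tnr,kept",
        [(0.10, 0.9, False), (0.5, 0.60, False), (0.5, 0.9, True), (0.15, 0.65, True)],
    )
    def test_detection_and_tnr_thresholds(self, detection, tnr, kept):
        assert apply_filters(self._result(detection, tnr)).passed_filters is kept


class TestScoreGene:
    def test_perfect_marker(self, toy_matrix, toy_label_vector):
        scaled = min_max_scale(toy_matrix)
        r = score_gene("g1", scaled, toy_matrix, toy_label_vector)
        assert r.tpr == 1.0 and r.tnr == 1.0 and r.passed_filters

    def test_negative_direction_equals_inverted_positive(self, toy_matrix, toy_label_vector):
        scaled = min_max_scale(toy_matrix)
        neg = score_gene("g1", scaled, toy_matrix, toy_label_vector, direction="negative")
        inverted = ExpressionMatrix(
            1.0 - scaled.values, toy_matrix.cell_ids, toy_matrix.gene_ids
        )
        inv_scaled = min_max_scale(inverted)
        pos = score_gene("g1", inv_scaled, inverted, toy_label_vector)
        assert neg.ranking_score == pos.ranking_score
        assert neg.alpha == pos.alpha

    def test_unknown_gene_raises(self, toy_matrix, toy_label_vector):
        with pytest.raises(KeyError):
            score_gene("absent", min_max_scale(toy_matrix), toy_matrix, toy_label_vector)

    def test_label_permutation_degrades_planted_marker(self, toy_matrix):
        rng = np.random.default_rng(42)
        labels = ["A", "A", "B", "B", "B"]
        scaled = min_max_scale(toy_matrix)
        ref = score_gene(
            "g1", scaled, toy_matrix, CellLabelVector(dict(zip(toy_matrix.cell_ids, labels)), "A")
        ).ranking_score
        exceed = 0
        for _ in range(100):
            perm = rng.permutation(labels)
            score = score_gene(
                "g1", scaled, toy_matrix,
                CellLabelVector(dict(zip(toy_matrix.cell_ids, perm)), "A"),
            ).ranking_score
            if score >= ref:
                exceed += 1
        # identity permutations occur by chance; anything else scores lower
        assert exceed <= 15


class TestRankMarkers:
    def test_only_true_marker_survives(self, toy_matrix, toy_labels):
        ranked = rank_markers(toy_matrix, toy_labels, "A")
        assert [r.gene_id for r in ranked] == ["g1"]

    def test_whitelist_can_remove_all_markers(self, toy_matrix, toy_labels):
        assert rank_markers(toy_matrix, toy_labels, "A", gene_whitelist={"g2"}) == []

    def test_planted_markers_rank_top5(self, golden_dataset):
        for target, genes in golden_dataset.truth.items():
            ranked = rank_markers(golden_dataset.matrix, golden_dataset.labels, target)
            top5 = {r.gene_id for r in ranked[:5]}
            assert set(genes) <= top5

    def test_scale_and_shift_invariance(self, toy_matrix, toy_labels):
        ref = rank_markers(toy_matrix, toy_labels, "A")
        for transform in (lambda v: v * 10, lambda v: v + 3):
            values = toy_matrix.values.copy()
            values[:, 0] = transform(values[:, 0])
            moved = ExpressionMatrix(values, toy_matrix.cell_ids, toy_matrix.gene_ids)
            got = rank_markers(moved, toy_labels, "A")
            assert [(r.gene_id, r.alpha) for r in got] == [(r.gene_id, r.alpha) for r in ref]
            assert np.allclose(
                [r.ranking_score for r in got], [r.ranking_score for r in ref], atol=TOL
            )

    def test_perfect_marker_ceiling(self):
        # a 0/1 perfect marker outscores any other gene with the same class sizes
        rng = np.random.default_rng(3)
        n_pos, n_neg = 4, 8
        values = np.column_stack(
            [np.r_[np.ones(n_pos), np.zeros(n_neg)]]
            + [rng.random(n_pos + n_neg) for _ in range(6)]
        )
        mat = ExpressionMatrix(
            values, tuple(f"c{i}" for i in range(n_pos + n_neg)),
            tuple(f"g{j}" for j in range(7)),
        )
        labels = {f"c{i}": ("A" if i < n_pos else "B") for i in range(n_pos + n_neg)}
        ranked = rank_markers(mat, labels, "A", ScoringConfig(min_detection=0.0, min_tnr=0.0))
        assert ranked[0].gene_id == "g0"
        assert ranked[0].tpr == 1.0 and ranked[0].tnr == 1.0
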