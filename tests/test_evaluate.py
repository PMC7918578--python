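"""Evaluation metrics against hand arithmetic and brute-force recounts."""

import numpy as np
import pytest

from surgspeech.evaluate import (
    cohen_kappa,
    confusion_matrix,
    error_rates,
    evaluate_predictions,
    prf_scores,
    timeline_report,
)


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        y = [1, 2, 3, 8]
        cm = confusion_matrix(y, y)
        assert cm.sum() == 4
        assert np.trace(cm) == 4

    def test_cell_placement(self):
        cm = confusion_matrix([2, 2], [2, 4])
        assert cm[1, 1] == 1 and cm[1, 3] == 1
        assert cm.sum() == 2

    def test_empty_input(self):
        assert confusion_matrix([], []).sum() == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_matrix([1], [1, 2])

    def test_labels_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([9], [1])


class TestPrfScores:
    def test_hand_arithmetic_oracle(self):
        scores = prf_scores(np.array([[1, 1], [0, 2]]))
        assert scores["precision"][0] == pytest.approx(1.0)
        assert scores["recall"][0] == pytest.approx(0.5)
        assert scores["f1"][0] == pytest.approx(2 / 3)
        assert scores["precision"][1] == pytest.approx(2 / 3)
        assert scores["recall"][1] == pytest.approx(1.0)
        assert scores["f1"][1] == pytest.approx(0.8)
        assert scores["macro_f1"] == pytest.approx(11 / 15)

    def test_perfect_diagonal(self):
        scores = prf_scores(np.diag([3, 2, 5]))
        assert scores["macro_f1"] == 1.0
        assert (scores["precision"] == 1).all()

    def test_absent_class_excluded_from_macro(self):
        cm = np.array([[2, 0, 0], [0, 3, 0], [0, 0, 0]])
        scores = prf_scores(cm)
        assert scores["macro_f1"] == 1.0  # class 3 absent everywhere

    def test_degenerate_class_flagged(self):
        cm = np.array([[0, 2], [0, 3]])  # class 1 never predicted
        scores = prf_scores(cm)
        assert 1 in scores["degenerate_classes"]
        assert scores["f1"][0] == 0.0


class TestErrorRates:
    def test_hand_arithmetic_oracle(self):
        per_phase, average, total = error_rates(np.array([[1, 1], [0, 2]]))
        assert per_phase[0] == pytest.approx(0.5)
        assert per_phase[1] == pytest.approx(0.0)
        assert average == pytest.approx(0.25)
        assert total == pytest.approx(0.25)

    def test_diagonal_is_error_free(self):
        per_phase, average, total = error_rates(np.diag([4, 4]))
        assert np.nansum(per_phase) == 0 and average == 0 and total == 0

    def test_fully_misclassified_row(self):
        per_phase, _, _ = error_rates(np.array([[0, 3], [0, 1]]))
        assert per_phase[0] == 1.0

    def test_total_error_plus_accuracy_is_one(self, rng):
        for _ in range(10):
            y_true = rng.integers(1, 9, 40)
            y_pred = rng.integers(1, 9, 40)
            report = evaluate_predictions(y_true, y_pred)
            assert report.total_error + report.accuracy == 1.0


class TestCohenKappa:
    def test_identical_labels(self):
        assert cohen_kappa([1, 2, 3], [1, 2, 3]) == 1.0

    def test_chance_level_agreement(self):
        # agreement table [[1,1],[1,1]]: p_o = 0.5 = p_e -> kappa = 0
        assert cohen_kappa([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(0.0)

    def test_hand_arithmetic_oracle(self):
        # p_o = 0.75, p_e = 0.5 -> kappa = 0.5
        assert cohen_kappa([1, 1, 2, 2], [1, 2, 2, 2]) == pytest.approx(0.5)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(20):
            a = rng.integers(1, 5, 30)
            b = rng.integers(1, 5, 30)
            assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa([1], [1, 2])
        with pytest.raises(ValueError):
            cohen_kappa([], [])


class TestTimelineReport:
    def test_perfect_monotone_prediction(self):
        truth = [1, 2, 3, 4]
        triples, disruptions = timeline_report(truth, truth)
        assert disruptions == 0
        assert triples == [(i, p, p) for i, p in enumerate(truth)]

    def test_backward_jump_counted(self):
        _, disruptions = timeline_report([1, 2, 3], [1, 2, 1])
        assert disruptions == 1

    def test_extra_phase_ignored_by_rule(self):
        _, disruptions = timeline_report([1, 2, 3], [1, 8, 2])
        assert disruptions == 0

    def test_return_after_conversation_counts(self):
        # 1 -> 2 -> 8 -> 1: the final 1 is below the earlier maximum 2
        _, disruptions = timeline_report([1, 2, 8, 1], [1, 2, 8, 1])
        assert disruptions == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            timeline_report([1, 2], [1])


class TestBruteForceRecount:
    def test_scores_match_independent_recount(self, rng):
        """Oracle: recount P/R/F1 and error rates from raw label pairs on
        100 random instances."""
        for _ in range(100):
            n = int(rng.integers(5, 60))
            y_true = rng.integers(1, 9, n)
            y_pred = rng.integers(1, 9, n)
            report = evaluate_predictions(y_true, y_pred)
            f1s = []
            for c in range(1, 9):
                tp = int(np.sum((y_true == c) & (y_pred == c)))
                fp = int(np.sum((y_true != c) & (y_pred == c)))
                fn = int(np.sum((y_true == c) & (y_pred != c)))
                p = tp / (tp + fp) if tp + fp else 0.0
                r = tp / (tp + fn) if tp + fn else 0.0
                f1 = 2 * p * r / (p + r) if p + r else 0.0
                assert report.precision[c - 1] == pytest.approx(p)
                assert report.recall[c - 1] == pytest.approx(r)
                if np.any(y_true == c):
                    f1s.append(f1)
                    assert report.per_phase_error[c - 1] == pytest.approx(
                        1 - tp / np.sum(y_true == c)
                    )
            assert report.macro_f1 == pytest.approx(np.mean(f1s))
            assert report.total_error == pytest.approx(np.mean(y_true != y_pred))

    def test_macro_f1_invariant_to_relabeling(self, rng):
        y_true = rng.integers(1, 9, 50)
        y_pred = rng.integers(1, 9, 50)
        perm = rng.permutation(np.arange(1, 9))
        mapped = {old: int(new) for old, new in zip(range(1, 9), perm)}
        r1 = evaluate_predictions(y_true, y_pred)
        r2 = evaluate_predictions(
            [mapped[v] for v in y_true], [mapped[v] for v in y_pred]
        )
        assert r1.macro_f1 == pytest.approx(r2.macro_f1)
        assert r1.accuracy == pytest.approx(r2.accuracy)
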