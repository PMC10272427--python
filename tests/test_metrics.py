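"""Weighted multi-class metrics against brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from gabnet.metrics import (
    ConfusionMatrix,
    accuracy,
    compute_report,
    confusion_matrix,
    per_class_counts,
    weighted_auc,
    weighted_f1,
    weighted_metric,
)

NAMES4 = ["CNV", "DME", "DRUSEN", "NORMAL"]


def random_cm(rng, n=4, lam=40):
    return ConfusionMatrix(rng.poisson(lam, size=(n, n)) + 1, [str(i) for i in range(n)])


def binarized_counts(cm, i):
    """Brute-force one-vs-rest counting from expanded label pairs."""
    pairs = [
        (a, p)
        for a in range(cm.n_classes)
        for p in range(cm.n_classes)
        for _ in range(cm.counts[a, p])
    ]
    tp = sum(1 for a, p in pairs if a == i and p == i)
    fp = sum(1 for a, p in pairs if a != i and p == i)
    fn = sum(1 for a, p in pairs if a == i and p != i)
    tn = sum(1 for a, p in pairs if a != i and p != i)
    return tp, fp, fn, tn


class TestConfusionMatrix:
    def test_perfect_diagonal(self):
        cm = confusion_matrix([0, 1, 2, 3], [0, 1, 2, 3], 4)
        assert np.array_equal(cm.counts, np.eye(4, dtype=int))

    def test_single_off_diagonal_cell(self):
        cm = confusion_matrix([0, 0], [1, 1], 4)
        assert cm.counts[0, 1] == 2 and cm.counts.sum() == 2

    def test_matches_pairwise_counting(self, rng):
        y_true = rng.integers(0, 4, size=500)
        y_pred = rng.integers(0, 4, size=500)
        cm = confusion_matrix(y_true, y_pred, 4)
        for i in range(4):
            for j in range(4):
                assert cm.counts[i, j] == int(np.sum((y_true == i) & (y_pred == j)))

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 4], [0, 0], 4)


class TestPerClassCounts:
    def test_identity_matrix_counts(self):
        cm = ConfusionMatrix(np.diag([250] * 4), NAMES4)
        c = per_class_counts(cm, 0)
        assert (c.tp, c.fp, c.fn, c.tn) == (250, 0, 0, 750)
        assert c.support == 250

    def test_single_cell(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 1] = 5
        c = per_class_counts(ConfusionMatrix(counts, NAMES4), 0)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 5, 0)

    def test_matches_binarized_oracle(self, rng):
        for _ in range(20):
            cm = random_cm(rng)
            for i in range(4):
                c = per_class_counts(cm, i)
                assert (c.tp, c.fp, c.fn, c.tn) == binarized_counts(cm, i)

    def test_counts_partition_total(self, rng):
        for _ in range(200):
            cm = random_cm(rng, n=int(rng.integers(2, 6)))
            for i in range(cm.n_classes):
                c = per_class_counts(cm, i)
                assert c.tp + c.fp + c.fn + c.tn == cm.total


class TestWeightedMetrics:
    def test_identity_is_perfect(self):
        cm = ConfusionMatrix(np.diag([9, 5, 3, 7]), NAMES4)
        assert accuracy(cm) == 1.0
        for kind in ("recall", "precision", "specificity"):
            assert weighted_metric(cm, kind) == 1.0
        assert weighted_f1(cm) == 1.0

    def test_all_predicted_one_class_equal_support(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[:, 0] = 10
        assert accuracy(ConfusionMatrix(counts, NAMES4)) == 0.25

    def test_perfect_inversion_recall_zero(self):
        cm = ConfusionMatrix([[0, 5], [5, 0]], ["a", "b"])
        assert weighted_metric(cm, "recall") == 0.0

    def test_zero_over_zero_defined_as_zero_with_warning(self):
        # class "b" never predicted: precision_b = 0/0
        cm = ConfusionMatrix([[5, 0], [5, 0]], ["a", "b"])
        with pytest.warns(UserWarning, match="precision"):
            assert weighted_metric(cm, "precision") == pytest.approx(0.25)

    def test_matches_hand_rolled_weighted_sums(self, rng):
        for _ in range(50):
            cm = random_cm(rng)
            total_support = cm.counts.sum()
            for kind, num, den in (
                ("recall", lambda c: c.tp, lambda c: c.tp + c.fn),
                ("precision", lambda c: c.tp, lambda c: c.tp + c.fp),
                ("specificity", lambda c: c.tn, lambda c: c.tn + c.fp),
            ):
                expected = sum(
                    (num(c) / den(c)) * c.support
                    for c in (per_class_counts(cm, i) for i in range(4))
                ) / total_support
                assert weighted_metric(cm, kind) == pytest.approx(expected, abs=1e-12)

    def test_weighted_recall_equals_accuracy_identity(self, rng):
        """Algebraic identity: sum_i TP_i / sum_i support_i == trace/total."""
        for _ in range(200):
            cm = random_cm(rng, n=int(rng.integers(2, 7)))
            assert weighted_metric(cm, "recall") == pytest.approx(accuracy(cm), abs=1e-12)

    def test_scale_invariance(self, rng):
        cm = random_cm(rng)
        scaled = ConfusionMatrix(cm.counts * 7, cm.class_names)
        for kind in ("recall", "precision", "specificity"):
            assert weighted_metric(cm, kind) == pytest.approx(
                weighted_metric(scaled, kind), abs=1e-12
            )
        assert weighted_f1(cm) == pytest.approx(weighted_f1(scaled), abs=1e-12)

    def test_f1_is_harmonic_mean_of_weighted_p_and_r(self, rng):
        for _ in range(20):
            cm = random_cm(rng)
            p = weighted_metric(cm, "precision")
            r = weighted_metric(cm, "recall")
            assert weighted_f1(cm) == pytest.approx(2 * p * r / (p + r), abs=1e-12)

    def test_f1_fixed_point_when_p_equals_r(self):
        cm = ConfusionMatrix(np.full((3, 3), 5), ["a", "b", "c"])  # symmetric
        p = weighted_metric(cm, "precision")
        assert weighted_f1(cm) == pytest.approx(p, abs=1e-12)

    def test_per_class_f1_flag_matches_sklearn(self, rng):
        from sklearn.metrics import f1_score

        y_true = rng.integers(0, 4, size=300)
        y_pred = rng.integers(0, 4, size=300)
        cm = confusion_matrix(y_true, y_pred, 4)
        ours = weighted_f1(cm, from_per_class=True)
        assert ours == pytest.approx(f1_score(y_true, y_pred, average="weighted"), abs=1e-12)


def auc_pair_counting(pos_scores, neg_scores):
    """Mann-Whitney oracle: P(pos > neg) + 0.5 P(tie)."""
    wins = ties = 0
    for p in pos_scores:
        for q in neg_scores:
            wins += p > q
            ties += p == q
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))


class TestWeightedAuc:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        assert weighted_auc(y, scores) == 1.0

    def test_identical_scores_give_half(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        scores = np.ones((6, 3))
        assert weighted_auc(y, scores) == pytest.approx(0.5)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(10):
            y = rng.integers(0, 4, size=50)
            scores = np.round(rng.random((50, 4)), 2)  # ties occur
            expected_terms = []
            supports = []
            for i in range(4):
                pos = scores[y == i, i]
                neg = scores[y != i, i]
                if len(pos) == 0 or len(neg) == 0:
                    continue
                expected_terms.append(auc_pair_counting(pos, neg))
                supports.append(len(pos))
            expected = np.dot(expected_terms, supports) / np.sum(supports)
            assert weighted_auc(y, scores) == pytest.approx(expected, abs=1e-9)

    def test_absent_class_excluded_with_warning(self, rng):
        y = np.array([0, 0, 1, 1])  # class 2 absent
        scores = rng.random((4, 3))
        with pytest.warns(UserWarning, match="excluded"):
            val = weighted_auc(y, scores)
        assert 0.0 <= val <= 1.0

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 3, size=60)
        scores = rng.random((60, 3))
        a = weighted_auc(y, scores)
        b = weighted_auc(y, np.exp(5 * scores))
        assert a == pytest.approx(b, abs=1e-12)


class TestReport:
    def test_report_consistent_with_module_functions(self, rng):
        y_true = rng.integers(0, 4, size=200)
        y_pred = rng.integers(0, 4, size=200)
        scores = rng.random((200, 4))
        rep = compute_report(y_true, y_pred, scores, class_names=NAMES4)
        cm = confusion_matrix(y_true, y_pred, 4, NAMES4)
        assert rep.accuracy == pytest.approx(accuracy(cm))
        assert rep.recall == pytest.approx(weighted_metric(cm, "recall"))
        assert rep.f1 == pytest.approx(weighted_f1(cm))
        assert rep.auc == pytest.approx(weighted_auc(y_true, scores))
        assert np.array_equal(np.array(rep.confusion), cm.counts)

    def test_serialization_roundtrip(self, rng, tmp_path):
        import json

        y = rng.integers(0, 4, size=50)
        rep = compute_report(y, y, class_names=NAMES4)
        text = rep.to_json(tmp_path / "r.json")
        loaded = json.loads(text)
        assert loaded["accuracy"] == 1.0
        rep.to_csv(tmp_path / "r.csv")
        assert (tmp_path / "r.csv").read_text().startswith("metric,value")
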