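"""Metrics, stratified reports, McNemar, similarity baseline, screening."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn import metrics as skm

from subport.evaluation import (
    BaselineConfig,
    binary_metrics,
    confidence_bins,
    confusion_matrix_table,
    mcnemar_test,
    screening_projection,
    similarity_baseline,
    stratified_report,
)
from subport.records import InteractionPair, Label, Provenance, TransporterRecord


def positive(t, m):
    return InteractionPair(t, m, Label.POSITIVE, Provenance.GO)


class FakeIdentity:
    def __init__(self, values):
        self._values = values

    def known_ids(self):
        ids = set()
        for a, b in self._values:
            ids |= {a, b}
        return sorted(ids)

    def identity(self, a, b):
        if a == b:
            return 100.0
        key = (a, b) if (a, b) in self._values else (b, a)
        return self._values[key]


class TestBinaryMetrics:
    def test_perfect_scores(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([1.0, 1.0, 0.0, 0.0])
        m = binary_metrics(labels, scores)
        assert (m.accuracy, m.mcc, m.roc_auc) == (1.0, 1.0, 1.0)

    def test_hand_computed_confusion(self):
        """TP=4, TN=2, FP=1, FN=1 -> MCC = 7/sqrt(5*5*3*3) = 7/15."""
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0])
        scores = np.array([0.9, 0.9, 0.9, 0.9, 0.1, 0.9, 0.1, 0.1])
        m = binary_metrics(labels, scores)
        assert m.mcc == pytest.approx(7 / math.sqrt(225))
        assert m.precision == pytest.approx(4 / 5)
        assert m.recall == pytest.approx(4 / 5)

    def test_always_negative_on_3_to_1_imbalance(self):
        """A constant negative predictor scores 75% accuracy at 3:1."""
        labels = np.array([0] * 300 + [1] * 100)
        scores = np.zeros(400)
        assert binary_metrics(labels, scores).accuracy == 0.75

    def test_invalid_labels_error(self):
        with pytest.raises(ValueError, match="0/1"):
            binary_metrics(np.array([0, 2]), np.array([0.1, 0.9]))

    def test_oracle_equivalence_on_random_instances(self):
        """Agreement with the scikit-learn reference on 1,000 random draws."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(5, 60))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.random(n).round(2)  # rounded -> exercises tie handling
            m = binary_metrics(labels, scores)
            predicted = (scores > 0.5).astype(int)
            assert m.accuracy == pytest.approx(skm.accuracy_score(labels, predicted))
            assert m.precision == pytest.approx(
                skm.precision_score(labels, predicted, zero_division=0)
            )
            assert m.recall == pytest.approx(
                skm.recall_score(labels, predicted, zero_division=0)
            )
            assert m.mcc == pytest.approx(skm.matthews_corrcoef(labels, predicted), abs=1e-12)
            assert m.roc_auc == pytest.approx(skm.roc_auc_score(labels, scores))

    def test_auc_equals_mann_whitney_normalization(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, size=200)
        labels[:2] = [0, 1]
        scores = rng.permutation(np.linspace(0, 1, 200))  # tie-free
        pos, neg = scores[labels == 1], scores[labels == 0]
        u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert binary_metrics(labels, scores).roc_auc == pytest.approx(
            u / (len(pos) * len(neg))
        )


class TestStratifiedReport:
    def test_single_stratum_equals_overall(self):
        labels = np.array([1, 0, 1, 0])
        scores = np.array([0.9, 0.2, 0.8, 0.6])
        ann = pd.DataFrame({"domain": ["Bacteria"] * 4})
        report = stratified_report(labels, scores, ann, "domain")
        assert len(report.strata) == 1
        assert report.strata[0]["metrics"].as_dict() == report.overall.as_dict()

    def test_stratum_counts_conserved(self):
        rng = np.random.default_rng(2)
        n = 60
        labels = rng.integers(0, 2, size=n)
        scores = rng.random(n)
        ann = pd.DataFrame({"identity": rng.uniform(0, 100, size=n)})
        report = stratified_report(
            labels, scores, ann, "identity", bin_edges=(0, 40, 50, 60, 70, 80, 90, 100)
        )
        assert sum(s["n"] for s in report.strata) == n

    def test_signal_trend_across_identity_bins(self):
        """Scores degrade in low-identity bins -> MCC rises from the lowest
        to the highest bin, as the report must surface."""
        rng = np.random.default_rng(3)
        rows, labels, scores = [], [], []
        for identity, flip in ((20.0, 0.4), (95.0, 0.0)):
            for _ in range(200):
                y = int(rng.random() < 0.5)
                correct = rng.random() >= flip
                s = (0.9 if y else 0.1) if correct else (0.1 if y else 0.9)
                rows.append(identity)
                labels.append(y)
                scores.append(s)
        report = stratified_report(
            np.array(labels),
            np.array(scores),
            pd.DataFrame({"identity": rows}),
            "identity",
            bin_edges=(0, 40, 90, 100),
        )
        populated = [s for s in report.strata if s["n"] > 0]
        assert populated[0]["metrics"].mcc < populated[-1]["metrics"].mcc

    def test_empty_stratum_reported_with_null_metrics(self):
        labels = np.array([1, 0])
        scores = np.array([0.9, 0.1])
        ann = pd.DataFrame({"identity": [95.0, 96.0]})
        report = stratified_report(
            labels, scores, ann, "identity", bin_edges=(0, 40, 90, 100)
        )
        assert report.strata[0]["n"] == 0 and report.strata[0]["metrics"] is None


class TestConfidenceBins:
    def test_all_extreme_scores(self):
        frac, acc_conf, _ = confidence_bins(
            np.array([0.0, 1.0, 1.0, 0.0]), np.array([0, 1, 1, 0])
        )
        assert frac == 1.0 and acc_conf == 1.0

    def test_all_midrange_scores(self):
        frac, _, acc_unc = confidence_bins(np.array([0.5, 0.5]), np.array([0, 1]))
        assert frac == 0.0 and acc_unc == 0.5

    def test_hand_counted_mixed_vector(self):
        scores = np.array([0.05, 0.95, 0.45, 0.55, 0.39, 0.61, 0.5, 0.99, 0.01, 0.41])
        labels = np.array([0, 1, 1, 0, 0, 1, 1, 0, 0, 1])
        frac, acc_conf, acc_unc = confidence_bins(scores, labels)
        # confident: 0.05, 0.95, 0.39, 0.61, 0.99, 0.01 -> 6/10
        assert frac == pytest.approx(0.6)
        # confident correct: all but 0.99 (label 0, predicted 1) -> 5/6
        assert acc_conf == pytest.approx(5 / 6)
        # uncertain: 0.45(1,p0 wrong), 0.55(0,p1 wrong), 0.5(1,p0 wrong), 0.41(1,p0 wrong) -> 0/4
        assert acc_unc == pytest.approx(0.0)

    def test_invalid_bounds_error(self):
        with pytest.raises(ValueError, match="low"):
            confidence_bins(np.array([0.5]), np.array([1]), low=0.6, high=0.4)


class TestMcNemar:
    def test_identical_classifiers(self):
        v = np.array([1, 0, 1, 1, 0])
        assert mcnemar_test(v, v) == 1.0

    def test_exact_binomial_10_vs_2(self):
        """Discordant 10 vs 2 -> two-sided exact binomial p ~= 0.0386."""
        a = np.array([1] * 10 + [0] * 2 + [1] * 5)
        b = np.array([0] * 10 + [1] * 2 + [1] * 5)
        assert mcnemar_test(a, b) == pytest.approx(0.03857, abs=1e-4)

    def test_zero_discordant(self):
        assert mcnemar_test(np.array([1, 0]), np.array([1, 0])) == 1.0

    def test_chi_square_branch_matches_formula(self):
        a = np.concatenate([np.ones(30), np.zeros(10), np.ones(5)])
        b = np.concatenate([np.zeros(30), np.ones(10), np.ones(5)])
        statistic = (abs(30 - 10) - 1) ** 2 / 40
        assert mcnemar_test(a, b) == pytest.approx(float(stats.chi2.sf(statistic, 1)))

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError, match="paired"):
            mcnemar_test(np.array([1]), np.array([1, 0]))


class TestSimilarityBaseline:
    def test_identical_twin_recovers_exact_set(self):
        train_pairs = [positive("TR1", "A"), positive("TR1", "B"), positive("TR2", "C")]
        test_recs = [TransporterRecord("TE1", "ACDEFGHIKL")]
        test_pos = [positive("TE1", "A"), positive("TE1", "B")]
        ident = FakeIdentity({("TE1", "TR1"): 100.0, ("TE1", "TR2"): 20.0})
        predictions, m = similarity_baseline(
            test_recs, test_pos, train_pairs, ident, BaselineConfig(k=1)
        )
        assert predictions["TE1"] == {"A", "B"}
        assert m["precision"] == m["recall"] == m["accuracy"] == 1.0

    def test_k_equals_all_predicts_union(self):
        train_pairs = [positive("TR1", "A"), positive("TR2", "B"), positive("TR3", "C")]
        test_recs = [TransporterRecord("TE1", "ACDEFGHIKL")]
        ident = FakeIdentity(
            {("TE1", "TR1"): 50.0, ("TE1", "TR2"): 40.0, ("TE1", "TR3"): 30.0}
        )
        predictions, m = similarity_baseline(
            test_recs, [positive("TE1", "A")], train_pairs, ident, BaselineConfig(k=3)
        )
        assert predictions["TE1"] == {"A", "B", "C"}
        assert m["recall"] == 1.0 and m["precision"] == pytest.approx(1 / 3)

    def test_hand_enumerated_k2(self):
        """3 train proteins with hand-set identities and substrate sets."""
        train_pairs = [
            positive("TR1", "A"),
            positive("TR1", "B"),
            positive("TR2", "B"),
            positive("TR2", "C"),
            positive("TR3", "D"),
        ]
        test_recs = [TransporterRecord("TE1", "ACDEFGHIKL")]
        test_pos = [positive("TE1", "A"), positive("TE1", "D")]
        ident = FakeIdentity(
            {("TE1", "TR1"): 80.0, ("TE1", "TR2"): 70.0, ("TE1", "TR3"): 10.0}
        )
        predictions, m = similarity_baseline(
            test_recs, test_pos, train_pairs, ident, BaselineConfig(k=2)
        )
        # nearest two: TR1 {A,B} and TR2 {B,C} -> predicted {A,B,C}
        # TP = {A}, FP = {B,C}, FN = {D}
        assert predictions["TE1"] == {"A", "B", "C"}
        assert m["precision"] == pytest.approx(1 / 3)
        assert m["recall"] == pytest.approx(1 / 2)
        assert m["accuracy"] == pytest.approx(1 / 4)

    def test_k_larger_than_train_set_error(self):
        with pytest.raises(ValueError, match="k="):
            similarity_baseline(
                [TransporterRecord("TE1", "ACDEF")],
                [],
                [positive("TR1", "A")],
                FakeIdentity({("TE1", "TR1"): 50.0}),
                BaselineConfig(k=2),
            )


class TestScreeningProjection:
    def test_worked_example_five_false_positives(self):
        fp, tp = screening_projection(50, 1, fpr=0.11, tpr=0.82)
        assert fp == 5
        assert tp == pytest.approx(0.82)

    def test_zero_fpr(self):
        assert screening_projection(100, 10, fpr=0.0, tpr=1.0)[0] == 0

    def test_no_true_substrates(self):
        fp, tp = screening_projection(100, 0, fpr=0.5, tpr=0.9)
        assert fp == 50 and tp == 0.0

    def test_invalid_rate_error(self):
        with pytest.raises(ValueError, match="fpr"):
            screening_projection(10, 1, fpr=1.5, tpr=0.5)


def test_confusion_matrix_counts():
    labels = np.array([0, 0, 1, 2, 2, 2])
    predicted = np.array([0, 1, 1, 2, 2, 0])
    table = confusion_matrix_table(labels, predicted, ["a", "b", "c"])
    assert table.loc["a", "a"] == 1 and table.loc["a", "b"] == 1
    assert table.loc["c", "c"] == 2 and table.loc["c", "a"] == 1
    assert table.to_numpy().sum() == 6


def test_random_labeling_gives_chance_metrics():
    """Uniform random labels on 10,000 items: accuracy ~50%, MCC ~0."""
    rng = np.random.default_rng(4)
    labels = (rng.random(10_000) < 0.25).astype(int)  # 3:1 negative:positive
    predicted = rng.integers(0, 2, size=10_000).astype(float)
    m = binary_metrics(labels, predicted)
    assert m.accuracy == pytest.approx(0.5, abs=0.02)
    assert m.mcc == pytest.approx(0.0, abs=0.03)
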