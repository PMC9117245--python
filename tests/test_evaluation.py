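"""Evaluation protocol: confusion algebra, AUC oracles, sweeps, misprediction."""

import numpy as np
import pytest

from uqpath import (MeanScoreVector, UncertaintyVector, UndefinedMetricError,
                    accuracy, accuracy_sweep, build_report, confusion_counts,
                    misprediction_auc, misprediction_labels, pr_auc, roc_auc)
from uqpath.evaluation import ConfusionCounts, default_grid, fpr, precision, recall
from uqpath.synthetic import SyntheticSpec, generate_samples


def _pairwise_auc(scores, labels):
    """Brute-force Mann–Whitney with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def _uvec(values):
    return UncertaintyVector(np.asarray(values, float), metric="baseline",
                             range=(0.0, 1.0))


class TestConfusionCounts:
    def test_hand_example(self):
        c = confusion_counts(np.array([0.9, 0.1]), np.array([1, 0]), 0.5)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 1, 0)

    def test_all_below_threshold(self):
        c = confusion_counts(np.array([0.1, 0.2]), np.array([1, 0]), 0.9)
        assert c.tp == 0 and c.fp == 0

    def test_boundary_score_counts_as_negative(self):
        c = confusion_counts(np.array([0.5]), np.array([1]), 0.5)
        assert c.fn == 1 and c.tp == 0

    def test_matches_per_element_loop(self, rng):
        scores = rng.uniform(0, 1, 500)
        labels = rng.integers(0, 2, 500)
        for t in (0.25, 0.5, 0.75):
            c = confusion_counts(scores, labels, t)
            tp = sum(1 for s, y in zip(scores, labels) if s > t and y == 1)
            fp = sum(1 for s, y in zip(scores, labels) if s > t and y == 0)
            fn = sum(1 for s, y in zip(scores, labels) if s <= t and y == 1)
            tn = sum(1 for s, y in zip(scores, labels) if s <= t and y == 0)
            assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
            assert c.total == 500

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.array([0.5]), np.array([1, 0]), 0.5)


class TestRatioMetrics:
    def test_textbook_ratios(self):
        c = ConfusionCounts(tp=45, fp=5, tn=40, fn=10)
        assert accuracy(c) == pytest.approx(0.85)
        assert precision(c) == pytest.approx(0.9)
        assert recall(c) == pytest.approx(45 / 55)
        assert fpr(c) == pytest.approx(5 / 45)

    def test_degenerate_inputs_flagged_not_zeroed(self):
        all_neg = ConfusionCounts(tp=0, fp=0, tn=10, fn=0)
        assert accuracy(all_neg) == 1.0
        with pytest.raises(UndefinedMetricError):
            recall(all_neg)
        with pytest.raises(UndefinedMetricError):
            precision(all_neg)
        with pytest.raises(UndefinedMetricError):
            accuracy(ConfusionCounts(0, 0, 0, 0))


class TestRocAuc:
    def test_perfect_separation(self):
        curve = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert curve.auc == 1.0
        np.testing.assert_array_equal(curve.points[0], [0, 0])
        np.testing.assert_array_equal(curve.points[-1], [1, 1])

    def test_all_tied_scores_give_half(self):
        assert roc_auc(np.full(20, 0.5),
                       np.r_[np.ones(10), np.zeros(10)]).auc == 0.5

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for trial in range(40):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.uniform(0, 1, n), 1)  # induces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            got = roc_auc(scores, labels).auc
            assert got == pytest.approx(_pairwise_auc(scores, labels),
                                        abs=1e-12)

    def test_complement_symmetry(self, rng):
        scores = rng.uniform(0, 1, 200)
        labels = rng.integers(0, 2, 200)
        assert roc_auc(scores, labels).auc + roc_auc(-scores, labels).auc == \
            pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_strictly_monotone_transform(self, rng):
        scores = rng.uniform(0, 1, 150)
        labels = rng.integers(0, 2, 150)
        base = roc_auc(scores, labels).auc
        for transform in (lambda x: 3 * x + 1, np.exp,
                          lambda x: x ** 3, lambda x: np.log(x + 1e-9)):
            assert roc_auc(transform(scores), labels).auc == \
                pytest.approx(base, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc(np.array([0.2, 0.8]), np.array([1, 1]))

    def test_curve_monotone_and_auc_is_trapezoid(self, rng):
        scores = rng.uniform(0, 1, 100)
        labels = rng.integers(0, 2, 100)
        curve = roc_auc(scores, labels)
        assert (np.diff(curve.points[:, 0]) >= 0).all()
        assert (np.diff(curve.points[:, 1]) >= 0).all()
        assert curve.auc == pytest.approx(
            np.trapezoid(curve.points[:, 1], curve.points[:, 0]), abs=1e-12)


class TestPrAuc:
    def test_perfect_separation(self):
        assert pr_auc(np.array([0.9, 0.8, 0.2, 0.1]),
                      np.array([1, 1, 0, 0])).auc == 1.0

    def test_constant_scores_give_prevalence(self):
        labels = np.r_[np.ones(30), np.zeros(70)]
        assert pr_auc(np.full(100, 0.5), labels).auc == pytest.approx(0.3)

    def test_matches_precision_at_rank_oracle(self, rng):
        # untied scores: AP = mean of precision@k over positive ranks
        for trial in range(20):
            n = int(rng.integers(5, 40))
            scores = rng.uniform(0, 1, n)
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                continue
            order = np.argsort(-scores)
            ranked = labels[order]
            hits = np.cumsum(ranked)
            ap = np.mean([hits[k] / (k + 1)
                          for k in range(n) if ranked[k] == 1])
            assert pr_auc(scores, labels).auc == pytest.approx(ap, abs=1e-12)

    def test_recall_nondecreasing_along_curve(self, rng):
        scores = rng.uniform(0, 1, 60)
        labels = rng.integers(0, 2, 60)
        pts = pr_auc(scores, labels).points
        assert (np.diff(pts[:, 0]) >= 0).all()

    def test_no_positives_raises(self):
        with pytest.raises(UndefinedMetricError):
            pr_auc(np.array([0.2, 0.8]), np.array([0, 0]))


class TestAccuracySweep:
    def test_perfect_separation_plateau_spans_the_gap(self):
        scores = np.r_[np.full(50, 0.2), np.full(50, 0.8)]
        labels = np.r_[np.zeros(50, int), np.ones(50, int)]
        sweep = accuracy_sweep(scores, labels, default_grid(0, 1, 101))
        assert sweep.peak_accuracy == 1.0
        # accuracy is 1 on [0.2, 0.8) thresholds
        assert sweep.plateau_width == pytest.approx(0.6, abs=0.021)

    def test_constant_scores_give_flat_majority_accuracy(self):
        labels = np.r_[np.ones(30, int), np.zeros(70, int)]
        sweep = accuracy_sweep(np.full(100, 0.4), labels)
        np.testing.assert_allclose(sweep.accuracies[sweep.thresholds >= 0.4],
                                   0.7)
        assert sweep.peak_accuracy == 0.7

    def test_each_grid_point_matches_confusion_recomputation(self, rng):
        scores = rng.uniform(0, 1, 300)
        labels = rng.integers(0, 2, 300)
        grid = default_grid(0, 1, 41)
        sweep = accuracy_sweep(scores, labels, grid)
        for t, a in zip(grid, sweep.accuracies):
            assert a == pytest.approx(
                accuracy(confusion_counts(scores, labels, t)), abs=1e-12)

    def test_bad_grids_rejected(self, rng):
        scores, labels = rng.uniform(0, 1, 10), rng.integers(0, 2, 10)
        with pytest.raises(ValueError):
            accuracy_sweep(scores, labels, np.array([]))
        with pytest.raises(ValueError):
            accuracy_sweep(scores, labels, np.array([0.5, 0.2]))


class TestMisprediction:
    def test_perfect_and_inverted_classifiers(self):
        labels = np.array([0, 0, 1, 1])
        perfect = MeanScoreVector(np.array([0.1, 0.2, 0.8, 0.9]))
        np.testing.assert_array_equal(
            misprediction_labels(perfect, labels, 0.5), [0, 0, 0, 0])
        inverted = MeanScoreVector(1.0 - np.array(labels, dtype=float))
        np.testing.assert_array_equal(
            misprediction_labels(inverted, labels, 0.5), [1, 1, 1, 1])

    def test_matches_confusion_assignment_loop(self, rng):
        scores = rng.uniform(0, 1, 200)
        labels = rng.integers(0, 2, 200)
        mis = misprediction_labels(MeanScoreVector(scores), labels, 0.3)
        for s, y, m in zip(scores, labels, mis):
            assert m == int((s > 0.3) != y)

    def test_oracle_and_anti_oracle_uncertainty(self, rng):
        mis = rng.integers(0, 2, 100)
        if mis.sum() == 0:
            mis[0] = 1
        assert misprediction_auc(_uvec(mis.astype(float)), mis) == 1.0
        assert misprediction_auc(_uvec(1.0 - mis), mis) == 0.0

    def test_zero_mispredictions_raises_with_explanation(self):
        with pytest.raises(UndefinedMetricError, match="no\\s+mispredictions"):
            misprediction_auc(_uvec([0.5, 0.5]), np.array([0, 0]))


class TestBuildReport:
    def test_cells_match_direct_composition(self):
        from uqpath.metrics import METRICS, baseline_uncertainty
        sm = generate_samples(SyntheticSpec(n_per_class=150, T=8, seed=21))
        single = MeanScoreVector(sm.column(0))
        reports = build_report({"ensemble": sm}, single, sm.labels,
                               thresholds=(0.5,))
        assert len(reports) == 1
        rep = reports[0]
        mis = misprediction_labels(single, sm.labels, 0.5)
        assert rep.accuracy == pytest.approx(1.0 - mis.mean())
        for name, fn in METRICS.items():
            expected = misprediction_auc(fn(sm), mis)
            assert rep.rows[("ensemble", name)] == pytest.approx(
                expected, abs=1e-12)
        assert rep.baseline_auc == pytest.approx(
            misprediction_auc(baseline_uncertainty(single), mis), abs=1e-12)

    def test_perfect_classifier_raises_per_threshold(self):
        labels = np.array([0, 1])
        sm_samples = np.array([[0.05, 0.06], [0.95, 0.96]])
        from uqpath import SampleMatrix
        sm = SampleMatrix(sm_samples, labels, method="ensemble")
        single = MeanScoreVector(np.array([0.05, 0.95]))
        with pytest.raises(UndefinedMetricError):
            build_report({"ensemble": sm}, single, labels, thresholds=(0.5,))

    def test_report_frame_shape(self):
        sm = generate_samples(SyntheticSpec(n_per_class=100, T=5, seed=2))
        single = MeanScoreVector(sm.column(0))
        reports = build_report({"ensemble": sm}, single, sm.labels)
        assert len(reports) == 3
        frame = reports[0].to_frame()
        assert set(frame["metric"]) == {"sample_mean_uncertainty",
                                        "sample_variance", "entropy",
                                        "mutual_information", "baseline"}
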