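"""Ranking/threshold metrics against brute-force oracles, bootstrap CI
behavior, and the ICD contingency baseline."""

import numpy as np
import pytest

from nidphen.corpus import ClinicalNote
from nidphen.evaluate import (
    Contingency,
    bootstrap_ci,
    evaluate_scores,
    icd_baseline,
    rank_metrics,
    threshold_metrics,
)


def auroc_pairwise(scores, labels):
    """Literal pairwise definition: P(pos > neg) + 1/2 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def ap_literal(scores, labels):
    """Literal average precision: precision at each distinct threshold,
    weighted by the recall increment, counted by full scans."""
    n_pos = sum(labels)
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and not y)
        recall = tp / n_pos
        ap += (recall - prev_recall) * (tp / (tp + fp))
        prev_recall = recall
    return ap


class TestRankMetrics:
    def test_perfect_separation(self):
        m = rank_metrics([0.9, 0.8, 0.1, 0.2], [True, True, False, False])
        assert m["auroc"] == 1.0
        assert m["auprc"] == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(2000)
        labels = rng.random(2000) < 0.3
        m = rank_metrics(scores, labels)
        assert abs(m["auroc"] - 0.5) < 0.05

    def test_tie_handling_matches_pairwise(self):
        scores = [0.5, 0.5, 0.3, 0.8, 0.3, 0.1]
        labels = [True, False, True, True, False, False]
        m = rank_metrics(scores, labels)
        assert m["auroc"] == pytest.approx(auroc_pairwise(scores, labels), abs=1e-12)

    def test_oracle_agreement_random_instances(self):
        """100 random small instances: exact agreement with the pairwise
        AUROC and literal average-precision oracles."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(4, 51))
            scores = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], size=n).tolist()
            labels = (rng.random(n) < 0.4).tolist()
            if not any(labels) or all(labels):
                labels[0], labels[1] = True, False
            m = rank_metrics(scores, labels)
            assert m["auroc"] == pytest.approx(
                auroc_pairwise(scores, labels), abs=1e-12)
            assert m["auprc"] == pytest.approx(
                ap_literal(scores, labels), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.random(100)
        labels = rng.random(100) < 0.3
        base = rank_metrics(scores, labels)
        warped = rank_metrics(np.exp(3 * scores), labels)
        assert warped["auroc"] == pytest.approx(base["auroc"], abs=1e-12)
        assert warped["auprc"] == pytest.approx(base["auprc"], abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rank_metrics([0.1, 0.2], [True, True])

    def test_agrees_with_sklearn(self):
        """Independent cross-check against another implementation."""
        from sklearn.metrics import average_precision_score, roc_auc_score

        rng = np.random.default_rng(3)
        scores = rng.random(500)
        labels = rng.random(500) < 0.2
        m = rank_metrics(scores, labels)
        assert m["auroc"] == pytest.approx(roc_auc_score(labels, scores), abs=1e-10)
        assert m["auprc"] == pytest.approx(
            average_precision_score(labels, scores), abs=1e-10)


class TestThresholdMetrics:
    def test_perfect_classifier(self):
        m = threshold_metrics([0.9, 0.1], [True, False], 0.5)
        assert m == {"f1": 1.0, "recall": 1.0, "precision": 1.0,
                     "specificity": 1.0}

    def test_all_predicted_negative(self):
        m = threshold_metrics([0.1, 0.2], [True, False], 0.5)
        assert m["recall"] == 0.0
        assert m["specificity"] == 1.0
        assert m["precision"] is None and m["f1"] is None

    def test_direct_arithmetic(self):
        # tp=3 fp=1 fn=1 tn=5
        scores = [0.9] * 3 + [0.9] + [0.1] + [0.1] * 5
        labels = [True] * 3 + [False] + [True] + [False] * 5
        m = threshold_metrics(scores, labels, 0.5)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(5 / 6)

    def test_score_equal_threshold_called_positive(self):
        m = threshold_metrics([0.5, 0.4], [True, False], 0.5)
        assert m["recall"] == 1.0


class TestBootstrapCI:
    def test_constant_metric_zero_width(self):
        scores = [0.9, 0.9, 0.1, 0.1, 0.9, 0.1]
        labels = [True, True, False, False, True, False]
        ci = bootstrap_ci(scores, labels, "auroc", B=100, seed=0)
        assert ci["ci_low"] == ci["median"] == ci["ci_high"] == 1.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        scores = rng.random(60)
        labels = rng.random(60) < 0.4
        a = bootstrap_ci(scores, labels, "auprc", B=200, seed=9)
        b = bootstrap_ci(scores, labels, "auprc", B=200, seed=9)
        assert a == b

    def test_order_of_percentiles(self):
        rng = np.random.default_rng(5)
        scores = rng.random(80)
        labels = rng.random(80) < 0.3
        ci = bootstrap_ci(scores, labels, "f1", B=300, seed=0)
        assert ci["ci_low"] <= ci["median"] <= ci["ci_high"]

    def test_small_sample_redraws_counted(self):
        # 5 notes, 1 positive: many resamples will be single-class
        ci = bootstrap_ci([0.9, 0.1, 0.2, 0.3, 0.4],
                          [True, False, False, False, False],
                          "auroc", B=200, seed=0)
        assert ci["n_redrawn"] > 0

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(6)

        def width(n):
            pos = rng.normal(1.0, 1.0, int(n * 0.3))
            neg = rng.normal(0.0, 1.0, n - int(n * 0.3))
            scores = np.r_[pos, neg]
            labels = np.r_[np.ones(pos.size, bool), np.zeros(neg.size, bool)]
            ci = bootstrap_ci(scores, labels, "auroc", B=300, seed=1)
            return ci["ci_high"] - ci["ci_low"]

        assert width(800) < width(80)


class TestIcdBaseline:
    def _notes(self, tp, fp, fn, tn):
        notes = []
        combos = [(True, True)] * tp + [(False, True)] * fp + \
                 [(True, False)] * fn + [(False, False)] * tn
        for i, (label, flag) in enumerate(combos):
            notes.append(ClinicalNote(f"n{i}", f"p{i}", "", label=label,
                                      icd_nid_flag=flag))
        return notes

    def test_study_regime_counts(self):
        """465 confirmed among 1500 flagged, 14 among 1500 unflagged."""
        c = icd_baseline(self._notes(tp=465, fp=1035, fn=14, tn=1486))
        assert c.sensitivity == pytest.approx(465 / 479)
        assert c.sensitivity == pytest.approx(0.971, abs=5e-4)
        assert c.specificity == pytest.approx(1486 / 2521)
        assert c.ppv == pytest.approx(0.31, abs=5e-3)

    def test_no_flags(self):
        c = icd_baseline(self._notes(tp=0, fp=0, fn=3, tn=7))
        assert c.sensitivity == 0.0
        assert c.specificity == 1.0
        assert c.ppv is None

    def test_missing_label_lists_ids(self):
        notes = self._notes(1, 1, 1, 1)
        notes.append(ClinicalNote("nx", "px", "", label=None))
        with pytest.raises(ValueError, match="nx"):
            icd_baseline(notes)


class TestEvalReport:
    def test_report_structure_and_json(self, tmp_path):
        rng = np.random.default_rng(7)
        labels = rng.random(120) < 0.3
        scores = np.where(labels, rng.normal(0.8, 0.2, 120),
                          rng.normal(0.2, 0.2, 120))
        rep = evaluate_scores(scores, labels, B=100, seed=0)
        for name in ("auroc", "auprc", "f1", "recall", "precision",
                     "specificity"):
            m = rep.metrics[name]
            assert m["ci_low"] <= m["bootstrap_median"] <= m["ci_high"]
            assert 0.0 <= m["bootstrap_median"] <= 1.0
        rep.to_json(tmp_path / "r.json")
        assert (tmp_path / "r.json").exists()
        assert "auroc" in rep.table()
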