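import numpy as np
import pytest

from uroslide.aggregate import ClassScore, WSIConfidence
from uroslide.classifier import PatchPrediction
from uroslide.evaluate import (auc_bootstrap_ci, clopper_pearson,
                               evaluate_patches, evaluate_wsi, metric_with_ci,
                               roc_auc)
from uroslide.labels import ALL_CLASSES, DIAGNOSTIC_CLASSES, LabelClass


def auc_pairwise_oracle(scores, labels):
    """Brute force over all positive-negative pairs, half-credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestClopperPearson:
    def test_zero_successes_closed_form(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** 0.1, abs=1e-9)

    def test_all_successes_closed_form(self):
        lo, hi = clopper_pearson(10, 10)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** 0.1, abs=1e-9)

    def test_half_successes(self):
        lo, hi = clopper_pearson(5, 10)
        assert (lo, hi) == (pytest.approx(0.1871, abs=2e-4),
                            pytest.approx(0.8129, abs=2e-4))

    @pytest.mark.parametrize("k,n", [(0, 5), (3, 7), (25, 50), (49, 50),
                                     (1, 100), (60, 80)])
    def test_matches_statsmodels_exact_interval(self, k, n):
        from statsmodels.stats.proportion import proportion_confint
        lo, hi = clopper_pearson(k, n)
        slo, shi = proportion_confint(k, n, alpha=0.05, method="beta")
        assert lo == pytest.approx(slo, abs=1e-12)
        assert hi == pytest.approx(shi, abs=1e-12)

    def test_invalid_inputs(self):
        for k, n in [(-1, 10), (11, 10), (0, 0)]:
            with pytest.raises(ValueError):
                clopper_pearson(k, n)

    def test_metric_invariants(self):
        m = metric_with_ci(30, 40)
        assert 0 <= m.lower <= m.estimate <= m.upper <= 1
        assert m.estimate == 0.75


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_printed_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                auc_pairwise_oracle(scores, labels), abs=1e-12)

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.normal(0.4, 0.15, 40),
                                 rng.normal(0.7, 0.15, 40)])
        labels = np.array([0] * 40 + [1] * 40)
        lo, hi = auc_bootstrap_ci(scores, labels, n_boot=300, seed=1)
        assert lo <= roc_auc(scores, labels) <= hi


def make_conf(p_hgmi, p_hgnmi, p_lgnmi, slide_id="s"):
    prob = dict(zip(DIAGNOSTIC_CLASSES, (p_hgmi, p_hgnmi, p_lgnmi)))
    predicted = max(DIAGNOSTIC_CLASSES, key=lambda c: prob[c])
    return WSIConfidence(
        slide_id=slide_id, n=3, prob=prob,
        scores={c: ClassScore(c, 1, prob[c]) for c in DIAGNOSTIC_CLASSES},
        predicted_label=predicted, mibc_score=prob[LabelClass.HGMI],
        high_grade_score=prob[LabelClass.HGMI] + prob[LabelClass.HGNMI])


class TestEvaluateWSI:
    def one_hot_cohort(self, n=5):
        preds, truth = [], []
        for cls in DIAGNOSTIC_CLASSES:
            for _ in range(n):
                p = {c: 0.05 for c in DIAGNOSTIC_CLASSES}
                p[cls] = 0.9
                preds.append(make_conf(p[LabelClass.HGMI], p[LabelClass.HGNMI],
                                       p[LabelClass.LGNMI]))
                truth.append(cls)
        return preds, truth

    def test_perfect_predictions(self):
        preds, truth = self.one_hot_cohort()
        report = evaluate_wsi(preds, truth)
        assert report.overall_accuracy.estimate == 1.0
        assert all(v == 1.0 for v in report.auc.values())
        assert report.macro_auc == 1.0
        assert np.trace(report.confusion) == len(truth)
        assert report.binary["muscle_invasion"]["auc"] == 1.0
        assert report.binary["high_grade"]["auc"] == 1.0

    def test_confusion_rows_are_truth_counts(self):
        preds, truth = self.one_hot_cohort(4)
        report = evaluate_wsi(preds, truth)
        assert report.confusion.sum(axis=1).tolist() == [4, 4, 4]

    def test_degenerate_predictor_always_lgnmi(self):
        preds = [make_conf(0.1, 0.1, 0.8) for _ in range(30)]
        truth = ([LabelClass.HGMI] * 10 + [LabelClass.HGNMI] * 10
                 + [LabelClass.LGNMI] * 10)
        report = evaluate_wsi(preds, truth)
        pc = report.per_class
        assert pc[LabelClass.LGNMI]["sensitivity"].estimate == 1.0
        assert pc[LabelClass.HGMI]["sensitivity"].estimate == 0.0
        assert pc[LabelClass.HGNMI]["sensitivity"].estimate == 0.0

    def test_sens_spec_recompute_from_confusion(self):
        rng = np.random.default_rng(3)
        preds = [make_conf(*rng.dirichlet(np.ones(3))) for _ in range(60)]
        truth = [DIAGNOSTIC_CLASSES[i] for i in rng.integers(0, 3, 60)]
        report = evaluate_wsi(preds, truth)
        cm = report.confusion
        for j, cls in enumerate(DIAGNOSTIC_CLASSES):
            tp = cm[j, j]
            fn = cm[j].sum() - tp
            fp = cm[:, j].sum() - tp
            tn = cm.sum() - tp - fn - fp
            assert report.per_class[cls]["sensitivity"].estimate == pytest.approx(
                tp / (tp + fn))
            assert report.per_class[cls]["specificity"].estimate == pytest.approx(
                tn / (tn + fp))

    def test_macro_auc_is_mean_of_per_class(self):
        rng = np.random.default_rng(4)
        preds = [make_conf(*rng.dirichlet(np.ones(3))) for _ in range(50)]
        truth = [DIAGNOSTIC_CLASSES[i] for i in rng.integers(0, 3, 50)]
        report = evaluate_wsi(preds, truth)
        assert report.macro_auc == pytest.approx(
            np.mean([report.auc[c] for c in DIAGNOSTIC_CLASSES]))

    def test_random_labels_null_auc(self):
        """Permuting truth should drive macro AUC to chance level."""
        rng = np.random.default_rng(12)
        preds = [make_conf(*rng.dirichlet(np.ones(3))) for _ in range(300)]
        truth = [DIAGNOSTIC_CLASSES[i] for i in rng.integers(0, 3, 300)]
        report = evaluate_wsi(preds, truth)
        assert report.macro_auc == pytest.approx(0.5, abs=0.08)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_wsi([make_conf(1, 0, 0)], [])

    def test_report_serializes(self, tmp_path):
        preds, truth = self.one_hot_cohort(3)
        report = evaluate_wsi(preds, truth)
        report.save_json(tmp_path / "r.json")
        import json
        payload = json.loads((tmp_path / "r.json").read_text())
        assert payload["macro_auc"] == 1.0
        assert set(payload["per_class"]) == {"HGMI", "HGNMI", "LGNMI"}


class TestEvaluatePatches:
    def test_one_hot_identity_confusion(self):
        preds, truth = [], []
        for cls in ALL_CLASSES:
            for _ in range(3):
                v = np.full(6, 0.02)
                v[cls.channel_index] = 0.9
                preds.append(PatchPrediction(v / v.sum()))
                truth.append(cls)
        report = evaluate_patches(preds, truth)
        assert np.array_equal(report.confusion, np.eye(6, dtype=int) * 3)
        assert len(report.auc) == 6
        assert report.confusion.sum() == len(preds)

    def test_six_aucs_reported(self):
        rng = np.random.default_rng(1)
        preds = [PatchPrediction(rng.dirichlet(np.ones(6))) for _ in range(60)]
        truth = [ALL_CLASSES[i] for i in rng.integers(0, 6, 60)]
        report = evaluate_patches(preds, truth)
        assert list(report.classes) == list(ALL_CLASSES)
        assert len(report.auc) == 6
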