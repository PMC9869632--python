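import numpy as np
import pytest

from uroslide.aggregate import (ClassScore, ClassificationFailure,
                                ContourSummary, class_score, classify_heatmap,
                                classify_slide, extract_contours, read_report,
                                wsi_confidence, write_report)
from uroslide.inference import Heatmap, decision_map
from uroslide.labels import DIAGNOSTIC_CLASSES, LabelClass
from uroslide.sampling import PatchSpec


def heatmap_from_decision(dec, prob_map=None, fill=0.8):
    """Heatmap whose argmax reproduces `dec`; winning channel holds prob."""
    dec = np.asarray(dec)
    probs = np.zeros((6, *dec.shape), np.float32)
    cov = dec >= 0
    rest = None
    for r in range(dec.shape[0]):
        for c in range(dec.shape[1]):
            if dec[r, c] < 0:
                continue
            p = fill if prob_map is None else prob_map[r, c]
            probs[dec[r, c], r, c] = p
            for k in range(6):
                if k != dec[r, c]:
                    probs[k, r, c] = (1 - p) / 5
    return Heatmap(probs=probs, coverage=cov)


class TestExtractContours:
    def test_constant_region(self):
        dec = np.full((2, 5), 2, dtype=int)
        h = heatmap_from_decision(dec, fill=0.8)
        (c,) = extract_contours(dec, h)
        assert (c.k, c.area) == (LabelClass.LGNMI, 10)
        assert c.mean_prob == pytest.approx(0.8)

    def test_diagonal_points_are_one_component(self):
        dec = -np.ones((4, 4), int)
        dec[0, 0] = dec[1, 1] = 3
        h = heatmap_from_decision(dec)
        contours = extract_contours(dec, h)
        assert len(contours) == 1
        assert contours[0].area == 2

    def test_all_uncovered_empty(self):
        dec = -np.ones((3, 3), int)
        h = heatmap_from_decision(dec)
        assert extract_contours(dec, h) == []

    def test_two_classes_two_regions(self):
        dec = -np.ones((4, 8), int)
        dec[:2, :3] = 0
        dec[3, 5:] = 1
        h = heatmap_from_decision(dec)
        summary = {(c.k, c.area) for c in extract_contours(dec, h)}
        assert summary == {(LabelClass.HGMI, 6), (LabelClass.HGNMI, 3)}


class TestClassScore:
    def test_single_contour_identity(self):
        s = class_score(LabelClass.HGMI, [ContourSummary(LabelClass.HGMI, 4, 0.7)])
        assert s.P_k == pytest.approx(0.7)

    def test_area_weighted_mean(self):
        contours = [ContourSummary(LabelClass.HGNMI, 2, 0.5),
                    ContourSummary(LabelClass.HGNMI, 3, 1.0)]
        assert class_score(LabelClass.HGNMI, contours).P_k == pytest.approx(0.8)

    def test_no_contours_undefined(self):
        s = class_score(LabelClass.LGNMI, [])
        assert s.m == 0 and s.P_k is None and not s.defined

    def test_mixed_classes_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            class_score(LabelClass.HGMI, [ContourSummary(LabelClass.NIA, 1, 0.5)])

    def test_bounded_by_contour_probs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            contours = [ContourSummary(LabelClass.IA, int(rng.integers(1, 50)),
                                       float(rng.random()))
                        for _ in range(rng.integers(1, 6))]
            s = class_score(LabelClass.IA, contours)
            probs = [c.mean_prob for c in contours]
            assert min(probs) - 1e-12 <= s.P_k <= max(probs) + 1e-12

    def test_invariant_under_contour_splitting(self):
        """P_k depends only on the pointwise values, not the partition."""
        rng = np.random.default_rng(1)
        for _ in range(30):
            values = rng.random(rng.integers(2, 40))
            cut = rng.integers(1, len(values))
            whole = [ContourSummary(LabelClass.NA, len(values), float(values.mean()))]
            parts = [ContourSummary(LabelClass.NA, cut, float(values[:cut].mean())),
                     ContourSummary(LabelClass.NA, len(values) - cut,
                                    float(values[cut:].mean()))]
            assert class_score(LabelClass.NA, whole).P_k == pytest.approx(
                class_score(LabelClass.NA, parts).P_k, abs=1e-12)


def scores(p_hgmi=None, p_hgnmi=None, p_lgnmi=None):
    vals = dict(zip(DIAGNOSTIC_CLASSES, (p_hgmi, p_hgnmi, p_lgnmi)))
    return [ClassScore(c, m=(1 if v is not None else 0), P_k=v)
            for c, v in vals.items()]


class TestWSIConfidence:
    def test_softmax_of_exp_scores(self):
        conf = wsi_confidence(scores(0.9, 0.5, 0.1))
        assert conf.prob[LabelClass.HGMI] == pytest.approx(0.4718, abs=2e-4)
        assert conf.prob[LabelClass.HGNMI] == pytest.approx(0.3163, abs=2e-4)
        assert conf.prob[LabelClass.LGNMI] == pytest.approx(0.2120, abs=2e-4)
        assert conf.predicted_label == LabelClass.HGMI
        assert conf.n == 3

    def test_equal_scores_uniform(self):
        conf = wsi_confidence(scores(0.4, 0.4, 0.4))
        for c in DIAGNOSTIC_CLASSES:
            assert conf.prob[c] == pytest.approx(1 / 3)

    def test_undefined_classes_excluded(self):
        conf = wsi_confidence(scores(p_hgmi=0.7))
        assert conf.prob[LabelClass.HGMI] == 1.0
        assert conf.prob[LabelClass.HGNMI] == 0.0
        assert conf.predicted_label == LabelClass.HGMI
        assert conf.mibc_score == 1.0
        assert conf.n == 1

    def test_no_defined_scores_fails(self):
        with pytest.raises(ClassificationFailure):
            wsi_confidence(scores())

    def test_probabilities_sum_to_one_and_order_matches_P(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            p = rng.random(3)
            conf = wsi_confidence(scores(*p))
            assert sum(conf.prob.values()) == pytest.approx(1.0, abs=1e-9)
            order_p = np.argsort(p)
            order_prob = np.argsort([conf.prob[c] for c in DIAGNOSTIC_CLASSES])
            assert (order_p == order_prob).all()

    def test_derived_binary_scores(self):
        conf = wsi_confidence(scores(0.2, 0.9, 0.4))
        assert conf.mibc_score == conf.prob[LabelClass.HGMI]
        assert conf.high_grade_score == pytest.approx(
            conf.prob[LabelClass.HGMI] + conf.prob[LabelClass.HGNMI])


def brute_force_confidence(h: Heatmap):
    """Independent recomputation of both aggregation equations from a
    persisted heatmap: own flood-fill components + direct formula."""
    import math
    dec = np.full(h.shape, -1, int)
    rows, cols = np.nonzero(h.coverage)
    for r, c in zip(rows, cols):
        v = h.probs[:, r, c]
        dec[r, c] = int(np.argmax(v))
    P = {}
    for cls in DIAGNOSTIC_CLASSES:
        mask = dec == cls.channel_index
        seen = np.zeros_like(mask)
        num, den = 0.0, 0.0
        for r in range(mask.shape[0]):
            for c in range(mask.shape[1]):
                if mask[r, c] and not seen[r, c]:
                    stack, comp = [(r, c)], []
                    seen[r, c] = True
                    while stack:
                        y, x = stack.pop()
                        comp.append((y, x))
                        for dy in (-1, 0, 1):
                            for dx in (-1, 0, 1):
                                yy, xx = y + dy, x + dx
                                if (0 <= yy < mask.shape[0] and 0 <= xx < mask.shape[1]
                                        and mask[yy, xx] and not seen[yy, xx]):
                                    seen[yy, xx] = True
                                    stack.append((yy, xx))
                    a = len(comp)
                    p = sum(float(h.probs[cls.channel_index, y, x])
                            for y, x in comp) / a
                    num += a * p
                    den += a
        if den > 0:
            P[cls] = num / den
    exps = {c: math.exp(v) for c, v in P.items()}
    z = sum(exps.values())
    return {c: exps.get(c, 0.0) / z for c in DIAGNOSTIC_CLASSES}


class TestPipelineEquivalence:
    def test_equations_match_brute_force_on_random_heatmaps(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            shape = (int(rng.integers(6, 20)), int(rng.integers(6, 20)))
            probs = rng.dirichlet(np.ones(6), size=shape).transpose(2, 0, 1)
            cov = rng.random(shape) < 0.8
            probs[:, ~cov] = 0
            h = Heatmap(probs=probs.astype(np.float32), coverage=cov)
            try:
                conf = classify_heatmap(h)
            except ClassificationFailure:
                continue
            oracle = brute_force_confidence(h)
            for c in DIAGNOSTIC_CLASSES:
                assert conf.prob[c] == pytest.approx(oracle[c], abs=1e-9)

    def test_all_white_slide_fails_classification(self, study):
        rng = np.random.default_rng(0)
        img = np.clip(rng.normal(245, 5, (512, 512, 3)), 0, 255).astype(np.uint8)
        with pytest.raises(ClassificationFailure):
            classify_slide(study.model, img, roi_size=256,
                           spec=PatchSpec(256, 256))

    def test_classify_slide_deterministic(self, study, hgmi_slide):
        a = classify_slide(study.model, hgmi_slide.image, roi_size=512,
                           spec=PatchSpec(256, 256))
        b = classify_slide(study.model, hgmi_slide.image, roi_size=512,
                           spec=PatchSpec(256, 256))
        assert a.prob == b.prob and a.predicted_label == b.predicted_label

    def test_end_to_end_labels_on_study_cohort(self, study):
        """The small trained pipeline recovers most slide labels."""
        correct = sum(c.predicted_label == t
                      for c, t in zip(study.confidences, study.truth))
        assert correct >= len(study.truth) - 1


def test_report_round_trip(tmp_path, study):
    conf = study.confidences[0]
    p = tmp_path / "r.json"
    write_report(conf, p)
    back = read_report(p)
    assert back.predicted_label == conf.predicted_label
    assert back.mibc_score == pytest.approx(conf.mibc_score)
    for c in DIAGNOSTIC_CLASSES:
        assert back.prob[c] == pytest.approx(conf.prob[c])
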