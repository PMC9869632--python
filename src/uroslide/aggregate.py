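"""Slide-level confidence from heatmap contours.

The decision map partitions covered heatmap points into per-class connected
regions ("contours", 8-connectivity). Each contour *i* of class *k* is
summarized by its area :math:`a_i` (point count) and the mean probability
:math:`p_i` of channel *k* over its points. The class score is the
area-weighted mean

.. math:: P_k = \\frac{\\sum_i a_i p_i}{\\sum_i a_i}

and the slide-level confidence is its softmax over the diagnostic classes

.. math:: Prob_k = \\frac{e^{P_k}}{\\sum_k e^{P_k}}.

The softmax runs over the three diagnostic categories (HGMI, HGNMI, LGNMI)
— the slide-level task is three-way; IA/NIA/NA contours are computed and
reported but carry no diagnostic weight. A diagnostic class with no contour
is excluded from the softmax denominator and scored 0 (scoring an absent
class :math:`P_k = 0` would still grant it weight :math:`e^0`).

Derived binary scores: ``mibc_score`` (muscle invasion) is ``Prob_HGMI``;
``high_grade_score`` is ``Prob_HGMI + Prob_HGNMI`` (all muscle-invasive
disease is high-grade).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skimage import measure

from .inference import Heatmap, decision_map, infer_heatmap
from .labels import ALL_CLASSES, DIAGNOSTIC_CLASSES, LabelClass
from .preprocess import ROIManifest, filter_background
from .sampling import PatchSpec

__all__ = [
    "ContourSummary",
    "ClassScore",
    "WSIConfidence",
    "ClassificationFailure",
    "extract_contours",
    "class_score",
    "wsi_confidence",
    "classify_slide",
    "classify_heatmap",
    "write_report",
    "read_report",
]


class ClassificationFailure(RuntimeError):
    """No diagnostic class produced any contour (e.g. an all-background slide)."""


@dataclass(frozen=True)
class ContourSummary:
    k: LabelClass
    area: int           # heatmap points in the connected region
    mean_prob: float    # mean of channel k over the region

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("contour area must be >= 1")
        if not (0.0 <= self.mean_prob <= 1.0):
            raise ValueError("mean probability must lie in [0, 1]")


@dataclass(frozen=True)
class ClassScore:
    k: LabelClass
    m: int                       # number of contours
    P_k: Optional[float]         # area-weighted mean; None when m == 0

    @property
    def defined(self) -> bool:
        return self.m >= 1


@dataclass
class WSIConfidence:
    slide_id: str
    n: int                                   # classes in the softmax
    prob: dict[LabelClass, float]            # Prob_k per diagnostic class
    scores: dict[LabelClass, ClassScore]     # P_k per diagnostic class
    predicted_label: LabelClass
    mibc_score: float
    high_grade_score: float


def extract_contours(d: np.ndarray, h: Heatmap) -> list[ContourSummary]:
    """Connected per-class regions of the decision map, in scanline order."""
    out: list[ContourSummary] = []
    for cls in ALL_CLASSES:
        mask = d == cls.channel_index
        if not mask.any():
            continue
        lab, n = measure.label(mask, connectivity=2, return_num=True)
        channel = h.probs[cls.channel_index]
        for comp in range(1, n + 1):
            sel = lab == comp
            out.append(ContourSummary(
                k=cls, area=int(sel.sum()),
                mean_prob=float(channel[sel].mean(dtype=np.float64))))
    return out


def class_score(cls: LabelClass,
                contours: Sequence[ContourSummary]) -> ClassScore:
    """Area-weighted mean probability over the class's contours."""
    if any(c.k != cls for c in contours):
        raise ValueError("contours from mixed classes")
    if not contours:
        return ClassScore(k=cls, m=0, P_k=None)
    areas = np.array([c.area for c in contours], dtype=float)
    probs = np.array([c.mean_prob for c in contours], dtype=float)
    return ClassScore(k=cls, m=len(contours),
                      P_k=float((areas * probs).sum() / areas.sum()))


def wsi_confidence(scores: Sequence[ClassScore],
                   slide_id: str = "") -> WSIConfidence:
    """Softmax of e^{P_k} over diagnostic classes with defined scores."""
    by_class = {s.k: s for s in scores}
    diag = [by_class.get(c, ClassScore(c, 0, None)) for c in DIAGNOSTIC_CLASSES]
    defined = [s for s in diag if s.defined]
    if not defined:
        raise ClassificationFailure(
            f"slide {slide_id!r}: no diagnostic class has any contour")
    exps = np.exp(np.array([s.P_k for s in defined], dtype=np.float64))
    denom = exps.sum()
    prob = {c: 0.0 for c in DIAGNOSTIC_CLASSES}
    for s, e in zip(defined, exps):
        prob[s.k] = float(e / denom)
    predicted = max(DIAGNOSTIC_CLASSES, key=lambda c: (prob[c], -c.channel_index))
    return WSIConfidence(
        slide_id=slide_id,
        n=len(defined),
        prob=prob,
        scores={s.k: s for s in diag},
        predicted_label=predicted,
        mibc_score=prob[LabelClass.HGMI],
        high_grade_score=prob[LabelClass.HGMI] + prob[LabelClass.HGNMI],
    )


def classify_heatmap(h: Heatmap, slide_id: str = "") -> WSIConfidence:
    """Contours -> class scores -> slide confidence, from a heatmap."""
    d = decision_map(h)
    contours = extract_contours(d, h)
    scores = [class_score(c, [s for s in contours if s.k == c])
              for c in DIAGNOSTIC_CLASSES]
    return wsi_confidence(scores, slide_id=slide_id)


def classify_slide(model, image: np.ndarray, slide_id: str = "",
                   roi_size: int = 2048, min_fraction: float = 0.1,
                   spec: PatchSpec | None = None,
                   manifest: ROIManifest | None = None,
                   return_artifacts: bool = False):
    """Full per-slide pipeline: background filter, dense inference, scoring.

    With ``return_artifacts`` the manifest, heatmap, decision map and contour
    table are returned alongside the confidence (for reports and overlays).
    """
    if manifest is None:
        manifest = filter_background(image, slide_id=slide_id,
                                     roi_size=roi_size, min_fraction=min_fraction)
    h = infer_heatmap(model, image, manifest, spec=spec)
    d = decision_map(h)
    contours = extract_contours(d, h)
    scores = [class_score(c, [s for s in contours if s.k == c])
              for c in DIAGNOSTIC_CLASSES]
    conf = wsi_confidence(scores, slide_id=slide_id)
    if return_artifacts:
        return conf, {"manifest": manifest, "heatmap": h, "decision_map": d,
                      "contours": contours}
    return conf


def write_report(conf: WSIConfidence, path: str | Path,
                 contours: Sequence[ContourSummary] | None = None) -> None:
    """Per-slide JSON report: P_k, Prob_k, label, binary scores, contours."""
    payload = {
        "slide_id": conf.slide_id,
        "predicted_label": conf.predicted_label.name,
        "n_softmax_classes": conf.n,
        "prob": {c.name: conf.prob[c] for c in DIAGNOSTIC_CLASSES},
        "P": {c.name: conf.scores[c].P_k for c in DIAGNOSTIC_CLASSES},
        "mibc_score": conf.mibc_score,
        "high_grade_score": conf.high_grade_score,
    }
    if contours is not None:
        payload["contours"] = [
            {"class": c.k.name, "area": c.area, "mean_prob": c.mean_prob}
            for c in contours]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_report(path: str | Path) -> WSIConfidence:
    """Load a per-slide JSON report back into a :class:`WSIConfidence`."""
    with open(path) as fh:
        payload = json.load(fh)
    prob = {LabelClass[k]: float(v) for k, v in payload["prob"].items()}
    scores = {}
    for k, v in payload["P"].items():
        cls = LabelClass[k]
        scores[cls] = ClassScore(k=cls, m=(1 if v is not None else 0),
                                 P_k=(float(v) if v is not None else None))
    return WSIConfidence(
        slide_id=payload["slide_id"],
        n=int(payload["n_softmax_classes"]),
        prob=prob,
        scores=scores,
        predicted_label=LabelClass[payload["predicted_label"]],
        mibc_score=float(payload["mibc_score"]),
        high_grade_score=float(payload["high_grade_score"]),
    )
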