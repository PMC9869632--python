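"""End-to-end study orchestration on synthetic cohorts.

Ties the stages together the way the full workflow runs on real material:
generate (or load) slides, sample labeled patches from annotations, train
the patch classifier under the fixed recipe, then preprocess, densely
classify and aggregate every evaluation slide into a slide-level
confidence, and score the result. Slides are streamed one at a time so a
cohort never has to sit in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .aggregate import WSIConfidence, classify_slide
from .annotations import AnnotationSet
from .classifier import (CNNPatchClassifier, PatchDataset, TrainConfig, train)
from .evaluate import EvalReport, evaluate_wsi
from .labels import ALL_CLASSES, LabelClass
from .sampling import (LabeledPatch, PatchSpec, point_patches, split_slides,
                       sliding_window_patches)
from .synthetic import (SyntheticSpec, cohort_specs, generate_slide,
                        junction_points)

__all__ = ["sample_slide_patches", "StudyResult", "run_study"]

#: Sampling geometry used throughout the examples: 256-px patches, 128-px
#: sampling stride (denser than the patch so small regions still yield
#: fully-contained windows), 128-px junction spacing.
SAMPLING_SPEC = PatchSpec(size=256, stride=128)
JUNCTION_SPACING = 128


def sample_slide_patches(ann: AnnotationSet,
                         spec: PatchSpec = SAMPLING_SPEC,
                         junction_spacing: float = JUNCTION_SPACING,
                         ) -> list[LabeledPatch]:
    """All training patches of one slide: sliding windows for the five
    pure-tissue classes plus junction-centred HGMI patches."""
    patches: list[LabeledPatch] = []
    for cls in ALL_CLASSES:
        if cls == LabelClass.HGMI:
            continue
        patches.extend(sliding_window_patches(ann, cls, spec))
    pts = junction_points(ann, junction_spacing)
    patches.extend(point_patches(pts, spec, (ann.width, ann.height),
                                 slide_id=ann.slide_id))
    return patches


def _subsample_per_class(ds: PatchDataset, cap: int,
                         rng: np.random.Generator) -> PatchDataset:
    keep: list[np.ndarray] = []
    for c in range(len(ALL_CLASSES)):
        idx = np.flatnonzero(ds.labels == c)
        if len(idx) > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep.append(np.sort(idx))
    sel = np.concatenate(keep)
    return PatchDataset(ds.pooled[sel], ds.labels[sel], ds.input_size)


@dataclass
class StudyResult:
    model: CNNPatchClassifier
    training_log: list[dict]
    confidences: list[WSIConfidence]
    truth: list[LabelClass]
    report: EvalReport
    n_train_patches: int = 0
    n_tune_patches: int = 0


def run_study(seed: int,
              n_train_per_class: tuple[int, int, int] = (20, 20, 20),
              n_test_per_class: tuple[int, int, int] = (10, 10, 10),
              base_spec: Optional[SyntheticSpec] = None,
              cfg: Optional[TrainConfig] = None,
              max_patches_per_class: int = 400,
              tune_ratio: tuple[int, int] = (4, 1),
              roi_size: int = 512,
              min_fraction: float = 0.1,
              patch_spec: PatchSpec = SAMPLING_SPEC) -> StudyResult:
    """Train on one synthetic cohort and evaluate on an independent one.

    The training cohort is split by slide (never by patch) into a training
    and a tuning part at ``tune_ratio``; the evaluation cohort shares no
    slide with either. Every random choice descends from ``seed``.
    """
    base_spec = base_spec or SyntheticSpec()
    master = np.random.default_rng(seed)
    train_seed = int(master.integers(0, 2**31 - 1))
    test_seed = int(master.integers(0, 2**31 - 1))
    split_seed = int(master.integers(0, 2**31 - 1))
    sub_seed = int(master.integers(0, 2**31 - 1))
    cfg = cfg or TrainConfig(seed=int(master.integers(0, 2**31 - 1)))

    specs = cohort_specs(n_train_per_class, base_spec, train_seed)
    strata = {sid: label for sid, _, label in specs}
    train_ids, tune_ids = split_slides([s for s, _, _ in specs], tune_ratio,
                                       split_seed, strata)
    train_parts: list[PatchDataset] = []
    tune_parts: list[PatchDataset] = []
    infer_spec = PatchSpec(size=patch_spec.size, stride=patch_spec.size)
    for slide_id, spec, _label in specs:
        slide = generate_slide(spec, slide_id=slide_id)
        patches = sample_slide_patches(slide.annotations, patch_spec)
        if not patches:
            continue
        ds = PatchDataset.from_patches(patches, images={slide_id: slide.image})
        (train_parts if slide_id in train_ids else tune_parts).append(ds)

    rng = np.random.default_rng(sub_seed)
    train_ds = train_parts[0]
    for part in train_parts[1:]:
        train_ds = train_ds.extend(part)
    train_ds = _subsample_per_class(train_ds, max_patches_per_class, rng)
    tune_ds = tune_parts[0] if tune_parts else None
    for part in (tune_parts[1:] if tune_parts else []):
        tune_ds = tune_ds.extend(part)

    model, log = train(train_ds, cfg, tune_ds=tune_ds, patch_size=patch_spec.size)

    confidences: list[WSIConfidence] = []
    truth: list[LabelClass] = []
    for slide_id, spec, label in cohort_specs(n_test_per_class, base_spec,
                                              test_seed):
        slide = generate_slide(spec, slide_id=slide_id)
        conf = classify_slide(model, slide.image, slide_id=slide_id,
                              roi_size=roi_size, min_fraction=min_fraction,
                              spec=infer_spec)
        confidences.append(conf)
        truth.append(label)

    report = evaluate_wsi(confidences, truth)
    return StudyResult(model=model, training_log=log, confidences=confidences,
                       truth=truth, report=report,
                       n_train_patches=len(train_ds),
                       n_tune_patches=len(tune_ds) if tune_ds else 0)
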