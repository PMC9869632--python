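"""Labeled patch extraction: sliding windows inside annotations, and
point-centred sampling at tumour-muscle junctions.

Five classes (HGNMI, LGNMI, IA, NIA, NA) are sampled by a sliding window
anchored at the slide origin: a patch is kept only when its full rectangle
lies inside one polygon of the class, so every training patch is pure
tissue of one kind. HGMI patches cannot be sampled that way — the class is
defined by the *co-occurrence* of tumour and muscle — so they are centred
on junction points instead (see :func:`uroslide.synthetic.junction_points`),
clamped inward at image borders to preserve scarce examples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import box as shapely_box

from .annotations import AnnotationSet
from .labels import LabelClass

__all__ = [
    "PatchSpec",
    "LabeledPatch",
    "sliding_window_patches",
    "point_patches",
    "split_slides",
    "extract_patch",
    "write_patch_table",
    "read_patch_table",
]


@dataclass(frozen=True)
class PatchSpec:
    """Patch geometry. 256 px at full resolution pairs naturally with the
    stride-32 dense-inference grid (a 1/32-scale heatmap)."""

    size: int = 256
    stride: int = 256
    magnification_level: int = 1

    def __post_init__(self) -> None:
        if self.size <= 0 or self.stride <= 0:
            raise ValueError("size and stride must be positive")


@dataclass(frozen=True)
class LabeledPatch:
    slide_id: str
    x0: int
    y0: int
    size: int
    label: LabelClass


def sliding_window_patches(ann: AnnotationSet, cls: LabelClass,
                           spec: PatchSpec) -> list[LabeledPatch]:
    """Row-major grid patches fully contained in a polygon of ``cls``.

    Grid positions are multiples of ``spec.stride`` from the slide origin.
    HGMI is rejected: use :func:`point_patches` with junction points.
    """
    if cls == LabelClass.HGMI:
        raise ValueError(
            "HGMI patches are sampled at tumour-muscle junction points; "
            "use point_patches")
    geoms = [p.to_shapely() for p in ann.by_label(cls)]
    if not geoms:
        return []
    size, stride = spec.size, spec.stride
    out: list[LabeledPatch] = []
    # restrict the grid to the union bounding box of the class polygons
    xs = [g.bounds for g in geoms]
    minx = min(b[0] for b in xs)
    miny = min(b[1] for b in xs)
    maxx = max(b[2] for b in xs)
    maxy = max(b[3] for b in xs)
    y_start = max(0, int(np.floor(miny / stride)) * stride)
    x_start = max(0, int(np.floor(minx / stride)) * stride)
    for y0 in range(y_start, int(np.ceil(maxy)), stride):
        if y0 + size > ann.height:
            break
        for x0 in range(x_start, int(np.ceil(maxx)), stride):
            if x0 + size > ann.width:
                break
            rect = shapely_box(x0, y0, x0 + size, y0 + size)
            if any(g.contains(rect) for g in geoms):
                out.append(LabeledPatch(ann.slide_id, x0, y0, size, cls))
    return out


def point_patches(points: Sequence[tuple[float, float]], spec: PatchSpec,
                  bounds: tuple[int, int],
                  slide_id: str = "") -> list[LabeledPatch]:
    """One HGMI patch centred on each point, clamped inside ``bounds``.

    Duplicate points yield duplicate patches; an empty point list yields an
    empty result.
    """
    width, height = bounds
    size = spec.size
    out: list[LabeledPatch] = []
    for x, y in points:
        if not (0 <= x < width and 0 <= y < height):
            raise ValueError(f"point ({x}, {y}) outside bounds {bounds}")
        x0 = int(np.clip(int(round(x)) - size // 2, 0, width - size))
        y0 = int(np.clip(int(round(y)) - size // 2, 0, height - size))
        out.append(LabeledPatch(slide_id, x0, y0, size, LabelClass.HGMI))
    return out


def split_slides(slide_ids: Sequence[str], ratio: tuple[int, int], seed: int,
                 strata: dict[str, LabelClass]) -> tuple[list[str], list[str]]:
    """Stratified train/validation split *by slide*, never by patch.

    Within each slide-level category the validation share is
    ``ratio[1]/(ratio[0]+ratio[1])``, rounded to the nearest slide.
    """
    if ratio[0] <= 0 or ratio[1] <= 0:
        raise ValueError("ratio parts must be positive")
    unknown = [s for s in slide_ids if s not in strata]
    if unknown:
        raise ValueError(f"no stratum for slides: {unknown}")
    rng = np.random.default_rng(seed)
    val_frac = ratio[1] / (ratio[0] + ratio[1])
    train: list[str] = []
    val: list[str] = []
    for label in sorted({strata[s] for s in slide_ids}):
        members = [s for s in slide_ids if strata[s] == label]
        order = rng.permutation(len(members))
        n_val = int(round(len(members) * val_frac))
        shuffled = [members[i] for i in order]
        val.extend(shuffled[:n_val])
        train.extend(shuffled[n_val:])
    return train, val


def extract_patch(image: np.ndarray, patch: LabeledPatch) -> np.ndarray:
    """Crop the patch pixels (view, not copy) from the slide raster."""
    return image[patch.y0:patch.y0 + patch.size, patch.x0:patch.x0 + patch.size]


def write_patch_table(patches: Sequence[LabeledPatch], path: str | Path) -> None:
    """Text table ``slide_id x0 y0 size label`` — the training loader input."""
    with open(path, "w") as fh:
        for p in patches:
            fh.write(f"{p.slide_id} {p.x0} {p.y0} {p.size} {p.label.name}\n")


def read_patch_table(path: str | Path) -> list[LabeledPatch]:
    out: list[LabeledPatch] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{ln}: expected 5 fields")
            out.append(LabeledPatch(parts[0], int(parts[1]), int(parts[2]),
                                    int(parts[3]), LabelClass.from_name(parts[4])))
    return out
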