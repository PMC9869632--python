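"""Dense slide inference: a 6-channel probability heatmap at 1/32 scale.

Every 32 px along each axis, the classifier is evaluated on the patch
centred at that grid point (clamped so the patch stays inside the image);
its probability vector becomes one heatmap point, so the heatmap measures
``ceil(H/32) x ceil(W/32)``. Only points whose centre falls inside a
retained tissue ROI are evaluated; the rest are uncovered (all-zero, with a
boolean coverage mask). The per-point decision is the argmax channel.

The contract is per-point patch prediction; batching and the aligned
pool-once fast path are pure optimizations and match a naive per-point loop
to float tolerance (bitwise, in fact, for the reference classifier).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .labels import N_CLASSES
from .preprocess import ROIManifest
from .sampling import PatchSpec

__all__ = [
    "STRIDE",
    "Heatmap",
    "infer_heatmap",
    "decision_map",
    "coverage_mask",
    "save_heatmap",
    "load_heatmap",
]

#: Full-resolution pixels per heatmap point (the 1/32 output scale).
STRIDE = 32


@dataclass
class Heatmap:
    """probs: (6, Hh, Wh) float32; coverage: (Hh, Wh) bool."""

    probs: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        if self.probs.shape[0] != N_CLASSES:
            raise ValueError(f"heatmap must have {N_CLASSES} channels")
        if self.probs.shape[1:] != self.coverage.shape:
            raise ValueError("coverage shape must match heatmap spatial dims")

    @property
    def shape(self) -> tuple[int, int]:
        return self.coverage.shape


def heatmap_dims(height: int, width: int) -> tuple[int, int]:
    return (-(-height // STRIDE), -(-width // STRIDE))


def coverage_mask(manifest: ROIManifest, height: int, width: int) -> np.ndarray:
    """Points whose centre (32c+16, 32r+16) lies inside a retained ROI."""
    hh, ww = heatmap_dims(height, width)
    cov = np.zeros((hh, ww), dtype=bool)
    for roi in manifest.rois:
        x1 = min(roi.x0 + roi.size, width)
        y1 = min(roi.y0 + roi.size, height)
        # centres 32c+16 in [x0, x1)  <=>  c in [ceil((x0-16)/32), ceil((x1-16)/32))
        c0 = max(0, -(-(roi.x0 - 16) // STRIDE))
        c1 = min(ww, -(-(x1 - 16) // STRIDE))
        r0 = max(0, -(-(roi.y0 - 16) // STRIDE))
        r1 = min(hh, -(-(y1 - 16) // STRIDE))
        cov[r0:r1, c0:c1] = True
    return cov


def _patch_origins(rows: np.ndarray, cols: np.ndarray, size: int,
                   height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    cy = rows * STRIDE + STRIDE // 2
    cx = cols * STRIDE + STRIDE // 2
    y0 = np.clip(cy - size // 2, 0, max(0, height - size))
    x0 = np.clip(cx - size // 2, 0, max(0, width - size))
    return y0, x0


def infer_heatmap(model, image: np.ndarray, manifest: ROIManifest,
                  spec: PatchSpec | None = None,
                  batch_size: int = 256) -> Heatmap:
    """Classify every covered grid point of ``image`` (uint8 RGB HxWx3)."""
    spec = spec or PatchSpec()
    image = np.asarray(image)
    height, width = image.shape[:2]
    if spec.size > height or spec.size > width:
        raise ValueError("patch size exceeds image dimensions")
    hh, ww = heatmap_dims(height, width)
    cov = coverage_mask(manifest, height, width)
    probs = np.zeros((N_CLASSES, hh, ww), dtype=np.float32)
    if not cov.any():
        warnings.warn(f"slide {manifest.slide_id!r}: no tissue ROIs retained; "
                      "heatmap is fully uncovered")
        return Heatmap(probs=probs, coverage=cov)
    rows, cols = np.nonzero(cov)
    y0s, x0s = _patch_origins(rows, cols, spec.size, height, width)

    pooled_image = None
    f = None
    if hasattr(model, "input_size") and hasattr(model, "predict_batch_pooled"):
        f = spec.size // model.input_size
        aligned = (spec.size % model.input_size == 0 and STRIDE % f == 0
                   and (STRIDE // 2 - spec.size // 2) % f == 0
                   and (height - spec.size) % f == 0
                   and (width - spec.size) % f == 0)
        if aligned:
            hp, wp = height // f, width // f
            pooled_image = image[:hp * f, :wp * f].astype(np.float32).reshape(
                hp, f, wp, f, 3).mean(axis=(1, 3))

    for start in range(0, len(rows), batch_size):
        sl = slice(start, start + batch_size)
        if pooled_image is not None:
            n_in = model.input_size
            batch = np.stack([
                pooled_image[y // f:y // f + n_in, x // f:x // f + n_in]
                for y, x in zip(y0s[sl], x0s[sl])])
            p = model.predict_batch_pooled(batch)
        else:
            batch = np.stack([
                image[y:y + spec.size, x:x + spec.size]
                for y, x in zip(y0s[sl], x0s[sl])])
            p = model.predict_batch(batch)
        probs[:, rows[sl], cols[sl]] = np.asarray(p, dtype=np.float32).T
    return Heatmap(probs=probs, coverage=cov)


def decision_map(h: Heatmap) -> np.ndarray:
    """Argmax class per covered point (ties to the lowest channel); -1 elsewhere."""
    d = np.argmax(h.probs, axis=0).astype(np.int16)
    d[~h.coverage] = -1
    return d


def save_heatmap(h: Heatmap, path: str | Path) -> None:
    """Seven-page float32 TIFF: six probability channels then the coverage mask."""
    stack = np.concatenate([h.probs, h.coverage[None].astype(np.float32)])
    tifffile.imwrite(path, stack)


def load_heatmap(path: str | Path) -> Heatmap:
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != N_CLASSES + 1:
        raise ValueError(f"{path}: expected a {N_CLASSES + 1}-page float32 stack")
    return Heatmap(probs=stack[:N_CLASSES].astype(np.float32),
                   coverage=stack[N_CLASSES] > 0.5)
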