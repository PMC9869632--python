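"""White-background removal by Otsu thresholding over a fixed ROI grid.

Most of a scanned slide is empty glass; tiling the slide into square ROIs
(2048 px by default) and keeping only those with enough tissue makes all
downstream work proportional to tissue area. One global Otsu threshold is
computed from the whole-slide grayscale histogram (Rec.601 luminance);
pixels at or below the threshold count as tissue (tissue is darker than the
near-white background). ROIs whose tissue fraction falls below
``min_fraction`` are dropped. The retained set is persisted as a plain-text
manifest consumed by dense inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TissueROI",
    "ROIManifest",
    "otsu_threshold",
    "tissue_fraction",
    "filter_background",
    "to_grayscale",
    "write_manifest",
    "read_manifest",
    "ManifestParseError",
]

DEFAULT_ROI_SIZE = 2048
DEFAULT_MIN_FRACTION = 0.1


class ManifestParseError(ValueError):
    pass


@dataclass(frozen=True)
class TissueROI:
    grid_row: int
    grid_col: int
    x0: int
    y0: int
    size: int                 # nominal grid pitch; edge ROIs may be clipped
    tissue_fraction: float


@dataclass
class ROIManifest:
    slide_id: str
    threshold: int
    min_fraction: float
    rois: list[TissueROI] = field(default_factory=list)


def otsu_threshold(hist: np.ndarray) -> int:
    """Otsu's threshold from a 256-bin grayscale histogram.

    Maximizes between-class variance w0*w1*(mu0-mu1)^2 over thresholds t,
    where class 0 is gray <= t. Candidates are restricted to thresholds with
    nonzero class-0 mass (so a constant image yields its own gray level);
    ties go to the smallest candidate.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be non-negative")
    total = hist.sum()
    if total == 0:
        raise ValueError("histogram is empty")
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)                      # mass of class 0 at each t
    m0 = np.cumsum(hist * levels)             # unnormalized first moment
    w1 = total - w0
    mean_total = m0[-1] / total
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, m0 / w0, 0.0)
        mu1 = np.where(w1 > 0, (m0[-1] - m0) / w1, 0.0)
    var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[w0 == 0] = -np.inf            # candidate rule
    _ = mean_total
    return int(np.argmax(var_between))        # argmax takes the first maximum


def tissue_fraction(roi_pixels: np.ndarray, threshold: int) -> float:
    """Fraction of pixels at or below ``threshold`` (darker = tissue)."""
    roi_pixels = np.asarray(roi_pixels)
    if roi_pixels.size == 0:
        raise ValueError("empty ROI")
    return float(np.mean(roi_pixels <= threshold))


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Rec.601 luminance of an RGB raster, rounded to uint8."""
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(np.uint8)
    gray = (0.299 * image[..., 0] + 0.587 * image[..., 1] + 0.114 * image[..., 2])
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


def filter_background(image: np.ndarray, slide_id: str = "",
                      roi_size: int = DEFAULT_ROI_SIZE,
                      min_fraction: float = DEFAULT_MIN_FRACTION,
                      min_contrast: float = 30.0) -> ROIManifest:
    """Tile the slide into ``roi_size`` squares and keep tissue-bearing ones.

    The grid uses ceiling division, so edge ROIs are clipped to the image
    and their fraction is computed over the pixels they actually contain.
    The union of all grid ROIs (kept plus dropped) tiles the image exactly.

    Otsu always splits the histogram somewhere, even on a slide that is all
    background noise; the split only marks tissue when the two classes are
    genuinely apart. If the class means differ by less than ``min_contrast``
    gray levels the slide is treated as tissue-free and nothing is retained.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if not (0 < min_fraction <= 1):
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    gray = to_grayscale(image)
    hist = np.bincount(gray.ravel(), minlength=256)[:256]
    thr = otsu_threshold(hist)
    levels = np.arange(256)
    w0, w1 = hist[:thr + 1].sum(), hist[thr + 1:].sum()
    mu0 = (hist[:thr + 1] * levels[:thr + 1]).sum() / w0 if w0 else 0.0
    mu1 = (hist[thr + 1:] * levels[thr + 1:]).sum() / w1 if w1 else mu0
    if mu1 - mu0 < min_contrast:
        return ROIManifest(slide_id=slide_id, threshold=thr,
                           min_fraction=min_fraction, rois=[])
    h, w = gray.shape
    rois: list[TissueROI] = []
    for r in range(-(-h // roi_size)):
        for c in range(-(-w // roi_size)):
            y0, x0 = r * roi_size, c * roi_size
            block = gray[y0:min(y0 + roi_size, h), x0:min(x0 + roi_size, w)]
            frac = tissue_fraction(block, thr)
            if frac >= min_fraction:
                rois.append(TissueROI(r, c, x0, y0, roi_size, frac))
    return ROIManifest(slide_id=slide_id, threshold=thr,
                       min_fraction=min_fraction, rois=rois)


def write_manifest(m: ROIManifest, path: str | Path) -> None:
    """One header line, then ``grid_row grid_col x0 y0 size tissue_fraction``."""
    with open(path, "w") as fh:
        fh.write(f"{m.slide_id} {m.threshold} {m.min_fraction:.6f}\n")
        for roi in m.rois:
            fh.write(f"{roi.grid_row} {roi.grid_col} {roi.x0} {roi.y0} "
                     f"{roi.size} {roi.tissue_fraction:.6f}\n")


def read_manifest(path: str | Path) -> ROIManifest:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ManifestParseError(f"{path}: empty manifest")
    head = lines[0].split()
    if len(head) != 3:
        raise ManifestParseError(f"{path}:1: expected 'slide_id threshold min_fraction'")
    try:
        manifest = ROIManifest(slide_id=head[0], threshold=int(head[1]),
                               min_fraction=float(head[2]))
    except ValueError as exc:
        raise ManifestParseError(f"{path}:1: {exc}") from exc
    for ln, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ManifestParseError(
                f"{path}:{ln}: expected 6 fields, got {len(parts)}")
        try:
            manifest.rois.append(TissueROI(
                int(parts[0]), int(parts[1]), int(parts[2]), int(parts[3]),
                int(parts[4]), float(parts[5])))
        except ValueError as exc:
            raise ManifestParseError(f"{path}:{ln}: {exc}") from exc
    return manifest
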