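"""Overlay rendering of slide-level predictions.

Diagnostic-class regions of the decision map are tinted onto the slide:
HGMI red, HGNMI purple, LGNMI yellow by default. The decision map is
upscaled x32 (nearest neighbour) back to slide resolution. Two modes:
``mask`` tints every decided point at fixed opacity; ``heatmap`` scales the
tint by the point's class probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import STRIDE, Heatmap
from .labels import DIAGNOSTIC_CLASSES, LabelClass

__all__ = ["OverlayStyle", "render_overlay"]


@dataclass(frozen=True)
class OverlayStyle:
    colors: dict[LabelClass, tuple[int, int, int]] = field(
        default_factory=lambda: {
            LabelClass.HGMI: (255, 0, 0),
            LabelClass.HGNMI: (128, 0, 128),
            LabelClass.LGNMI: (255, 255, 0),
        })
    opacity: float = 0.45

    def __post_init__(self) -> None:
        if not (0.0 <= self.opacity <= 1.0):
            raise ValueError("opacity must be in [0, 1]")
        if len(set(self.colors.values())) != len(self.colors):
            raise ValueError("overlay colors must be distinct")


def render_overlay(image: np.ndarray, d: np.ndarray,
                   style: OverlayStyle | None = None,
                   heatmap: Heatmap | None = None,
                   mode: str = "mask") -> np.ndarray:
    """Tint diagnostic regions of the decision map onto the slide raster.

    IA/NIA/NA and uncovered points are left untouched. ``mode="heatmap"``
    requires the heatmap and modulates opacity by class probability.
    """
    style = style or OverlayStyle()
    image = np.asarray(image)
    hh, ww = d.shape
    if (-(-image.shape[0] // STRIDE), -(-image.shape[1] // STRIDE)) != (hh, ww):
        raise ValueError(
            f"decision map {d.shape} does not match image {image.shape[:2]} "
            f"at 1/{STRIDE} scale")
    if mode not in ("mask", "heatmap"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "heatmap" and heatmap is None:
        raise ValueError("heatmap mode needs the heatmap")
    out = image.astype(np.float32).copy()
    h, w = image.shape[:2]
    for cls in DIAGNOSTIC_CLASSES:
        if cls not in style.colors:
            continue
        sel = d == cls.channel_index
        if not sel.any():
            continue
        alpha = np.where(sel, style.opacity, 0.0).astype(np.float32)
        if mode == "heatmap":
            alpha = alpha * heatmap.probs[cls.channel_index]
        alpha_full = np.repeat(np.repeat(alpha, STRIDE, 0), STRIDE, 1)[:h, :w]
        color = np.asarray(style.colors[cls], dtype=np.float32)
        out = out * (1 - alpha_full[..., None]) + color * alpha_full[..., None]
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
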