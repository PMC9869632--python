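"""Deterministic synthetic slides with six procedurally textured tissue classes.

Real TURBT slides cannot be redistributed, so the package ships a generator
that emulates, at cartoon fidelity, the features the pipeline depends on:

* near-white background (so Otsu background filtering is meaningful);
* high-grade tumour texture: dense, large, dark nuclei on a saturated base;
* low-grade tumour texture: sparser, smaller nuclei on a lighter base;
* muscle texture: striped pink fibre bands with scarce nuclei;
* illegible areas (IA): tumour texture blurred as if out of focus;
* normal interstitium (NIA): pale base with sparse small nuclei;
* noise areas (NA): near-white base with large saturated stain blobs and no
  nuclei.

A muscle-invasive (HGMI) slide contains a high-grade tumour region abutting
a muscle region; the shared border is the tumour-muscle junction where
HGMI patches are sampled. Annotation convention: the muscle compartment is
annotated with the HGMI label (muscle adjacent to high-grade tumour is what
defines the category), tumour regions with HGNMI/LGNMI, so junctions are
recoverable from an :class:`~uroslide.annotations.AnnotationSet` alone.

All randomness flows from a single integer seed; identical specs produce
pixel-identical slides.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage
from shapely.geometry import box as shapely_box

from .annotations import AnnotationSet, Polygon, write_annotations
from .labels import LabelClass

__all__ = [
    "RegionKind",
    "SyntheticSpec",
    "SyntheticSlide",
    "SpecError",
    "generate_slide",
    "generate_cohort",
    "cohort_specs",
    "junction_points",
    "save_slide",
    "load_image",
    "write_index",
    "read_index",
]


class SpecError(ValueError):
    """Invalid synthetic-slide specification."""


class RegionKind(enum.Enum):
    """Texture vocabulary for placed regions (muscle is not a patch class)."""

    HG_TUMOR = "hg_tumor"
    LG_TUMOR = "lg_tumor"
    MUSCLE = "muscle"
    IA = "ia"
    NIA = "nia"
    NA = "na"


#: Annotation label carried by each region kind. Muscle is annotated HGMI:
#: its presence next to high-grade tumour is what defines that category.
REGION_LABEL: dict[RegionKind, LabelClass] = {
    RegionKind.HG_TUMOR: LabelClass.HGNMI,
    RegionKind.LG_TUMOR: LabelClass.LGNMI,
    RegionKind.MUSCLE: LabelClass.HGMI,
    RegionKind.IA: LabelClass.IA,
    RegionKind.NIA: LabelClass.NIA,
    RegionKind.NA: LabelClass.NA,
}


@dataclass(frozen=True)
class TextureParams:
    base_rgb: tuple[float, float, float]
    nucleus_density: float = 0.0          # nuclei per px^2
    nucleus_radius: tuple[float, float] = (2.0, 4.0)
    nucleus_rgb: tuple[float, float, float] = (64.0, 32.0, 96.0)
    stripe_amp: float = 0.0               # muscle fibre banding amplitude
    stripe_period: float = 32.0           # px
    blur_sigma: float = 0.0               # IA defocus
    blob_density: float = 0.0             # NA stain blobs per px^2
    blob_radius: tuple[float, float] = (16.0, 40.0)
    blob_rgb: tuple[float, float, float] = (70.0, 80.0, 150.0)


DEFAULT_TEXTURES: dict[RegionKind, TextureParams] = {
    RegionKind.HG_TUMOR: TextureParams(
        base_rgb=(168, 110, 172), nucleus_density=6e-4,
        nucleus_radius=(3, 6), nucleus_rgb=(64, 32, 96)),
    RegionKind.LG_TUMOR: TextureParams(
        base_rgb=(230, 140, 170), nucleus_density=2.5e-4,
        nucleus_radius=(2, 4), nucleus_rgb=(130, 60, 110)),
    RegionKind.MUSCLE: TextureParams(
        base_rgb=(210, 112, 122), nucleus_density=0.5e-4,
        nucleus_radius=(2, 4), nucleus_rgb=(90, 50, 110),
        stripe_amp=38.0, stripe_period=32.0),
    RegionKind.IA: TextureParams(
        base_rgb=(168, 110, 172), nucleus_density=6e-4,
        nucleus_radius=(3, 6), nucleus_rgb=(64, 32, 96), blur_sigma=10.0),
    RegionKind.NIA: TextureParams(
        base_rgb=(238, 214, 228), nucleus_density=0.8e-4,
        nucleus_radius=(1.5, 3), nucleus_rgb=(150, 110, 160)),
    RegionKind.NA: TextureParams(
        base_rgb=(242, 238, 240), blob_density=6e-5,
        blob_radius=(16, 40), blob_rgb=(70, 80, 150)),
}


Rect = tuple[int, int, int, int]  # x0, y0, w, h — half-open


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic slide; the seed fixes everything."""

    width: int = 2048
    height: int = 2048
    layout: tuple[tuple[RegionKind, Rect], ...] = ()
    textures: dict[RegionKind, TextureParams] = field(
        default_factory=lambda: dict(DEFAULT_TEXTURES))
    noise_sd: float = 6.0
    background_rgb: tuple[float, float, float] = (245.0, 244.0, 246.0)
    junction_spacing: int = 128
    seed: int = 0

    def validate(self) -> None:
        if self.width < 64 or self.height < 64:
            raise SpecError("slide dimensions too small")
        kinds = [k for k, _ in self.layout]
        if RegionKind.HG_TUMOR in kinds and RegionKind.LG_TUMOR in kinds:
            raise SpecError(
                "high-grade and low-grade tumour regions in the same slide "
                "are excluded by study design")
        for kind, (x0, y0, w, h) in self.layout:
            if w <= 0 or h <= 0:
                raise SpecError(f"{kind}: empty placement rectangle")
            if x0 < 0 or y0 < 0 or x0 + w > self.width - 1 or y0 + h > self.height - 1:
                raise SpecError(f"{kind}: rectangle {(x0, y0, w, h)} outside image")


@dataclass
class SyntheticSlide:
    slide_id: str
    image: np.ndarray                     # uint8 HxWx3
    annotations: AnnotationSet
    wsi_label: Optional[LabelClass]
    junction_points: list[tuple[float, float]]


def _rect_polygon(label: LabelClass, rect: Rect) -> Polygon:
    x0, y0, w, h = rect
    return Polygon(label=label, vertices=[
        (x0, y0), (x0 + w, y0), (x0 + w, y0 + h), (x0, y0 + h)])


_DISK_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _disk_offsets(r: int) -> tuple[np.ndarray, np.ndarray]:
    if r not in _DISK_CACHE:
        yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
        sel = yy * yy + xx * xx <= r * r
        _DISK_CACHE[r] = (yy[sel], xx[sel])
    return _DISK_CACHE[r]


def _stamp_disks(region: np.ndarray, n: int, radius: tuple[float, float],
                 rgb: Sequence[float], rng: np.random.Generator) -> None:
    """Stamp ``n`` filled disks of the given colour into ``region`` (in place)."""
    h, w = region.shape[:2]
    if n <= 0 or h == 0 or w == 0:
        return
    ys = rng.uniform(0, h, n)
    xs = rng.uniform(0, w, n)
    rs = rng.uniform(radius[0], radius[1], n)
    col = np.asarray(rgb, dtype=np.float32)
    for y, x, r in zip(ys, xs, rs):
        dy, dx = _disk_offsets(int(round(r)))
        py = (dy + int(y)).clip(0, h - 1)
        px = (dx + int(x)).clip(0, w - 1)
        region[py, px] = col


def _render_region(shape: tuple[int, int], kind: RegionKind,
                   params: TextureParams, rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    tex = np.empty((h, w, 3), dtype=np.float32)
    tex[:] = np.asarray(params.base_rgb, dtype=np.float32)
    if params.stripe_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        bands = params.stripe_amp * np.sin(
            2 * np.pi * np.arange(h)[:, None] / params.stripe_period + phase)
        tex += bands[..., None].astype(np.float32)
    n_nuclei = rng.poisson(params.nucleus_density * h * w)
    _stamp_disks(tex, n_nuclei, params.nucleus_radius, params.nucleus_rgb, rng)
    if params.blob_density > 0:
        n_blobs = max(1, rng.poisson(params.blob_density * h * w))
        _stamp_disks(tex, n_blobs, params.blob_radius, params.blob_rgb, rng)
    if params.blur_sigma > 0:
        for c in range(3):
            tex[..., c] = ndimage.gaussian_filter(tex[..., c], params.blur_sigma)
    return tex


def generate_slide(spec: SyntheticSpec, slide_id: str = "synthetic") -> SyntheticSlide:
    """Render one slide. Deterministic: same spec, same pixels."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    img = np.empty((spec.height, spec.width, 3), dtype=np.float32)
    img[:] = np.asarray(spec.background_rgb, dtype=np.float32)
    for kind, (x0, y0, w, h) in spec.layout:
        params = spec.textures[kind]
        img[y0:y0 + h, x0:x0 + w] = _render_region((h, w), kind, params, rng)
    img += rng.normal(0.0, spec.noise_sd, img.shape).astype(np.float32)
    image = np.clip(img, 0, 255).astype(np.uint8)

    polygons = [_rect_polygon(REGION_LABEL[kind], rect) for kind, rect in spec.layout]
    wsi_label = _derive_wsi_label(spec)
    ann = AnnotationSet(slide_id=slide_id, width=spec.width, height=spec.height,
                        polygons=polygons, wsi_label=wsi_label)
    pts = junction_points(ann, spec.junction_spacing) if wsi_label == LabelClass.HGMI else []
    return SyntheticSlide(slide_id=slide_id, image=image, annotations=ann,
                          wsi_label=wsi_label, junction_points=pts)


def _derive_wsi_label(spec: SyntheticSpec) -> Optional[LabelClass]:
    hg = [shapely_box(x, y, x + w, y + h)
          for k, (x, y, w, h) in spec.layout if k == RegionKind.HG_TUMOR]
    mus = [shapely_box(x, y, x + w, y + h)
           for k, (x, y, w, h) in spec.layout if k == RegionKind.MUSCLE]
    lg = any(k == RegionKind.LG_TUMOR for k, _ in spec.layout)
    for t in hg:
        for m in mus:
            if t.intersection(m).length > 0:
                return LabelClass.HGMI
    if hg:
        return LabelClass.HGNMI
    if lg:
        return LabelClass.LGNMI
    return None


def junction_points(ann: AnnotationSet, spacing: float) -> list[tuple[float, float]]:
    """Points along shared tumour-muscle borders, one every ``spacing`` px.

    Tumour polygons carry the HGNMI label, muscle polygons the HGMI label
    (see module docstring). A border shorter than ``spacing`` still yields
    one point at its midpoint, so every muscle-invasive slide has at least
    one HGMI sampling point.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    tumours = [p.to_shapely() for p in ann.by_label(LabelClass.HGNMI)]
    muscles = [p.to_shapely() for p in ann.by_label(LabelClass.HGMI)]
    pts: list[tuple[float, float]] = []
    for t in tumours:
        for m in muscles:
            inter = t.intersection(m)
            lines = getattr(inter, "geoms", [inter])
            for line in lines:
                length = getattr(line, "length", 0.0)
                if length <= 0:
                    continue
                n = max(1, int(length // spacing))
                if n == 1:
                    p = line.interpolate(0.5, normalized=True)
                    pts.append((p.x, p.y))
                else:
                    for i in range(n):
                        p = line.interpolate((i + 0.5) * spacing)
                        pts.append((p.x, p.y))
    return pts


# ---------------------------------------------------------------------------
# cohort generation

def _random_layout(label: LabelClass, width: int, height: int,
                   rng: np.random.Generator) -> tuple[tuple[RegionKind, Rect], ...]:
    """Randomized non-overlapping layout for one slide of the given category.

    Diagnostic tissue occupies the left half; interstitium, an illegible
    patch and a stain blot sit in fixed slots on the right, jittered. In
    HGMI slides the tumour is a strip abutting a muscle strip so that most
    tumour falls within one patch radius of the junction, as in a focus of
    muscle invasion.
    """
    def rect(fx, fy, fw, fh, jx=0.02, jy=0.03, jw=0.02, jh=0.04) -> Rect:
        x0 = (fx + rng.uniform(-jx, jx)) * width
        y0 = (fy + rng.uniform(-jy, jy)) * height
        w = (fw + rng.uniform(-jw, jw)) * width
        h = (fh + rng.uniform(-jh, jh)) * height
        return (int(x0), int(y0), int(w), int(h))

    layout: list[tuple[RegionKind, Rect]] = []
    if label == LabelClass.HGMI:
        # narrow strips: muscle invasion is a focus, not a sheet — nearly
        # every tumour point lies within one patch radius of the junction
        tx0, ty0, tw, th = rect(0.10, 0.12, 0.080, 0.55, jw=0.005, jh=0.06)
        layout.append((RegionKind.HG_TUMOR, (tx0, ty0, tw, th)))
        mw = int((0.100 + rng.uniform(-0.01, 0.01)) * width)
        layout.append((RegionKind.MUSCLE, (tx0 + tw, ty0, mw, th)))
    elif label == LabelClass.HGNMI:
        layout.append((RegionKind.HG_TUMOR, rect(0.06, 0.08, 0.38, 0.70)))
    elif label == LabelClass.LGNMI:
        layout.append((RegionKind.LG_TUMOR, rect(0.06, 0.08, 0.38, 0.70)))
    else:
        raise SpecError(f"not a diagnostic category: {label}")
    layout.append((RegionKind.NIA, rect(0.56, 0.06, 0.28, 0.30, jw=0.02, jh=0.02)))
    layout.append((RegionKind.IA, rect(0.57, 0.41, 0.22, 0.22, jy=0.01, jw=0.01, jh=0.01)))
    layout.append((RegionKind.NA, rect(0.57, 0.70, 0.22, 0.22, jy=0.01, jw=0.01, jh=0.01)))
    return tuple(layout)


def cohort_specs(n_per_class: tuple[int, int, int],
                 base_spec: SyntheticSpec,
                 seed: int) -> list[tuple[str, SyntheticSpec, LabelClass]]:
    """Slide ids, specs and labels for a cohort; cheap (no pixels rendered).

    ``n_per_class`` orders counts as (HGMI, HGNMI, LGNMI). Per-slide seeds
    are derived from ``seed``; two calls with the same arguments describe an
    identical cohort.
    """
    if any(n < 0 for n in n_per_class):
        raise ValueError("slide counts must be non-negative")
    rng = np.random.default_rng(seed)
    labels = [LabelClass.HGMI] * n_per_class[0] + \
             [LabelClass.HGNMI] * n_per_class[1] + \
             [LabelClass.LGNMI] * n_per_class[2]
    out = []
    for i, label in enumerate(labels):
        slide_seed = int(rng.integers(0, 2**31 - 1))
        layout_rng = np.random.default_rng(slide_seed)
        layout = _random_layout(label, base_spec.width, base_spec.height, layout_rng)
        spec = replace(base_spec, layout=layout, seed=slide_seed)
        out.append((f"slide_{i:04d}_{label.name.lower()}", spec, label))
    return out


def generate_cohort(n_per_class: tuple[int, int, int],
                    base_spec: SyntheticSpec,
                    seed: int) -> list[SyntheticSlide]:
    """Render a full cohort into memory (use :func:`iter_cohort` for large n)."""
    return list(iter_cohort(n_per_class, base_spec, seed))


def iter_cohort(n_per_class: tuple[int, int, int],
                base_spec: SyntheticSpec,
                seed: int) -> Iterator[SyntheticSlide]:
    for slide_id, spec, _label in cohort_specs(n_per_class, base_spec, seed):
        yield generate_slide(spec, slide_id=slide_id)


# ---------------------------------------------------------------------------
# disk I/O

def save_slide(slide: SyntheticSlide, directory: str | Path) -> tuple[Path, Path]:
    """Write ``<id>.png`` and ``<id>.xml``; returns the two paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img_path = directory / f"{slide.slide_id}.png"
    ann_path = directory / f"{slide.slide_id}.xml"
    Image.fromarray(slide.image).save(img_path)
    write_annotations(slide.annotations, ann_path)
    return img_path, ann_path


def load_image(path: str | Path) -> np.ndarray:
    """Read a slide raster (PNG/TIFF) as uint8 RGB HxWx3."""
    arr = np.asarray(Image.open(path).convert("RGB"))
    return arr


def write_index(entries: list[tuple[str, str, str]], path: str | Path) -> None:
    """Cohort manifest: one line per slide, ``slide_id path wsi_label``."""
    with open(path, "w") as fh:
        for slide_id, img_path, label in entries:
            fh.write(f"{slide_id} {img_path} {label}\n")


def read_index(path: str | Path) -> list[tuple[str, str, LabelClass]]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 'slide_id path label'")
            out.append((parts[0], parts[1], LabelClass.from_name(parts[2])))
    return out
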