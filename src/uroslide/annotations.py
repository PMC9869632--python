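"""Polygon annotations in an ASAP-style XML dialect.

Pathologist annotations are polygons in full-resolution slide pixel
coordinates, each carrying one of the six :class:`~uroslide.labels.LabelClass`
labels. The on-disk format mirrors the XML layout of open slide-annotation
viewers: one ``Annotation`` element per polygon with a ``PartOfGroup`` label
attribute and an ordered ``Coordinate`` list. The exact dialect is frozen
here:

.. code-block:: xml

    <SlideAnnotations SlideID="s01" Width="2048" Height="2048" WSILabel="HGMI">
      <Annotations>
        <Annotation Name="poly_0" Type="Polygon" PartOfGroup="HGNMI">
          <Coordinates>
            <Coordinate Order="0" X="10.0" Y="20.0"/>
            ...
          </Coordinates>
        </Annotation>
      </Annotations>
    </SlideAnnotations>

Conventions (used consistently across the package): 0-based pixel
coordinates, x rightward, y downward; rectangles are half-open
``[x0, x0+w) x [y0, y0+h)``; polygons are implicitly closed. Overlapping
polygons are resolved in file order, last writer wins.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import shapely

from .labels import DIAGNOSTIC_CLASSES, LabelClass

__all__ = [
    "Polygon",
    "AnnotationSet",
    "read_annotations",
    "write_annotations",
    "rasterize_labels",
    "AnnotationParseError",
]


class AnnotationParseError(ValueError):
    """Malformed annotation file (reports the offending line when known)."""


@dataclass
class Polygon:
    """A labeled, implicitly closed polygon in full-resolution pixels."""

    label: LabelClass
    vertices: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        arr = np.asarray(self.vertices, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("polygon vertices must be finite")
        if np.any(arr < 0):
            raise ValueError("polygon vertices must be non-negative")
        if self.to_shapely().area == 0:
            raise ValueError("polygon encloses zero area")

    def to_shapely(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)


@dataclass
class AnnotationSet:
    """All annotations of one slide, plus the slide-level diagnostic label."""

    slide_id: str
    width: int
    height: int
    polygons: list[Polygon] = field(default_factory=list)
    wsi_label: Optional[LabelClass] = None

    def __post_init__(self) -> None:
        if self.wsi_label is not None and self.wsi_label not in DIAGNOSTIC_CLASSES:
            raise ValueError(f"wsi_label must be diagnostic, got {self.wsi_label}")
        for poly in self.polygons:
            for x, y in poly.vertices:
                if not (0 <= x < self.width and 0 <= y < self.height):
                    raise ValueError(
                        f"vertex ({x}, {y}) outside slide bounds "
                        f"[0,{self.width})x[0,{self.height})"
                    )

    def by_label(self, label: LabelClass) -> list[Polygon]:
        return [p for p in self.polygons if p.label == label]


def _fmt(value: float) -> str:
    """Shortest exact decimal representation (round-trips through float)."""
    return repr(float(value))


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    """Write ``ann`` as XML. Byte-deterministic for identical input."""
    root = ET.Element(
        "SlideAnnotations",
        SlideID=ann.slide_id,
        Width=str(ann.width),
        Height=str(ann.height),
    )
    if ann.wsi_label is not None:
        root.set("WSILabel", ann.wsi_label.name)
    annots = ET.SubElement(root, "Annotations")
    for i, poly in enumerate(ann.polygons):
        el = ET.SubElement(
            annots,
            "Annotation",
            Name=f"poly_{i}",
            Type="Polygon",
            PartOfGroup=poly.label.name,
        )
        coords = ET.SubElement(el, "Coordinates")
        for j, (x, y) in enumerate(poly.vertices):
            ET.SubElement(coords, "Coordinate", Order=str(j), X=_fmt(x), Y=_fmt(y))
    tree = ET.ElementTree(root)
    ET.indent(tree, space="  ")
    tree.write(path, encoding="utf-8", xml_declaration=True)


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read an annotation XML file written by :func:`write_annotations`.

    Raises :class:`AnnotationParseError` on malformed XML (naming the line)
    and :class:`~uroslide.labels.VocabularyError` for labels outside the
    six-class vocabulary.
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        line, col = exc.position
        raise AnnotationParseError(
            f"{path}: malformed XML at line {line}, column {col}: {exc}"
        ) from exc
    root = tree.getroot()
    if root.tag != "SlideAnnotations":
        raise AnnotationParseError(f"{path}: unexpected root element {root.tag!r}")
    wsi_label = root.get("WSILabel")
    polygons: list[Polygon] = []
    annots = root.find("Annotations")
    if annots is not None:
        for el in annots.findall("Annotation"):
            label = LabelClass.from_name(el.get("PartOfGroup", ""))
            coords = el.find("Coordinates")
            pts: list[tuple[int, tuple[float, float]]] = []
            if coords is not None:
                for c in coords.findall("Coordinate"):
                    pts.append(
                        (int(c.get("Order", "0")), (float(c.get("X")), float(c.get("Y"))))
                    )
            pts.sort(key=lambda t: t[0])
            polygons.append(Polygon(label=label, vertices=[p for _, p in pts]))
    return AnnotationSet(
        slide_id=root.get("SlideID", ""),
        width=int(root.get("Width")),
        height=int(root.get("Height")),
        polygons=polygons,
        wsi_label=LabelClass.from_name(wsi_label) if wsi_label else None,
    )


def rasterize_labels(ann: AnnotationSet, downscale: int) -> np.ndarray:
    """Rasterize annotations to an integer label mask at ``1/downscale`` scale.

    Each cell holds the channel index of the polygon covering its *center*
    (last polygon in file order wins); uncovered cells hold -1. The mask has
    shape ``(ceil(height/downscale), ceil(width/downscale))``.
    """
    if downscale <= 0:
        raise ValueError(f"downscale must be positive, got {downscale}")
    h = -(-ann.height // downscale)
    w = -(-ann.width // downscale)
    mask = np.full((h, w), -1, dtype=np.int16)
    if not ann.polygons:
        return mask
    cx = (np.arange(w) + 0.5) * downscale
    cy = (np.arange(h) + 0.5) * downscale
    gx, gy = np.meshgrid(cx, cy)
    for poly in ann.polygons:
        geom = poly.to_shapely()
        x0, y0, x1, y1 = geom.bounds
        ci = (cx >= x0) & (cx <= x1)
        ri = (cy >= y0) & (cy <= y1)
        if not (ci.any() and ri.any()):
            continue
        sub = np.ix_(ri, ci)
        inside = shapely.contains_xy(geom, gx[sub], gy[sub])
        block = mask[sub]
        block[inside] = poly.label.channel_index
        mask[sub] = block
    return mask
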