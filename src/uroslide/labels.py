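"""Tissue-class vocabulary for bladder-cancer slide analysis.

Six patch-level classes are recognised, in a fixed channel order that every
probability vector and heatmap in this package follows:

======  =====  ==================================================
code    index  meaning
======  =====  ==================================================
HGMI    0      high-grade tumour with muscle invasion (tumour
               cells and bladder muscle tissue in one field)
HGNMI   1      high-grade tumour, no muscle present
LGNMI   2      low-grade tumour, no muscle present
IA      3      illegible area (blurred during scanning)
NIA     4      normal interstitial (mesenchymal) area
NA      5      noise area (non-cellular staining artefact)
======  =====  ==================================================

The first three also serve as the slide-level diagnostic categories:
muscle-invasive high-grade, non-muscle-invasive high-grade, and
non-muscle-invasive low-grade carcinoma.
"""

from __future__ import annotations

import enum


class LabelClass(enum.IntEnum):
    """One of the six tissue classes; the integer value is the channel index."""

    HGMI = 0
    HGNMI = 1
    LGNMI = 2
    IA = 3
    NIA = 4
    NA = 5

    @property
    def channel_index(self) -> int:
        return int(self)

    @property
    def is_diagnostic(self) -> bool:
        """Whether this class is one of the three slide-level categories."""
        return self in DIAGNOSTIC_CLASSES

    @classmethod
    def from_name(cls, name: str) -> "LabelClass":
        try:
            return cls[name]
        except KeyError:
            raise VocabularyError(
                f"unknown label {name!r}; expected one of "
                f"{[m.name for m in cls]}"
            ) from None


#: The three slide-level diagnostic categories, in channel order.
DIAGNOSTIC_CLASSES: tuple[LabelClass, ...] = (
    LabelClass.HGMI,
    LabelClass.HGNMI,
    LabelClass.LGNMI,
)

#: All six classes in channel order.
ALL_CLASSES: tuple[LabelClass, ...] = tuple(LabelClass)

N_CLASSES: int = 6


class VocabularyError(ValueError):
    """A label string outside the six-class vocabulary."""
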