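"""Deterministic four-class dendritic spine classification.

Spines are assigned by head/neck geometry to one of the four conventional
classes: mushroom (M), long thin (LT), stubby (S) and filopodia (F).

* headed, neck thicker than it is long (neck diameter > neck length) → M
* headed, neck longer than or equal to its diameter → LT (ties favour LT,
  because M demands a strictly thicker-than-long neck)
* headless, total length < 1 µm → S
* headless, total length > 10 µm → F

Headless protrusions with total length in [1 µm, 10 µm] fall between the S
and F criteria.  They are assigned to S but flagged (``S_EXT``) so the
partition stays exhaustive while the gap remains auditable; counts for
flagged spines are reported separately downstream.
"""

from __future__ import annotations

from collections import Counter
from enum import Enum
from typing import Iterable

from .morphology import SpineMetrics

__all__ = ["SpineClass", "CLASS_LABELS", "classify_spine", "classify_all"]

#: Reporting order of the four classes.
CLASS_LABELS = ("M", "LT", "S", "F")


class SpineClass(Enum):
    """Spine class label; S_EXT is a gap-rule stubby (reported as S, flagged)."""

    M = "M"
    LT = "LT"
    S = "S"
    F = "F"
    S_EXT = "S_EXT"

    @property
    def reported(self) -> str:
        """Label used in density/reporting tables (S_EXT folds into S)."""
        return "S" if self is SpineClass.S_EXT else self.value

    @property
    def gap_flag(self) -> bool:
        return self is SpineClass.S_EXT


def classify_spine(
    metrics: SpineMetrics, headless_filopodium_min_length: float = 10.0
) -> SpineClass:
    """Classify one spine from its measured geometry (total function)."""
    if metrics.has_head:
        if metrics.neck_max_diameter > metrics.neck_length:
            return SpineClass.M
        return SpineClass.LT
    if metrics.total_length < 1.0:
        return SpineClass.S
    if metrics.total_length > headless_filopodium_min_length:
        return SpineClass.F
    return SpineClass.S_EXT


def classify_all(
    spines: Iterable[SpineMetrics], headless_filopodium_min_length: float = 10.0
) -> tuple[list[SpineClass], dict[str, int]]:
    """Classify a collection of spines.

    Returns the per-spine labels and a count summary over the reported
    labels (M, LT, S, F) plus an ``S_EXT`` entry tallying gap-rule stubbies
    (already included in the S count).  Counts over M/LT/S/F always sum to
    the number of input spines.
    """
    labels = [classify_spine(m, headless_filopodium_min_length) for m in spines]
    counts = Counter(lab.reported for lab in labels)
    summary = {c: counts.get(c, 0) for c in CLASS_LABELS}
    summary["S_EXT"] = sum(1 for lab in labels if lab.gap_flag)
    return labels, summary
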