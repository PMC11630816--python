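"""Element segmentation of call contours and five-subtype categorization.

A contour is cut into constant-frequency *elements* at instantaneous
frequency jumps (|delta f| above a threshold between points close enough
in time).  Short leading/trailing portions (*prefix*/*suffix*) under 1/5th
the length of their neighboring element are trimmed before counting:

* 1 element -> ``flat``
* 2 elements, rising -> ``step_up``; falling -> ``step_down``
* 3 elements (middle differs from both neighbors) -> ``insert``
* more than 3 -> ``complex``

Element frequency is summarized by the median of its contour samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from usv44.calltable_io import CallContour, Subtype


@dataclass(frozen=True)
class Element:
    """A constant-frequency segment of a call (times call-relative)."""

    start: float
    end: float
    median_frequency: float

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError("element end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SubtypeParams:
    jump_threshold: float = 4_000.0  # Hz
    max_jump_gap: float = 0.010  # s; jumps across longer contour gaps are drift
    affix_ratio: float = 0.2  # 1/5th rule
    flatness_tolerance: float = 2_000.0  # Hz

    def __post_init__(self):
        if min(self.jump_threshold, self.max_jump_gap, self.flatness_tolerance) <= 0:
            raise ValueError("all parameters must be positive")
        if not 0 < self.affix_ratio < 1:
            raise ValueError("affix_ratio must be in (0, 1)")


def segment_elements(contour: CallContour, params: SubtypeParams = SubtypeParams()) -> list[Element]:
    """Cut the contour at instantaneous frequency jumps.

    A boundary falls between consecutive points i, i+1 when
    ``|f[i+1] - f[i]| > jump_threshold`` and ``t[i+1] - t[i] <= max_jump_gap``.
    Element edges are placed at the midpoint between the two points, so the
    concatenated elements exactly cover the contour's time span.
    """
    t, f = contour.times, contour.frequencies
    if t.size < 2:
        raise ValueError("contour must have at least 2 points")
    df = np.abs(np.diff(f))
    dt = np.diff(t)
    cuts = np.flatnonzero((df > params.jump_threshold) & (dt <= params.max_jump_gap))
    starts = np.concatenate(([0], cuts + 1))
    ends = np.concatenate((cuts, [t.size - 1]))  # inclusive point indices
    elements = []
    for s, e in zip(starts, ends):
        left = t[0] if s == 0 else (t[s - 1] + t[s]) / 2
        right = t[-1] if e == t.size - 1 else (t[e] + t[e + 1]) / 2
        elements.append(Element(start=float(left), end=float(right), median_frequency=float(np.median(f[s : e + 1]))))
    return elements


def trim_affixes(elements: Sequence[Element], params: SubtypeParams = SubtypeParams()) -> list[Element]:
    """Drop a prefix/suffix element shorter than ``affix_ratio`` times its
    neighbor.  Applied exactly once per end, on the untrimmed neighbors; at
    least one element is always retained."""
    if not elements:
        raise ValueError("need at least one element")
    elements = list(elements)
    if len(elements) == 1:
        return elements
    drop_first = elements[0].duration < params.affix_ratio * elements[1].duration
    drop_last = elements[-1].duration < params.affix_ratio * elements[-2].duration
    if drop_first and drop_last and len(elements) == 2:
        # mutually exclusive in practice (a < 0.2b and b < 0.2a cannot both
        # hold), but guard the degenerate case: keep the longer one
        if elements[0].duration >= elements[1].duration:
            drop_first = False
        else:
            drop_last = False
    lo = 1 if drop_first else 0
    hi = len(elements) - 1 if drop_last else len(elements)
    return elements[lo:hi]


def categorize_subtype(elements: Sequence[Element]) -> Subtype:
    """Map an affix-trimmed element sequence to one of the five subtypes."""
    n = len(elements)
    if n == 0:
        raise ValueError("need at least one element")
    if n == 1:
        return Subtype.FLAT
    if n == 2:
        if elements[1].median_frequency > elements[0].median_frequency:
            return Subtype.STEP_UP
        return Subtype.STEP_DOWN
    if n == 3:
        mid = elements[1].median_frequency
        if mid == elements[0].median_frequency or mid == elements[2].median_frequency:
            raise RuntimeError(
                "internal consistency error: adjacent elements with equal median frequency"
            )
        return Subtype.INSERT
    return Subtype.COMPLEX


def subtype_of_contour(contour: CallContour, params: SubtypeParams = SubtypeParams()) -> tuple[Subtype, list[Element]]:
    """segment -> trim -> categorize; returns (subtype, retained elements)."""
    elements = trim_affixes(segment_elements(contour, params), params)
    return categorize_subtype(elements), elements


def element_ratio(elements: Sequence[Element]) -> float:
    """Higher/lower median-frequency ratio of a two-element call (>= 1)."""
    if len(elements) != 2:
        raise ValueError(f"element_ratio requires exactly 2 elements, got {len(elements)}")
    a, b = elements[0].median_frequency, elements[1].median_frequency
    return max(a, b) / min(a, b)


def pair_ratio_22_44(
    long22_frequencies: Sequence[float], fortyfour_frequencies: Sequence[float]
) -> float:
    """Ratio mean(high-type peak frequencies) / mean(low-type peak
    frequencies) for a within-rat transition sample."""
    lo = np.asarray(long22_frequencies, dtype=float)
    hi = np.asarray(fortyfour_frequencies, dtype=float)
    if lo.size == 0 or hi.size == 0:
        raise ValueError("both frequency sequences must be non-empty")
    return float(hi.mean() / lo.mean())
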