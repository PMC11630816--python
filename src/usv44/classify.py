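"""Threshold-rule call typing and per-inter-trial-interval (ITI) profiles.

The four-type partition of the (peak frequency, duration) plane:

* ``fortyfour``: frequency > 32 kHz and duration > 150 ms
* ``fifty``:     frequency > 32 kHz and duration <= 150 ms
* ``long22``:    frequency <= 32 kHz and duration > 300 ms
* ``short22``:   frequency <= 32 kHz and duration <= 300 ms

Boundaries use strict ``>`` on the high/long side, so equals-boundary
values fall to the low/short class.  The partition is total: every
positive (frequency, duration) pair gets exactly one label.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from usv44.calltable_io import (
    TYPE_ORDER,
    CallRecord,
    CallType,
    RowValidationError,
    SessionMeta,
)


@dataclass(frozen=True)
class ClassRules:
    """Thresholds of the four-type rule (Hz / seconds)."""

    high_low_boundary: float = 32_000.0
    long_high_min_duration: float = 0.150
    long_low_min_duration: float = 0.300

    def __post_init__(self):
        if min(self.high_low_boundary, self.long_high_min_duration, self.long_low_min_duration) <= 0:
            raise ValueError("all rule thresholds must be strictly positive")
        if not self.long_high_min_duration < self.long_low_min_duration:
            raise ValueError("long_high_min_duration must be < long_low_min_duration")


def classify_call(peak_frequency: float, duration: float, rules: ClassRules = ClassRules()) -> CallType:
    """Assign one of the four call types.  Total and exclusive."""
    if not peak_frequency > 0:
        raise ValueError(f"peak_frequency must be > 0, got {peak_frequency}")
    if not duration > 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if peak_frequency > rules.high_low_boundary:
        if duration > rules.long_high_min_duration:
            return CallType.FORTYFOUR
        return CallType.FIFTY
    if duration > rules.long_low_min_duration:
        return CallType.LONG22
    return CallType.SHORT22


def classify_table(
    records: Sequence[CallRecord],
    rules: ClassRules = ClassRules(),
    modulation_veto_hz: Optional[float] = None,
) -> tuple[list[CallRecord], Counter]:
    """Label every record; return ``(labeled records, per-type counts)``.

    ``modulation_veto_hz`` optionally demotes a ``fortyfour`` assignment to
    ``fifty`` when the call's contour spans more than the given frequency
    range (off by default).
    """
    labeled: list[CallRecord] = []
    counts: Counter = Counter({t: 0 for t in TYPE_ORDER})
    for rec in records:
        try:
            call_type = classify_call(rec.peak_frequency, rec.duration, rules)
        except ValueError as exc:
            raise RowValidationError(f"call {rec.call_id}: {exc}") from None
        if (
            modulation_veto_hz is not None
            and call_type is CallType.FORTYFOUR
            and rec.contour is not None
            and float(rec.contour.frequencies.max() - rec.contour.frequencies.min())
            > modulation_veto_hz
        ):
            call_type = CallType.FIFTY
        labeled.append(rec.with_type(call_type))
        counts[call_type] += 1
    return labeled, counts


@dataclass
class ITIProfile:
    """Per-window call-type counts and 44-kHz shares.

    Window k (1-based) follows the k-th shock: ITI-k spans
    ``(shock_k, shock_{k+1}]`` and the last ITI runs to session end.  The
    pre-first-shock window is kept separately.  A call belongs to the
    window containing its onset.
    """

    pre_shock_counts: Counter = field(default_factory=Counter)
    iti_counts: list[Counter] = field(default_factory=list)

    @property
    def n_itis(self) -> int:
        return len(self.iti_counts)

    def proportion(self, call_type: CallType) -> list[float]:
        """Share of ``call_type`` among all calls, per ITI (NaN if empty)."""
        out = []
        for c in self.iti_counts:
            total = sum(c.values())
            out.append(c[call_type] / total if total else float("nan"))
        return out

    @property
    def fortyfour_share(self) -> list[float]:
        return self.proportion(CallType.FORTYFOUR)


def iti_profile(records: Sequence[CallRecord], meta: SessionMeta) -> ITIProfile:
    """Assign each call to its ITI window by onset and tally types."""
    shocks = list(meta.shock_times)
    profile = ITIProfile(iti_counts=[Counter() for _ in shocks])
    for rec in records:
        if rec.onset > meta.session_length:
            raise RowValidationError(
                f"call {rec.call_id}: onset {rec.onset:g}s beyond session length "
                f"{meta.session_length:g}s"
            )
        k = bisect_left(shocks, rec.onset)  # shocks strictly before onset
        if k == 0:
            profile.pre_shock_counts[rec.call_type] += 1
        else:
            profile.iti_counts[k - 1][rec.call_type] += 1
    return profile


def merge_iti_profiles(profiles: Sequence[ITIProfile]) -> ITIProfile:
    """Pool counts over sessions (sessions must share the shock count)."""
    if not profiles:
        return ITIProfile()
    n = {p.n_itis for p in profiles}
    if len(n) != 1:
        raise ValueError(f"cannot merge profiles with differing ITI counts: {sorted(n)}")
    merged = ITIProfile(iti_counts=[Counter() for _ in range(n.pop())])
    for p in profiles:
        merged.pre_shock_counts.update(p.pre_shock_counts)
        for acc, c in zip(merged.iti_counts, p.iti_counts):
            acc.update(c)
    return merged
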