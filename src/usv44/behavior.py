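"""Freezing scoring and its linkage to call emission.

A video frame is *frozen* when it lies in a maximal run of at least
``min_frames`` consecutive frames with motion index below threshold
(defaults: threshold 18, 30 frames at 30 fps, i.e. one second of
stillness).  Linkage splits the session into fixed bins (default 10 s),
categorizes each bin by the call types whose onsets fall inside, and
reports per-bin freezing percentages; a call-nested variant measures
freezing inside matched per-call windows with a reduced run minimum.

Frame k covers ``[k/fps, (k+1)/fps)``; a frame counts toward a window iff
its start lies inside the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from usv44.calltable_io import CallRecord, CallType, MotionSeries, SessionMeta

BASELINE_WINDOW_S = 300.0  # first 5 minutes, truncated at the first shock


@dataclass(frozen=True)
class FreezeParams:
    motion_threshold: float = 18.0
    min_frames: int = 30
    frame_rate: float = 30.0

    def __post_init__(self):
        if self.min_frames < 1:
            raise ValueError("min_frames must be >= 1")
        if self.motion_threshold < 0:
            raise ValueError("motion_threshold must be >= 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")


def score_freezing(motion: MotionSeries, params: FreezeParams = FreezeParams()) -> np.ndarray:
    """Boolean per-frame freeze mask (run-length rule described above)."""
    below = motion.values < params.motion_threshold
    mask = np.zeros(below.size, dtype=bool)
    i = 0
    while i < below.size:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < below.size and below[j]:
            j += 1
        if j - i >= params.min_frames:
            mask[i:j] = True
        i = j
    return mask


def _window_frame_slice(start: float, end: float, frame_rate: float, n_frames: int) -> slice:
    """Frames whose start time lies in [start, end)."""
    first = int(np.ceil(start * frame_rate - 1e-9))
    last = int(np.ceil(end * frame_rate - 1e-9))  # exclusive
    return slice(max(0, first), min(n_frames, last))


def freezing_percent(mask: np.ndarray, start: float, end: float, frame_rate: float) -> float:
    """Percentage of frozen frames among frames starting in [start, end)."""
    sl = _window_frame_slice(start, end, frame_rate, mask.size)
    n = sl.stop - sl.start
    if n <= 0:
        raise ValueError(f"window [{start:g}, {end:g}) contains no frames")
    return 100.0 * float(np.count_nonzero(mask[sl])) / n


BIN_CATEGORIES = ("baseline", "no_calls", "only_long22", "only_fortyfour", "mixed")


@dataclass
class Bin:
    start: float
    category: str
    freezing: float  # percent


@dataclass
class BinReport:
    bin_length: float
    bins: list[Bin]

    def freezing_by_category(self) -> dict[str, float]:
        """Mean freezing % per category (categories with no bins omitted)."""
        acc: dict[str, list[float]] = {}
        for b in self.bins:
            acc.setdefault(b.category, []).append(b.freezing)
        return {cat: float(np.mean(vals)) for cat, vals in acc.items()}

    def to_dict(self) -> dict:
        return {
            "bin_length_s": self.bin_length,
            "bins": [
                {"start_s": b.start, "category": b.category, "freezing_pct": b.freezing}
                for b in self.bins
            ],
            "mean_freezing_by_category": self.freezing_by_category(),
        }


def bin_linkage(
    records: Sequence[CallRecord],
    mask: np.ndarray,
    meta: SessionMeta,
    bin_length: float = 10.0,
) -> BinReport:
    """Categorize fixed-length bins by the call types emitted in them.

    * ``baseline`` — call-free bins in the first 5 min, pre-first-shock
      (truncated at the first shock if it comes earlier);
    * ``no_calls`` — call-free bins after the first shock;
    * ``only_long22`` / ``only_fortyfour`` — bins whose calls (by onset)
      are exclusively of that type;
    * ``mixed`` — bins with calls of more than one type, or exclusively of
      a type outside the two long monotonous classes.

    Call-free bins between the baseline window and the first shock match
    no category and are omitted.  The mask must cover the session.
    """
    fps = meta.frame_rate
    if mask.size / fps < meta.session_length - 0.5 / fps:
        raise ValueError(
            f"freeze mask covers {mask.size / fps:g}s but session is {meta.session_length:g}s"
        )
    first_shock = meta.shock_times[0] if meta.shock_times else meta.session_length
    baseline_end = min(BASELINE_WINDOW_S, first_shock)
    n_bins = int(np.ceil(meta.session_length / bin_length))
    types_in_bin: list[set] = [set() for _ in range(n_bins)]
    for rec in records:
        b = int(rec.onset // bin_length)
        if b >= n_bins:
            raise ValueError(f"call {rec.call_id} onset beyond session length")
        types_in_bin[b].add(rec.call_type)

    bins: list[Bin] = []
    for b in range(n_bins):
        start = b * bin_length
        end = min(start + bin_length, meta.session_length)
        types = types_in_bin[b]
        if not types:
            if end <= baseline_end:
                category = "baseline"
            elif start >= first_shock:
                category = "no_calls"
            else:
                continue
        elif types == {CallType.LONG22}:
            category = "only_long22"
        elif types == {CallType.FORTYFOUR}:
            category = "only_fortyfour"
        else:
            category = "mixed"
        bins.append(Bin(start=start, category=category, freezing=freezing_percent(mask, start, end, fps)))
    return BinReport(bin_length=bin_length, bins=bins)


def call_nested_freezing(
    call_a: CallRecord,
    call_b: CallRecord,
    motion: MotionSeries,
    params: FreezeParams,
) -> tuple[float, float]:
    """Freezing % during a matched pair of calls.

    The window length is the shorter call's full duration; the longer call
    contributes a centered window of the same length.  The freeze mask is
    recomputed globally from ``motion`` with the (reduced) ``min_frames``
    in ``params``.  Returns percentages in the order (call_a, call_b).
    """
    mask = score_freezing(motion, params)
    floor = params.min_frames / params.frame_rate
    for rec in (call_a, call_b):
        if rec.duration < floor:
            raise ValueError(
                f"call {rec.call_id} ({rec.duration:g}s) shorter than the "
                f"{params.min_frames}-frame minimum ({floor:g}s)"
            )
    win = min(call_a.duration, call_b.duration)
    out = []
    for rec in (call_a, call_b):
        center = rec.onset + rec.duration / 2
        out.append(freezing_percent(mask, center - win / 2, center + win / 2, params.frame_rate))
    return out[0], out[1]
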