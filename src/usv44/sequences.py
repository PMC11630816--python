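"""Bout segmentation and call-type transition statistics.

A *bout* is a maximal run of calls whose silent gaps (next onset minus
previous offset) are all under ``max_gap`` (default 320 ms; a gap exactly
equal to ``max_gap`` splits).  Transition probabilities are conditional:
counts[a][b] / sum_b counts[a][b], pooled over sessions with no
cross-session pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from usv44.calltable_io import TYPE_ORDER, CallRecord, CallType

DEFAULT_MAX_GAP = 0.320


@dataclass
class Bout:
    call_ids: list[str]
    start: float
    end: float

    def __len__(self) -> int:
        return len(self.call_ids)


def _check_sorted(records: Sequence[CallRecord]) -> None:
    for prev, cur in zip(records, records[1:]):
        if cur.onset < prev.onset:
            raise ValueError(f"records not sorted by onset near call {cur.call_id}")
        if cur.onset < prev.offset:
            raise ValueError(
                f"overlapping calls: {prev.call_id} ends at {prev.offset:g}s, "
                f"{cur.call_id} starts at {cur.onset:g}s"
            )


def segment_bouts(records: Sequence[CallRecord], max_gap: float = DEFAULT_MAX_GAP) -> list[Bout]:
    """Greedy left-to-right grouping of one session's time-ordered calls."""
    _check_sorted(records)
    bouts: list[Bout] = []
    last_offset = None
    for rec in records:
        if last_offset is not None and rec.onset - last_offset < max_gap:
            bouts[-1].call_ids.append(rec.call_id)
            bouts[-1].end = rec.offset
        else:
            bouts.append(Bout(call_ids=[rec.call_id], start=rec.onset, end=rec.offset))
        last_offset = rec.offset
    return bouts


@dataclass
class TransitionMatrix:
    """Directed pair counts and row-normalized conditional probabilities."""

    types: tuple[CallType, ...] = TYPE_ORDER
    counts: np.ndarray = field(default_factory=lambda: np.zeros((len(TYPE_ORDER), len(TYPE_ORDER)), dtype=int))

    @property
    def probabilities(self) -> np.ndarray:
        """Row-stochastic where a row has outgoing pairs; zero rows stay 0."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(totals > 0, self.counts / np.maximum(totals, 1), 0.0)
        return p

    def probability(self, from_type: CallType, to_type: CallType) -> float:
        i, j = self.types.index(from_type), self.types.index(to_type)
        return float(self.probabilities[i, j])

    def count(self, from_type: CallType, to_type: CallType) -> int:
        return int(self.counts[self.types.index(from_type), self.types.index(to_type)])

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict:
        return {
            "types": [t.value for t in self.types],
            "counts": self.counts.tolist(),
            "probabilities": self.probabilities.tolist(),
        }


def _session_groups(records: Iterable[CallRecord]) -> list[list[CallRecord]]:
    groups: dict[tuple[str, str], list[CallRecord]] = {}
    for rec in records:
        groups.setdefault((rec.rat_id, rec.session_id), []).append(rec)
    return list(groups.values())


def transition_matrix(
    records: Iterable[CallRecord],
    scope: str = "all",
    max_gap: float = DEFAULT_MAX_GAP,
) -> TransitionMatrix:
    """Count consecutive same-session type pairs.

    ``scope="all"`` counts every consecutive pair; ``scope="within_bout"``
    only pairs whose silent gap is < ``max_gap``.  Calls typed ``unknown``
    break pairs (no pair is counted on either side of them).  Fewer than
    two calls everywhere yields an all-zero matrix, not an error.
    """
    if scope not in ("all", "within_bout"):
        raise ValueError(f"scope must be 'all' or 'within_bout', got {scope!r}")
    tm = TransitionMatrix()
    index = {t: i for i, t in enumerate(tm.types)}
    for session in _session_groups(records):
        session = sorted(session, key=lambda r: r.onset)
        _check_sorted(session)
        for prev, cur in zip(session, session[1:]):
            if prev.call_type not in index or cur.call_type not in index:
                continue
            if scope == "within_bout" and cur.onset - prev.offset >= max_gap:
                continue
            tm.counts[index[prev.call_type], index[cur.call_type]] += 1
    return tm


def per_session_matrices(
    records: Iterable[CallRecord], scope: str = "all", max_gap: float = DEFAULT_MAX_GAP
) -> dict[tuple[str, str], TransitionMatrix]:
    """Unpooled per-(rat, session) transition matrices."""
    out = {}
    for session in _session_groups(records):
        key = (session[0].rat_id, session[0].session_id)
        out[key] = transition_matrix(session, scope=scope, max_gap=max_gap)
    return out
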