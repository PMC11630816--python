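"""Seeded synthetic vocal-session generator.

Produces cohorts of sessions — call tables with frequency contours, shock
schedules, and per-frame motion-index series — carrying the statistical
structure the analysis pipeline assumes:

* four call classes sampled strictly inside their (frequency, duration)
  regions with a safety margin off every class boundary, so threshold
  classification agrees with the planted labels 100% of the time;
* window-dependent emission: low-frequency alarm calls peaking mid-session
  and the high-frequency long class rising over later inter-shock windows;
* a within-session upward drift of class mean frequencies;
* first-order Markov type sequencing with configurable self-transition
  probabilities;
* bout-structured timing (within-bout silent gaps under 320 ms, longer
  gaps between bouts);
* step-subtype contours whose two elements sit near a 3:2 frequency ratio;
* a freezing signal elevated around call emission, more strongly for the
  high-frequency long class.

Every quantity is drawn from ``numpy.random.Generator`` streams derived
deterministically from a master seed, so identical inputs give
byte-identical outputs.  Ground-truth labels ride along in each record's
``annotations`` (``gt_type`` / ``gt_subtype``) and are stripped on export
unless explicitly requested.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from usv44.calltable_io import (
    TYPE_ORDER,
    CallContour,
    CallRecord,
    CallType,
    MotionSeries,
    SessionMeta,
    Subtype,
    write_call_table,
    write_contours,
    write_motion_series,
    write_session_meta,
)

_SUBTYPE_ORDER = (Subtype.FLAT, Subtype.STEP_UP, Subtype.STEP_DOWN, Subtype.INSERT, Subtype.COMPLEX)


def _default_window_weights(
    n_shocks: int,
    self_transitions: Optional[dict] = None,
) -> list[list[float]]:
    """Per-window switch-target type weights (rows: pre-shock, then one per
    ITI; columns in TYPE_ORDER).

    The stay-or-switch chain used by :func:`generate_session` has a
    stationary type distribution of approximately ``w_t / (1 - s_t)``
    (``s_t`` the self-transition probability), so target per-window type
    *shares* are converted to weights by multiplying with ``(1 - s_t)``.
    The high-frequency long class's share rises monotonically through the
    next-to-last window (then dips), the low alarm class peaks early.
    """
    s = self_transitions or {"long22": 0.95, "short22": 0.50, "fifty": 0.50, "fortyfour": 0.85}
    stay = np.array([s.get(t.value, 0.5) for t in (CallType.LONG22, CallType.SHORT22, CallType.FIFTY, CallType.FORTYFOUR)])
    # target stationary shares per ITI
    share44 = np.concatenate(
        [np.linspace(0.01, 0.48, max(n_shocks - 1, 1)), [0.42] if n_shocks > 1 else []]
    )[:n_shocks]
    share22 = 0.88 - share44  # short/modulated classes keep a constant 12%
    rows = [[0.05 * 0.05, 0.15 * 0.5, 0.80 * 0.5, 0.0]]  # pre-shock: mostly short appetitive
    rows[0] = (np.array(rows[0]) / np.sum(rows[0])).tolist()
    for i in range(n_shocks):
        shares = np.array([share22[i], 0.08, 0.04, share44[i]])
        row = shares * (1.0 - stay)
        rows.append((row / row.sum()).tolist())
    return rows


@dataclass
class SyntheticConfig:
    """Full distributional specification of a simulated cohort."""

    n_rats: int = 8
    n_shocks: int = 10
    session_length: float = 3120.0
    pre_period: float = 600.0
    frame_rate: float = 30.0

    #: expected call count per window (pre-shock window first)
    calls_per_window: Optional[list[float]] = None
    #: per-window type weights; defaults via :func:`_default_window_weights`
    window_type_weights: Optional[list[list[float]]] = None
    #: Markov self-transition probability per type (off-diagonal mass is
    #: spread over the other types proportionally to the window weights)
    self_transitions: dict = field(
        default_factory=lambda: {"long22": 0.95, "short22": 0.50, "fifty": 0.50, "fortyfour": 0.85}
    )

    # class feature distributions (Hz / s); drift endpoints span ITI-1..n
    long22_freq_drift: tuple[float, float] = (24_500.0, 27_900.0)
    long22_freq_sd: float = 800.0
    long22_duration_mean: float = 0.90
    long22_duration_sd: float = 0.20
    fortyfour_freq_drift: tuple[float, float] = (37_800.0, 39_600.0)
    fortyfour_freq_sd: float = 1_500.0
    fortyfour_duration_mean: float = 0.62
    fortyfour_duration_sd: float = 0.15
    short22_freq_mean: float = 25_000.0
    short22_freq_sd: float = 2_000.0
    fifty_freq_mean: float = 60_000.0
    fifty_freq_sd: float = 4_000.0

    #: keep every draw at least this far from a class boundary
    frequency_margin: float = 500.0
    duration_margin: float = 0.010

    # bout timing
    p_between_bout: float = 0.15
    within_bout_gap: tuple[float, float] = (0.02, 0.25)  # uniform range, s
    between_bout_gap_min: float = 0.40
    between_bout_gap_mean: float = 1.50  # exponential tail added to the min

    # contours
    contour_dt: float = 0.005
    contour_jitter: float = 300.0
    step_ratio_mean: float = 1.5
    step_ratio_sd: float = 0.05
    subtype_mix: dict = field(
        default_factory=lambda: {
            "flat": 0.80,
            "step_up": 0.07,
            "step_down": 0.06,
            "insert": 0.04,
            "complex": 0.03,
        }
    )

    # freezing model (per-second freeze probabilities)
    baseline_freeze_p: float = 0.10
    long22_freeze_p: float = 0.45
    fortyfour_freeze_p: float = 0.80
    freeze_halo_s: float = 5.0
    motion_threshold: float = 18.0

    def __post_init__(self):
        if self.calls_per_window is None:
            # overall emission peaks around the 3rd window, when the low
            # alarm class dominates
            self.calls_per_window = [10.0] + [
                round(50.0 + 30.0 * float(np.exp(-(((i - 3) / 2.0) ** 2))), 1)
                for i in range(1, self.n_shocks + 1)
            ]
        if self.window_type_weights is None:
            self.window_type_weights = _default_window_weights(self.n_shocks, self.self_transitions)
        if len(self.calls_per_window) != self.n_shocks + 1:
            raise ValueError("calls_per_window must have n_shocks + 1 entries")
        if len(self.window_type_weights) != self.n_shocks + 1:
            raise ValueError("window_type_weights must have n_shocks + 1 rows")
        if any(r < 0 for r in self.calls_per_window):
            raise ValueError("emission rates must be non-negative")
        for row in self.window_type_weights:
            if len(row) != len(TYPE_ORDER) or any(w < 0 for w in row) or sum(row) <= 0:
                raise ValueError("each weight row needs non-negative weights summing > 0")
        for p in self.self_transitions.values():
            if not 0 <= p < 1:
                raise ValueError("self-transition probabilities must lie in [0, 1)")
        if self.pre_period >= self.session_length:
            raise ValueError("pre_period must be shorter than the session")
        # feasibility: expected occupied time must fit each window
        spacing = (self.session_length - self.pre_period) / self.n_shocks
        min_call_span = 0.05 + self.within_bout_gap[0]
        windows = [self.pre_period] + [spacing] * self.n_shocks
        for rate, length in zip(self.calls_per_window, windows):
            if rate * min_call_span > length:
                raise ValueError(
                    f"infeasible config: {rate:g} calls cannot fit a {length:g}s window"
                )

    @property
    def shock_times(self) -> tuple[float, ...]:
        spacing = (self.session_length - self.pre_period) / self.n_shocks
        return tuple(self.pre_period + i * spacing for i in range(self.n_shocks))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticConfig":
        data = dict(data)
        for key in ("long22_freq_drift", "fortyfour_freq_drift", "within_bout_gap"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# feature draws


def _clipped_normal(rng, mean, sd, lo, hi) -> float:
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _draw_features(config: SyntheticConfig, call_type: CallType, window: int, rng) -> tuple[float, float]:
    """(peak frequency Hz, duration s), strictly inside the class region."""
    boundary_f = 32_000.0
    f_lo_margin = boundary_f - config.frequency_margin
    f_hi_margin = boundary_f + config.frequency_margin
    d150, d300 = 0.150, 0.300
    frac = 0.0 if config.n_shocks <= 1 else max(window - 1, 0) / (config.n_shocks - 1)
    if call_type is CallType.LONG22:
        mean = config.long22_freq_drift[0] + frac * (config.long22_freq_drift[1] - config.long22_freq_drift[0])
        f = _clipped_normal(rng, mean, config.long22_freq_sd, 18_000.0, f_lo_margin)
        d = _clipped_normal(rng, config.long22_duration_mean, config.long22_duration_sd, d300 + config.duration_margin + 1e-3, 3.0)
    elif call_type is CallType.SHORT22:
        f = _clipped_normal(rng, config.short22_freq_mean, config.short22_freq_sd, 18_000.0, f_lo_margin)
        d = float(rng.uniform(0.06, d300 - config.duration_margin))
    elif call_type is CallType.FIFTY:
        f = _clipped_normal(rng, config.fifty_freq_mean, config.fifty_freq_sd, f_hi_margin + 3_000.0, 90_000.0)
        d = float(rng.uniform(0.02, d150 - config.duration_margin))
    elif call_type is CallType.FORTYFOUR:
        mean = config.fortyfour_freq_drift[0] + frac * (config.fortyfour_freq_drift[1] - config.fortyfour_freq_drift[0])
        f = _clipped_normal(rng, mean, config.fortyfour_freq_sd, f_hi_margin, 51_500.0)
        d = _clipped_normal(rng, config.fortyfour_duration_mean, config.fortyfour_duration_sd, d150 + config.duration_margin + 1e-3, 2.0)
    else:
        raise ValueError(f"cannot draw features for {call_type}")
    return f, d


# ---------------------------------------------------------------------------
# contours


def _segment_durations(rng, duration: float, n: int) -> np.ndarray:
    """Split ``duration`` into n parts, each within [0.6, 1.4]x the even
    share, so no part falls under 1/5th of its neighbor (affix-safe)."""
    parts = 1.0 + 0.4 * (2 * rng.random(n) - 1)
    return duration * parts / parts.sum()


def _piecewise_contour(rng, config: SyntheticConfig, duration: float, freqs: Sequence[float], seg_durs: Sequence[float]) -> CallContour:
    dt = config.contour_dt
    times, values = [], []
    t0 = 0.0
    for f, d in zip(freqs, seg_durs):
        n_pts = max(2, int(round(d / dt)))
        seg_t = t0 + np.linspace(0.0, d, n_pts, endpoint=False)
        times.append(seg_t)
        values.append(f + rng.uniform(-config.contour_jitter, config.contour_jitter, n_pts))
        t0 += d
    t = np.concatenate(times)
    v = np.concatenate(values)
    t = np.append(t, duration)
    v = np.append(v, v[-1])
    t -= t[0]
    return CallContour(times=t, frequencies=np.clip(v, 1_000.0, 120_000.0))


def generate_contour(
    call_type: CallType,
    subtype: Optional[Subtype],
    duration: float,
    peak_frequency: float,
    seed,
    config: Optional[SyntheticConfig] = None,
) -> CallContour:
    """Synthesize a contour matching the planted type/subtype.

    ``seed`` may be an int or a ``numpy.random.Generator``.  Step subtypes
    place their two elements at a frequency ratio drawn from the step-ratio
    distribution (default Normal(1.5, 0.05)); the short appetitive class is
    sinusoidally frequency-modulated; everything else is flat plus jitter.
    """
    config = config or SyntheticConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(call_type, str):
        call_type = CallType(call_type)
    if subtype is not None and isinstance(subtype, str):
        subtype = Subtype(subtype)
    if subtype is not None and call_type is not CallType.FORTYFOUR:
        raise ValueError("subtype applies only to the high-frequency long class")
    base = peak_frequency
    if call_type is CallType.FIFTY:
        n_pts = max(4, int(round(duration / config.contour_dt)))
        t = np.linspace(0.0, duration, n_pts)
        f = base + 5_000.0 * np.sin(2 * np.pi * t / 0.05)
        return CallContour(times=t, frequencies=np.clip(f, 1_000.0, 120_000.0))
    if call_type is not CallType.FORTYFOUR or subtype in (None, Subtype.FLAT):
        return _piecewise_contour(rng, config, duration, [base], [duration])

    ratio = max(1.2, float(rng.normal(config.step_ratio_mean, config.step_ratio_sd)))
    low = base / ratio
    if subtype is Subtype.STEP_UP:
        freqs = [low, base]
        n = 2
    elif subtype is Subtype.STEP_DOWN:
        freqs = [base, low]
        n = 2
    elif subtype is Subtype.INSERT:
        freqs = [base, low, base + 600.0]
        n = 3
    elif subtype is Subtype.COMPLEX:
        n = int(rng.integers(4, 7))
        freqs = [(base if i % 2 == 0 else low) + 400.0 * (i // 2) for i in range(n)]
    else:
        raise ValueError(f"unknown subtype {subtype!r}")
    return _piecewise_contour(rng, config, duration, freqs, _segment_durations(rng, duration, n))


# ---------------------------------------------------------------------------
# sessions


def _markov_sequence(
    rng,
    config: SyntheticConfig,
    weights: np.ndarray,
    n: int,
    prev: Optional[CallType] = None,
) -> list[CallType]:
    """First-order chain: stay with the type's self-transition probability,
    otherwise switch to another type drawn from the window weights.

    ``prev`` continues the chain from an earlier window, so every
    consecutive pair in a session is a genuine Markov transition and the
    planted self-transition probabilities are recovered without boundary
    bias.
    """
    if n == 0:
        return []
    types = list(TYPE_ORDER)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    seq: list[CallType] = []
    if prev is None:
        seq.append(types[rng.choice(len(types), p=w)])
    while len(seq) < n:
        cur = seq[-1] if seq else prev
        stay = config.self_transitions.get(cur.value, 0.5)
        if rng.random() < stay:
            seq.append(cur)
            continue
        mask = np.array([t is not cur for t in types])
        p = w * mask
        if p.sum() <= 0:
            seq.append(cur)
            continue
        seq.append(types[rng.choice(len(types), p=p / p.sum())])
    return seq


def generate_session(
    config: SyntheticConfig, rat_index: int, seed: int
) -> tuple[SessionMeta, list[CallRecord], MotionSeries]:
    """One deterministic session: metadata, contoured call records with
    hidden ground-truth labels, and a motion-index series."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(rat_index,)))
    rat_id = f"rat{rat_index:03d}"
    session_id = f"{rat_id}_s{seed}"
    shocks = config.shock_times
    meta = SessionMeta(
        rat_id=rat_id,
        session_id=session_id,
        phase="training",
        shock_times=shocks,
        session_length=config.session_length,
        frame_rate=config.frame_rate,
    )

    subtype_names = [s.value for s in _SUBTYPE_ORDER]
    subtype_p = np.array([config.subtype_mix.get(nm, 0.0) for nm in subtype_names])
    subtype_p = subtype_p / subtype_p.sum()

    windows = [(0.0, shocks[0] if shocks else config.session_length)]
    for i, t in enumerate(shocks):
        end = shocks[i + 1] if i + 1 < len(shocks) else config.session_length
        windows.append((t, end))

    records: list[CallRecord] = []
    counter = 0
    prev_type: Optional[CallType] = None
    for w, (start, end) in enumerate(windows):
        n_calls = int(rng.poisson(config.calls_per_window[w]))
        seq = _markov_sequence(
            rng, config, np.array(config.window_type_weights[w]), n_calls, prev=prev_type
        )
        cursor = start + 0.2 + float(rng.exponential(2.0))
        for call_type in seq:
            freq, dur = _draw_features(config, call_type, w, rng)
            if cursor + dur > end - 0.05:
                break  # window full; drop the remainder of the sequence
            subtype = None
            if call_type is CallType.FORTYFOUR:
                subtype = _SUBTYPE_ORDER[rng.choice(len(subtype_p), p=subtype_p)]
            contour = generate_contour(call_type, subtype, dur, freq, rng, config)
            records.append(
                CallRecord(
                    call_id=f"{session_id}_c{counter:05d}",
                    rat_id=rat_id,
                    session_id=session_id,
                    onset=round(cursor, 6),
                    duration=round(dur, 6),
                    peak_frequency=round(freq, 3),
                    mean_power=round(float(rng.normal(-55.0, 4.0)), 3),
                    contour=contour,
                    annotations={
                        "gt_type": call_type.value,
                        "gt_subtype": subtype.value if subtype else "",
                    },
                )
            )
            counter += 1
            prev_type = call_type
            if rng.random() < config.p_between_bout:
                gap = config.between_bout_gap_min + float(
                    rng.exponential(config.between_bout_gap_mean)
                )
            else:
                gap = float(rng.uniform(*config.within_bout_gap))
            cursor += dur + gap

    motion = _generate_motion(rng, config, records)
    return meta, records, motion


def _generate_motion(rng, config: SyntheticConfig, records: Sequence[CallRecord]) -> MotionSeries:
    """Per-second two-state freeze process expanded to frames.  Freeze
    probability is elevated in a halo around call emission, most strongly
    for the high-frequency long class."""
    fps = config.frame_rate
    n_sec = int(np.ceil(config.session_length))
    p = np.full(n_sec, config.baseline_freeze_p)
    halo = config.freeze_halo_s
    for rec in records:
        gt = rec.annotations.get("gt_type", "")
        if gt == "long22":
            level = config.long22_freeze_p
        elif gt == "fortyfour":
            level = config.fortyfour_freeze_p
        else:
            continue
        lo = max(0, int(np.floor(rec.onset - halo)))
        hi = min(n_sec, int(np.ceil(rec.offset + halo)))
        p[lo:hi] = np.maximum(p[lo:hi], level)
    frozen_sec = rng.random(n_sec) < p
    frames_per_sec = int(round(fps))
    quiet = rng.uniform(0.0, config.motion_threshold * 0.6, size=(n_sec, frames_per_sec))
    active = rng.uniform(config.motion_threshold + 12.0, 200.0, size=(n_sec, frames_per_sec))
    values = np.where(frozen_sec[:, None], quiet, active).ravel()
    n_frames = int(round(config.session_length * fps))
    return MotionSeries(values=values[:n_frames], frame_rate=fps)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class Cohort:
    config: SyntheticConfig
    seed: int
    sessions: list[tuple[SessionMeta, list[CallRecord], MotionSeries]]
    manifest: dict

    def all_records(self) -> list[CallRecord]:
        return [rec for _, recs, _ in self.sessions for rec in recs]


def _session_checksum(meta: SessionMeta, records: Sequence[CallRecord], motion: MotionSeries) -> str:
    h = hashlib.sha256()
    for rec in records:
        h.update(
            f"{rec.call_id},{rec.onset!r},{rec.duration!r},{rec.peak_frequency!r},"
            f"{rec.annotations.get('gt_type', '')}\n".encode()
        )
    h.update(np.ascontiguousarray(motion.values).tobytes())
    return h.hexdigest()


def generate_cohort(config: SyntheticConfig, seed: int) -> Cohort:
    """Generate ``config.n_rats`` sessions with per-rat streams derived
    deterministically from the master seed, plus a checksum manifest."""
    sessions = [generate_session(config, i, seed) for i in range(config.n_rats)]
    manifest = {
        "seed": seed,
        "n_rats": config.n_rats,
        "config_hash": config.config_hash(),
        "sessions": {
            meta.session_id: {
                "rat_id": meta.rat_id,
                "n_calls": len(recs),
                "checksum": _session_checksum(meta, recs, motion),
            }
            for meta, recs, motion in sessions
        },
    }
    return Cohort(config=config, seed=seed, sessions=sessions, manifest=manifest)


def write_cohort(cohort: Cohort, outdir, include_ground_truth: bool = False) -> None:
    """Export a cohort as native-dialect CSVs plus sidecars and manifest.

    Ground-truth annotation columns are stripped unless requested.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for meta, records, motion in cohort.sessions:
        stem = outdir / meta.session_id
        to_write = records
        if not include_ground_truth:
            to_write = [
                CallRecord(
                    call_id=r.call_id,
                    rat_id=r.rat_id,
                    session_id=r.session_id,
                    onset=r.onset,
                    duration=r.duration,
                    peak_frequency=r.peak_frequency,
                    mean_power=r.mean_power,
                    contour=r.contour,
                )
                for r in records
            ]
        write_call_table(to_write, f"{stem}_calls.csv")
        write_contours(to_write, f"{stem}_contours.csv")
        write_motion_series(motion, f"{stem}_motion.csv")
        write_session_meta(meta, f"{stem}_session.cfg")
    (outdir / "manifest.json").write_text(json.dumps(cohort.manifest, indent=2) + "\n")
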