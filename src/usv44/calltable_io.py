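"""Domain types and call-table / session / motion-series I/O.

All in-memory quantities are SI-normalized: times in seconds from session
start, frequencies in Hz, powers in dB.  File dialects may store other
units (e.g. ms / kHz); conversion happens at the I/O boundary, driven by
the column maps in the versioned ``dialects.json`` resource shipped with
the package.

Intervals are half-open ``[onset, onset + duration)``.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

#: Nyquist frequency of the recordings (250 kHz sampling).
NYQUIST_HZ = 125_000.0


class CallTableFormatError(ValueError):
    """A file does not match the declared dialect (e.g. missing column)."""


class RowValidationError(ValueError):
    """A single row fails validation; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


class CallType(str, enum.Enum):
    """The four-type call taxonomy plus an unassigned placeholder."""

    LONG22 = "long22"
    SHORT22 = "short22"
    FIFTY = "fifty"
    FORTYFOUR = "fortyfour"
    UNKNOWN = "unknown"


class Subtype(str, enum.Enum):
    """Element-composition subtypes of high-frequency long calls."""

    FLAT = "flat"
    STEP_UP = "step_up"
    STEP_DOWN = "step_down"
    INSERT = "insert"
    COMPLEX = "complex"


#: Ordered label set used by transition matrices and summaries.
TYPE_ORDER: tuple[CallType, ...] = (
    CallType.LONG22,
    CallType.SHORT22,
    CallType.FIFTY,
    CallType.FORTYFOUR,
)


@dataclass
class CallContour:
    """Per-call dominant-frequency track, times relative to call onset.

    ``times`` are strictly increasing seconds with ``times[0] == 0``;
    ``frequencies`` are Hz in ``(0, NYQUIST_HZ)``; ``amplitudes`` (dB) are
    optional and, when present, the same length.
    """

    times: np.ndarray
    frequencies: np.ndarray
    amplitudes: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.amplitudes is not None:
            self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("contour needs at least 2 points")
        if self.frequencies.shape != self.times.shape:
            raise ValueError("times and frequencies must have equal length")
        if self.amplitudes is not None and self.amplitudes.shape != self.times.shape:
            raise ValueError("amplitudes must match times length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("contour times must be strictly increasing")
        if self.times[0] != 0.0:
            raise ValueError("contour times must start at 0 (call-relative)")
        if not np.all((self.frequencies > 0) & (self.frequencies < NYQUIST_HZ)):
            raise ValueError(f"contour frequencies must lie in (0, {NYQUIST_HZ:g}) Hz")

    def __len__(self) -> int:
        return int(self.times.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CallContour):
            return NotImplemented
        amp_eq = (self.amplitudes is None) == (other.amplitudes is None) and (
            self.amplitudes is None or np.array_equal(self.amplitudes, other.amplitudes)
        )
        return (
            np.array_equal(self.times, other.times)
            and np.array_equal(self.frequencies, other.frequencies)
            and amp_eq
        )


@dataclass
class CallRecord:
    """One detected vocalization."""

    call_id: str
    rat_id: str
    session_id: str
    onset: float
    duration: float
    peak_frequency: float
    mean_power: Optional[float] = None
    contour: Optional[CallContour] = None
    call_type: CallType = CallType.UNKNOWN
    subtype: Optional[Subtype] = None
    #: Opaque extra columns preserved through I/O (and, in synthetic data,
    #: hidden ground-truth labels).
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        self.onset = float(self.onset)
        self.duration = float(self.duration)
        self.peak_frequency = float(self.peak_frequency)
        if isinstance(self.call_type, str) and not isinstance(self.call_type, CallType):
            self.call_type = CallType(self.call_type)
        if isinstance(self.subtype, str) and not isinstance(self.subtype, Subtype):
            self.subtype = Subtype(self.subtype)
        if not (self.onset >= 0 and math.isfinite(self.onset)):
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if not (self.duration > 0 and math.isfinite(self.duration)):
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if not (0 < self.peak_frequency < NYQUIST_HZ):
            raise ValueError(
                f"peak_frequency must be in (0, {NYQUIST_HZ:g}) Hz, got {self.peak_frequency}"
            )
        if self.subtype is not None and self.call_type is not CallType.FORTYFOUR:
            raise ValueError("subtype may be set only for fortyfour calls")

    @property
    def offset(self) -> float:
        """End of the call, seconds from session start."""
        return self.onset + self.duration

    def with_type(self, call_type: CallType, subtype: Optional[Subtype] = None) -> "CallRecord":
        return replace(self, call_type=call_type, subtype=subtype)


@dataclass
class SessionMeta:
    """Identity, shock schedule and recording parameters of one session."""

    rat_id: str
    session_id: str
    phase: str = "training"
    shock_times: Sequence[float] = ()
    session_length: float = 3120.0
    frame_rate: float = 30.0
    #: (frequency Hz, offset dB) pairs; strictly increasing frequencies.
    attenuation_profile: Sequence[tuple[float, float]] = ((20_000.0, 0.0), (40_000.0, 10.0))

    def __post_init__(self):
        self.shock_times = tuple(float(t) for t in self.shock_times)
        self.attenuation_profile = tuple(
            (float(f), float(d)) for f, d in self.attenuation_profile
        )
        if self.phase not in ("training", "test", "playback"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if any(b < a for a, b in zip(self.shock_times, self.shock_times[1:])):
            raise ValueError("shock_times must be sorted ascending")
        if self.shock_times and not (
            0 <= self.shock_times[0] and self.shock_times[-1] <= self.session_length
        ):
            raise ValueError("shock_times must lie within [0, session_length]")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")
        freqs = [f for f, _ in self.attenuation_profile]
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("attenuation_profile frequencies must be strictly increasing")


@dataclass
class MotionSeries:
    """Per-video-frame motion index."""

    values: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("motion series must be a non-empty 1-D sequence")
        if np.any(self.values < 0):
            raise ValueError("motion index values must be non-negative")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        return len(self) / self.frame_rate


# ---------------------------------------------------------------------------
# dialect machinery


def _load_dialects() -> dict:
    with resources.files("usv44").joinpath("dialects.json").open("r") as fh:
        return json.load(fh)["dialects"]


_DIALECTS = _load_dialects()

_TIME_SCALE = {"s": 1.0, "ms": 1e-3}
_FREQ_SCALE = {"hz": 1.0, "khz": 1e3}

_MANDATORY_FIELDS = ("onset", "duration", "peak_frequency")


def dialect_names() -> tuple[str, ...]:
    return tuple(_DIALECTS)


def _dialect(name: str) -> dict:
    try:
        return _DIALECTS[name]
    except KeyError:
        raise CallTableFormatError(
            f"unknown dialect {name!r}; known: {', '.join(_DIALECTS)}"
        ) from None


def _fmt(value: float) -> str:
    """Round-trip-exact, stable decimal formatting for floats."""
    return repr(float(value))


# ---------------------------------------------------------------------------
# call tables


def read_call_table(path, dialect: str = "native"):
    """Read a call table; return ``(records, session_meta_stub)``.

    Records are unit-normalized (seconds / Hz) and sorted by onset with a
    stable sort (file order breaks ties).  Unknown columns are preserved in
    each record's ``annotations``.
    """
    spec = _dialect(dialect)
    colmap = spec["columns"]
    tscale = _TIME_SCALE[spec["time_unit"]]
    fscale = _FREQ_SCALE[spec["frequency_unit"]]

    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CallTableFormatError(f"{path}: empty file, no header")
        header = list(reader.fieldnames)
        field_to_col = {v: k for k, v in colmap.items()}
        for fld in _MANDATORY_FIELDS:
            col = field_to_col.get(fld)
            if col is None or col not in header:
                raise CallTableFormatError(
                    f"{path}: missing mandatory column {col or fld!r} for dialect {dialect!r}"
                )
        rows = list(reader)

    records: list[CallRecord] = []
    rat_ids, session_ids = set(), set()
    for i, row in enumerate(rows):
        fields: dict = {}
        annotations: dict = {}
        for col, raw in row.items():
            fld = colmap.get(col)
            if fld is None:
                annotations[col] = raw
                continue
            raw = (raw or "").strip()
            if fld in ("call_id", "rat_id", "session_id"):
                if raw:
                    fields[fld] = raw
            elif fld == "call_type":
                fields[fld] = CallType(raw) if raw else CallType.UNKNOWN
            elif fld == "subtype":
                fields[fld] = Subtype(raw) if raw else None
            else:
                if raw == "":
                    if fld in _MANDATORY_FIELDS:
                        raise RowValidationError(f"empty value for {fld!r}", row=i)
                    fields[fld] = None
                    continue
                try:
                    value = float(raw)
                except ValueError:
                    raise RowValidationError(
                        f"non-numeric value {raw!r} for {fld!r}", row=i
                    ) from None
                if fld == "onset":
                    value *= tscale
                elif fld == "duration":
                    value *= tscale
                    if value <= 0:
                        raise RowValidationError(f"non-positive duration {raw!r}", row=i)
                elif fld == "peak_frequency":
                    value *= fscale
                fields[fld] = value
        fields.setdefault("call_id", str(i))
        fields.setdefault("rat_id", "unknown")
        fields.setdefault("session_id", path.stem)
        try:
            rec = CallRecord(annotations=annotations, **fields)
        except ValueError as exc:
            raise RowValidationError(str(exc), row=i) from None
        rat_ids.add(rec.rat_id)
        session_ids.add(rec.session_id)
        records.append(rec)

    records.sort(key=lambda r: r.onset)  # timsort: stable, ties keep file order
    meta = SessionMeta(
        rat_id=rat_ids.pop() if len(rat_ids) == 1 else "mixed",
        session_id=session_ids.pop() if len(session_ids) == 1 else "mixed",
        session_length=max((r.offset for r in records), default=0.0),
        shock_times=(),
    )
    return records, meta


def write_call_table(records: Sequence[CallRecord], path, dialect: str = "native") -> None:
    """Write a call table.  The native dialect is lossless (modulo contours,
    which live in a sidecar file; see :func:`write_contours`)."""
    spec = _dialect(dialect)
    colmap = spec["columns"]
    tscale = _TIME_SCALE[spec["time_unit"]]
    fscale = _FREQ_SCALE[spec["frequency_unit"]]
    header = list(spec["header"])
    extra_cols: list[str] = []
    for rec in records:
        for key in rec.annotations:
            if key not in header and key not in extra_cols:
                extra_cols.append(key)

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header + extra_cols)
        for rec in records:
            row = []
            for col in header:
                fld = colmap[col]
                if fld == "call_id":
                    row.append(rec.call_id)
                elif fld == "rat_id":
                    row.append(rec.rat_id)
                elif fld == "session_id":
                    row.append(rec.session_id)
                elif fld == "onset":
                    row.append(_fmt(rec.onset / tscale))
                elif fld == "duration":
                    row.append(_fmt(rec.duration / tscale))
                elif fld == "peak_frequency":
                    row.append(_fmt(rec.peak_frequency / fscale))
                elif fld == "mean_power":
                    row.append("" if rec.mean_power is None else _fmt(rec.mean_power))
                elif fld == "call_type":
                    row.append(rec.call_type.value)
                elif fld == "subtype":
                    row.append("" if rec.subtype is None else rec.subtype.value)
            for col in extra_cols:
                row.append(str(rec.annotations.get(col, "")))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# contour sidecar files (native dialect only)


def write_contours(records: Sequence[CallRecord], path) -> None:
    """Write all attached contours to a sidecar CSV
    (``call_id,t_s,freq_hz,amp_db``)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["call_id", "t_s", "freq_hz", "amp_db"])
        for rec in records:
            c = rec.contour
            if c is None:
                continue
            for j in range(len(c)):
                amp = "" if c.amplitudes is None else _fmt(c.amplitudes[j])
                writer.writerow([rec.call_id, _fmt(c.times[j]), _fmt(c.frequencies[j]), amp])


def read_contours(path) -> dict[str, CallContour]:
    """Read a contour sidecar CSV into a ``call_id -> CallContour`` map."""
    per_call: dict[str, list[tuple[float, float, Optional[float]]]] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        needed = {"call_id", "t_s", "freq_hz"}
        if reader.fieldnames is None or not needed.issubset(reader.fieldnames):
            raise CallTableFormatError(f"{path}: contour file must have columns {sorted(needed)}")
        for i, row in enumerate(reader):
            amp_raw = (row.get("amp_db") or "").strip()
            try:
                per_call.setdefault(row["call_id"], []).append(
                    (
                        float(row["t_s"]),
                        float(row["freq_hz"]),
                        float(amp_raw) if amp_raw else None,
                    )
                )
            except ValueError:
                raise RowValidationError("non-numeric contour value", row=i) from None
    out = {}
    for call_id, pts in per_call.items():
        pts.sort(key=lambda p: p[0])
        times = np.array([p[0] for p in pts])
        freqs = np.array([p[1] for p in pts])
        amps = None
        if all(p[2] is not None for p in pts):
            amps = np.array([p[2] for p in pts])
        out[call_id] = CallContour(times=times, frequencies=freqs, amplitudes=amps)
    return out


def attach_contours(records: Sequence[CallRecord], contours: dict[str, CallContour]) -> list[CallRecord]:
    return [
        replace(r, contour=contours[r.call_id]) if r.call_id in contours else r
        for r in records
    ]


# ---------------------------------------------------------------------------
# motion series


def read_motion_series(path, frame_rate: float = 30.0) -> MotionSeries:
    """Read a one-value-per-line (or single-column CSV) motion-index file."""
    values = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if lineno == 1 and text.lower() in ("motion", "motion_index", "value"):
                continue  # optional single-column header
            if not text:
                raise RowValidationError(f"blank line {lineno} in motion file")
            try:
                v = float(text)
            except ValueError:
                raise RowValidationError(
                    f"non-numeric motion value {text!r} at line {lineno}"
                ) from None
            if v < 0:
                raise RowValidationError(f"negative motion value at line {lineno}")
            values.append(v)
    return MotionSeries(values=np.array(values), frame_rate=frame_rate)


def write_motion_series(series: MotionSeries, path) -> None:
    with Path(path).open("w") as fh:
        for v in series.values:
            fh.write(_fmt(v) + "\n")


# ---------------------------------------------------------------------------
# session metadata (flat key=value config)


def write_session_meta(meta: SessionMeta, path) -> None:
    lines = [
        f"rat_id={meta.rat_id}",
        f"session_id={meta.session_id}",
        f"phase={meta.phase}",
        "shock_times=" + ",".join(_fmt(t) for t in meta.shock_times),
        f"session_length={_fmt(meta.session_length)}",
        f"frame_rate={_fmt(meta.frame_rate)}",
        "attenuation_profile="
        + ";".join(f"{_fmt(f)}:{_fmt(d)}" for f, d in meta.attenuation_profile),
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_session_meta(path) -> SessionMeta:
    kv: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise CallTableFormatError(f"{path}: line {lineno} is not key=value")
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    try:
        shock = tuple(float(t) for t in kv.get("shock_times", "").split(",") if t)
        profile = tuple(
            (float(pair.split(":")[0]), float(pair.split(":")[1]))
            for pair in kv.get("attenuation_profile", "").split(";")
            if pair
        )
        return SessionMeta(
            rat_id=kv["rat_id"],
            session_id=kv["session_id"],
            phase=kv.get("phase", "training"),
            shock_times=shock,
            session_length=float(kv.get("session_length", 3120.0)),
            frame_rate=float(kv.get("frame_rate", 30.0)),
            attenuation_profile=profile
            or ((20_000.0, 0.0), (40_000.0, 10.0)),
        )
    except KeyError as exc:
        raise CallTableFormatError(f"{path}: missing key {exc}") from None
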