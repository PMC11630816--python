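"""Spectrograms, peak frequency, contour mean power, attenuation correction.

Peak frequency of a call is defined as the frequency bin with the highest
power in the spectrum averaged (in the linear power domain) over all
spectrogram frames spanned by the call.  The default short-time analysis
is a 512-sample Hann window with 75% overlap at 250 kHz sampling
(~2.05 ms frames, ~488 Hz bins).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.io import wavfile

from usv44.calltable_io import CallContour

DEFAULT_FS = 250_000.0
DEFAULT_WINDOW = 512
DEFAULT_OVERLAP = 0.75

#: Power floor (dB) used in place of log(0) for silent cells.
POWER_FLOOR_DB = -200.0

#: Default microphone-angle attenuation offsets: +10 dB at 40 kHz relative
#: to 20 kHz (conservative two-point profile; no gain below 20 kHz).
DEFAULT_ATTENUATION_PROFILE = ((20_000.0, 0.0), (40_000.0, 10.0))


@dataclass
class Spectrogram:
    """Power spectrogram in dB; ``power`` is (frequency x time)."""

    times: np.ndarray
    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (self.frequencies.size, self.times.size):
            raise ValueError("power must be (n_frequencies, n_times)")
        df = np.diff(self.frequencies)
        if df.size and not np.allclose(df, df[0]):
            raise ValueError("frequency bins must be uniform")

    @property
    def bin_width(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


def compute_spectrogram(
    waveform: Sequence[float],
    fs: float,
    window_length: int = DEFAULT_WINDOW,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> Spectrogram:
    """Short-time power spectrogram (Hann window), dB re full scale.

    Frames are non-padded: ``n_frames = floor((N - L) / hop) + 1``.
    """
    x = np.asarray(waveform, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if window_length < 16:
        raise ValueError("window_length must be >= 16 samples")
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if x.ndim != 1 or x.size < window_length:
        raise ValueError("waveform shorter than one analysis window")

    hop = max(1, int(round(window_length * (1 - overlap_fraction))))
    freqs, times, psd = signal.spectrogram(
        x,
        fs=fs,
        window="hann",
        nperseg=window_length,
        noverlap=window_length - hop,
        detrend=False,
        scaling="spectrum",
        mode="psd",
    )
    with np.errstate(divide="ignore"):
        power_db = 10.0 * np.log10(psd)
    power_db = np.maximum(power_db, POWER_FLOOR_DB)
    return Spectrogram(times=times, frequencies=freqs, power=power_db)


def _frames_in(spec: Spectrogram, onset: float, offset: float) -> np.ndarray:
    return np.flatnonzero((spec.times >= onset) & (spec.times < offset))


def peak_frequency(spec: Spectrogram, onset: float, offset: float) -> float:
    """Frequency-bin center maximizing the time-averaged power over frames
    whose centers lie in ``[onset, offset)``.  Ties break toward the lower
    frequency bin; a flat (silent) averaged spectrum is an error."""
    idx = _frames_in(spec, onset, offset)
    if idx.size == 0:
        raise ValueError(f"no spectrogram frames overlap [{onset:g}, {offset:g})")
    linear = 10.0 ** (spec.power[:, idx] / 10.0)
    mean_spectrum = linear.mean(axis=1)
    if np.ptp(mean_spectrum) <= 1e-12 * max(mean_spectrum.max(), 1e-30):
        raise ValueError("no spectral peak: averaged spectrum is flat (silence)")
    return float(spec.frequencies[int(np.argmax(mean_spectrum))])  # argmax: first == lowest bin


def mean_power(spec: Spectrogram, contour: CallContour, onset: float) -> float:
    """Mean dB power sampled at each contour point's nearest (time,
    frequency) spectrogram cell.  Contour times are call-relative; ``onset``
    places them on the spectrogram's session time axis."""
    t = contour.times + onset
    f = contour.frequencies
    half_dt = float(np.median(np.diff(spec.times))) / 2 if spec.times.size > 1 else 0.0
    half_df = spec.bin_width / 2
    if t.min() < spec.times[0] - half_dt or t.max() > spec.times[-1] + half_dt:
        raise ValueError("contour times fall outside the spectrogram range")
    if f.min() < spec.frequencies[0] - half_df or f.max() > spec.frequencies[-1] + half_df:
        raise ValueError("contour frequencies fall outside the spectrogram range")
    ti = np.clip(np.searchsorted(spec.times, t), 1, spec.times.size - 1)
    ti = np.where(t - spec.times[ti - 1] <= spec.times[ti] - t, ti - 1, ti)
    fi = np.clip(np.round((f - spec.frequencies[0]) / spec.bin_width).astype(int), 0, spec.frequencies.size - 1)
    return float(spec.power[fi, ti].mean())


def attenuation_correction(
    peak_frequency_hz: float,
    power_db: float,
    profile: Sequence[tuple[float, float]] = DEFAULT_ATTENUATION_PROFILE,
) -> float:
    """Add the frequency-dependent microphone-angle attenuation offset.

    The offset is piecewise-linear over ``profile`` (frequency Hz -> dB),
    with constant extrapolation beyond the endpoints.
    """
    profile = list(profile)
    if not profile:
        raise ValueError("attenuation profile must be non-empty")
    freqs = np.array([f for f, _ in profile], dtype=float)
    offsets = np.array([d for _, d in profile], dtype=float)
    return float(power_db + np.interp(peak_frequency_hz, freqs, offsets))


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a mono PCM WAV file; returns (float waveform in [-1, 1], fs)."""
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("expected mono WAV")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return data, float(fs)
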