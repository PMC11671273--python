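"""Dominant gamma-frequency estimation from oscillation cycle periods.

The CSD signal of a hotspot electrode is band-passed to 35-120 Hz (stops
25/140 Hz, 20 dB, zero phase) and Hilbert transformed into instantaneous
phase and amplitude; the amplitude envelope is smoothed with a 10-ms
Gaussian.  Within time spans of at least 40 ms in which the amplitude
continuously exceeds its per-trial median over MCs 2/3, oscillation
troughs are located where the unwrapped phase crosses pi (+ 2 pi k),
using linear interpolation between samples.  Cycle periods are the
differences between successive troughs of the same span; periods outside
the filter passband (> 1/35 s or < 1/120 s) are discarded.  The dominant
frequency of a session x condition is the reciprocal of the median period
pooled across trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import hilbert

from .preprocess import GAMMA_BANDPASS, zero_phase_filter

__all__ = [
    "CycleSeries",
    "DominantFrequency",
    "bandpass_gamma",
    "analytic_phase_amplitude",
    "detect_gamma_troughs",
    "dominant_frequency_from_periods",
    "PERIOD_BOUNDS_S",
]

#: Periods compatible with the 35-120 Hz passband.
PERIOD_BOUNDS_S = (1.0 / 120.0, 1.0 / 35.0)
MIN_RUN_MS = 40.0
AMP_SMOOTH_SIGMA_MS = 10.0


@dataclass
class CycleSeries:
    """Trough times and cycle periods of one trial's gamma episodes."""

    trough_times_ms: np.ndarray
    periods_s: np.ndarray
    accepted: np.ndarray

    def __post_init__(self) -> None:
        self.trough_times_ms = np.asarray(self.trough_times_ms, dtype=float)
        self.periods_s = np.asarray(self.periods_s, dtype=float)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        if np.any(np.diff(self.trough_times_ms) <= 0):
            raise ValueError("trough times must be strictly increasing")

    @property
    def accepted_periods_s(self) -> np.ndarray:
        return self.periods_s[self.accepted]


@dataclass(frozen=True)
class DominantFrequency:
    """Reciprocal of the pooled median gamma cycle period."""

    median_period_s: float
    n_cycles: int

    @property
    def freq_hz(self) -> float:
        return 1.0 / self.median_period_s


def bandpass_gamma(x: np.ndarray, fs: float = 1000.0) -> np.ndarray:
    """Zero-phase 35-120 Hz FIR band-pass (stops 25/140 Hz, 20 dB)."""
    if not np.isclose(fs, 1000.0):
        raise ValueError("gamma band-pass is specified for 1 kHz signals")
    x = np.asarray(x, dtype=np.float64)
    return zero_phase_filter(x, GAMMA_BANDPASS, fs).reshape(x.shape)


def analytic_phase_amplitude(narrowband: np.ndarray, fs: float = 1000.0,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase and smoothed amplitude of a narrowband signal.

    Phase in (-pi, pi] from the analytic signal; the amplitude envelope is
    smoothed with a Gaussian of sigma 10 ms truncated at +-3 sigma
    (unit-sum kernel).
    """
    x = np.asarray(narrowband, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty series")
    analytic = hilbert(x)
    phase = np.angle(analytic)
    amp = gaussian_filter1d(np.abs(analytic),
                            sigma=AMP_SMOOTH_SIGMA_MS * fs / 1000.0,
                            truncate=3.0, mode="reflect")
    return phase, amp


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True in ``mask``."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def detect_gamma_troughs(phase: np.ndarray, amp: np.ndarray,
                         window: slice, fs: float = 1000.0) -> CycleSeries:
    """Trough times and periods within above-median-amplitude episodes.

    The amplitude median is taken over ``window`` (the trial's MC2/3
    samples).  Maximal runs with amplitude strictly above the median and
    duration >= 40 ms are scanned for crossings of pi + 2 pi k of the
    unwrapped phase, located by linear interpolation; periods never span
    separate runs.
    """
    phase = np.asarray(phase, dtype=float)
    amp = np.asarray(amp, dtype=float)
    w_amp = amp[window]
    if w_amp.size == 0:
        raise ValueError("empty analysis window")
    median_amp = np.median(w_amp)
    offset = window.start or 0
    mask = w_amp > median_amp
    min_run = int(round(MIN_RUN_MS * fs / 1000.0))

    troughs: list[float] = []
    periods: list[float] = []
    for start, stop in _runs_above(mask):
        if stop - start < min_run:
            continue
        seg = np.unwrap(phase[offset + start:offset + stop])
        # crossing levels pi + 2 pi k inside the segment's phase range
        k_lo = int(np.ceil((seg.min() - np.pi) / (2 * np.pi)))
        k_hi = int(np.floor((seg.max() - np.pi) / (2 * np.pi)))
        run_troughs: list[float] = []
        for k in range(k_lo, k_hi + 1):
            level = np.pi + 2 * np.pi * k
            d = seg - level
            cross = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0))
            for c in cross:
                frac = -d[c] / (d[c + 1] - d[c])
                t_ms = (offset + start + c + frac) / fs * 1000.0
                run_troughs.append(t_ms)
        run_troughs.sort()
        troughs.extend(run_troughs)
        periods.extend(np.diff(run_troughs) / 1000.0)

    periods_arr = np.asarray(periods, dtype=float)
    accepted = ((periods_arr >= PERIOD_BOUNDS_S[0])
                & (periods_arr <= PERIOD_BOUNDS_S[1]))
    return CycleSeries(trough_times_ms=np.asarray(sorted(troughs)),
                       periods_s=periods_arr, accepted=accepted)


def dominant_frequency_from_periods(series: list[CycleSeries],
                                    ) -> DominantFrequency:
    """Pool accepted periods across trials; frequency = 1/median period.

    An even number of periods uses the midpoint of the two central values.
    Raises when no accepted periods exist.
    """
    pooled = np.concatenate([s.accepted_periods_s for s in series]
                            or [np.empty(0)])
    if pooled.size == 0:
        raise ValueError("no accepted gamma cycle periods")
    med = float(np.median(pooled))
    return DominantFrequency(median_period_s=med, n_cycles=int(pooled.size))
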