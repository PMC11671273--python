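"""LFP and entire-spiking-activity (ESA) extraction from broadband traces.

The LFP is the low-frequency part of the extracellular potential: a
zero-phase low-pass FIR (passband < 160 Hz, stopband from 300 Hz, 80 dB
stopband attenuation as a single-pass spec) followed by decimation to
1 kHz.  ESA is a continuous measure of population spiking that avoids
spike thresholding: high-pass (> 400 Hz, stop 300 Hz, 80 dB), full-wave
rectification, then the same low-pass and decimation as the LFP.

Filters are Kaiser-window FIR designs and are applied forward and backward
(zero phase); the forward-backward pass doubles the stopband attenuation of
the single-pass design.  Trials are reflect-padded by three filter lengths
before filtering to contain edge transients.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .session import BroadbandTrial, EsaTrial, LfpTrial

__all__ = [
    "FilterKind",
    "FilterSpec",
    "LFP_LOWPASS",
    "ESA_HIGHPASS",
    "BASELINE_LOWPASS",
    "design_fir",
    "zero_phase_filter",
    "extract_lfp",
    "extract_esa",
]

FS_DERIVED = 1000.0


class FilterKind(str, Enum):
    LOWPASS = "lowpass"
    HIGHPASS = "highpass"
    BANDPASS = "bandpass"


@dataclass(frozen=True)
class FilterSpec:
    """FIR filter contract: pass/stop edges (Hz) and stopband attenuation.

    ``pass_hz``/``stop_hz`` are scalars for low/high-pass and ``(lo, hi)``
    pairs for band-pass.  ``atten_db`` is the single-pass stopband
    attenuation; ``zero_phase`` applies the filter forward and backward.
    """

    kind: FilterKind
    pass_hz: float | tuple[float, float]
    stop_hz: float | tuple[float, float]
    atten_db: float
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.atten_db <= 0:
            raise ValueError("atten_db must be positive")
        if self.kind == FilterKind.LOWPASS and not self.pass_hz < self.stop_hz:
            raise ValueError("lowpass needs pass_hz < stop_hz")
        if self.kind == FilterKind.HIGHPASS and not self.pass_hz > self.stop_hz:
            raise ValueError("highpass needs pass_hz > stop_hz")
        if self.kind == FilterKind.BANDPASS:
            (p_lo, p_hi), (s_lo, s_hi) = self.pass_hz, self.stop_hz
            if not (s_lo < p_lo < p_hi < s_hi):
                raise ValueError("bandpass needs stop_lo < pass_lo < pass_hi < stop_hi")


LFP_LOWPASS = FilterSpec(FilterKind.LOWPASS, pass_hz=160.0, stop_hz=300.0,
                         atten_db=80.0)
ESA_HIGHPASS = FilterSpec(FilterKind.HIGHPASS, pass_hz=400.0, stop_hz=300.0,
                          atten_db=80.0)
BASELINE_LOWPASS = FilterSpec(FilterKind.LOWPASS, pass_hz=15.0, stop_hz=20.0,
                              atten_db=35.0)
GAMMA_BANDPASS = FilterSpec(FilterKind.BANDPASS, pass_hz=(35.0, 120.0),
                            stop_hz=(25.0, 140.0), atten_db=20.0)


@lru_cache(maxsize=32)
def design_fir(spec: FilterSpec, fs: float) -> np.ndarray:
    """Kaiser-window FIR taps meeting ``spec`` at sampling rate ``fs``."""
    nyq = fs / 2.0
    if spec.kind == FilterKind.BANDPASS:
        (p_lo, p_hi), (s_lo, s_hi) = spec.pass_hz, spec.stop_hz
        width = min(p_lo - s_lo, s_hi - p_hi)
        cutoff = [(s_lo + p_lo) / 2.0, (p_hi + s_hi) / 2.0]
        pass_zero = False
    else:
        width = abs(float(spec.stop_hz) - float(spec.pass_hz))
        cutoff = [(float(spec.stop_hz) + float(spec.pass_hz)) / 2.0]
        pass_zero = spec.kind == FilterKind.LOWPASS
    if cutoff[-1] >= nyq:
        raise ValueError(f"filter edges exceed Nyquist ({nyq} Hz)")
    # Kaiser designs tie passband ripple to stopband attenuation; floor the
    # design attenuation at 40 dB so low-suppression specs (e.g. 20 dB) do
    # not ripple the passband, while still exceeding the stated suppression.
    numtaps, beta = sps.kaiserord(max(spec.atten_db, 40.0), width / nyq)
    numtaps += (numtaps + 1) % 2  # odd length: exact linear phase, HP-safe
    return sps.firwin(numtaps, cutoff, window=("kaiser", beta), fs=fs,
                      pass_zero=pass_zero)


def zero_phase_filter(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Apply ``spec`` to ``x`` along the last axis with zero phase.

    Forward-backward application of the (symmetric) FIR via FFT convolution;
    the input is reflect-padded by three filter lengths and trimmed after.
    """
    taps = design_fir(spec, fs)
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    n = x.shape[-1]
    pad = min(3 * len(taps), n - 1)
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    # symmetric taps: forward+backward == convolving twice
    h2 = np.convolve(taps, taps[::-1])
    y = sps.fftconvolve(xp, h2[np.newaxis, :], mode="same", axes=-1)
    y = y[..., pad:pad + n]
    if not spec.zero_phase:
        # single-pass variant retained for completeness
        y = sps.fftconvolve(xp, taps[np.newaxis, :], mode="same", axes=-1)
        y = y[..., pad:pad + n]
    return y


def _decimation_factor(fs: float) -> int:
    if fs < 2000.0:
        raise ValueError("broadband sampling rate must be at least 2,000 Hz")
    q = fs / FS_DERIVED
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"sampling rate {fs} Hz is not an integer multiple of 1 kHz")
    return int(round(q))


def extract_lfp(trial: BroadbandTrial) -> LfpTrial:
    """Low-pass filter (zero phase) and decimate the trial to 1 kHz."""
    q = _decimation_factor(trial.fs)
    low = zero_phase_filter(trial.data, LFP_LOWPASS, trial.fs)
    return LfpTrial(data=low[:, ::q], fs=FS_DERIVED, epochs=trial.epochs,
                    condition=trial.condition)


def extract_esa(trial: BroadbandTrial) -> EsaTrial:
    """Entire spiking activity: high-pass, rectify, LFP low-pass, 1 kHz."""
    q = _decimation_factor(trial.fs)
    high = zero_phase_filter(trial.data, ESA_HIGHPASS, trial.fs)
    env = zero_phase_filter(np.abs(high), LFP_LOWPASS, trial.fs)
    return EsaTrial(data=env[:, ::q], fs=FS_DERIVED, epochs=trial.epochs,
                    condition=trial.condition)
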