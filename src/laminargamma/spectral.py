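"""Morlet wavelet time-frequency analysis and gamma-band determination.

Signals are convolved with complex Morlet wavelets

    Psi(t, f0) = A exp(-t^2 / (2 sigma_t^2)) exp(2 i pi f0 t),

with sigma_f = 1/(pi sigma_t), a constant quality factor f0/sigma_f = 6,
and A = (sigma_t sqrt(pi))^(-1/2) so that each wavelet has unit energy.
Center frequencies span 5-160 Hz on a geometric grid (8 voices/octave by
default).  Power spectral density is |W|^2 divided by the 500 Hz Nyquist
frequency of the 1 kHz derived signals; the 1/f bias is corrected by
multiplying each PSD value by its wavelet's center frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "WaveletBank",
    "Tfr",
    "build_wavelet_bank",
    "morlet_wavelet",
    "wavelet_transform",
    "psd_spectrum",
    "determine_gamma_band",
    "GAMMA_BAND_WIDE",
    "GAMMA_BAND_ESA",
]

NYQUIST_HZ = 500.0
Q_FACTOR = 6.0  # f0 / sigma_f
EDGE_SIGMAS = 3.0  # samples within 3 sigma_t of an edge are invalid

#: Full-width-half-maximum gamma band of the grand-mean corrected PSD,
#: used for hotspot detection and attention analyses.
GAMMA_BAND_WIDE = (42.5, 130.5)
#: Narrower gamma band used for the ESA domain-preference profiles.
GAMMA_BAND_ESA = (28.0, 78.0)


@dataclass(frozen=True)
class WaveletBank:
    """Morlet wavelet family over a geometric center-frequency grid."""

    f0_hz: np.ndarray
    fs: float = 1000.0

    @property
    def sigma_f(self) -> np.ndarray:
        return self.f0_hz / Q_FACTOR

    @property
    def sigma_t(self) -> np.ndarray:
        return 1.0 / (np.pi * self.sigma_f)

    @property
    def nyquist_hz(self) -> float:
        return self.fs / 2.0

    def restrict(self, band: tuple[float, float]) -> "WaveletBank":
        """Sub-bank with center frequencies inside ``band`` (inclusive)."""
        lo, hi = band
        sel = (self.f0_hz >= lo) & (self.f0_hz <= hi)
        if not sel.any():
            raise ValueError(f"no wavelet frequencies inside {band}")
        return WaveletBank(f0_hz=self.f0_hz[sel], fs=self.fs)


def build_wavelet_bank(fmin: float = 5.0, fmax: float = 160.0,
                       voices_per_octave: int = 8,
                       fs: float = 1000.0) -> WaveletBank:
    """Geometric grid ``fmin * 2^(i/voices)`` truncated at ``fmax``."""
    if not 0 < fmin < fmax:
        raise ValueError("need 0 < fmin < fmax")
    n = int(np.floor(voices_per_octave * np.log2(fmax / fmin))) + 1
    f0 = fmin * 2.0 ** (np.arange(n) / voices_per_octave)
    f0 = f0[f0 <= fmax * (1 + 1e-12)]
    return WaveletBank(f0_hz=f0, fs=fs)


def morlet_wavelet(f0: float, fs: float,
                   n_sigmas: float = 5.0) -> np.ndarray:
    """Sampled unit-energy complex Morlet wavelet at center frequency f0."""
    sigma_t = Q_FACTOR / (np.pi * f0)
    half = int(np.ceil(n_sigmas * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    a = (sigma_t * np.sqrt(np.pi)) ** -0.5
    return a * np.exp(-t * t / (2 * sigma_t * sigma_t)) * np.exp(2j * np.pi * f0 * t)


@dataclass
class Tfr:
    """Time-frequency representation: frequencies x channels x time.

    ``values`` holds complex wavelet coefficients (or nonnegative power
    after squaring); ``edge_invalid`` gives, per frequency, the number of
    samples at each end contaminated by edge effects (3 sigma_t).
    """

    values: np.ndarray
    f0_hz: np.ndarray
    fs: float
    edge_invalid: np.ndarray
    one_over_f_corrected: bool = False


def wavelet_transform(data: np.ndarray, bank: WaveletBank) -> Tfr:
    """Complex Morlet transform of ``data`` (channels x time, or 1-D).

    The convolution approximates the continuous integral (sum times the
    sampling step).  Raises if the signal is shorter than six sigma_t of
    the lowest-frequency wavelet.
    """
    x = np.atleast_2d(np.asarray(data, dtype=np.float64))
    n = x.shape[-1]
    sigma_t = bank.sigma_t
    if n <= 6.0 * sigma_t.max() * bank.fs:
        raise ValueError("signal too short for the lowest wavelet frequency")
    out = np.empty((bank.f0_hz.size,) + x.shape, dtype=np.complex128)
    dt = 1.0 / bank.fs
    for i, f0 in enumerate(bank.f0_hz):
        w = morlet_wavelet(f0, bank.fs)
        out[i] = sps.fftconvolve(x, w[np.newaxis, :], mode="same", axes=-1) * dt
    edge = np.ceil(EDGE_SIGMAS * sigma_t * bank.fs).astype(int)
    return Tfr(values=out, f0_hz=bank.f0_hz, fs=bank.fs, edge_invalid=edge)


def psd_spectrum(tfr: Tfr, window: slice | None = None,
                 one_over_f_correct: bool = True) -> np.ndarray:
    """Time-mean power spectral density over ``window``.

    PSD(f) is the mean over valid window samples of |W|^2 / 500 Hz; with
    ``one_over_f_correct`` each value is additionally multiplied by its
    wavelet's center frequency.  Returns frequencies x channels.
    """
    vals = tfr.values
    n = vals.shape[-1]
    start = window.start if window and window.start is not None else 0
    stop = window.stop if window and window.stop is not None else n
    out = np.empty(vals.shape[:-1])
    for i in range(tfr.f0_hz.size):
        lo = max(start, int(tfr.edge_invalid[i]))
        hi = min(stop, n - int(tfr.edge_invalid[i]))
        if hi <= lo:
            raise ValueError("window empty after edge exclusion")
        seg = vals[i, ..., lo:hi]
        out[i] = np.mean(np.abs(seg) ** 2, axis=-1) / NYQUIST_HZ
    if one_over_f_correct:
        out = out * tfr.f0_hz.reshape((-1,) + (1,) * (out.ndim - 1))
    return out


def determine_gamma_band(f0_hz: np.ndarray, psd: np.ndarray,
                         search_hz: tuple[float, float] = (30.0, 120.0),
                         ) -> tuple[float, float]:
    """Gamma band as the FWHM of the corrected-PSD peak within ``search_hz``.

    Finds the maximum of the 1/f-corrected mean PSD within the search
    range and returns the frequencies where the PSD crosses half that
    value on each side (linear interpolation between grid points).
    Raises when no peak stands above its surroundings.
    """
    f0_hz = np.asarray(f0_hz, dtype=float)
    psd = np.asarray(psd, dtype=float)
    sel = np.flatnonzero((f0_hz >= search_hz[0]) & (f0_hz <= search_hz[1]))
    if sel.size == 0:
        raise ValueError("no grid frequencies inside the search range")
    ipk = sel[np.argmax(psd[sel])]
    half = psd[ipk] / 2.0

    def _cross(indices: range) -> float | None:
        prev = ipk
        for i in indices:
            if psd[i] <= half:
                f1, f2 = f0_hz[i], f0_hz[prev]
                p1, p2 = psd[i], psd[prev]
                if p2 == p1:
                    return float(f1)
                return float(f1 + (half - p1) * (f2 - f1) / (p2 - p1))
            prev = i
        return None

    lo = _cross(range(ipk - 1, -1, -1))
    hi = _cross(range(ipk + 1, f0_hz.size))
    if lo is None or hi is None:
        raise ValueError("no gamma peak above the surrounding baseline")
    return (lo, hi)
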