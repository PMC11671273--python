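"""Trial-structured laminar recording sessions.

A :class:`Session` holds the broadband traces of one linear-probe recording
together with the probe geometry, per-trial epoch timing and attention
condition labels.  Sessions live on disk as a plain directory: a UTF-8 JSON
manifest plus one little-endian float32 binary per trial (channel-major).

Conventions used throughout the package
---------------------------------------
* time is measured in milliseconds from trial start; intervals are half-open
  ``[start, end)``;
* channel 0 is the most superficial contact and depth increases downward;
* derived signals (LFP, ESA, CSD) are sampled at 1 kHz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Attention",
    "ProbeGeometry",
    "TrialEpochs",
    "Condition",
    "BroadbandTrial",
    "DerivedTrial",
    "LfpTrial",
    "EsaTrial",
    "CsdTrial",
    "Session",
    "write_session",
    "read_session",
    "slice_epoch",
]


class Attention(str, Enum):
    """The three spatial-attention conditions of the tracking task."""

    ATTEND_IN = "attend_in"
    ATTEND_NEARBY = "attend_nearby"
    ATTEND_AWAY = "attend_away"


@dataclass(frozen=True)
class ProbeGeometry:
    """Linear multi-contact probe with equidistant contacts.

    Parameters
    ----------
    n_channels : int
        Number of contacts (16 or 32 for the probes modelled here).
    pitch_um : float
        Center-to-center contact spacing in micrometers (default 100).
    """

    n_channels: int = 16
    pitch_um: float = 100.0

    def __post_init__(self) -> None:
        if self.n_channels < 4:
            raise ValueError("probe needs at least 4 channels")
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")

    def depth_of(self, channel: int) -> float:
        """Depth (um below the topmost contact) of ``channel``."""
        if not 0 <= channel < self.n_channels:
            raise IndexError(f"channel {channel} outside probe")
        return channel * self.pitch_um

    @property
    def depths_um(self) -> np.ndarray:
        return np.arange(self.n_channels) * self.pitch_um

    @property
    def span_um(self) -> float:
        return (self.n_channels - 1) * self.pitch_um


@dataclass(frozen=True)
class TrialEpochs:
    """Epoch timing of one trial, in ms from trial start.

    The default layout is a 1,050-ms baseline, stimulus onset, a 520-ms
    static period, then contiguous 1,000-ms morph cycles (MCs).  When the
    lever release falls inside the analysed window (MC2 start to MC3 end),
    analysis stops 150 ms before the release; otherwise it runs to the end
    of MC3.
    """

    fs_raw: float
    baseline_ms: tuple[float, float] = (0.0, 1050.0)
    stim_onset_ms: float = 1050.0
    static_end_ms: float = 1570.0
    mc_bounds_ms: tuple[tuple[float, float], ...] = (
        (1570.0, 2570.0),
        (2570.0, 3570.0),
        (3570.0, 4570.0),
    )
    lever_release_ms: float | None = None

    def __post_init__(self) -> None:
        if self.fs_raw <= 0:
            raise ValueError("fs_raw must be positive")
        prev_end = self.static_end_ms
        for start, end in self.mc_bounds_ms:
            if not np.isclose(end - start, 1000.0):
                raise ValueError("each morph cycle must last exactly 1,000 ms")
            if not np.isclose(start, prev_end):
                raise ValueError("morph cycles must be contiguous")
            prev_end = end

    @property
    def n_morph_cycles(self) -> int:
        return len(self.mc_bounds_ms)

    def mc(self, index: int) -> tuple[float, float]:
        """Bounds of morph cycle ``index`` (1-based, as in MC2/MC3)."""
        return self.mc_bounds_ms[index - 1]

    @property
    def analysis_end_ms(self) -> float:
        """End of the analysed window (150 ms before release if inside it)."""
        if self.n_morph_cycles < 3:
            end = self.mc_bounds_ms[-1][1]
        else:
            end = self.mc(3)[1]
        start = self.mc(2)[0] if self.n_morph_cycles >= 2 else self.mc_bounds_ms[0][0]
        if self.lever_release_ms is not None and start < self.lever_release_ms <= end:
            return self.lever_release_ms - 150.0
        return end

    @property
    def mc23_ms(self) -> tuple[float, float]:
        """The MC2-start-to-analysis-end window used by most analyses."""
        return (self.mc(2)[0], self.analysis_end_ms)


@dataclass(frozen=True)
class Condition:
    """Per-trial task condition: attention target, stimulus flags, outcome."""

    attention: Attention
    rf_stim_present: bool = True
    nearby_stim_present: bool = True
    correct: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "attention", Attention(self.attention))


def _check_finite(data: np.ndarray) -> None:
    if not np.all(np.isfinite(data)):
        raise ValueError("trial data contains non-finite samples")


@dataclass
class BroadbandTrial:
    """Raw multichannel trace of one trial (channels x samples, volts)."""

    data: np.ndarray
    fs: float
    epochs: TrialEpochs
    condition: Condition

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("trial data must be 2-D (channels x samples)")
        _check_finite(self.data)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0


@dataclass
class DerivedTrial:
    """Depth x time signal derived from one trial, sampled at 1 kHz.

    Pipeline products (LFP, ESA, and the CSD inverted from them) are
    sampled at 1 kHz; simulated ground-truth CSD may instead live on a
    fine depth grid at the raw sampling rate (``_enforce_1khz`` is off
    for :class:`CsdTrial` for that reason).
    """

    data: np.ndarray
    fs: float
    epochs: TrialEpochs
    condition: Condition
    positions_um: np.ndarray | None = None

    _enforce_1khz = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("derived data must be 2-D (positions x samples)")
        if self._enforce_1khz and not np.isclose(self.fs, 1000.0):
            raise ValueError("derived signals are sampled at 1,000 Hz")
        if self.positions_um is not None:
            self.positions_um = np.asarray(self.positions_um, dtype=float)
            if self.positions_um.size != self.data.shape[0]:
                raise ValueError("positions/rows mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


class LfpTrial(DerivedTrial):
    pass


class EsaTrial(DerivedTrial):
    pass


class CsdTrial(DerivedTrial):
    """CSD at electrode depths (or a fine grid for simulated ground truth)."""

    _enforce_1khz = False


@dataclass
class Session:
    """An ordered collection of trials sharing a probe and sampling rate."""

    probe: ProbeGeometry
    trials: list[BroadbandTrial]
    performance: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.performance <= 1.0:
            raise ValueError("performance must be a fraction in [0, 1]")
        for t in self.trials:
            if t.n_channels != self.probe.n_channels:
                raise ValueError(
                    f"trial has {t.n_channels} channels, probe has "
                    f"{self.probe.n_channels}"
                )
        fss = {t.fs for t in self.trials}
        if len(fss) > 1:
            raise ValueError("all trials must share the sampling rate")

    @property
    def fs(self) -> float:
        return self.trials[0].fs if self.trials else float("nan")

    def __len__(self) -> int:
        return len(self.trials)

    def select(self, **flags) -> list[int]:
        """Indices of trials matching condition attributes (e.g. attention)."""
        out = []
        for i, t in enumerate(self.trials):
            cond = t.condition
            ok = True
            for key, val in flags.items():
                if key == "attention":
                    ok &= cond.attention == Attention(val)
                else:
                    ok &= getattr(cond, key) == val
            if ok:
                out.append(i)
        return out


# ---------------------------------------------------------------------------
# Disk format


def _epochs_to_json(ep: TrialEpochs) -> dict:
    return {
        "fs_raw": ep.fs_raw,
        "baseline_ms": list(ep.baseline_ms),
        "stim_onset_ms": ep.stim_onset_ms,
        "static_end_ms": ep.static_end_ms,
        "mc_bounds_ms": [list(b) for b in ep.mc_bounds_ms],
        "lever_release_ms": ep.lever_release_ms,
    }


def _epochs_from_json(d: dict) -> TrialEpochs:
    return TrialEpochs(
        fs_raw=d["fs_raw"],
        baseline_ms=tuple(d["baseline_ms"]),
        stim_onset_ms=d["stim_onset_ms"],
        static_end_ms=d["static_end_ms"],
        mc_bounds_ms=tuple(tuple(b) for b in d["mc_bounds_ms"]),
        lever_release_ms=d["lever_release_ms"],
    )


def write_session(session: Session, path: str | Path) -> None:
    """Write ``session`` to ``path`` as manifest + float32 binaries.

    Round-trips losslessly at float32 precision via :func:`read_session`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trials_meta = []
    for i, trial in enumerate(session.trials):
        fname = f"trial_{i:04d}.f32"
        arr = trial.data.astype("<f4")
        arr.tofile(path / fname)
        trials_meta.append(
            {
                "file": fname,
                "n_channels": trial.n_channels,
                "n_samples": trial.n_samples,
                "epochs": _epochs_to_json(trial.epochs),
                "condition": {
                    "attention": trial.condition.attention.value,
                    "rf_stim_present": trial.condition.rf_stim_present,
                    "nearby_stim_present": trial.condition.nearby_stim_present,
                    "correct": trial.condition.correct,
                },
            }
        )
    manifest = {
        "format": "laminargamma-session-v1",
        "probe": {"n_channels": session.probe.n_channels,
                  "pitch_um": session.probe.pitch_um},
        "fs": session.fs,
        "performance": session.performance,
        "meta": session.meta,
        "trials": trials_meta,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1),
                                        encoding="utf-8")


def read_session(path: str | Path) -> Session:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    probe = ProbeGeometry(**manifest["probe"])
    trials = []
    for tm in manifest["trials"]:
        fpath = path / tm["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"missing trial binary {fpath}")
        arr = np.fromfile(fpath, dtype="<f4")
        expected = tm["n_channels"] * tm["n_samples"]
        if arr.size != expected:
            raise ValueError(
                f"{fpath}: expected {expected} samples, found {arr.size}"
            )
        data = arr.reshape(tm["n_channels"], tm["n_samples"]).astype(np.float64)
        trials.append(
            BroadbandTrial(
                data=data,
                fs=manifest["fs"],
                epochs=_epochs_from_json(tm["epochs"]),
                condition=Condition(**tm["condition"]),
            )
        )
    return Session(
        probe=probe,
        trials=trials,
        performance=manifest["performance"],
        meta=manifest.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# Epoch slicing

_NAMED_WINDOWS = ("baseline", "static", "mc1", "mc2", "mc3", "mc23")


def _resolve_window(epochs: TrialEpochs,
                    window: str | tuple[float, float]) -> tuple[float, float]:
    if isinstance(window, str):
        if window == "baseline":
            return epochs.baseline_ms
        if window == "static":
            return (epochs.stim_onset_ms, epochs.static_end_ms)
        if window.startswith("mc") and window != "mc23":
            return epochs.mc(int(window[2:]))
        if window == "mc23":
            return epochs.mc23_ms
        raise ValueError(f"unknown window {window!r}; use one of {_NAMED_WINDOWS}")
    start, end = window
    return float(start), float(end)


def slice_epoch(trial: BroadbandTrial | DerivedTrial,
                window: str | tuple[float, float]) -> np.ndarray:
    """Samples of ``trial`` within a half-open ms window ``[start, end)``.

    ``window`` may be a named epoch (``"baseline"``, ``"static"``, ``"mc1"``
    ... ``"mc3"``, ``"mc23"``) or a ``(start_ms, end_ms)`` pair.  ``"mc23"``
    runs from MC2 start to the analysis end (150 ms before lever release when
    the release falls inside the window).
    """
    start_ms, end_ms = _resolve_window(trial.epochs, window)
    if start_ms > end_ms:
        raise ValueError("window start after end")
    i0 = int(round(start_ms * trial.fs / 1000.0))
    i1 = int(round(end_ms * trial.fs / 1000.0))
    if i0 < 0 or i1 > trial.n_samples:
        raise ValueError(
            f"window [{start_ms}, {end_ms}) ms outside trial of "
            f"{trial.n_samples / trial.fs * 1000.0:.0f} ms"
        )
    return trial.data[:, i0:i1]


def window_slice(epochs: TrialEpochs, fs: float,
                 window: str | tuple[float, float]) -> slice:
    """Sample-index slice of a named or explicit ms window."""
    start_ms, end_ms = _resolve_window(epochs, window)
    return slice(int(round(start_ms * fs / 1000.0)),
                 int(round(end_ms * fs / 1000.0)))
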