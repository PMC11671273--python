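"""Shared fixtures: small synthetic sessions and probe geometry."""

from __future__ import annotations

import numpy as np
import pytest

from laminargamma import ProbeGeometry
from laminargamma.session import (Attention, BroadbandTrial, Condition,
                                  Session, TrialEpochs)
from laminargamma.synth import build_ground_truth, simulate_session


@pytest.fixture(scope="session")
def probe16() -> ProbeGeometry:
    return ProbeGeometry(n_channels=16, pitch_um=100.0)


@pytest.fixture(scope="session")
def default_gt():
    return build_ground_truth(seed=7)


@pytest.fixture(scope="session")
def small_session(default_gt):
    """Six trials per condition: enough for every stage to run."""
    return simulate_session(default_gt, n_trials_per_condition=6)


def make_trial(data: np.ndarray, fs: float = 5000.0,
               attention: str = "attend_in", **cond) -> BroadbandTrial:
    return BroadbandTrial(data=data, fs=fs, epochs=TrialEpochs(fs_raw=fs),
                          condition=Condition(attention=attention, **cond))


@pytest.fixture()
def toy_session(probe16) -> Session:
    """Two trials of low-amplitude noise, 16 channels at 5 kHz."""
    rng = np.random.default_rng(0)
    n = int(4.75 * 5000)
    trials = [make_trial(1e-6 * rng.standard_normal((16, n)))
              for _ in range(2)]
    return Session(probe=probe16, trials=trials, performance=0.8)
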