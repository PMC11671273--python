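"""Session container, disk round trip, and epoch slicing."""

import numpy as np
import pytest

from laminargamma.session import (Attention, BroadbandTrial, Condition,
                                  ProbeGeometry, Session, TrialEpochs,
                                  read_session, slice_epoch, write_session)

from conftest import make_trial


def test_probe_depths_increase():
    probe = ProbeGeometry(16, 100.0)
    assert probe.depth_of(0) == 0.0
    assert np.all(np.diff(probe.depths_um) > 0)
    with pytest.raises(ValueError):
        ProbeGeometry(n_channels=3)
    with pytest.raises(ValueError):
        ProbeGeometry(pitch_um=-1.0)


def test_epoch_defaults_and_analysis_end():
    ep = TrialEpochs(fs_raw=5000.0)
    assert ep.baseline_ms == (0.0, 1050.0)
    assert ep.static_end_ms - ep.stim_onset_ms == 520.0
    assert all(b - a == 1000.0 for a, b in ep.mc_bounds_ms)
    # no lever release: analysis runs to the end of MC3
    assert ep.analysis_end_ms == ep.mc(3)[1] == 4570.0
    # release inside the analysed window truncates 150 ms before it
    ep2 = TrialEpochs(fs_raw=5000.0, lever_release_ms=3770.0)
    assert ep2.analysis_end_ms == 3620.0
    assert ep2.mc23_ms == (2570.0, 3620.0)
    # release after MC3: no truncation
    ep3 = TrialEpochs(fs_raw=5000.0, lever_release_ms=4700.0)
    assert ep3.analysis_end_ms == 4570.0


def test_epochs_must_be_contiguous_seconds():
    with pytest.raises(ValueError):
        TrialEpochs(fs_raw=5000.0, mc_bounds_ms=((1570.0, 2500.0),))
    with pytest.raises(ValueError):
        TrialEpochs(fs_raw=5000.0,
                    mc_bounds_ms=((1570.0, 2570.0), (2600.0, 3600.0)))


def test_trial_rejects_non_finite():
    data = np.zeros((16, 1000))
    data[3, 5] = np.nan
    with pytest.raises(ValueError):
        make_trial(data)


def test_session_rejects_channel_mismatch(probe16):
    trial = make_trial(np.zeros((8, 1000)))
    with pytest.raises(ValueError):
        Session(probe=probe16, trials=[trial])


def test_write_read_round_trip(tmp_path, toy_session):
    write_session(toy_session, tmp_path / "sess")
    back = read_session(tmp_path / "sess")
    assert len(back) == len(toy_session)
    assert back.probe == toy_session.probe
    assert back.performance == toy_session.performance
    for a, b in zip(toy_session.trials, back.trials):
        np.testing.assert_allclose(b.data, a.data, rtol=1e-6, atol=1e-12)
        assert b.condition == a.condition
        assert b.epochs == a.epochs


def test_read_missing_binary_raises(tmp_path, toy_session):
    write_session(toy_session, tmp_path / "sess")
    (tmp_path / "sess" / "trial_0001.f32").unlink()
    with pytest.raises(FileNotFoundError):
        read_session(tmp_path / "sess")


def test_read_shape_mismatch_raises(tmp_path, toy_session):
    write_session(toy_session, tmp_path / "sess")
    path = tmp_path / "sess" / "trial_0000.f32"
    path.write_bytes(path.read_bytes()[:-8])
    with pytest.raises(ValueError):
        read_session(tmp_path / "sess")


def test_low_performance_session_still_loads(tmp_path, toy_session):
    toy_session.performance = 0.60
    write_session(toy_session, tmp_path / "sess")
    back = read_session(tmp_path / "sess")
    assert back.performance == 0.60  # filtering is the pipeline's job


def test_slice_epoch_baseline_sample_count():
    data = np.zeros((4, 5000))
    trial = BroadbandTrial(data=data, fs=1000.0,
                          epochs=TrialEpochs(fs_raw=1000.0),
                          condition=Condition(attention="attend_in"))
    assert slice_epoch(trial, "baseline").shape == (4, 1050)
    assert slice_epoch(trial, (100.0, 100.0)).shape == (4, 0)
    with pytest.raises(ValueError):
        slice_epoch(trial, (0.0, 10_000.0))


def test_slice_epoch_halfopen_concatenation():
    rng = np.random.default_rng(1)
    data = rng.standard_normal((2, 5000))
    trial = BroadbandTrial(data=data, fs=1000.0,
                          epochs=TrialEpochs(fs_raw=1000.0),
                          condition=Condition(attention="attend_away"))
    joined = np.concatenate(
        [slice_epoch(trial, (0.0, 1700.0)),
         slice_epoch(trial, (1700.0, 3200.0)),
         slice_epoch(trial, (3200.0, 5000.0))], axis=1)
    np.testing.assert_array_equal(joined, data)


def test_mc23_truncated_by_lever_release():
    ep = TrialEpochs(fs_raw=1000.0, lever_release_ms=3770.0)
    trial = BroadbandTrial(data=np.zeros((2, 5000)), fs=1000.0, epochs=ep,
                          condition=Condition(attention="attend_in"))
    # MC2 starts at 2,570 ms; release 200 ms into MC3 ends analysis at 3,620
    assert slice_epoch(trial, "mc23").shape == (2, 1050)


def test_session_select_by_attention(toy_session):
    idx = toy_session.select(attention=Attention.ATTEND_IN)
    assert idx == [0, 1]
    assert toy_session.select(attention="attend_away") == []
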