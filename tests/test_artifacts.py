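"""Artifact detectors against brute-force sliding-window oracles."""

import numpy as np
import pandas as pd
import pytest

from wmcda.cda import (
    EpochSet,
    detect_abs_and_steps,
    detect_drift,
    detect_eog,
    detect_gaze,
    detect_p2p,
    reject_and_exclude,
)
from wmcda._utils import CDA_CHANNELS

from oracles import oracle_drift, oracle_p2p, oracle_step


def _epochs_from_array(data, sfreq=500.0, channels=None):
    n_trials = data.shape[0]
    channels = channels or [*CDA_CHANNELS, "VEOG", "HEOG"]
    meta = pd.DataFrame({"participant": np.zeros(n_trials, int),
                         "cue_side": "left", "set_size": 3, "stim_type": "CLR_REP"})
    return EpochSet(data=data, sfreq=sfreq, tmin_ms=-200.0, channels=channels, metadata=meta)


@pytest.fixture(scope="module")
def random_epochs():
    """100 random epochs with heavy-tailed noise so flags are mixed."""
    rng = np.random.default_rng(12345)
    data = 25.0 * rng.standard_t(df=3, size=(100, 10, 550))
    return _epochs_from_array(data)


class TestOracleAgreement:
    def test_eog_detectors_match_oracle(self, random_epochs):
        ep = random_epochs
        abs_flags, step_flags = detect_eog(ep)
        eog = ep.data[:, ep.channel_index(["VEOG", "HEOG"]), :]
        win, step = 50, 5  # 100 ms / 10 ms at 500 Hz
        for t in range(ep.n_trials):
            assert abs_flags[t] == bool((np.abs(eog[t]) > 50.0).any())
            expect = any(oracle_step(eog[t, c], win, step, 30.0) for c in range(2))
            assert step_flags[t] == expect

    def test_eeg_step_matches_oracle(self, random_epochs):
        ep = random_epochs
        flags = detect_abs_and_steps(ep)["eeg_step"]
        idx = ep.channel_index(ep.eeg_channels)
        win, step = 75, 5  # 150 ms / 10 ms
        for t in range(ep.n_trials):
            expect = any(oracle_step(ep.data[t, c], win, step, 60.0) for c in idx)
            assert flags[t] == expect

    def test_p2p_matches_oracle(self, random_epochs):
        ep = random_epochs
        flags = detect_p2p(ep)
        idx = ep.channel_index(ep.eeg_channels)
        win, step = 100, 50  # 200 ms / 100 ms
        for t in range(ep.n_trials):
            expect = any(oracle_p2p(ep.data[t, c], win, step, 75.0) for c in idx)
            assert flags[t] == expect

    def test_drift_matches_oracle(self, random_epochs):
        ep = random_epochs
        # add slow ramps to some trials so both outcomes occur
        data = ep.data.copy()
        rng = np.random.default_rng(99)
        ramps = rng.uniform(-150, 150, data.shape[0])
        data += ramps[:, None, None] * np.linspace(0, 1, data.shape[2])
        ep2 = _epochs_from_array(data)
        flags = detect_drift(ep2)
        idx = ep2.channel_index(ep2.eeg_channels)
        for t in range(ep2.n_trials):
            expect = any(oracle_drift(ep2.data[t, c].astype(float), 75.0, 0.3) for c in idx)
            assert flags[t] == expect

    def test_gaze_matches_oracle(self):
        rng = np.random.default_rng(7)
        channels = [*CDA_CHANNELS, "VEOG", "HEOG", "GAZE_X", "GAZE_Y"]
        data = np.zeros((40, 12, 550))
        data[:, 10:, :] = 0.3 * rng.standard_normal((40, 2, 550))
        ep = _epochs_from_array(data, channels=channels)
        flags = detect_gaze(ep)
        for t in range(40):
            expect = any(oracle_step(data[t, c], 50, 5, 0.5) for c in (10, 11))
            assert flags[t] == expect


class TestThresholdCases:
    def test_eog_plateau_above_threshold_flagged(self, blank_epochs):
        ep = blank_epochs()
        ep.data[0, ep.channels.index("VEOG"), 200:400] = 60.0
        abs_flags, _ = detect_eog(ep)
        assert abs_flags[0] and not abs_flags[1:].any()

    def test_heog_step_above_threshold_flagged(self, blank_epochs):
        ep = blank_epochs()
        ep.data[1, ep.channels.index("HEOG"), 500:] = 40.0
        _, step_flags = detect_eog(ep)
        assert step_flags[1] and not step_flags[0]

    def test_slow_ramp_not_step_flagged(self, blank_epochs):
        # 100 uV spread over 2200 ms: per-100-ms half-difference stays small
        ep = blank_epochs()
        ramp = np.linspace(0.0, 100.0, ep.n_samples)
        ep.data[0, ep.channels.index("HEOG"), :] = ramp
        _, step_flags = detect_eog(ep)
        assert not step_flags[0]
        assert oracle_step(ramp, 50, 5, 30.0) is False

    def test_gaze_step_threshold(self, blank_epochs):
        channels = [*CDA_CHANNELS, "VEOG", "HEOG", "GAZE_X", "GAZE_Y"]
        ep = blank_epochs(channels=channels)
        ep.data[0, channels.index("GAZE_X"), 600:] = 1.0   # saccade
        ep.data[1, channels.index("GAZE_Y"), 600:] = 0.4   # below threshold
        flags = detect_gaze(ep)
        assert flags[0] and not flags[1]

    def test_gaze_absent_skipped_with_notice(self, blank_epochs):
        ep = blank_epochs()
        with pytest.warns(UserWarning, match="gaze"):
            assert detect_gaze(ep) is None

    def test_pure_ramp_drift_flagged_flat_not(self, blank_epochs):
        ep = blank_epochs()
        ep.data[0, 0, :] = np.linspace(0, 100, ep.n_samples)
        flags = detect_drift(ep)
        assert flags[0] and not flags[1:].any()

    def test_noisy_ramp_below_r2_not_flagged(self, blank_epochs):
        # noise sized so R^2 ~ 0.2 < 0.3 while fitted change > 75
        rng = np.random.default_rng(0)
        ep = blank_epochs()
        n = ep.n_samples
        ramp = np.linspace(0, 100, n)
        ramp_var = ramp.var()
        noise_sd = np.sqrt(ramp_var * 4.0)  # R2 = 1/(1+4) = 0.2
        sig = ramp + rng.normal(0, noise_sd, n)
        ep.data[0, 0, :] = sig
        assert detect_drift(ep)[0] == oracle_drift(sig, 75.0, 0.3) == False

    def test_spike_p2p_flagged(self, blank_epochs):
        ep = blank_epochs()
        ep.data[0, 2, 300:325] = 80.0  # 50-ms 80 uV excursion
        assert detect_p2p(ep)[0]

    def test_full_epoch_ramp_not_p2p_flagged(self, blank_epochs):
        # 60 uV over the whole epoch: per-200-ms excursion ~5.5 uV
        ep = blank_epochs()
        ep.data[:, :, :] = np.linspace(0, 60, ep.n_samples)
        assert not detect_p2p(ep).any()

    def test_abs_step_flatline_detectors(self, blank_epochs):
        ep = blank_epochs(n_trials=4)
        ep.data += 1e-3 * np.random.default_rng(1).standard_normal(ep.data.shape)
        ep.data[0, 1, 400] = 120.0            # absolute voltage
        ep.data[1, 3, 700:] += 70.0           # DC shift
        ep.data[2, 5, :] = 0.0                # flatline channel
        out = detect_abs_and_steps(ep)
        assert out["abs_volt"][0] and not out["abs_volt"][[1, 2, 3]].any()
        assert out["eeg_step"][1] and not out["eeg_step"][[0, 2, 3]].any()
        assert out["flatline"][2] and not out["flatline"][[0, 1, 3]].any()

    def test_missing_ocular_channels_raise(self, blank_epochs):
        ep = blank_epochs(channels=list(CDA_CHANNELS))
        with pytest.raises(ValueError, match="ocular"):
            detect_eog(ep)


class TestRejectAndExclude:
    def test_exclusion_rule_exact_at_30_percent(self, blank_epochs):
        # participant 0: 35% of trials flagged; participant 1: 10%
        n = 40
        ep = blank_epochs(n_trials=n, participants=[0] * 20 + [1] * 20)
        ep.data += 1e-3 * np.random.default_rng(0).standard_normal(ep.data.shape)
        v = ep.channels.index("VEOG")
        for t in range(7):       # 7/20 = 35%
            ep.data[t, v, 100:200] = 80.0
        for t in range(20, 22):  # 2/20 = 10%
            ep.data[t, v, 100:200] = 80.0
        report, kept, participants = reject_and_exclude(ep)
        assert report.excluded_participants == [0]
        assert participants == [1]
        assert kept.n_trials == 18

    def test_rate_exactly_30_percent_is_retained(self, blank_epochs):
        ep = blank_epochs(n_trials=10, participants=[0] * 10)
        ep.data += 1e-3 * np.random.default_rng(1).standard_normal(ep.data.shape)
        v = ep.channels.index("VEOG")
        for t in range(3):  # exactly 30%: rule is strictly greater than
            ep.data[t, v, 100:200] = 80.0
        report, kept, participants = reject_and_exclude(ep)
        assert participants == [0]
        assert kept.n_trials == 7

    def test_bookkeeping_retained_plus_rejected_total(self, blank_epochs):
        ep = blank_epochs(n_trials=30, participants=[0] * 15 + [1] * 15)
        ep.data += 1e-3 * np.random.default_rng(3).standard_normal(ep.data.shape)
        v = ep.channels.index("VEOG")
        for t in (0, 3, 7, 16, 22):  # 3/15 and 2/15 flagged: both retained
            ep.data[t, v, 100:300] = 80.0
        report, kept, participants = reject_and_exclude(ep)
        assert participants == [0, 1]
        assert kept.n_trials + int(report.rejected.sum()) == 30
        assert report.participant_rates.loc[0] == pytest.approx(3 / 15)

    def test_all_excluded_raises(self, blank_epochs):
        ep = blank_epochs(n_trials=4)
        ep.data[:, ep.channels.index("VEOG"), :] = 80.0
        with pytest.raises(ValueError, match="all participants"):
            reject_and_exclude(ep)
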