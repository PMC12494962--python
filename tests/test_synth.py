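"""Synthetic-recording generators: determinism, constraints, round trips."""

import numpy as np
import pytest

from ctcloop.analysis import phase_relation
from ctcloop.behavior import detect_movement_onsets
from ctcloop.synth import (STIM_INTERVALS_MS, gen_lagged_lfp,
                           gen_spike_trains, gen_stim_times, gen_whisker,
                           make_recording)


class TestGenWhisker:
    def test_deterministic(self):
        a, ba = gen_whisker(20_000.0, seed=5)
        b, bb = gen_whisker(20_000.0, seed=5)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(ba, bb)

    def test_zero_rate_flat(self):
        trace, bouts = gen_whisker(10_000.0, bout_rate_hz=0.0, seed=1)
        assert bouts.size == 0
        assert len(detect_movement_onsets(trace)) == 0

    def test_detector_round_trip(self):
        # generated bouts are recovered with high precision and recall
        trace, truth = gen_whisker(120_000.0, bout_rate_hz=0.35,
                                   bout_dur_range_ms=(280.0, 600.0), seed=2)
        assert truth.size >= 15
        found = detect_movement_onsets(trace).onsets
        tol = 30.0
        hits = sum(np.min(np.abs(found - t)) < tol for t in truth
                   if found.size)
        recall = hits / truth.size
        precision = sum(np.min(np.abs(truth - f)) < tol for f in found) / \
            max(found.size, 1)
        assert recall >= 0.9
        assert precision >= 0.9

    def test_infeasible_params(self):
        with pytest.raises(ValueError):
            gen_whisker(10_000.0, bout_rate_hz=2.0,
                        bout_dur_range_ms=(300.0, 600.0))


class TestGenLaggedLfp:
    def test_zero_lag_full_share(self):
        lfp, _ = gen_lagged_lfp(4000.0, fs=1000.0,
                                n_channels={"M1": 2, "CB": 2},
                                lags_ms={"M1": 0.0}, shared_fraction=1.0,
                                snr=50.0, seed=0)
        res = phase_relation(lfp["M1"][0], lfp["CB"][0], fs=1000.0)
        assert abs(res.phase_relation) <= 1.0
        assert res.peak_value > 0.9

    @pytest.mark.parametrize("lag", [-10.0, -2.0, 5.0])
    def test_injected_lag_recovered(self, lag):
        lfp, truth = gen_lagged_lfp(4000.0, fs=1000.0,
                                    n_channels={"M1": 1, "CB": 1},
                                    lags_ms={"M1": lag},
                                    shared_fraction=0.9, snr=4.0, seed=3)
        res = phase_relation(lfp["M1"][0], lfp["CB"][0], fs=1000.0)
        assert res.phase_relation == pytest.approx(lag, abs=1.0)
        assert truth.pair_lags_ms[("pre", "M1")] == lag

    def test_zero_share_uncorrelated(self):
        lfp, _ = gen_lagged_lfp(4000.0, fs=1000.0,
                                n_channels={"M1": 1, "CB": 1},
                                lags_ms={"M1": 0.0}, shared_fraction=0.0,
                                snr=4.0, seed=4)
        res = phase_relation(lfp["M1"][0], lfp["CB"][0], fs=1000.0)
        assert abs(res.peak_value) < 0.2

    def test_epoch_lag_flip(self):
        lfp, _ = gen_lagged_lfp(8000.0, fs=1000.0,
                                n_channels={"M1": 1, "CB": 1},
                                lags_ms={"M1": -5.0},
                                post_lags_ms={"M1": 5.0}, onset_ms=4000.0,
                                shared_fraction=0.95, snr=5.0, seed=5)
        pre = phase_relation(lfp["M1"][0, 1000:3800],
                             lfp["CB"][0, 1000:3800], fs=1000.0)
        post = phase_relation(lfp["M1"][0, 4200:7000],
                              lfp["CB"][0, 4200:7000], fs=1000.0)
        assert pre.phase_relation == pytest.approx(-5.0, abs=1.5)
        assert post.phase_relation == pytest.approx(5.0, abs=1.5)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            gen_lagged_lfp(1000.0, shared_fraction=1.5)
        with pytest.raises(ValueError):
            gen_lagged_lfp(1000.0, lags_ms={"M1": 150.0})


class TestGenSpikeTrains:
    def test_pc_constraints(self):
        ss, cs = gen_spike_trains(60_000.0, seed=0)
        assert ss.kind == "simple" and cs.kind == "complex"
        assert len(ss) > 1000
        # 3 ms simple-spike dead time
        assert np.diff(ss.times).min() >= 3.0
        # >= 8 ms simple-spike pause after every complex spike
        for t_cs in cs.times:
            after = ss.times[(ss.times >= t_cs) & (ss.times < t_cs + 8.0)]
            assert after.size == 0

    def test_rate_modulation_recorded(self, rng):
        driver = np.sin(2 * np.pi * 1.0 * np.arange(30_000) / 1000.0)
        ss, _ = gen_spike_trains(30_000.0, driver=driver,
                                 modulation_gain=0.8, seed=1)
        # spikes should concentrate where the driver is high
        phase = driver[np.clip(ss.times.astype(int), 0, 29_999)]
        assert phase.mean() > 0.1

    def test_unrealizable(self):
        with pytest.raises(ValueError):
            gen_spike_trains(1000.0, base_rate_hz=500.0)


class TestGenStimTimes:
    def test_fixed_interval(self):
        times = gen_stim_times(5, intervals_ms=(1000.0,), seed=0)
        np.testing.assert_allclose(times,
                                   [1000.0, 2000.0, 3000.0, 4000.0, 5000.0])

    def test_uniform_gap_frequencies(self):
        times = gen_stim_times(10_000, seed=1)
        gaps = np.diff(np.concatenate([[0.0], times]))
        counts = np.array([np.sum(gaps == g) for g in STIM_INTERVALS_MS])
        expected = 10_000 / 7.0
        sd = np.sqrt(10_000 * (1 / 7) * (6 / 7))
        assert np.all(np.abs(counts - expected) < 3.0 * sd)

    def test_deterministic_and_errors(self):
        np.testing.assert_array_equal(gen_stim_times(20, seed=9),
                                      gen_stim_times(20, seed=9))
        with pytest.raises(ValueError):
            gen_stim_times(0)
        with pytest.raises(ValueError):
            gen_stim_times(3, intervals_ms=())


def test_make_recording_truth_closure():
    rec = make_recording(T_ms=12_000.0, lfp_fs=1000.0, n_stim=3, seed=7)
    assert rec.lfp["M1"].shape[0] == 16
    assert rec.lfp["S1"].shape[0] == 16
    assert rec.lfp["CB"].shape[0] == 12
    assert rec.whisker.size == 12_000
    assert rec.stim_times_ms.size == 3
    assert ("pre", "M1") in rec.truth.pair_lags_ms
    assert "ss_gain" in rec.truth.modulation
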