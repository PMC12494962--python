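"""Cross-correlation, MI, spike-density and trial-correlation operations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctcloop.analysis import (CrossCorrelogram, SpikeTrain, asymmetry_index,
                              count_cc_peaks, cross_correlogram,
                              lfp_response, mutual_information,
                              phase_relation, shuffle_zscore, spike_density,
                              trial_corr_matrix)


class TestPhaseRelation:
    def test_identity(self, rng):
        x = rng.standard_normal(500)
        res = phase_relation(x, x, fs=1000.0)
        assert res.phase_relation == 0.0
        assert res.peak_value == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("shift", [-10, -5, -2, 2, 5, 10])
    def test_lag_recovery_sign_convention(self, rng, shift):
        # x(t) = y(t + d), d > 0 (cerebral copy earlier) => phase = -d
        s = np.cumsum(rng.standard_normal(3000))
        s -= np.linspace(s[0], s[-1], s.size)  # detrended random walk
        y = s[500:2500]
        x = s[500 + shift:2500 + shift]
        res = phase_relation(x, y, fs=1000.0)
        assert res.phase_relation == pytest.approx(-shift, abs=1.0)

    def test_antisymmetry(self, rng):
        x = rng.standard_normal(800)
        y = np.roll(x, 7) + 0.1 * rng.standard_normal(800)
        a = phase_relation(x, y, fs=1000.0)
        b = phase_relation(y, x, fs=1000.0)
        assert a.phase_relation == pytest.approx(-b.phase_relation)
        assert a.peak_value == pytest.approx(b.peak_value, rel=1e-9)

    def test_zero_variance_flagged(self):
        res = phase_relation(np.ones(300), np.arange(300.0), fs=1000.0)
        assert not res.valid
        assert np.isnan(res.phase_relation)

    def test_tie_breaks_to_smallest_abs_lag(self):
        # a perfectly periodic signal has equal-height peaks at 0, +-T
        x = np.sin(2 * np.pi * 50.0 * np.arange(1000) / 1000.0)
        res = phase_relation(x, x, fs=1000.0, max_lag_ms=45.0)
        assert res.phase_relation == 0.0

    def test_independent_noise_mean_zero(self, rng):
        lags = []
        for _ in range(300):
            res = phase_relation(rng.standard_normal(200),
                                 rng.standard_normal(200), fs=1000.0)
            lags.append(res.phase_relation)
        lags = np.array(lags)
        assert abs(lags.mean()) < 3.0 * lags.std() / np.sqrt(lags.size) + 5.0
        assert np.abs(lags).max() <= 100.0


class TestShuffleZscore:
    def test_coherent_pair_significant(self, rng):
        s = np.convolve(rng.standard_normal(21000), np.ones(20) / 20.0,
                        mode="same")
        x = s + 0.2 * rng.standard_normal(21000)
        y = s + 0.2 * rng.standard_normal(21000)
        z = shuffle_zscore(x, y, fs=1000.0, window_start=5000,
                           window_len=500, rng=1)
        assert z > 2.0

    def test_independent_pair_not_significant(self, rng):
        hits = 0
        n_rep = 40
        for i in range(n_rep):
            x = rng.standard_normal(4000)
            y = rng.standard_normal(4000)
            z = shuffle_zscore(x, y, fs=1000.0, window_start=1000,
                               window_len=200, rng=i)
            hits += z > 2.0
        assert hits <= 6  # ~binomial(40, 0.05) upper range

    def test_too_short_recording(self, rng):
        with pytest.raises(ValueError):
            shuffle_zscore(rng.standard_normal(250),
                           rng.standard_normal(250), fs=1000.0,
                           window_start=0, window_len=200, n_shuffles=100)


class TestCountCcPeaks:
    fs = 25000.0

    def _ccg(self, values):
        lags = (np.arange(len(values)) - len(values) // 2) * 1000.0 / self.fs
        return CrossCorrelogram(lags=lags, values=values, normalized=True)

    def test_single_gaussian_bump(self):
        t = np.arange(-2500, 2501) / self.fs * 1000.0  # +-100 ms
        assert count_cc_peaks(self._ccg(0.5 * np.exp(-0.5 * (t / 15) ** 2))) \
            == 1

    def test_two_bumps(self):
        t = np.arange(-2500, 2501) / self.fs * 1000.0
        v = 0.3 * np.exp(-0.5 * ((t - 20) / 10) ** 2) + \
            0.3 * np.exp(-0.5 * ((t + 20) / 10) ** 2)
        assert count_cc_peaks(self._ccg(v)) == 2

    def test_flat_zero(self):
        assert count_cc_peaks(self._ccg(np.zeros(5001))) == 0


class TestMutualInformation:
    def test_discrete_identity_is_entropy(self, rng):
        a = rng.integers(0, 4, size=5000)
        p = np.bincount(a) / a.size
        h = -(p[p > 0] * np.log2(p[p > 0])).sum()
        assert mutual_information(a, a, mode="disc_disc") == \
            pytest.approx(h, abs=1e-12)

    def test_independent_near_zero(self, rng):
        a = rng.standard_normal(20000)
        b = rng.standard_normal(20000)
        mi = mutual_information(a, b, mode="cont_cont")
        assert 0.0 <= mi < 0.05

    def test_gaussian_closed_form(self, rng):
        # MI of a bivariate Gaussian: -0.5 log2(1 - rho^2)
        n, rho = 100_000, 0.8
        z = rng.standard_normal((2, n))
        a = z[0]
        b = rho * z[0] + np.sqrt(1 - rho ** 2) * z[1]
        mi = mutual_information(a, b, mode="cont_cont")
        assert mi == pytest.approx(-0.5 * np.log2(1 - rho ** 2), abs=0.05)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mutual_information([], [], mode="disc_disc")


class TestSpikeDensity:
    def test_empty_and_single(self):
        t, sdf = spike_density([])
        assert np.all(sdf == 0.0)
        t, sdf = spike_density([100.0])
        assert np.trapezoid(sdf, t) == pytest.approx(1.0, abs=1e-6)
        assert t[np.argmax(sdf)] == pytest.approx(100.0, abs=1.0)

    @given(st.lists(st.floats(min_value=0.0, max_value=5000.0),
                    min_size=1, max_size=120, unique=True))
    @settings(max_examples=30, deadline=None)
    def test_integral_equals_spike_count(self, times):
        times = np.sort(np.asarray(times))
        times = times[np.r_[True, np.diff(times) > 1e-6]]
        _, sdf = spike_density(times)
        assert sdf.sum() * 1.0 == pytest.approx(len(times), abs=1e-6)

    def test_spike_train_container_validation(self):
        with pytest.raises(ValueError):
            SpikeTrain(times=[3.0, 2.0, 5.0])


class TestTrialCorrMatrix:
    def test_diagonal_one_for_identical_units(self, rng):
        amp = rng.uniform(0.5, 2.0, size=(30, 1))
        template = np.exp(-0.5 * ((np.arange(800) - 400) / 50.0) ** 2)
        sdf = amp * template[None, :] + 0.01 * rng.standard_normal((30, 800))
        r = trial_corr_matrix(sdf, sdf)
        assert r.shape == (80, 80)
        assert np.nanmin(np.diag(r)) > 0.99

    def test_lagged_amplitude_ridge(self, rng):
        # B repeats A's trial amplitudes 50 ms later -> ridge at +5 bins
        amp = rng.uniform(0.5, 2.0, size=(40, 1))
        t = np.arange(800)
        bump_a = np.exp(-0.5 * ((t - 300) / 30.0) ** 2)
        bump_b = np.exp(-0.5 * ((t - 350) / 30.0) ** 2)
        noise = 0.02 * rng.standard_normal((2, 40, 800))
        ra = trial_corr_matrix(amp * bump_a + noise[0],
                               amp * bump_b + noise[1])
        i, j = np.unravel_index(np.nanargmax(ra), ra.shape)
        assert j - i == 5

    def test_degenerate_and_min_trials(self, rng):
        flat = np.ones((5, 800))
        r = trial_corr_matrix(flat, flat)
        assert np.isnan(r).all()
        with pytest.raises(ValueError):
            trial_corr_matrix(np.ones((2, 800)), np.ones((2, 800)))


class TestAsymmetryIndex:
    def test_symmetric_matrix_zero(self, rng):
        a = rng.standard_normal((80, 80))
        sym = (a + a.T) / 2.0
        assert asymmetry_index(sym, "pre") == pytest.approx(0.0, abs=1e-12)

    def test_lower_triangular_positive(self):
        m = np.tril(np.ones((80, 80)), k=-1)
        assert asymmetry_index(m, "pre") > 0
        assert asymmetry_index(m, "move") > 0

    def test_ridge_sign_matches_construction(self, rng):
        # A leads B: correlations concentrate below the diagonal
        m = np.zeros((80, 80))
        for k in range(1, 4):
            m += np.diag(np.ones(80 - k), k=-k)
        assert asymmetry_index(m, "move") > 0
        assert asymmetry_index(m.T, "move") < 0


class TestLfpResponse:
    fs = 1000.0

    def _traces(self, step_sign, rng, onset_ms=16.0, n=40):
        t = np.arange(600)
        stim_idx = 300
        edge = 1.0 / (1.0 + np.exp(-(t - stim_idx - onset_ms) / 2.0))
        base = 0.5 * rng.standard_normal((6, 600))
        return 0.5 * rng.standard_normal((n, 600)) + \
            step_sign * edge[None, :], base, stim_idx

    def test_step_onset_detected(self, rng):
        stim, base, idx = self._traces(+1.0, rng)
        res = lfp_response(stim, base, self.fs, idx)
        assert res.significant
        assert 10.0 <= res.onset_ms <= 20.0
        assert res.peak > 0.5

    def test_inverted_step_same_onset_opposite_peak(self, rng):
        stim, base, idx = self._traces(-1.0, rng)
        res = lfp_response(stim, base, self.fs, idx)
        assert res.significant
        assert 10.0 <= res.onset_ms <= 20.0
        assert res.peak < -0.5

    def test_flat_trace_not_significant(self, rng):
        flat = 0.5 * rng.standard_normal((40, 600))
        base = 0.5 * rng.standard_normal((6, 600))
        res = lfp_response(flat, base, self.fs, 300)
        assert not res.significant
        assert res.onset_ms is None


def test_cross_correlogram_container(rng):
    x = rng.standard_normal(400)
    ccg = cross_correlogram(x, np.roll(x, 5), fs=1000.0, max_lag_ms=50.0)
    assert ccg.lags[0] == -50.0 and ccg.lags[-1] == 50.0
    assert np.nanmax(np.abs(ccg.values)) <= 1.0 + 1e-9
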