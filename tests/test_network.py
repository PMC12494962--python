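"""Network simulation: fixed points, determinism, pulses, LFP proxy."""

import numpy as np
import pytest
from dataclasses import replace

from ctcloop.network import (ModelConfig, PulseSpec, TrialProtocol,
                             lfp_proxy, simulate, solve_fixed_point)
from ctcloop.noise import OUProcessSpec
from ctcloop.populations import POPULATION_NAMES, default_populations


def noiseless_config(open_loop=False):
    """All noise off; optionally with the mossy-fiber input to PC cut,
    which opens the loop and makes the noiseless dynamics settle to a
    stable fixed point (the default closed loop settles onto a ~6 Hz
    limit cycle instead)."""
    pops = {n: replace(p, sigma=0.0)
            for n, p in default_populations().items()}
    cfg = ModelConfig.default()
    ous = tuple(replace(o, sigma_x=0.0) for o in cfg.ou_processes)
    cfg = replace(cfg, populations=pops, ou_processes=ous)
    if open_loop:
        cfg = cfg.with_descending(GrC__PC=0.0)
    return cfg


def independent_fixed_point(cfg):
    """Oracle: solve r = transfer(I(r)) with scipy's root finder and a
    from-scratch transfer implementation."""
    from scipy.optimize import root

    pops = [cfg.populations[n] for n in POPULATION_NAMES]
    W = cfg.connectome.matrix(POPULATION_NAMES)
    I_bg = np.array([p.I_bg for p in pops])

    def transfer(I):
        out = np.empty_like(I)
        for j, p in enumerate(pops):
            u = I[j] + p.theta  # theta = background current
            t = p.beta * u
            if abs(t) < 1e-9:
                g = 1.0 / p.beta
            elif t < -500:
                g = 0.0
            else:
                g = u / (1.0 - np.exp(-t))
            out[j] = p.gain_A * g
        return out

    sol = root(lambda r: transfer(I_bg + W @ r) - r,
               np.full(len(pops), 5.0), method="hybr", tol=1e-13)
    assert sol.success
    return sol.x


class TestFixedPoint:
    def test_long_run_matches_independent_root(self):
        cfg = noiseless_config(open_loop=True)
        fp_pkg = solve_fixed_point(cfg)
        traces = simulate(cfg, TrialProtocol.rest(t_stop=6000.0),
                          n_trials=1, seed=0, record_dtype=np.float64)
        end = traces.rates[0, -1, :]
        oracle = independent_fixed_point(cfg)
        np.testing.assert_allclose(end, oracle, atol=1e-6)
        np.testing.assert_allclose(fp_pkg, oracle, atol=1e-6)

    def test_step_size_convergence(self):
        # halving dt changes noiseless trajectories by < 1e-3 relative
        cfg = noiseless_config(open_loop=True)
        proto = TrialProtocol.rest(t_stop=300.0)
        a = simulate(cfg, proto, seed=0, record_dtype=np.float64)
        b = simulate(replace(cfg, dt=0.05), proto, seed=0,
                     record_dtype=np.float64)
        end_a = a.rates[0, -1, :]
        end_b = b.rates[0, -1, :]
        rel = np.abs(end_a - end_b) / np.maximum(np.abs(end_b), 1.0)
        assert rel.max() < 1e-3

    def test_dt_guard(self):
        with pytest.raises(ValueError):
            simulate(replace(ModelConfig.default(), dt=1.0),
                     TrialProtocol.rest(t_stop=10.0), seed=0)


class TestSimulate:
    def test_deterministic_and_nonnegative(self):
        cfg = ModelConfig.default()
        proto = TrialProtocol(t_start=-300.0, t_stop=100.0)
        a = simulate(cfg, proto, n_trials=3, seed=42)
        b = simulate(cfg, proto, n_trials=3, seed=42)
        np.testing.assert_array_equal(a.rates, b.rates)
        assert np.all(np.isfinite(a.rates))
        assert np.all(a.rates >= 0.0)

    def test_epoch_labels(self):
        tr = simulate(ModelConfig.default(),
                      TrialProtocol(t_start=-300.0, t_stop=300.0),
                      n_trials=1, seed=0)
        assert set(tr.epoch_labels) == {"pre_movement", "movement", "rest"}
        assert tr.epoch_labels[0] == "pre_movement"
        assert tr.epoch_labels[-1] == "rest"
        mv = tr.epoch_slice("movement")
        assert tr.times[mv.start] == pytest.approx(0.0)

    def test_ramp_only_during_pre_movement(self):
        # with only the preparatory ramp active, M1 deep variance is far
        # larger before movement onset than after
        cfg = ModelConfig.default()
        pops = {n: replace(p, sigma=0.0)
                for n, p in default_populations().items()}
        ous = tuple(o if o.name == "preparatory_ramp"
                    else replace(o, sigma_x=0.0) for o in cfg.ou_processes)
        cfg = replace(cfg, populations=pops, ou_processes=ous)
        tr = simulate(cfg, n_trials=20, seed=5)
        pre = tr.get("M1deep_E")[:, tr.window_slice(-400.0, 0.0)].std()
        post = tr.get("M1deep_E")[:, tr.window_slice(200.0, 400.0)].std()
        assert pre > 3.0 * post


class TestPulses:
    def test_zero_amplitude_is_identity(self):
        cfg = ModelConfig.default()
        proto = TrialProtocol(t_start=-300.0, t_stop=100.0)
        pulse = PulseSpec("PC", 0.0, onset=-100.0, duration=100.0)
        a = simulate(cfg, proto, n_trials=2, seed=9)
        b = simulate(cfg, proto, n_trials=2, seed=9, pulses=(pulse,))
        np.testing.assert_array_equal(a.rates, b.rates)

    def test_vl_inhibition_lowers_vl(self):
        # compare the early pulse window before loop feedback reshapes
        # the (oscillatory) trajectories
        cfg = noiseless_config()
        proto = TrialProtocol.rest(t_stop=900.0)
        pulse = PulseSpec("VL", -0.6, onset=500.0, duration=200.0)
        ctrl = simulate(cfg, proto, seed=0)
        pert = simulate(cfg, proto, seed=0, pulses=(pulse,))
        sl = ctrl.window_slice(505.0, 545.0)
        assert pert.get("VL")[0, sl].mean() < ctrl.get("VL")[0, sl].mean()

    def test_pc_excitation_lowers_cn(self):
        # PC -> CN is inhibitory: driving PC suppresses the nuclei
        cfg = noiseless_config()
        proto = TrialProtocol.rest(t_stop=900.0)
        pulse = PulseSpec("PC", +0.6, onset=500.0, duration=200.0)
        ctrl = simulate(cfg, proto, seed=0)
        pert = simulate(cfg, proto, seed=0, pulses=(pulse,))
        sl = ctrl.window_slice(505.0, 545.0)
        assert pert.get("CN")[0, sl].mean() < ctrl.get("CN")[0, sl].mean()

    def test_pulse_window_and_target_validated(self):
        with pytest.raises(ValueError):
            PulseSpec("nonsense", 0.6, 0.0, 100.0)
        with pytest.raises(ValueError):
            simulate(ModelConfig.default(), TrialProtocol.rest(500.0),
                     seed=0,
                     pulses=(PulseSpec("PC", 0.6, 450.0, 100.0),))


class TestLfpProxy:
    def test_weighting(self):
        # superficial:deep = 20:80
        assert lfp_proxy(1.0, 0.0) == pytest.approx(0.2)
        assert lfp_proxy(0.0, 1.0) == pytest.approx(0.8)
        assert lfp_proxy(3.0, 3.0) == pytest.approx(3.0)

    def test_traces_lfp(self):
        tr = simulate(ModelConfig.default(), TrialProtocol.rest(100.0),
                      n_trials=1, seed=0)
        expected = 0.2 * tr.get("M1sup_E") + 0.8 * tr.get("M1deep_E")
        np.testing.assert_allclose(tr.lfp("M1"), expected, rtol=1e-6)


def test_config_yaml_round_trip(tmp_path):
    cfg = ModelConfig.default()
    path = tmp_path / "model.yaml"
    cfg.to_yaml(path)
    back = ModelConfig.from_yaml(path)
    assert back.to_dict() == cfg.to_dict()
    # round-tripped config simulates identically
    a = simulate(cfg, TrialProtocol.rest(50.0), seed=1)
    b = simulate(back, TrialProtocol.rest(50.0), seed=1)
    np.testing.assert_array_equal(a.rates, b.rates)
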