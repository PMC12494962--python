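"""The four modeled optogenetic/stage experiments.

Each experiment is an ensemble of independent simulations (default 10,
each with its own noise seed and 200 trials).  Per simulation, phase
relations and zero-lag Pearson correlations between the cortical LFP
proxies (M1, S1) and the Purkinje-cell rate are averaged over trials per
epoch; ensemble-level paired contrasts summarise the stage or
perturbation effects.

Perturbation ensembles are paired by construction: the control and
perturbed arms of one simulation share the seed, hence every noise draw;
only the pulse current differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import _xcorr_matrix
from .network import (ModelConfig, PulseSpec, RateTraces, TrialProtocol,
                      simulate)
from .stats import ContrastResult, paired_contrast

__all__ = [
    "ExperimentSpec", "ExperimentResult",
    "run_baseline_ensemble", "run_perturbation_ensemble",
    "run_pc_stimulation",
]

EPOCH_WINDOWS = {"pre": (-200.0, 0.0), "move": (0.0, 200.0)}
PAIRS = ("M1", "S1")

#: pulse magnitude of the simulated optogenetic currents
PULSE_AMPLITUDE = 0.6
#: perturbation pulses last 500 ms with the analysed 200 ms epoch centred
PERTURBATION_PULSE_MS = 500.0
#: PC stimulation pulses last 100 ms
PC_PULSE_MS = 100.0


@dataclass
class ExperimentSpec:
    """Configuration of one ensemble experiment."""

    name: str
    n_sims: int = 10
    trials_per_sim: int = 200
    seed: int = 0
    config: ModelConfig = field(default_factory=ModelConfig.default)

    def __post_init__(self):
        if self.n_sims < 2:
            raise ValueError("need at least 2 simulations")

    def sim_seeds(self):
        return np.random.SeedSequence(self.seed).spawn(self.n_sims)


@dataclass
class ExperimentResult:
    """Per-simulation measures plus ensemble contrasts."""

    name: str
    per_sim: pd.DataFrame
    contrasts: dict[str, ContrastResult] = field(default_factory=dict)
    excluded_trials: int = 0

    def sim_values(self, column: str, **filters) -> np.ndarray:
        df = self.per_sim
        for key, val in filters.items():
            df = df[df[key] == val]
        return df.sort_values("sim")[column].to_numpy()


def _epoch_measures(traces: RateTraces, condition: str):
    """Trial-averaged phase relation, peak correlation and Pearson R per
    (epoch, pair) for one simulation.  Trials with degenerate windows are
    excluded and counted."""
    rows = []
    n_bad = 0
    pc = traces.get("PC").astype(float)
    L = int(round(100.0 * traces.fs / 1000.0))
    for epoch, (t0, t1) in EPOCH_WINDOWS.items():
        sl = traces.window_slice(t0, t1)
        Y = pc[:, sl]
        for area in PAIRS:
            X = traces.lfp(area)[:, sl].astype(float)
            vals, norm = _xcorr_matrix(X, Y, L, normalized=True)
            ok = norm > 0
            n_bad += int((~ok).sum())
            peaks = np.nanmax(vals[ok], axis=1)
            lags = (np.nanargmax(vals[ok], axis=1) - L) * 1000.0 / traces.fs
            r0 = vals[ok][:, L]
            rows.append(dict(condition=condition, epoch=epoch, pair=area,
                             phase_ms=float(np.mean(lags)),
                             peak_corr=float(np.mean(peaks)),
                             pearson_r=float(np.mean(r0)),
                             n_trials=int(ok.sum())))
    return rows, n_bad


def _check_nonconstant(traces: RateTraces):
    sl = traces.window_slice(*EPOCH_WINDOWS["move"])
    pc = traces.get("PC")[:, sl]
    trial_var = pc.std(axis=0).max() if traces.n_trials > 1 else pc.std()
    # tolerance, not exact zero: round-off seeds microscopic trial-to-trial
    # differences even in fully deterministic runs
    if pc.std() < 1e-3 or traces.lfp("M1")[:, sl].std() < 1e-3 or \
            trial_var < 1e-3:
        raise ValueError(
            "constant signals across trials (all noise off?): "
            "correlations degenerate")


def run_baseline_ensemble(spec: ExperimentSpec | None = None,
                          **kw) -> ExperimentResult:
    """Baseline stage comparison: phase relations and correlations of the
    M1/S1 LFP proxies with PC activity in the pre-movement versus movement
    epochs, over ``n_sims`` independent simulations.

    Contrasts (paired over simulations): pre vs movement phase per pair,
    M1 vs S1 Pearson R per epoch, and S1 R pre vs movement.
    """
    spec = spec or ExperimentSpec(name="baseline", **kw)
    rows, n_bad = [], 0
    for i, seed in enumerate(spec.sim_seeds()):
        traces = simulate(spec.config, TrialProtocol.stage(),
                          n_trials=spec.trials_per_sim, seed=seed)
        _check_nonconstant(traces)
        sim_rows, bad = _epoch_measures(traces, "control")
        for row in sim_rows:
            row["sim"] = i
        rows.extend(sim_rows)
        n_bad += bad
    df = pd.DataFrame(rows)
    res = ExperimentResult(name=spec.name, per_sim=df,
                           excluded_trials=n_bad)
    for area in PAIRS:
        res.contrasts[f"phase_pre_vs_move_{area}"] = paired_contrast(
            res.sim_values("phase_ms", epoch="pre", pair=area),
            res.sim_values("phase_ms", epoch="move", pair=area))
    for epoch in EPOCH_WINDOWS:
        res.contrasts[f"pearson_M1_vs_S1_{epoch}"] = paired_contrast(
            res.sim_values("pearson_r", epoch=epoch, pair="M1"),
            res.sim_values("pearson_r", epoch=epoch, pair="S1"))
    res.contrasts["pearson_S1_pre_vs_move"] = paired_contrast(
        res.sim_values("pearson_r", epoch="pre", pair="S1"),
        res.sim_values("pearson_r", epoch="move", pair="S1"), sided=1,
        direction="less")
    return res


def _perturbation_pulses(target: str, amplitude: float):
    """Two pulse schedules, each centring the analysed epoch in a 500 ms
    pulse: one covering the pre-movement epoch, one the movement epoch."""
    half_extra = (PERTURBATION_PULSE_MS - 200.0) / 2.0
    return {
        "pre": PulseSpec(target=target, amplitude=amplitude,
                         onset=-200.0 - half_extra,
                         duration=PERTURBATION_PULSE_MS),
        "move": PulseSpec(target=target, amplitude=amplitude,
                          onset=-half_extra,
                          duration=PERTURBATION_PULSE_MS),
    }


def run_perturbation_ensemble(target: str,
                              spec: ExperimentSpec | None = None,
                              amplitude: float = -PULSE_AMPLITUDE,
                              **kw) -> ExperimentResult:
    """Paired control-vs-perturbation ensemble (PN or VL inhibition).

    For each simulation seed, three runs share every noise draw: a control
    run, a run with the 500 ms pulse covering the pre-movement epoch, and
    one covering the movement epoch.  The perturbed phase relation of each
    epoch is taken from the run whose pulse covers it.

    Contrasts: control vs perturbed phase per epoch and pair (paired over
    simulations, two-sided).
    """
    if target not in ("PN", "VL"):
        raise ValueError("perturbation target must be PN or VL")
    spec = spec or ExperimentSpec(name=f"{target.lower()}_inhibition", **kw)
    pulses = _perturbation_pulses(target, amplitude)
    rows, n_bad = [], 0
    for i, seed in enumerate(spec.sim_seeds()):
        for condition, pulse in [("control", None),
                                 ("perturbed_pre", pulses["pre"]),
                                 ("perturbed_move", pulses["move"])]:
            # a SeedSequence is stateless: re-seeding from it gives the
            # identical stream, so all three arms share every noise draw
            rng = np.random.default_rng(seed)
            traces = simulate(spec.config, TrialProtocol.stage(),
                              n_trials=spec.trials_per_sim, seed=rng,
                              pulses=() if pulse is None else (pulse,))
            sim_rows, bad = _epoch_measures(traces, condition)
            for row in sim_rows:
                row["sim"] = i
            rows.extend(sim_rows)
            n_bad += bad
    df = pd.DataFrame(rows)
    # keep only the epoch each perturbed run is about
    keep = (df["condition"] == "control") | \
        ((df["condition"] == "perturbed_pre") & (df["epoch"] == "pre")) | \
        ((df["condition"] == "perturbed_move") & (df["epoch"] == "move"))
    df = df[keep].replace({"condition": {"perturbed_pre": "perturbed",
                                         "perturbed_move": "perturbed"}})
    res = ExperimentResult(name=spec.name, per_sim=df,
                           excluded_trials=n_bad)
    for epoch in EPOCH_WINDOWS:
        for area in PAIRS:
            a = res.sim_values("phase_ms", epoch=epoch, pair=area,
                               condition="control")
            b = res.sim_values("phase_ms", epoch=epoch, pair=area,
                               condition="perturbed")
            try:
                res.contrasts[f"phase_{epoch}_{area}"] = paired_contrast(a, b)
            except ValueError:
                # a null perturbation leaves the paired arms identical
                res.contrasts[f"phase_{epoch}_{area}"] = None
    return res


def run_pc_stimulation(spec: ExperimentSpec | None = None,
                       amplitude: float = PULSE_AMPLITUDE,
                       duration: float = PC_PULSE_MS,
                       n_pulses: int = 15,
                       interval_ms: float = 2000.0) -> ExperimentResult:
    """Purkinje-cell stimulation: peak cortical LFP responses.

    Each of ``n_sims`` repetitions simulates a stationary run carrying a
    train of +0.6 current pulses to PC (100 ms each, 2 s apart, matching
    the experimental photostimulation protocol).  Per repetition and
    area, the stimulus-locked average LFP is formed and its response is
    the peak absolute deviation, within 100 ms of pulse onset, from the
    mean of the 200 ms pre-pulse baseline.  (Averaging over the train is
    required because single-pulse responses are buried in the loop's
    ongoing ~6 Hz fluctuations.)  Contrast: paired M1 vs S1 peak.
    """
    if spec is None:
        spec = ExperimentSpec(name="pc_stimulation", n_sims=10)
    onsets = 500.0 + interval_ms * np.arange(n_pulses)
    protocol = TrialProtocol.rest(t_stop=onsets[-1] + 400.0)
    pulses = tuple(PulseSpec(target="PC", amplitude=amplitude, onset=o,
                             duration=duration) for o in onsets)
    rows = []
    for i, seed in enumerate(spec.sim_seeds()):
        traces = simulate(spec.config, protocol, n_trials=1, seed=seed,
                          pulses=pulses)
        n_pre = int(round(200.0 / traces.dt))
        n_post = int(round(100.0 / traces.dt))
        for area in PAIRS:
            lfp = traces.lfp(area)[0].astype(float)
            segs = [lfp[int(round(o / traces.dt)) - n_pre:
                        int(round(o / traces.dt)) + n_post] for o in onsets]
            mean_trace = np.mean(segs, axis=0)
            baseline = mean_trace[:n_pre].mean()
            peak = float(np.max(np.abs(mean_trace[n_pre:] - baseline)))
            rows.append(dict(sim=i, epoch="stimulus", pair=area,
                             condition="stimulated", peak_response=peak))
    df = pd.DataFrame(rows)
    res = ExperimentResult(name=spec.name, per_sim=df)
    res.contrasts["peak_M1_vs_S1"] = paired_contrast(
        res.sim_values("peak_response", pair="M1"),
        res.sim_values("peak_response", pair="S1"))
    return res
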