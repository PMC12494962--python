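"""Stochastic firing-rate simulation of the full loop.

Each population obeys ``tau dr/dt = -r + transfer(I) + sqrt(tau) sigma xi(t)``
(the noise term only for cortical populations), discretised by
Euler-Maruyama with ``dt = 0.1 ms``::

    r <- max(0, r + (dt/tau) * (-r + transfer(I)) + sigma*sqrt(dt/tau)*N(0,1))

The input current of a population assembles its constant background
``I_bg``, the weighted rates of its presynaptic populations, any OU input
processes targeting it, and any active stimulation pulses.  Subcortical
populations additionally carry their ``theta`` background current inside the
transfer: ``rate = A * g_beta(I + theta)`` with the smooth rectifier ``g``
(see :mod:`ctcloop.transfer` for why ``theta`` is additive).

Trials are simulated as independent batch members sharing the parameter set
but not the noise; a trial follows the stage protocol (default: t in
[-600, 400) ms around movement onset at t=0, preparatory ramp on for t < 0,
analysis epochs [-200, 0) and [0, 200)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .connectome import Connectome, default_connectome
from .noise import OUProcessSpec, default_ou_processes
from .populations import POPULATION_NAMES, PopulationSpec, default_populations
from .transfer import rectifier, subcortical_transfer

__all__ = [
    "PulseSpec", "TrialProtocol", "ModelConfig", "RateTraces",
    "simulate", "network_step", "lfp_proxy", "solve_fixed_point",
]

#: layer weighting of the model LFP: superficial:deep = 20:80
LFP_SUP_WEIGHT = 0.2
LFP_DEEP_WEIGHT = 0.8


def lfp_proxy(sup_rate, deep_rate):
    """Model LFP of a cortical area: ``0.2*r_supE + 0.8*r_deepE``.

    The 20:80 superficial-to-deep weighting reflects the dominant
    contribution of large layer-5/6 pyramidal neurons to the field
    potential.
    """
    return LFP_SUP_WEIGHT * np.asarray(sup_rate) + \
        LFP_DEEP_WEIGHT * np.asarray(deep_rate)


@dataclass(frozen=True)
class PulseSpec:
    """A simulated optogenetic current pulse.

    Negative amplitude models inhibition (PN, VL protocols), positive
    models excitation (PC protocol); magnitude 0.6 in the replication
    protocols, duration 100, 200 or 500 ms.
    """

    target: str
    amplitude: float
    onset: float
    duration: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")
        if self.target not in POPULATION_NAMES:
            raise ValueError(f"unknown pulse target {self.target!r}")

    def active(self, t: float) -> bool:
        return self.onset <= t < self.onset + self.duration


@dataclass(frozen=True)
class TrialProtocol:
    """Timing and stage structure of one simulated trial.

    ``epochs`` is a tuple of ``(start, stop, label)``; times outside every
    window get the ``fill`` label.
    """

    t_start: float = -600.0
    t_stop: float = 400.0
    epochs: tuple = ((-600.0, 0.0, "pre_movement"), (0.0, 200.0, "movement"))
    fill: str = "rest"

    def labels(self, times: np.ndarray) -> np.ndarray:
        lab = np.full(times.shape, self.fill, dtype=object)
        for start, stop, name in self.epochs:
            lab[(times >= start) & (times < stop)] = name
        return lab.astype(str)

    @classmethod
    def stage(cls) -> "TrialProtocol":
        """The default movement-onset protocol."""
        return cls()

    @classmethod
    def rest(cls, t_stop: float = 800.0) -> "TrialProtocol":
        """A stationary protocol with the ramp never active."""
        return cls(t_start=0.0, t_stop=t_stop, epochs=())


@dataclass
class ModelConfig:
    """Declarative description of the model: populations, weights, inputs."""

    populations: dict = field(default_factory=default_populations)
    connectome: Connectome = field(default_factory=default_connectome)
    ou_processes: tuple = field(default_factory=default_ou_processes)
    dt: float = 0.1
    subcortical_form: str = "shifted"
    #: how OU processes couple to their targets: "rate" adds them to the
    #: rate equation like the white-noise term (default), "current" adds
    #: them to the input current inside the transfer function
    ou_coupling: str = "rate"

    @classmethod
    def default(cls) -> "ModelConfig":
        return cls()

    def with_descending(self, **weights) -> "ModelConfig":
        return replace(self,
                       connectome=self.connectome.replace_descending(**weights))

    # -- declarative text round trip -------------------------------------
    def to_dict(self) -> dict:
        return {
            "dt": self.dt,
            "subcortical_form": self.subcortical_form,
            "ou_coupling": self.ou_coupling,
            "populations": {
                n: {k: getattr(p, k) for k in
                    ("tau", "sigma", "beta", "gain_A", "theta", "I_bg")}
                for n, p in self.populations.items()},
            "connectome": {f"{s}->{t}": w for (s, t), w
                           in self.connectome.weights.items()},
            "descending": {f"{s}->{t}": w for (s, t), w
                           in self.connectome.descending_weights.items()},
            "ou_processes": [
                {"name": o.name, "tau_x": o.tau_x, "sigma_x": o.sigma_x,
                 "targets": list(o.targets),
                 "active_epochs": (None if o.active_epochs is None
                                   else list(o.active_epochs)),
                 "target_delays": (None if o.target_delays is None
                                   else list(o.target_delays)),
                 "target_weights": (None if o.target_weights is None
                                    else list(o.target_weights))}
                for o in self.ou_processes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        pops = {n: PopulationSpec(name=n, **p)
                for n, p in d["populations"].items()}

        def _edges(key):
            out = {}
            for edge, w in d[key].items():
                src, tgt = edge.split("->")
                out[(src, tgt)] = float(w)
            return out

        conn = Connectome(weights=_edges("connectome"),
                          descending_weights=_edges("descending"))
        ous = tuple(
            OUProcessSpec(name=o["name"], tau_x=o["tau_x"],
                          sigma_x=o["sigma_x"], targets=tuple(o["targets"]),
                          active_epochs=(None if o["active_epochs"] is None
                                         else tuple(o["active_epochs"])),
                          target_delays=(None
                                         if o.get("target_delays") is None
                                         else tuple(o["target_delays"])),
                          target_weights=(None
                                          if o.get("target_weights") is None
                                          else tuple(o["target_weights"])))
            for o in d["ou_processes"])
        return cls(populations=pops, connectome=conn, ou_processes=ous,
                   dt=float(d["dt"]),
                   subcortical_form=d.get("subcortical_form", "shifted"),
                   ou_coupling=d.get("ou_coupling", "rate"))

    def to_yaml(self, path):
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class _Params:
    """Vectorised parameter bundle in canonical population order."""

    def __init__(self, config: ModelConfig):
        pops = [config.populations[n] for n in POPULATION_NAMES]
        self.names = POPULATION_NAMES
        self.tau = np.array([p.tau for p in pops])
        self.sigma = np.array([p.sigma for p in pops])
        self.I_bg = np.array([p.I_bg for p in pops])
        self.A = np.array([p.gain_A for p in pops])
        self.beta = np.array([p.beta for p in pops])
        self.theta = np.array([p.theta for p in pops])
        self.cortical = np.array([p.is_cortical for p in pops])
        self.W = config.connectome.matrix(POPULATION_NAMES)
        self.form = config.subcortical_form
        self.ou_coupling = config.ou_coupling
        if self.ou_coupling not in ("rate", "current"):
            raise ValueError(f"unknown ou_coupling {config.ou_coupling!r}")
        self.dt = config.dt
        if config.dt > self.tau.min() / 10.0:
            raise ValueError(
                f"dt={config.dt} exceeds min(tau)/10={self.tau.min() / 10.0}")
        self.drift = config.dt / self.tau
        self.noise_amp = self.sigma * np.sqrt(config.dt / self.tau)

    def transfer(self, I: np.ndarray) -> np.ndarray:
        """Steady-state rate for input current ``I`` (per population)."""
        if self.form == "shifted":
            # theta acts as additive background: rate = A * g_beta(I + theta)
            return self.A * _rect_rows(I + self.theta, self.beta)
        # literal printed form (non-viable working point; kept selectable)
        out = np.empty_like(I)
        for j in range(len(self.names)):
            out[..., j] = subcortical_transfer(
                I[..., j], self.A[j], self.beta[j], self.theta[j],
                form="printed") if not self.cortical[j] else \
                rectifier(I[..., j], self.beta[j])
        return out


def _rect_rows(u: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """rectifier() with per-column beta, vectorised over leading axes."""
    t = beta * u
    tc = np.clip(t, -30.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        main = u / (-np.expm1(-tc))
    series = (1.0 + t / 2.0 + t * t / 12.0) / beta
    asym = -u * np.exp(np.clip(t, None, 0.0))
    out = np.where(np.abs(t) < 1e-4, series, main)
    return np.where(t < -30.0, asym, out)


@dataclass
class RateTraces:
    """Time-indexed firing rates of all populations for a batch of trials.

    ``rates`` has shape ``(n_trials, n_times, n_populations)`` in the
    canonical :data:`~ctcloop.populations.POPULATION_NAMES` order.
    """

    dt: float
    times: np.ndarray
    rates: np.ndarray
    epoch_labels: np.ndarray
    seed: object
    names: tuple = POPULATION_NAMES

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.dt

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    def get(self, name: str) -> np.ndarray:
        """Rate series of one population, shape ``(n_trials, n_times)``."""
        return self.rates[:, :, self.names.index(name)]

    def lfp(self, area: str) -> np.ndarray:
        """Model LFP of ``area`` ('M1' or 'S1'), layer-weighted 20:80."""
        return lfp_proxy(self.get(f"{area}sup_E"), self.get(f"{area}deep_E"))

    def epoch_slice(self, label: str) -> slice:
        """Contiguous sample slice carrying ``label``."""
        idx = np.flatnonzero(self.epoch_labels == label)
        if idx.size == 0:
            raise KeyError(f"no samples labelled {label!r}")
        return slice(idx[0], idx[-1] + 1)

    def window_slice(self, t0: float, t1: float) -> slice:
        """Sample slice for times in ``[t0, t1)``."""
        idx = np.flatnonzero((self.times >= t0) & (self.times < t1))
        return slice(idx[0], idx[-1] + 1)


def network_step(r, I, params: _Params, rng=None, noise=None):
    """One Euler-Maruyama update given fully assembled input currents.

    ``r`` and ``I`` have shape ``(..., n_populations)``.  Pass either a
    Generator (``rng``) or a pre-drawn standard-normal array (``noise``);
    with neither, the update is deterministic.
    """
    target = params.transfer(I)
    r_new = r + params.drift * (target - r)
    if noise is None and rng is not None:
        noise = rng.standard_normal(np.shape(r))
    if noise is not None:
        r_new = r_new + params.noise_amp * noise
    return np.maximum(r_new, 0.0)


def solve_fixed_point(config: ModelConfig, pulses=(), ou_values=None,
                      damping: float = 0.05, tol: float = 1e-12,
                      max_iter: int = 200_000,
                      prefer_quiet: bool = True) -> np.ndarray:
    """Noise-free fixed point ``r* = transfer(I(r*))`` by damped iteration.

    ``ou_values`` optionally maps OU process names to frozen values that are
    added to their targets' currents; ``pulses`` contribute their amplitude
    (treated as tonically active).  Used to initialise simulations; an
    independent root-finder should be preferred as a cross-check oracle.

    The loop can be bistable: besides the state in which the cerebellar
    nuclei are pinned at their threshold by Purkinje inhibition, a second
    state can exist in which tonic Purkinje firing silences CN (and hence
    VL).  With ``prefer_quiet`` (default) the CN-silent branch is returned
    whenever it exists -- it is the operating point of the default model.
    """
    params = _Params(config)
    idx = {n: i for i, n in enumerate(POPULATION_NAMES)}
    I_extra = np.zeros(len(POPULATION_NAMES))
    rate_extra = np.zeros(len(POPULATION_NAMES))
    for p in pulses:
        I_extra[idx[p.target]] += p.amplitude
    if ou_values:
        for spec in config.ou_processes:
            if spec.name in ou_values:
                weights = spec.target_weights or (1.0,) * len(spec.targets)
                for t, w in zip(spec.targets, weights):
                    if params.ou_coupling == "current":
                        I_extra[idx[t]] += w * ou_values[spec.name]
                    else:
                        rate_extra[idx[t]] += w * ou_values[spec.name]
    from scipy.optimize import root

    def residual(v):
        return params.transfer(params.I_bg + params.W @ v + I_extra) + \
            rate_extra - v

    def damped_from(r):
        for _ in range(max_iter):
            I = params.I_bg + params.W @ r + I_extra
            r_new = (1.0 - damping) * r + \
                damping * (params.transfer(I) + rate_extra)
            if np.max(np.abs(r_new - r)) < \
                    tol * max(1.0, np.max(np.abs(r_new))):
                return np.maximum(r_new, 0.0)
            r = r_new
        # heavily damped iteration can cycle near rectification corners;
        # fall back to a root finder seeded with the last iterate
        sol = root(residual, r, method="hybr", tol=1e-13)
        if sol.success and np.max(np.abs(residual(sol.x))) < 1e-8:
            return np.maximum(sol.x, 0.0)
        raise RuntimeError("fixed-point iteration did not converge")

    fp = damped_from(np.zeros(len(POPULATION_NAMES)))
    if not prefer_quiet:
        return fp
    i_pc = POPULATION_NAMES.index("PC")
    i_cn = POPULATION_NAMES.index("CN")
    theta_cn = config.populations["CN"].theta
    if fp[i_pc] > theta_cn and fp[i_cn] < 0.5:
        return fp
    # look for the CN-silent branch from a high-PC seed
    seed_state = fp.copy()
    seed_state[i_pc] = max(3.0 * theta_cn, 2.0 * fp[i_pc])
    for name in ("CN", "VL", "ZI"):
        seed_state[POPULATION_NAMES.index(name)] = 0.0
    sol = root(residual, seed_state, method="hybr", tol=1e-13)
    if sol.success and np.max(np.abs(residual(sol.x))) < 1e-8 \
            and np.all(sol.x > -1e-9) and sol.x[i_pc] > theta_cn:
        return np.maximum(sol.x, 0.0)
    return fp


def simulate(config: ModelConfig, protocol: TrialProtocol | None = None,
             n_trials: int = 1, seed=0, pulses=(),
             record_dtype=np.float32) -> RateTraces:
    """Simulate a batch of independent trials of the full network.

    Parameters
    ----------
    config : ModelConfig
    protocol : TrialProtocol
        Trial timing / stage structure (default: the movement-onset stage
        protocol).
    n_trials : int
        Independent noise realisations simulated in parallel.
    seed : int or numpy SeedSequence/Generator
        All randomness (rate noise and OU paths) derives from this seed;
        identical ``(config, protocol, n_trials, seed)`` give bit-identical
        output.
    pulses : sequence of PulseSpec
        Stimulation currents; windows must lie within the simulated span.

    Returns
    -------
    RateTraces
    """
    if protocol is None:
        protocol = TrialProtocol.stage()
    params = _Params(config)
    dt = params.dt
    n_pop = len(POPULATION_NAMES)
    idx = {n: i for i, n in enumerate(POPULATION_NAMES)}

    for p in pulses:
        if p.onset < protocol.t_start or \
                p.onset + p.duration > protocol.t_stop:
            raise ValueError(
                f"pulse on {p.target} [{p.onset}, {p.onset + p.duration}) "
                f"outside simulated span "
                f"[{protocol.t_start}, {protocol.t_stop})")

    n_steps = int(round((protocol.t_stop - protocol.t_start) / dt))
    times = protocol.t_start + dt * np.arange(n_steps)
    labels = protocol.labels(times)

    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    # OU bookkeeping: per process -> target rows grouped by conduction
    # delay, activity per step
    ou_specs = list(config.ou_processes)
    n_ou = len(ou_specs)
    ou_active = np.ones((n_ou, n_steps), dtype=bool)
    ou_a = np.array([dt / s.tau_x for s in ou_specs])
    ou_amp = np.array([s.sigma_x * np.sqrt(dt / s.tau_x) for s in ou_specs])
    # entries: (process j, delay in steps, indicator row over populations)
    ou_entries: list = []
    for j, s in enumerate(ou_specs):
        delays = s.target_delays or (0.0,) * len(s.targets)
        weights = s.target_weights or (1.0,) * len(s.targets)
        by_delay: dict[int, np.ndarray] = {}
        for t, d, w in zip(s.targets, delays, weights):
            d_steps = int(round(d / dt))
            row = by_delay.setdefault(d_steps, np.zeros(n_pop))
            row[idx[t]] += w
        for d_steps, row in by_delay.items():
            ou_entries.append((j, d_steps, row))
        if s.active_epochs is not None:
            ou_active[j] = np.isin(labels, s.active_epochs)
    max_delay = max((d for _, d, _ in ou_entries), default=0)
    hist_len = max_delay + 1

    # pulse current per step (n_steps, n_pop), usually all-zero and sparse
    pulse_I = None
    if pulses:
        pulse_I = np.zeros((n_steps, n_pop))
        for p in pulses:
            on = (times >= p.onset) & (times < p.onset + p.duration)
            pulse_I[on, idx[p.target]] += p.amplitude

    # initial state: deterministic fixed point with mean OU input (zero),
    # with the stationary OU spread on the processes
    r0 = solve_fixed_point(config)
    r = np.tile(r0, (n_trials, 1))
    ou = rng.normal(0.0, 1.0, size=(n_ou, n_trials)) * \
        (np.array([s.sigma_x for s in ou_specs]) / np.sqrt(2.0))[:, None]
    # delayed-copy ring buffer, prefilled with the initial OU state
    ou_hist = np.repeat(ou[:, :, None], hist_len, axis=2)
    ptr = 0

    out = np.empty((n_trials, n_steps, n_pop), dtype=record_dtype)
    out[:, 0, :] = r

    noisy = params.noise_amp > 0
    rate_coupled = params.ou_coupling == "rate"
    for k in range(1, n_steps):
        # currents from the state at step k-1
        I = params.I_bg + r @ params.W.T
        ou_term = None
        if n_ou:
            for j, d_steps, row in ou_entries:
                if not ou_active[j, k - 1]:
                    continue
                val = ou_hist[j, :, (ptr - d_steps) % hist_len]
                contrib = val[:, None] * row[None, :]
                ou_term = contrib if ou_term is None else ou_term + contrib
        if not rate_coupled and ou_term is not None:
            I = I + ou_term
        if pulse_I is not None:
            I = I + pulse_I[k - 1]
        noise = rng.standard_normal((n_trials, n_pop))
        target = params.transfer(I)
        if rate_coupled and ou_term is not None:
            target = target + ou_term
        r = r + params.drift * (target - r)
        r += np.where(noisy, params.noise_amp, 0.0) * noise
        np.maximum(r, 0.0, out=r)
        if not np.all(np.isfinite(r)):
            bad = np.flatnonzero(~np.isfinite(r).all(axis=0))[0]
            raise FloatingPointError(
                f"non-finite rate in population "
                f"{POPULATION_NAMES[bad]} at t={times[k]:.1f} ms")
        # advance OU processes and their delay buffer
        if n_ou:
            ou_noise = rng.standard_normal((n_ou, n_trials))
            ou = ou - ou_a[:, None] * ou + ou_amp[:, None] * ou_noise
            ptr = (ptr + 1) % hist_len
            ou_hist[:, :, ptr] = ou
        out[:, k, :] = r

    return RateTraces(dt=dt, times=times, rates=out, epoch_labels=labels,
                      seed=seed)
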