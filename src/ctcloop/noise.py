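"""Ornstein-Uhlenbeck input processes.

The loop receives three structured (low-pass filtered Gaussian) inputs:

* a private process to the Purkinje cells (tau_x = 80 ms, sigma_x = 0.5),
  a natural source of PC rate variability;
* a shared sensory process to PC and superficial S1 (tau_x = 80 ms,
  sigma_x = 2), the joint sensory afferent responsible for the high
  S1-cerebellar coherence;
* a preparatory "ramp" to the deep layers of M1 (tau_x = 200 ms,
  sigma_x = 100), active only during the pre-movement stage and switched
  off at movement onset.

Each process follows ``tau_x dx = -x dt + sqrt(tau_x) sigma_x dW-ish``,
i.e. the SDE ``dx = -(x/tau_x) dt + (sigma_x/sqrt(tau_x)) dW`` with
stationary variance ``sigma_x**2 / 2`` and autocorrelation
``exp(-lag/tau_x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OUProcessSpec", "default_ou_processes", "ou_generate"]


@dataclass(frozen=True)
class OUProcessSpec:
    """One OU input process.

    Attributes
    ----------
    name : str
        Identifier used in configs and logs.
    tau_x : float
        Correlation time, ms.
    sigma_x : float
        Noise amplitude (stationary SD is ``sigma_x / sqrt(2)``).
    targets : tuple of str
        Populations whose input current receives this process.
    active_epochs : tuple of str or None
        Epoch labels during which the process is on; ``None`` = always on.
    """

    name: str
    tau_x: float
    sigma_x: float
    targets: tuple[str, ...]
    active_epochs: tuple[str, ...] | None = None
    #: per-target conduction delay, ms (same order as ``targets``); a shared
    #: afferent reaches the cerebellum earlier than cortex, so the cortical
    #: copy of the shared sensory process is delayed by ~10 ms
    target_delays: tuple[float, ...] | None = None
    #: per-target synaptic weight (same order as ``targets``); the
    #: preparatory ramp engages deep inhibition slightly less than deep
    #: excitation, leaving a controlled net drive after E-I cancellation
    target_weights: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.tau_x <= 0:
            raise ValueError("tau_x must be positive")
        if self.sigma_x < 0:
            raise ValueError("sigma_x must be non-negative")
        for attr in (self.target_delays, self.target_weights):
            if attr is not None and len(attr) != len(self.targets):
                raise ValueError("need one entry per target")


def default_ou_processes(shared_to_deep_s1: bool = False,
                         ramp_inhibitory_weight: float = 0.85,
                         cortical_sensory_delay_ms: float = 10.0):
    """The three default processes.

    Parameters
    ----------
    shared_to_deep_s1 : bool
        Also deliver the shared sensory process to S1 deep excitatory cells
        (default: superficial only; sensory afferents target upper layers).
    ramp_to_deep_inhibitory : bool
        Deliver the preparatory ramp to both deep M1 populations (default)
        rather than the excitatory one alone.  Joint E/I targeting lets the
        laminar module cancel most of the large common drive, keeping the
        descending currents on the same O(1) scale as the published
        perturbation pulses.
    """
    shared_targets = ["PC", "S1sup_E"]
    shared_delays = [0.0, cortical_sensory_delay_ms]
    if shared_to_deep_s1:
        shared_targets.append("S1deep_E")
        shared_delays.append(cortical_sensory_delay_ms)
    return (
        OUProcessSpec("pc_private", tau_x=80.0, sigma_x=0.5, targets=("PC",)),
        OUProcessSpec("shared_sensory", tau_x=80.0, sigma_x=2.0,
                      targets=tuple(shared_targets),
                      target_delays=tuple(shared_delays)),
        OUProcessSpec("preparatory_ramp", tau_x=200.0, sigma_x=100.0,
                      targets=("M1deep_E", "M1deep_I"),
                      target_weights=(1.0, ramp_inhibitory_weight),
                      active_epochs=("pre_movement",)),
    )


def ou_generate(spec: OUProcessSpec, dt: float, T: float, seed,
                x0: float | None = None) -> np.ndarray:
    """Euler-Maruyama path of an OU process.

    Parameters
    ----------
    spec : OUProcessSpec
    dt : float
        Step, ms; must satisfy ``dt <= tau_x / 10``.
    T : float
        Duration, ms.
    seed : int or numpy Generator
    x0 : float, optional
        Initial value; defaults to a draw from the stationary distribution.

    Returns
    -------
    ndarray of shape ``(round(T/dt) + 1,)`` including the initial sample.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if dt > spec.tau_x / 10.0:
        raise ValueError(
            f"dt={dt} too large for tau_x={spec.tau_x}; need dt <= tau_x/10")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    n = int(round(T / dt))
    x = np.empty(n + 1)
    if x0 is None:
        x[0] = rng.normal(0.0, spec.sigma_x / np.sqrt(2.0))
    else:
        x[0] = x0
    a = dt / spec.tau_x
    amp = spec.sigma_x * np.sqrt(a)
    noise = rng.standard_normal(n)
    # the recursion x[k+1] = (1-a) x[k] + amp*noise[k] is an AR(1) filter
    from scipy.signal import lfilter

    driven = lfilter([1.0], [1.0, -(1.0 - a)], amp * noise)
    decay = x[0] * (1.0 - a) ** np.arange(1, n + 1)
    x[1:] = decay + driven
    return x
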