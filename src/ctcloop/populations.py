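"""Population catalogue of the cerebello-thalamo-cortical loop model.

The network has 15 neural-mass populations: two laminar modules (superficial
and deep, each with an excitatory and an inhibitory population) for each of
M1 and S1, plus single-population nodes for the pontine nuclei (PN),
cerebellar granule cells (GrC), Purkinje cells (PC), cerebellar nuclei (CN),
zona incerta (ZI), ventrolateral thalamus (VL) and medial posterior thalamus
(Pom).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["PopulationSpec", "POPULATION_NAMES", "default_populations"]

#: canonical population ordering used by all vectorised network code
POPULATION_NAMES = (
    "M1sup_E", "M1sup_I", "M1deep_E", "M1deep_I",
    "S1sup_E", "S1sup_I", "S1deep_E", "S1deep_I",
    "PN", "GrC", "PC", "CN", "ZI", "VL", "Pom",
)

_CORTICAL = POPULATION_NAMES[:8]
_SUBCORTICAL = POPULATION_NAMES[8:]


@dataclass(frozen=True)
class PopulationSpec:
    """Dynamical parameters of one neural-mass population.

    Attributes
    ----------
    name : str
        Population label, one of :data:`POPULATION_NAMES`.
    tau : float
        Rate time constant, ms.
    sigma : float
        White-noise SD of the rate equation (cortical populations only;
        0 for subcortical).
    beta : float
        Transfer-function onset sensitivity (1 cortical, 15 subcortical).
    gain_A : float
        Transfer gain (1 for cortical populations).
    theta : float
        Background current of the transfer function (subcortical only;
        positive values depolarise -- e.g. the cerebellar nuclei are
        tonically active through theta = 21 and are held down by Purkinje
        inhibition).
    I_bg : float
        Constant background current (cortical excitatory populations only).
    """

    name: str
    tau: float
    sigma: float = 0.0
    beta: float = 1.0
    gain_A: float = 1.0
    theta: float = 0.0
    I_bg: float = 0.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError(f"{self.name}: tau must be positive")
        if self.name not in POPULATION_NAMES:
            raise ValueError(f"unknown population {self.name!r}")

    @property
    def is_cortical(self) -> bool:
        return self.name in _CORTICAL


# time constants: superficial modules are fast (tauE=6, tauI=15 ms), deep
# modules slow (tauE=48, tauI=120 ms); rate noise sigma = 0.3 / 0.45
_CORTICAL_PARAMS = {
    "sup_E": dict(tau=6.0, sigma=0.3, I_bg=4.0),
    "sup_I": dict(tau=15.0, sigma=0.3, I_bg=0.0),
    "deep_E": dict(tau=48.0, sigma=0.45, I_bg=1.0),
    "deep_I": dict(tau=120.0, sigma=0.45, I_bg=0.0),
}

# (gain A, background theta) per subcortical population; tau = 6 ms, beta = 15
_SUBCORTICAL_PARAMS = {
    "PN": (1.0, 0.0),
    "GrC": (1.0, 0.0),
    "PC": (10.0, 0.1),
    "CN": (1.0, 21.0),
    "ZI": (1.0, -12.0),
    "VL": (5.0, 0.0),
    "Pom": (0.2, 30.0),
}


def default_populations() -> dict[str, PopulationSpec]:
    """The 15 populations with their default parameters, keyed by name."""
    pops: dict[str, PopulationSpec] = {}
    for area in ("M1", "S1"):
        for layer_pop, p in _CORTICAL_PARAMS.items():
            name = f"{area}{layer_pop}"
            pops[name] = PopulationSpec(name=name, beta=1.0, **p)
    for name, (A, theta) in _SUBCORTICAL_PARAMS.items():
        pops[name] = PopulationSpec(name=name, tau=6.0, sigma=0.0,
                                    beta=15.0, gain_A=A, theta=theta)
    return pops
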