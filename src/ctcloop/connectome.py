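"""Signed synaptic weight table of the loop.

Weights are keyed ``(source, target)`` and enter the target's input current
as ``J * r_source``.  Inhibitory sources (cortical I populations, PC, CN->ZI,
ZI) carry negative weights.

Four edges of the descending pathway (M1/S1 deep -> PN, PN -> GrC,
GrC -> PC) have no published strengths; their defaults were frozen by a
one-time calibration (grid search over 0.25-2) that maximises reproduction
of the baseline phase-relation sign flip, see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .populations import POPULATION_NAMES

__all__ = ["Connectome", "default_connectome", "DESCENDING_EDGES"]

#: descending-pathway edges whose strengths are calibrated, not published
DESCENDING_EDGES = (
    ("M1deep_E", "PN"),
    ("S1deep_E", "PN"),
    ("PN", "GrC"),
    ("GrC", "PC"),
)

# frozen by the calibration procedure documented in docs/methods.md
DEFAULT_DESCENDING_WEIGHTS = {
    ("M1deep_E", "PN"): 0.1,
    ("S1deep_E", "PN"): 0.02,
    ("PN", "GrC"): 1.0,
    ("GrC", "PC"): 2.0,
}


def _local_edges(area: str) -> dict[tuple[str, str], float]:
    """Within-module and interlaminar cortical edges of one area."""
    e: dict[tuple[str, str], float] = {}
    for layer in ("sup", "deep"):
        E = f"{area}{layer}_E"
        I = f"{area}{layer}_I"
        e[(E, E)] = 1.5
        e[(I, E)] = -3.25
        e[(E, I)] = 3.5
        e[(I, I)] = -2.5
    # interlaminar: superficial E -> deep E (1), deep E -> superficial I (0.75)
    e[(f"{area}sup_E", f"{area}deep_E")] = 1.0
    e[(f"{area}deep_E", f"{area}sup_I")] = 0.75
    return e


def _longrange_edges() -> dict[tuple[str, str], float]:
    e: dict[tuple[str, str], float] = {}
    # S1 -> M1
    e[("S1sup_E", "M1sup_E")] = 0.52
    e[("S1sup_E", "M1deep_E")] = 0.25
    e[("S1deep_E", "M1sup_E")] = 0.25
    e[("S1deep_E", "M1deep_E")] = 0.75
    # M1 -> S1
    e[("M1sup_E", "S1sup_E")] = 0.5
    e[("M1sup_E", "S1deep_E")] = 1.0
    e[("M1deep_E", "S1deep_E")] = 1.0
    # cerebellar / thalamic core
    e[("PC", "CN")] = -1.0
    e[("CN", "ZI")] = -1.0
    e[("CN", "Pom")] = 0.2
    e[("ZI", "Pom")] = -0.5
    e[("CN", "VL")] = 1.0
    e[("ZI", "VL")] = -3.0
    # thalamus -> cortex
    for layer in ("sup", "deep"):
        e[("Pom", f"S1{layer}_E")] = 0.3
        e[("Pom", f"S1{layer}_I")] = 0.1
        e[("Pom", f"M1{layer}_E")] = 0.33
        e[("Pom", f"M1{layer}_I")] = 0.5
    e[("VL", "M1deep_E")] = 0.6
    return e


@dataclass
class Connectome:
    """Weight table of the network.

    Parameters
    ----------
    weights : dict
        ``(source, target) -> signed strength`` for the published edges.
    descending_weights : dict
        Strengths of the four calibrated descending edges.
    """

    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    descending_weights: dict[tuple[str, str], float] = field(
        default_factory=dict)

    def __post_init__(self):
        for (src, tgt) in {**self.weights, **self.descending_weights}:
            if src not in POPULATION_NAMES or tgt not in POPULATION_NAMES:
                raise ValueError(f"unknown edge ({src!r}, {tgt!r})")
        for edge in self.descending_weights:
            if edge not in DESCENDING_EDGES:
                raise ValueError(f"{edge} is not a descending-pathway edge")

    @property
    def all_weights(self) -> dict[tuple[str, str], float]:
        return {**self.weights, **self.descending_weights}

    def matrix(self, names=POPULATION_NAMES) -> np.ndarray:
        """Dense matrix ``W[target, source]`` in the given ordering."""
        idx = {n: i for i, n in enumerate(names)}
        W = np.zeros((len(names), len(names)))
        for (src, tgt), w in self.all_weights.items():
            W[idx[tgt], idx[src]] = w
        return W

    def replace_descending(self, **by_edge_name: float) -> "Connectome":
        """Return a copy with some descending weights replaced.

        Keys are ``"<source>__<target>"``, e.g. ``PN__GrC=0.5``.
        """
        new = dict(self.descending_weights)
        for key, w in by_edge_name.items():
            src, tgt = key.split("__")
            if (src, tgt) not in DESCENDING_EDGES:
                raise ValueError(f"({src}, {tgt}) is not a descending edge")
            new[(src, tgt)] = w
        return Connectome(weights=dict(self.weights), descending_weights=new)


def default_connectome(descending_weights=None) -> Connectome:
    """The published network plus (calibrated) descending weights."""
    weights = {}
    weights.update(_local_edges("M1"))
    weights.update(_local_edges("S1"))
    weights.update(_longrange_edges())
    dw = dict(DEFAULT_DESCENDING_WEIGHTS)
    if descending_weights:
        dw.update(descending_weights)
    return Connectome(weights=weights, descending_weights=dw)
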