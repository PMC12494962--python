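"""Population transfer functions.

Two families are used throughout the network:

* cortical populations use ``F(x) = x / (1 - exp(-beta*x))`` with ``beta = 1``
  -- a smooth, strictly positive rectifier with a removable singularity at
  ``x = 0`` (limit ``1/beta``);
* subcortical populations (pontine, cerebellar and thalamic nuclei, zona
  incerta) use the same rectifier scaled by a gain ``A`` and offset by a
  background parameter ``theta``, with ``beta = 15``.

The subcortical function as commonly printed,
``A*x / (1 - exp(-beta*(x - theta)))``, diverges at ``x = theta`` whenever
``theta != 0`` and yields negative rates below it; the regular (default)
variant shifts the numerator as well, ``A*(x - theta)/(1 - exp(-beta*(x -
theta)))``, which is continuous, strictly positive, and reduces to the
cortical form for ``A = 1, theta = 0``.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["rectifier", "cortical_transfer", "subcortical_transfer"]

# below this value of beta*u the transfer is evaluated by its asymptote
_T_FLOOR = -30.0
# half-width of the series expansion window around the removable singularity
_T_TINY = 1e-4


def rectifier(u, beta: float = 1.0):
    """Smooth rectifier ``g(u) = u / (1 - exp(-beta*u))``.

    Continuous at ``u = 0`` (value ``1/beta``), strictly positive, ``~u`` for
    large positive ``u`` and ``~|u|*exp(beta*u)`` for large negative ``u``.
    Evaluated stably for any real input (no overflow/NaN).
    """
    u = np.asarray(u, dtype=float)
    t = beta * u
    # main branch: clip the exponent so expm1 cannot overflow; clipped
    # entries are overwritten by the asymptotic branch below
    tc = np.clip(t, _T_FLOOR, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        main = u / (-np.expm1(-tc))
    # series around t = 0: g = (1/beta) * (1 + t/2 + t^2/12 + O(t^4))
    series = (1.0 + t / 2.0 + t * t / 12.0) / beta
    # asymptote for very negative t: g ~ -u * exp(t)  (underflows to 0)
    asym = -u * np.exp(np.clip(t, None, 0.0))
    out = np.where(np.abs(t) < _T_TINY, series, main)
    out = np.where(t < _T_FLOOR, asym, out)
    if out.ndim == 0:
        return float(out)
    return out


def cortical_transfer(x, beta: float = 1.0):
    """Cortical transfer ``F(x) = x / (1 - exp(-beta*x))``.

    Parameters
    ----------
    x : array_like
        Input current.
    beta : float
        Firing-onset sensitivity, ``> 0``.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    return rectifier(x, beta)


def subcortical_transfer(x, A: float, beta: float = 15.0, theta: float = 0.0,
                         form: str = "shifted"):
    """Subcortical transfer function.

    ``form="shifted"`` (default) evaluates the regular variant
    ``A*(x - theta) / (1 - exp(-beta*(x - theta)))``, continuous everywhere
    and strictly positive.

    ``form="printed"`` evaluates ``A*x / (1 - exp(-beta*(x - theta)))``
    literally; it has a pole at ``x = theta`` when ``theta != 0`` and a
    removable singularity when ``theta == 0``.  A warning is emitted when the
    input comes within ``1e-3`` of the pole.

    Note that inside the network the ``theta`` parameter of a population acts
    as a *background current* added to its synaptic input (tonically active
    nuclei such as CN carry positive theta); see :mod:`ctcloop.network`.
    """
    if A <= 0:
        raise ValueError("A must be positive")
    if beta <= 0:
        raise ValueError("beta must be positive")
    if form == "shifted":
        return A * rectifier(np.asarray(x, dtype=float) - theta, beta)
    if form == "printed":
        x = np.asarray(x, dtype=float)
        if theta == 0.0:
            # the printed and shifted variants coincide; use the stable
            # evaluation through the removable singularity
            return A * rectifier(x, beta)
        u = x - theta
        if theta != 0.0 and np.any(np.abs(u) < 1e-3):
            warnings.warn(
                "printed subcortical transfer evaluated near its pole "
                "x = theta; result is numerically unreliable",
                RuntimeWarning,
                stacklevel=2,
            )
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            denom = -np.expm1(-np.clip(beta * u, _T_FLOOR, None))
            out = np.where(beta * u < _T_FLOOR,
                           -A * x * np.exp(np.clip(beta * u, None, 0.0)),
                           A * x / denom)
        if out.ndim == 0:
            return float(out)
        return out
    raise ValueError(f"unknown form {form!r}")
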