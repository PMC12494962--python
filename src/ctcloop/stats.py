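"""Statistical contrasts reported the way the loop experiments report them.

Paired t-tests carry Cohen's d_z (mean of paired differences over their SD,
identically t/sqrt(n)); Mann-Whitney U contrasts carry the rank-biserial
correlation r = 1 - 2U/(n1*n2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

__all__ = ["ContrastResult", "paired_contrast", "mwu_contrast"]


@dataclass
class ContrastResult:
    """One reported contrast.

    ``sided`` is 1 or 2; one-sided tests state their direction through
    ``alternative`` ('greater' means a > b).
    """

    test: str
    statistic: float
    p: float
    df: float | None
    effect_size: float
    sided: int
    n: tuple
    alternative: str = "two-sided"

    def __str__(self):
        df = "" if self.df is None else f", df={self.df:g}"
        return (f"{self.test}: stat={self.statistic:.2f}{df}, "
                f"p={self.p:.5f}, effect={self.effect_size:.2f} "
                f"({self.sided}-sided)")


def _alt(sided: int, direction: str) -> str:
    if sided == 2:
        return "two-sided"
    if sided == 1:
        return direction
    raise ValueError("sided must be 1 or 2")


def paired_contrast(a, b, sided: int = 2,
                    direction: str = "greater") -> ContrastResult:
    """Paired t-test of ``a`` vs ``b`` with Cohen's d_z.

    ``d_z = mean(a - b) / SD(a - b)`` (sample SD), equal to ``t / sqrt(n)``.
    One-sided tests (``sided=1``) test ``a > b`` by default
    (``direction='greater'``) or ``a < b`` (``'less'``).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-d samples")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("NaN in paired samples")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    alternative = _alt(sided, direction)
    res = sst.ttest_rel(a, b, alternative=alternative)
    dz = float(diff.mean() / sd)
    return ContrastResult(test="paired_t", statistic=float(res.statistic),
                          p=float(res.pvalue), df=float(a.size - 1),
                          effect_size=dz, sided=sided, n=(a.size,),
                          alternative=alternative)


def mwu_contrast(a, b, sided: int = 2,
                 direction: str = "greater") -> ContrastResult:
    """Mann-Whitney U contrast with rank-biserial effect size.

    Uses the exact null distribution for small samples (both n <= 20,
    no ties) and the tie-corrected normal approximation otherwise.  The
    effect size is ``r = 1 - 2U/(n1*n2)`` with ``U`` the U-statistic of
    ``a`` (wins of ``a`` over ``b``): under this orientation ``r = +1``
    when every value of ``a`` lies below every value of ``b`` and ``-1``
    in the opposite extreme; only |r| is comparison-invariant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    alternative = _alt(sided, direction)
    exact = (a.size <= 20 and b.size <= 20
             and np.unique(np.concatenate([a, b])).size == a.size + b.size)
    res = sst.mannwhitneyu(a, b, alternative=alternative,
                           method="exact" if exact else "asymptotic")
    u1 = float(res.statistic)
    r_rb = 1.0 - 2.0 * u1 / (a.size * b.size)
    return ContrastResult(test="mannwhitney_u", statistic=u1,
                          p=float(res.pvalue), df=None, effect_size=r_rb,
                          sided=sided, n=(a.size, b.size),
                          alternative=alternative)
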