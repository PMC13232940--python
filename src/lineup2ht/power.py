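"""Power and sensitivity analysis for χ²-distributed test statistics.

The G² statistics used throughout the package are asymptotically
χ²-distributed, so power calculations follow the standard noncentral-χ²
framework: under an alternative of effect size w (Cohen's w,
w = sqrt(Σ (p1−p0)²/p0)), the test statistic is approximately noncentral
χ²(df, λ) with noncentrality λ = N·w², where N is the total number of
observations entering the test.

For the pooled lineup designs analysed here, N counts individual lineup
responses, i.e. participants × responses per participant — each participant
responds to four lineups, so a sample of 766 participants contributes
N = 3064 observations. This convention reproduces the sensitivity values
reported with standard power software and is a known point of confusion, so
it is spelled out wherever N appears.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq
from scipy.stats import chi2, ncx2

__all__ = ["PowerQuery", "power_chisq", "sensitivity_w"]


@dataclass(frozen=True)
class PowerQuery:
    """A fully specified χ² power problem.

    ``n_obs`` is the total number of responses entering the test (for
    lineup designs: participants × lineups per participant). The
    noncentrality is λ = n_obs · w².
    """

    alpha: float
    power: float
    df: int
    n_obs: int
    w: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        if not (0.0 < self.power < 1.0):
            raise ValueError(f"power must lie in (0, 1), got {self.power!r}")
        if self.df < 1:
            raise ValueError(f"df must be >= 1, got {self.df!r}")
        if self.n_obs < 1:
            raise ValueError(f"n_obs must be >= 1, got {self.n_obs!r}")
        if self.w < 0:
            raise ValueError(f"w must be >= 0, got {self.w!r}")

    @property
    def noncentrality(self) -> float:
        return self.n_obs * self.w**2


def power_chisq(w: float, n_obs: int, df: int, alpha: float) -> float:
    """Power of a χ² test of size alpha against effect size w.

    Returns P(X > x_crit) where X ~ noncentral χ²(df, λ = n_obs·w²) and
    x_crit is the central χ² critical value at level alpha. At w = 0 the
    distribution is central and the power equals alpha exactly.
    """
    if w < 0:
        raise ValueError(f"w must be >= 0, got {w!r}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df!r}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    if n_obs < 1:
        raise ValueError(f"n_obs must be >= 1, got {n_obs!r}")
    crit = chi2.ppf(1.0 - alpha, df)
    lam = n_obs * w * w
    if lam == 0.0:
        return float(alpha)
    return float(ncx2.sf(crit, df, lam))


def sensitivity_w(
    n_obs: int, df: int, alpha: float = 0.05, power: float = 0.95
) -> float:
    """Smallest detectable effect size w for given N, df, alpha and power.

    Solves power_chisq(w, n_obs, df, alpha) = power by bracketed
    root-finding on w ∈ [1e-6, 1] to high precision; the caller rounds for
    reporting. Power is strictly increasing in w, so the root is unique.
    """
    if not (0.0 < alpha < power < 1.0):
        raise ValueError(
            f"need 0 < alpha < power < 1, got alpha={alpha!r}, power={power!r}"
        )
    lo, hi = 1e-6, 1.0
    f_lo = power_chisq(lo, n_obs, df, alpha) - power
    f_hi = power_chisq(hi, n_obs, df, alpha) - power
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            "no root in [1e-6, 1]: the requested power is not attainable "
            f"with n_obs={n_obs}, df={df}, alpha={alpha}"
        )
    return float(
        brentq(
            lambda w: power_chisq(w, n_obs, df, alpha) - power,
            lo,
            hi,
            xtol=1e-10,
        )
    )
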