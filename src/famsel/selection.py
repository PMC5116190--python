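"""Selection-coefficient estimation and power analysis.

For cross types with a Mendelian 1:1 heterozygote:homozygote expectation,
an observed deficit of homozygotes yields the heterozygote-advantage
selection coefficient

    s = 1 - N_ii / (N_ij + 1)

with ``N_ii`` homozygous and ``N_ij`` heterozygous offspring counts.  Under
viability selection against homozygotes with fitness ``1 - s``, the
offspring heterozygote probability in such crosses is ``1 / (2 - s)``
(Mendelian 1/2 het and 1/2 (1-s) hom, renormalised).  Power of the 1-df
chi-squared test at level alpha is evaluated either by binomial simulation
of that model or by the noncentral chi-squared approximation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import stats

__all__ = ["selection_coefficient", "het_probability", "power_of_test",
           "min_detectable_s", "PowerCurve"]


def selection_coefficient(n_homozygous: int, n_heterozygous: int) -> float:
    """Estimate s from offspring counts of a 1:1-expectation cross.

    ``s = 1 - N_ii / (N_ij + 1)``; zero when ``N_ii = N_ij + 1``, one when
    homozygotes are absent, negative when homozygotes are in excess.
    """
    if n_homozygous < 0 or n_heterozygous < 0:
        raise ValueError("counts must be non-negative")
    return 1.0 - n_homozygous / (n_heterozygous + 1)


def het_probability(s: float) -> float:
    """Offspring P(het) in a 1:1 cross under selection s against homozygotes."""
    if not 0 <= s < 1:
        raise ValueError(f"s must be in [0, 1), got {s}")
    return 1.0 / (2.0 - s)


def power_of_test(s: float, n: int, *, alpha: float = 0.05,
                  method: str = "mc", reps: int = 5000,
                  seed=None) -> float:
    """Power of the 1-df chi-squared test to detect selection s with n pups.

    ``method="mc"``: simulate heterozygote counts from Binomial(n, 1/(2-s))
    and reject when the chi-squared statistic exceeds its asymptotic
    alpha-critical value.  ``method="approx"``: noncentral chi-squared
    approximation with noncentrality ``4 n (p1 - 1/2)^2``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p1 = het_probability(s)
    crit = stats.chi2.ppf(1 - alpha, df=1)
    if method == "approx":
        lam = n * (p1 - 0.5) ** 2 * (1 / 0.5 + 1 / 0.5)
        return float(stats.ncx2.sf(crit, df=1, nc=lam))
    if method == "mc":
        rng = np.random.default_rng(seed)
        het = rng.binomial(n, p1, size=reps)
        chi2 = (het - n / 2) ** 2 / (n / 2) + ((n - het) - n / 2) ** 2 / (n / 2)
        return float(np.mean(chi2 > crit))
    raise ValueError("method must be 'mc' or 'approx'")


@dataclass
class PowerCurve:
    """Power over a grid of selection coefficients at fixed n and alpha."""
    n: int
    alpha: float
    target_power: float
    s_grid: np.ndarray
    power: np.ndarray
    min_detectable_s: Optional[float]    # None when target unreachable

    def as_frame(self):
        import pandas as pd
        return pd.DataFrame({"s": self.s_grid, "power": self.power})


def min_detectable_s(n: int, *, alpha: float = 0.05,
                     target_power: float = 0.80, method: str = "approx",
                     reps: int = 5000, seed=None,
                     grid_step: float = 0.01) -> PowerCurve:
    """Smallest s on a grid whose detection power reaches *target_power*.

    Scans s = 0, grid_step, ..., 0.99.  When even s = 0.99 falls short the
    curve's ``min_detectable_s`` is None (reported as "> 0.99").
    """
    if not (alpha < target_power < 1):
        raise ValueError("target_power must be in (alpha, 1)")
    rng = np.random.default_rng(seed)
    s_grid = np.round(np.arange(0.0, 1.0, grid_step), 10)
    s_grid = s_grid[s_grid <= 0.99]
    power = np.array([
        power_of_test(s, n, alpha=alpha, method=method, reps=reps, seed=rng)
        for s in s_grid])
    reaching = np.nonzero(power >= target_power)[0]
    s_star = float(s_grid[reaching[0]]) if reaching.size else None
    return PowerCurve(n=n, alpha=alpha, target_power=target_power,
                      s_grid=s_grid, power=power, min_detectable_s=s_star)
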