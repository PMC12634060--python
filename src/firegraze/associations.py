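"""Dual inferential approach: Spearman rank correlations plus linear fits
retained only when their residuals pass a normality check (Shapiro–Wilk).

Raw variables in this setting (influx, richness) are rarely normal, so rank
correlations carry the monotone-association evidence; the ordinary linear
fit and its R^2 are reported only when its residuals are compatible with
normality, mirroring standard practice for these proxy series.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

from .model import ComputationError


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with two-sided p.

    Average ranks for ties; the p-value is exact (full permutation
    enumeration) for n <= 9 without ties, otherwise the usual
    t-approximation.  A constant vector yields (nan, nan) as an
    undefined-correlation flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ComputationError("paired vectors differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ComputationError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    no_ties = np.unique(x).size == n and np.unique(y).size == n
    if no_ties and n <= 9:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rho_obs = 1.0 - 6.0 * np.sum((rx - ry) ** 2) / (n * (n * n - 1))
        # enumerate all rank permutations of one margin
        perms = np.array(list(permutations(range(1, n + 1))), dtype=float)
        d2 = ((perms - rx[None, :]) ** 2).sum(axis=1)
        rhos = 1.0 - 6.0 * d2 / (n * (n * n - 1))
        p = float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))
        return float(rho_obs), p
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AssociationResult:
    pair: str
    rho: float
    p_spearman: float
    r_squared: float | None
    p_linear: float | None
    residuals_normal: bool
    interpretation_retained: bool
    n: int


def gated_linear_fit(
    x, y, pair: str = "", alpha_normality: float = 0.05
) -> AssociationResult:
    """OLS fit of y on x, retained only if Shapiro–Wilk accepts residual
    normality at ``alpha_normality``; rho is always reported."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ComputationError("gated linear fit needs n >= 4")
    rho, p_s = spearman(x, y)
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    p_sw = float(stats.shapiro(resid).pvalue)
    normal = p_sw >= alpha_normality
    return AssociationResult(
        pair=pair,
        rho=rho,
        p_spearman=p_s,
        r_squared=float(fit.rvalue**2) if normal else None,
        p_linear=float(fit.pvalue) if normal else None,
        residuals_normal=normal,
        interpretation_retained=normal,
        n=int(x.size),
    )


#: default battery: (name, x column, y column) on the diversity table
DEFAULT_PAIRS = (
    ("pollen_influx~spore_influx", "spore_influx", "pollen_influx_total"),
    ("richness~spore_influx", "spore_influx", "DPRI"),
    ("richness~spore_richness", "spore_richness", "DPRI"),
)


def association_battery(
    diversity: pd.DataFrame,
    pairs=DEFAULT_PAIRS,
    use_detrended_richness: bool = True,
    alpha_normality: float = 0.05,
) -> pd.DataFrame:
    """Run the headline correlation battery on a diversity table.

    With ``use_detrended_richness=False`` the raw rarefied richness (PRI)
    replaces DPRI on the richness axes.
    """
    rows = []
    for name, xcol, ycol in pairs:
        if not use_detrended_richness:
            xcol = "PRI" if xcol == "DPRI" else xcol
            ycol = "PRI" if ycol == "DPRI" else ycol
        res = gated_linear_fit(
            diversity[xcol], diversity[ycol], pair=name,
            alpha_normality=alpha_normality,
        )
        rows.append(res.__dict__)
    return pd.DataFrame(rows).set_index("pair")
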