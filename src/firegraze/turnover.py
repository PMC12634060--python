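"""Rate-of-change (RoC) analysis of the assemblage time series.

The sequence is cut into moving-window time bins (working units) under
several shifted binnings; each randomization selects one sample per bin,
standardizes it to the global minimum count by subsampling without
replacement, applies age-weighted smoothing, and measures the chi-squared
dissimilarity between temporally adjacent units,

    d(p, q) = sqrt( sum_k (p_k - q_k)^2 / (p_k + q_k) ),

rescaled to dissimilarity per ``time_standardisation_yr`` years.  Values are
pooled across shifts and randomizations and summarized per output bin as the
median with 5%/95% quantiles.  Peaks are units whose median RoC exceeds a
locally weighted (LOESS) trend by 1.96 residual standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .model import (
    ComputationError,
    ConfigError,
    Chronology,
    CountTable,
    TaxonMeta,
)


@dataclass
class RoCConfig:
    bin_size_yr: int = 200
    n_shifts: int = 5
    dissimilarity: str = "chisq"
    smooth: str = "age_weighted"
    n_randomizations: int = 100
    standardize_to: str = "min_count"
    time_standardisation_yr: int = 200
    peak_method: str = "trend_non_linear"
    peak_span: float = 0.5
    peak_multiplier: float = 1.96
    smooth_window_yr: float | None = None  # defaults to bin_size_yr
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size_yr % self.n_shifts != 0:
            raise ConfigError("bin_size_yr must be divisible by n_shifts")
        if self.dissimilarity != "chisq":
            raise ConfigError(f"unsupported dissimilarity {self.dissimilarity!r}")
        if self.n_randomizations < 1:
            raise ConfigError("n_randomizations must be >= 1")


def chisq_dissimilarity(p, q) -> float:
    """Chi-squared distance between two proportion vectors (0/0 terms vanish)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ComputationError("proportion vectors differ in length")
    if np.any(p < 0) or np.any(q < 0):
        raise ComputationError("proportions must be non-negative")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ComputationError(f"{name} does not sum to 1 (got {v.sum()!r})")
    denom = p + q
    mask = denom > 0
    return float(np.sqrt(np.sum((p[mask] - q[mask]) ** 2 / denom[mask])))


def bin_working_units(
    ages, bin_size: float, n_shifts: int
) -> list[list[tuple[float, list[int]]]]:
    """Moving-window binnings: ``n_shifts`` binnings whose edges are offset by
    ``bin_size / n_shifts``; each non-empty bin is one working unit, returned
    as ``(bin midpoint age, sample indices ordered by age)``."""
    ages = np.asarray(ages, dtype=float)
    if ages.size < 2:
        raise ComputationError("need at least two samples to bin")
    order = np.argsort(ages)
    start = ages.min()
    binnings = []
    for s in range(n_shifts):
        offset = s * bin_size / n_shifts
        idx = np.floor((ages[order] - (start - offset)) / bin_size).astype(int)
        units: list[tuple[float, list[int]]] = []
        for k in np.unique(idx):
            mid = start - offset + (k + 0.5) * bin_size
            units.append((mid, [int(i) for i in order[idx == k]]))
        binnings.append(units)
    return binnings


def age_weighted_smooth(counts_by_sample, ages, window: float) -> np.ndarray:
    """Age-weighted moving average of taxon vectors.

    Each row (one unit's taxon vector) is replaced by the weighted mean of
    rows within +-window/2 years, with weights 1/(1 + |delta age|) so the
    unit itself always carries the largest weight.
    """
    x = np.asarray(counts_by_sample, dtype=float)
    ages = np.asarray(ages, dtype=float)
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        d = np.abs(ages - ages[i])
        in_win = d <= window / 2.0
        w = 1.0 / (1.0 + d[in_win])
        out[i] = w @ x[in_win] / w.sum()
    return out


def detect_peaks(
    ages,
    roc_median,
    span: float = 0.5,
    multiplier: float = 1.96,
) -> np.ndarray:
    """Flag units whose median RoC exceeds a LOESS trend by ``multiplier``
    residual standard deviations."""
    ages = np.asarray(ages, dtype=float)
    roc = np.asarray(roc_median, dtype=float)
    if ages.size < 5:
        raise ComputationError("need at least 5 working units for peak detection")
    # plain (non-robust) local regression: robustifying iterations degenerate
    # to interpolation when most of the series sits at one value (MAD = 0)
    trend = lowess(roc, ages, frac=span, it=0, return_sorted=False)
    resid = roc - trend
    sd = float(np.std(resid))
    eps = 1e-9 * (np.max(np.abs(roc)) + 1.0)  # guard against float fuzz on flat series
    return roc > trend + multiplier * sd + eps


def roc_series(
    counts: CountTable,
    meta: TaxonMeta,
    chron: Chronology,
    config: RoCConfig | None = None,
) -> pd.DataFrame:
    """Randomized moving-window RoC series with 5%/95% envelope and peak flags.

    Deterministic under a fixed ``config.seed``.
    """
    config = config or RoCConfig()
    taxa = [t for t in meta.terrestrial_taxa if t in counts.counts.index]
    mat = counts.counts.loc[taxa].to_numpy().T  # samples x taxa
    ages = chron.table.loc[counts.samples, "age_calBP"].to_numpy()
    totals = mat.sum(axis=1)
    if np.any(totals == 0):
        raise ComputationError("sample with zero terrestrial count")
    min_count = int(totals.min())
    window = config.smooth_window_yr or float(config.bin_size_yr)

    binnings = bin_working_units(ages, config.bin_size_yr, config.n_shifts)
    if len(binnings[0]) < 3:
        raise ComputationError("fewer than 3 working units")

    rng = np.random.default_rng(config.seed)
    mids: list[float] = []
    rocs: list[float] = []
    for _ in range(config.n_randomizations):
        for units in binnings:
            u_ages = np.empty(len(units))
            u_counts = np.empty((len(units), mat.shape[1]))
            for i, (mid, members) in enumerate(units):
                pick = members[rng.integers(len(members))] if len(members) > 1 else members[0]
                vec = mat[pick]
                if totals[pick] > min_count:
                    vec = rng.multivariate_hypergeometric(vec, min_count)
                u_counts[i] = vec
                u_ages[i] = mid
            smoothed = age_weighted_smooth(u_counts, u_ages, window)
            props = smoothed / smoothed.sum(axis=1, keepdims=True)
            for i in range(len(units) - 1):
                gap = u_ages[i + 1] - u_ages[i]
                if gap <= 0:
                    continue
                d = chisq_dissimilarity(props[i], props[i + 1])
                rocs.append(d / gap * config.time_standardisation_yr)
                mids.append(0.5 * (u_ages[i] + u_ages[i + 1]))

    mids_arr = np.asarray(mids)
    rocs_arr = np.asarray(rocs)
    start = ages.min()
    bin_idx = np.floor((mids_arr - start) / config.bin_size_yr).astype(int)
    rows = []
    for k in np.unique(bin_idx):
        vals = rocs_arr[bin_idx == k]
        rows.append(
            {
                "age_calBP": start + (k + 0.5) * config.bin_size_yr,
                "roc_median": float(np.median(vals)),
                "roc_q05": float(np.quantile(vals, 0.05)),
                "roc_q95": float(np.quantile(vals, 0.95)),
                "n_values": int(vals.size),
            }
        )
    out = pd.DataFrame(rows).sort_values("age_calBP").reset_index(drop=True)
    if len(out) >= 5:
        out["peak"] = detect_peaks(
            out["age_calBP"], out["roc_median"],
            span=config.peak_span, multiplier=config.peak_multiplier,
        )
    else:
        warnings.warn("too few working units for peak detection", stacklevel=2)
        out["peak"] = False
    return out
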