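"""Diversity metrics: rarefied richness, Hurlbert's PIE, detrended richness,
and coprophilous-spore richness/influx series.

Rarefied (palynological) richness is the expected number of taxa in a random
subsample of fixed size n drawn without replacement,

    E[S_n] = sum_i [ 1 - C(N - N_i, n) / C(N, n) ],

evaluated with log-gamma terms for numerical stability.  PIE (probability of
interspecific encounter) is the chance that two grains drawn without
replacement belong to different taxa,

    PIE = N/(N-1) * (1 - sum_i (N_i/N)^2).

Detrended richness (DPRI) removes the linear dependence of richness on
evenness: the OLS residuals of richness regressed on PIE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .model import (
    ComputationError,
    ConfigError,
    Chronology,
    CountTable,
    TaxonMeta,
)
from .quantities import terrestrial_sum


def rarefied_richness(counts_for_sample, n: int) -> float:
    """Expected taxon count in a subsample of size ``n`` without replacement.

    Returns NaN (undefined flag) when the sample holds fewer than ``n``
    grains — richness is never extrapolated.
    """
    c = np.asarray(counts_for_sample, dtype=float)
    if np.any(c < 0) or np.any(c != np.floor(c)):
        raise ComputationError("counts must be non-negative integers")
    if n < 1:
        raise ComputationError("rarefaction size must be >= 1")
    c = c[c > 0]
    N = c.sum()
    if N < n:
        return float("nan")
    # log C(N - N_i, n) - log C(N, n); taxa with N - N_i < n always appear
    lncn = gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)
    terms = np.ones_like(c)
    keep = (N - c) >= n
    m = N - c[keep]
    ln_miss = gammaln(m + 1) - gammaln(n + 1) - gammaln(m - n + 1) - lncn
    terms[keep] = 1.0 - np.exp(ln_miss)
    return float(terms.sum())


def pie_evenness(counts_for_sample) -> float:
    """Hurlbert's PIE; NaN when fewer than two grains are present."""
    c = np.asarray(counts_for_sample, dtype=float)
    if np.any(c < 0):
        raise ComputationError("counts must be non-negative")
    N = c.sum()
    if N < 2:
        return float("nan")
    return float(N / (N - 1.0) * (1.0 - np.sum((c / N) ** 2)))


def detrended_richness(pri_series, pie_series) -> np.ndarray:
    """OLS residuals of richness on evenness (NaN-propagating).

    With constant evenness the regression is degenerate; the centered
    richness is returned with a warning.
    """
    pri = np.asarray(pri_series, dtype=float)
    pie = np.asarray(pie_series, dtype=float)
    if pri.shape != pie.shape:
        raise ComputationError("richness and evenness series differ in length")
    out = np.full(pri.shape, np.nan)
    ok = np.isfinite(pri) & np.isfinite(pie)
    if ok.sum() < 2:
        raise ComputationError("need at least two complete (PRI, PIE) pairs")
    if np.ptp(pie[ok]) == 0:
        warnings.warn(
            "constant evenness: detrending degenerates to centering richness",
            stacklevel=2,
        )
        out[ok] = pri[ok] - pri[ok].mean()
        return out
    fit = stats.linregress(pie[ok], pri[ok])
    out[ok] = pri[ok] - (fit.intercept + fit.slope * pie[ok])
    return out


def spore_metrics(
    counts: CountTable,
    meta: TaxonMeta,
    influx: pd.DataFrame,
    subset: str = "all",
) -> pd.DataFrame:
    """Per-sample coprophilous-spore richness (taxa with count > 0 — counts
    are too low for rarefaction) and summed spore influx, over all spore
    types or the well-documented herbivory indicators only."""
    taxa = [t for t in meta.spore_taxa(subset) if t in counts.counts.index]
    if taxa:
        richness = (counts.counts.loc[taxa] > 0).sum(axis=0)
        flux = influx.loc[taxa].sum(axis=0)
    else:
        richness = pd.Series(0, index=counts.counts.columns)
        flux = pd.Series(0.0, index=counts.counts.columns)
    return pd.DataFrame({"spore_richness": richness, "spore_influx": flux})


@dataclass
class DiversityConfig:
    """Parameters for the diversity stage.

    ``rarefaction_n`` defaults to the minimum terrestrial pollen sum across
    samples (the deposited study standardizes on n = 92, its terrestrial
    minimum).  ``spore_subset`` chooses between all spore types and the
    well-documented herbivory indicators.
    """

    rarefaction_n: int | None = None
    spore_subset: str = "all"
    terrestrial_only: bool = True

    def __post_init__(self) -> None:
        if self.rarefaction_n is not None and self.rarefaction_n < 1:
            raise ConfigError("rarefaction_n must be >= 1")
        if self.spore_subset not in ("all", "reliable_only"):
            raise ConfigError(f"unknown spore subset {self.spore_subset!r}")


def diversity_series(
    counts: CountTable,
    meta: TaxonMeta,
    influx: pd.DataFrame,
    chron: Chronology,
    config: DiversityConfig | None = None,
) -> pd.DataFrame:
    """Per-sample diversity table: PRI, PIE, DPRI, spore richness/influx and
    total pollen influx, indexed by sample with age attached."""
    config = config or DiversityConfig()
    if config.terrestrial_only:
        taxa = [t for t in meta.terrestrial_taxa if t in counts.counts.index]
    else:
        taxa = [
            t
            for t in counts.taxa
            if meta.table.loc[t, "group"] in ("terrestrial_pollen", "aquatic_pollen")
        ]
    block = counts.counts.loc[taxa]
    sums = block.sum(axis=0)
    base = config.rarefaction_n or int(sums.min())
    pri = np.array([rarefied_richness(block[s], base) for s in block.columns])
    pie = np.array([pie_evenness(block[s]) for s in block.columns])
    dpri = detrended_richness(pri, pie)
    spores = spore_metrics(counts, meta, influx, config.spore_subset)
    out = pd.DataFrame(
        {
            "age_calBP": chron.table.loc[block.columns, "age_calBP"],
            "PRI": pri,
            "PIE": pie,
            "DPRI": dpri,
            "spore_richness": spores["spore_richness"],
            "spore_influx": spores["spore_influx"],
            "pollen_influx_total": influx.loc[taxa].sum(axis=0),
        },
        index=block.columns,
    )
    out.index.name = "sample"
    out.attrs["rarefaction_n"] = base
    return out
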