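"""Habitat-level influx and the influx-weighted mean combustibility index.

Each of the six classed habitats carries an ordinal combustibility class
(1 = beech forest / white oak coppice ... 5 = dry grassland).  The
per-sample index is the influx-weighted average of those classes:

    mean_combustibility = sum_h(influx_h * class_h) / sum_h(influx_h)

taken over classed habitats only; taxa in the "other" habitat (riparian,
floodplain, unassignable) are excluded from both numerator and denominator
by default so the index stays on the 1–5 scale.

Period comparison uses pairwise two-sided Mann–Whitney U tests with a
compact letter display (groups sharing a letter are not significantly
different at the chosen alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    ComputationError,
    ConfigError,
    Chronology,
    CountTable,
    HABITAT_COMBUSTIBILITY,
    HABITATS,
    OTHER_HABITAT,
    TaxonMeta,
)


def habitat_influx(influx: pd.DataFrame, meta: TaxonMeta) -> pd.DataFrame:
    """Sum per-taxon influx into habitat rows; "other" is kept as its own row."""
    habitats = meta.table.loc[influx.index, "habitat"]
    grouped = influx.groupby(habitats).sum()
    return grouped.reindex(list(HABITATS), fill_value=0.0)


def mean_combustibility(
    habitat_influx_column: pd.Series,
    class_map: dict | None = None,
    include_other_in_denominator: bool = False,
) -> float:
    """Influx-weighted mean combustibility class for one sample.

    Returns NaN (an undefined-value flag) when no classed habitat carries
    influx.
    """
    class_map = class_map or HABITAT_COMBUSTIBILITY
    classed = [h for h in habitat_influx_column.index if h in class_map]
    w = habitat_influx_column[classed].to_numpy(dtype=float)
    if np.any(w < 0):
        raise ComputationError("negative influx")
    num = float(np.dot(w, [class_map[h] for h in classed]))
    denom = float(w.sum())
    if include_other_in_denominator:
        denom = float(habitat_influx_column.sum())
    if denom == 0:
        return float("nan")
    return num / denom


def combustibility_series(
    influx: pd.DataFrame,
    meta: TaxonMeta,
    chron: Chronology,
    include_other_in_denominator: bool = False,
) -> pd.DataFrame:
    """Per-sample combustibility index, classed influx total and "other" share."""
    hab = habitat_influx(influx, meta)
    classed = hab.drop(index=OTHER_HABITAT)
    total = hab.sum(axis=0)
    out = pd.DataFrame(
        {
            "age_calBP": chron.table.loc[hab.columns, "age_calBP"],
            "mean_combustibility": [
                mean_combustibility(hab[s], include_other_in_denominator=include_other_in_denominator)
                for s in hab.columns
            ],
            "classed_influx_total": classed.sum(axis=0),
            "other_influx_fraction": np.where(
                total > 0, hab.loc[OTHER_HABITAT] / total, np.nan
            ),
        },
        index=hab.columns,
    )
    out.index.name = "sample"
    return out


# --- periods ------------------------------------------------------------------


@dataclass
class PeriodConfig:
    """Half-open period intervals on the cal BP axis, oldest first.

    Boundaries are inclusive on the older side and exclusive on the younger:
    an age exactly equal to a boundary belongs to the younger period.
    """

    boundaries_calBP: Sequence[float] = (6500.0, 4000.0, 1000.0)
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        b = list(self.boundaries_calBP)
        if any(b[i] <= b[i + 1] for i in range(len(b) - 1)):
            raise ConfigError("period boundaries must be strictly descending")
        if self.labels is None:
            self.labels = [f"Period {k + 1}" for k in range(len(b) + 1)]
        elif len(self.labels) != len(b) + 1:
            raise ConfigError("need exactly one more label than boundaries")


def assign_periods(ages, config: PeriodConfig | None = None) -> list[str]:
    """Label each age with its period (oldest period open-ended at the old end)."""
    config = config or PeriodConfig()
    ages = np.asarray(ages, dtype=float)
    if not np.all(np.isfinite(ages)):
        raise ComputationError("ages must be finite")
    bounds = np.asarray(config.boundaries_calBP, dtype=float)
    idx = (ages[:, None] <= bounds[None, :]).sum(axis=1)
    return [config.labels[i] for i in idx]


# --- tests and letters ---------------------------------------------------------


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact enumeration when n_x + n_y <= 12 with no ties; tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ComputationError("Mann–Whitney requires two non-empty groups")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compact_letter_display(
    groups: Sequence[str], significant_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing at least one letter are not significantly different;
    significantly different pairs never share a letter.
    """
    sig = {frozenset(p) for p in significant_pairs}
    letter_sets: list[set[str]] = [set(groups)]
    for pair in sig:
        a, b = tuple(pair)
        for current in list(letter_sets):
            if a in current and b in current:
                letter_sets.remove(current)
                for reduced in (current - {a}, current - {b}):
                    if reduced and not any(
                        reduced <= other for other in letter_sets
                    ):
                        letter_sets.append(reduced)
        # absorb sets that became redundant
        letter_sets = [
            s
            for i, s in enumerate(letter_sets)
            if not any(s < t or (s == t and i > j) for j, t in enumerate(letter_sets))
        ]
    # stable letter order: by first group each set contains
    order = {g: i for i, g in enumerate(groups)}
    letter_sets.sort(key=lambda s: min(order[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


@dataclass
class PeriodComparison:
    means: pd.Series
    pairwise: pd.DataFrame
    letters: dict[str, str]


def compare_periods(
    values, labels, alpha: float = 0.05, min_per_period: int = 2
) -> PeriodComparison:
    """All pairwise Mann–Whitney U tests between periods plus letter display.

    ``values`` is a per-sample series (e.g. mean combustibility); NaN entries
    are dropped.  Raw p-values are reported without multiplicity correction.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    lab = pd.Series(list(labels))
    keep = s.notna().to_numpy()
    s, lab = s[keep], lab[keep]
    periods = list(dict.fromkeys(lab))  # preserve order of appearance
    sizes = lab.value_counts()
    small = [p for p in periods if sizes.get(p, 0) < min_per_period]
    if len(periods) < 2 or small:
        raise ComputationError(
            f"need >=2 periods with >={min_per_period} samples each; "
            f"degenerate: {small}"
        )
    rows = []
    sig_pairs: set[tuple[str, str]] = set()
    for a, b in combinations(periods, 2):
        u, p = mann_whitney_u(s[lab == a], s[lab == b])
        rows.append({"period_a": a, "period_b": b, "U": u, "p_value": p,
                     "significant": p < alpha})
        if p < alpha:
            sig_pairs.add((a, b))
    means = s.groupby(lab.values).mean().reindex(periods)
    means.index.name = "period"
    return PeriodComparison(
        means=means,
        pairwise=pd.DataFrame(rows),
        letters=compact_letter_display(periods, sig_pairs),
    )
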