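"""Counts -> percentages, concentrations (grains/cm^3) and influx (grains/cm^2/yr).

Concentration uses the exotic-marker (Lycopodium tablet) ratio:

    concentration = count * (spike_added / spike_counted) / volume_cm3

and influx divides by the per-sample deposition time (yr/cm) taken from the
chronology.  Percentages use the terrestrial pollen sum; non-terrestrial
groups are expressed relative to (terrestrial sum + own group sum), the
standard palynological convention for taxa excluded from the pollen sum.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd

from .model import (
    ChronologyError,
    ComputationError,
    CountTable,
    Chronology,
    GROUP_TERRESTRIAL,
    TaxonMeta,
)

ArrayLike = Union[float, int, np.ndarray, pd.Series]


def terrestrial_sum(counts: CountTable, meta: TaxonMeta, sample=None):
    """Terrestrial pollen sum (excludes (semi)aquatics and spores).

    Returns a per-sample Series, or a single integer if ``sample`` is given.
    """
    taxa = [t for t in meta.terrestrial_taxa if t in counts.counts.index]
    sums = counts.counts.loc[taxa].sum(axis=0)
    if sample is None:
        return sums
    if sample not in sums.index:
        raise ComputationError(f"unknown sample {sample!r}")
    return int(sums[sample])


def percentages(counts: CountTable, meta: TaxonMeta) -> pd.DataFrame:
    """Percent abundances: terrestrial taxa on the terrestrial sum, each other
    group on (terrestrial sum + own group sum)."""
    groups = meta.table.loc[counts.taxa, "group"]
    ts = terrestrial_sum(counts, meta)
    if (ts == 0).any():
        bad = ts.index[ts == 0].tolist()
        raise ComputationError(f"zero terrestrial pollen sum in sample(s) {bad}")
    out = pd.DataFrame(0.0, index=counts.counts.index, columns=counts.counts.columns)
    for group, taxa in groups.groupby(groups).groups.items():
        taxa = list(taxa)
        block = counts.counts.loc[taxa]
        denom = ts if group == GROUP_TERRESTRIAL else ts + block.sum(axis=0)
        out.loc[taxa] = 100.0 * block / denom
    return out


def concentration(
    count: ArrayLike,
    spike_counted: ArrayLike,
    spike_added: ArrayLike,
    volume_cm3: ArrayLike,
) -> ArrayLike:
    """Grains per cm^3 from the marker-grain ratio."""
    spike_counted = np.asarray(spike_counted, dtype=float)
    if np.any(spike_counted <= 0):
        raise ComputationError(
            "spike_counted is zero: concentration undefined (flag the sample, "
            "do not zero it)"
        )
    return count * (np.asarray(spike_added, dtype=float) / spike_counted) / np.asarray(
        volume_cm3, dtype=float
    )


def influx(conc: ArrayLike, deposition_time_yr_per_cm: ArrayLike) -> ArrayLike:
    """Grains per cm^2 per year: concentration / deposition time."""
    dep = np.asarray(deposition_time_yr_per_cm, dtype=float)
    if np.any(dep <= 0):
        raise ChronologyError("non-positive deposition time")
    return conc / dep


def concentration_table(counts: CountTable) -> pd.DataFrame:
    """Per-taxon concentration matrix (taxa x samples)."""
    bad = counts.spike_counted.index[counts.spike_counted <= 0].tolist()
    if bad:
        raise ComputationError(
            f"spike_counted is zero in sample(s) {bad}: concentration undefined"
        )
    factor = counts.spike_added / counts.spike_counted / counts.volume_cm3
    return counts.counts * factor


def influx_table(counts: CountTable, chron: Chronology) -> pd.DataFrame:
    """Per-taxon influx matrix (taxa x samples), grains cm^-2 yr^-1."""
    conc = concentration_table(counts)
    dep = chron.table.loc[conc.columns, "deposition_time_yr_per_cm"]
    if (dep <= 0).any():
        raise ChronologyError("non-positive deposition time in chronology")
    return conc / dep
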