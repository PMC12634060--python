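"""Core data model for stratigraphic pollen / coprophilous-spore count datasets.

The pipeline operates on three tables:

* :class:`CountTable` — integer counts of palynomorphs (taxon x sample),
  together with the per-sample exotic-marker (*Lycopodium*) spike data and
  the processed sediment volume, which turn counts into concentrations.
* :class:`TaxonMeta` — per-taxon ecological group, habitat assignment and
  the fixed habitat -> combustibility-class mapping (Trabaud-style 1–5
  scale, 1 = beech forest ... 5 = dry grassland).
* :class:`Chronology` — per-sample depth, calibrated age (cal BP, larger =
  older) and deposition time (yr/cm) from a pre-computed age–depth model.

All containers wrap :class:`pandas.DataFrame` / :class:`pandas.Series`
objects and validate their invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class FiregrazeError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(FiregrazeError):
    """A table violates its structural contract (bad cell, bad label, duplicate)."""


class ConsistencyError(FormatError):
    """Two fields of a table contradict each other (e.g. habitat vs class)."""


class ConfigError(FiregrazeError):
    """A configuration value or combination of values is invalid."""


class ComputationError(FiregrazeError):
    """A quantity is undefined for the given input (e.g. zero pollen sum)."""


class ChronologyError(ComputationError):
    """Chronology-derived inputs are unusable (e.g. non-positive deposition time)."""


# --- controlled vocabularies -------------------------------------------------

GROUP_TERRESTRIAL = "terrestrial_pollen"
GROUP_AQUATIC = "aquatic_pollen"
GROUP_SPORE = "coprophilous_spore"
GROUP_OTHER = "other_palynomorph"
GROUPS = (GROUP_TERRESTRIAL, GROUP_AQUATIC, GROUP_SPORE, GROUP_OTHER)

OTHER_HABITAT = "other"

#: Fixed habitat -> combustibility class mapping (ordinal 1–5).
HABITAT_COMBUSTIBILITY: dict[str, int] = {
    "beech_forest": 1,
    "white_oak_coppice": 1,
    "green_oak_coppice": 2,
    "pine_forest": 3,
    "garrigue_heathland": 4,
    "grassland": 5,
}

#: The six classed habitats, in fixed (class-ascending) order.
CLASSED_HABITATS: tuple[str, ...] = tuple(HABITAT_COMBUSTIBILITY)
HABITATS: tuple[str, ...] = CLASSED_HABITATS + (OTHER_HABITAT,)


# --- containers --------------------------------------------------------------


@dataclass
class CountTable:
    """Taxon x sample integer counts plus per-sample spike and volume data.

    Parameters
    ----------
    counts
        Integer DataFrame, taxa as the index, samples as columns, ordered
        stratigraphically (top to bottom).
    spike_counted
        Marker grains tallied per sample (>= 0).
    spike_added
        Marker grains added per sample (> 0).
    volume_cm3
        Processed sediment volume per sample in cm^3 (> 0).
    """

    counts: pd.DataFrame
    spike_counted: pd.Series
    spike_added: pd.Series
    volume_cm3: pd.Series

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicated taxon names: {dups}")
        if c.columns.duplicated().any():
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicated sample names: {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("counts must be numeric")
        if not np.all(np.isfinite(arr)):
            raise FormatError("counts contain non-finite values")
        if np.any(arr != np.floor(arr)):
            t, s = np.argwhere(arr != np.floor(arr))[0]
            raise FormatError(
                f"non-integer count at taxon {c.index[t]!r}, sample {c.columns[s]!r}"
            )
        if np.any(arr < 0):
            t, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at taxon {c.index[t]!r}, sample {c.columns[s]!r}"
            )
        c = c.astype(np.int64)
        c.index.name = "taxon"
        c.columns.name = "sample"
        self.counts = c
        for name in ("spike_counted", "spike_added", "volume_cm3"):
            ser = getattr(self, name)
            ser = ser.reindex(c.columns)
            if ser.isna().any():
                missing = ser.index[ser.isna()].tolist()
                raise FormatError(f"{name} missing for samples {missing}")
            setattr(self, name, ser.astype(float))
        if (self.spike_counted < 0).any():
            raise FormatError("spike_counted must be >= 0")
        if (self.spike_added <= 0).any():
            raise FormatError("spike_added must be > 0")
        if (self.volume_cm3 <= 0).any():
            raise FormatError("volume_cm3 must be > 0")

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    @property
    def taxa(self) -> list:
        return list(self.counts.index)


@dataclass
class TaxonMeta:
    """Per-taxon metadata: ecological group, habitat, combustibility class.

    ``table`` is indexed by taxon with columns ``group``, ``habitat``,
    ``combustibility_class`` (nullable integer; null exactly when
    ``habitat == "other"``) and ``reliable_herbivory_indicator`` (bool,
    only ever true for coprophilous spores).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        if t.index.duplicated().any():
            raise FormatError("duplicated taxon names in metadata")
        for col in ("group", "habitat"):
            if col not in t.columns:
                raise FormatError(f"taxon metadata lacks required column {col!r}")
        bad_group = set(t["group"]) - set(GROUPS)
        if bad_group:
            raise FormatError(f"unknown ecological group label(s): {sorted(bad_group)}")
        bad_hab = set(t["habitat"]) - set(HABITATS)
        if bad_hab:
            raise FormatError(f"unknown habitat label(s): {sorted(bad_hab)}")
        expected = t["habitat"].map(HABITAT_COMBUSTIBILITY)  # NaN for "other"
        if "combustibility_class" not in t.columns:
            t["combustibility_class"] = expected
        else:
            given = pd.to_numeric(t["combustibility_class"], errors="coerce")
            conflict = given.notna() & expected.notna() & (given != expected)
            if conflict.any():
                taxon = t.index[conflict][0]
                raise ConsistencyError(
                    f"taxon {taxon!r}: explicit combustibility class "
                    f"{given[conflict].iloc[0]:g} conflicts with habitat "
                    f"{t.loc[taxon, 'habitat']!r} (class {expected[conflict].iloc[0]:g})"
                )
            stray = given.notna() & expected.isna()
            if stray.any():
                raise ConsistencyError(
                    f"taxon {t.index[stray][0]!r}: combustibility class given "
                    "for habitat 'other'"
                )
            t["combustibility_class"] = expected
        if "reliable_herbivory_indicator" not in t.columns:
            t["reliable_herbivory_indicator"] = False
        t["reliable_herbivory_indicator"] = t["reliable_herbivory_indicator"].astype(bool)
        bad = t["reliable_herbivory_indicator"] & (t["group"] != GROUP_SPORE)
        if bad.any():
            raise ConsistencyError(
                f"taxon {t.index[bad][0]!r} flagged as herbivory indicator "
                "but is not a coprophilous spore"
            )
        self.table = t

    def taxa_in_group(self, group: str) -> list:
        return list(self.table.index[self.table["group"] == group])

    @property
    def terrestrial_taxa(self) -> list:
        return self.taxa_in_group(GROUP_TERRESTRIAL)

    def spore_taxa(self, subset: str = "all") -> list:
        """Coprophilous spore taxa, optionally restricted to the well-documented set."""
        t = self.table
        mask = t["group"] == GROUP_SPORE
        if subset == "reliable_only":
            mask &= t["reliable_herbivory_indicator"]
        elif subset != "all":
            raise ConfigError(f"unknown spore subset {subset!r}")
        return list(t.index[mask])


@dataclass
class Chronology:
    """Per-sample depth (cm), age (cal BP) and deposition time (yr/cm)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("depth_cm", "age_calBP", "deposition_time_yr_per_cm"):
            if col not in t.columns:
                raise FormatError(f"chronology lacks required column {col!r}")
        if t.index.duplicated().any():
            raise FormatError("duplicated sample names in chronology")
        if (t["deposition_time_yr_per_cm"] <= 0).any():
            bad = t.index[t["deposition_time_yr_per_cm"] <= 0][0]
            raise ChronologyError(f"non-positive deposition time for sample {bad!r}")
        by_depth = t.sort_values("depth_cm")
        if not by_depth["age_calBP"].is_monotonic_increasing:
            raise FormatError("age must increase strictly with depth")
        if by_depth["age_calBP"].duplicated().any():
            raise FormatError("age must increase strictly with depth (ties found)")
        self.table = t.astype(float)

    @property
    def ages(self) -> pd.Series:
        return self.table["age_calBP"]


@dataclass
class ValidationReport:
    """Report-only result of cross-checking the three input tables."""

    problems: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.problems


def validate_dataset(
    counts: CountTable, meta: TaxonMeta, chron: Chronology
) -> ValidationReport:
    """Cross-validate counts, taxon metadata and chronology.

    Side-effect free and idempotent; returns a report rather than raising, so
    callers can surface all problems at once.  Pipeline entry points refuse to
    run when ``report.ok`` is false.
    """
    problems: list[str] = []
    unmapped = [t for t in counts.taxa if t not in meta.table.index]
    problems += [f"unmapped taxon: {t!r} (present in counts, absent from metadata)"
                 for t in unmapped]
    missing_chron = [s for s in counts.samples if s not in chron.table.index]
    problems += [f"missing chronology: sample {s!r} has no age/depth entry"
                 for s in missing_chron]

    summary: dict = {"n_samples": len(counts.samples), "n_taxa": len(counts.taxa)}
    mapped_terr = [t for t in meta.terrestrial_taxa if t in counts.counts.index]
    if mapped_terr and not missing_chron:
        ts = counts.counts.loc[mapped_terr].sum(axis=0)
        summary["terrestrial_sum_min"] = int(ts.min())
        summary["terrestrial_sum_max"] = int(ts.max())
        ages = chron.table.loc[counts.samples, "age_calBP"]
        depths = chron.table.loc[counts.samples, "depth_cm"]
        if not (depths.is_monotonic_increasing or depths.is_monotonic_decreasing):
            problems.append("sample order is not monotone in depth")
        summary["age_range_calBP"] = (float(ages.min()), float(ages.max()))
    return ValidationReport(problems=problems, summary=summary)


def require_valid(counts: CountTable, meta: TaxonMeta, chron: Chronology) -> None:
    """Raise :class:`FormatError` if the dataset fails validation."""
    report = validate_dataset(counts, meta, chron)
    if not report.ok:
        raise FormatError("dataset failed validation:\n" + "\n".join(report.problems))
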