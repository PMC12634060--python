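"""Synthetic stratigraphic datasets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a four-period Holocene sequence (boundaries 6500 / 4000 / 1000 cal
BP) alternating open and closed vegetation, multinomial pollen counting
noise around a mean terrestrial sum of 450 grains, Poisson exotic-marker
spike counts, and coprophilous-spore deposition whose intensity is coupled
to landscape openness (grassland + garrigue mass) with overdispersed
(gamma-Poisson) noise.

Within each forest habitat one tree taxon dominates, while open habitats
spread their mass evenly over several herb taxa — so rarefied richness and
evenness genuinely differ between open and closed phases, as in real
Mediterranean pollen sequences.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .combustibility import PeriodConfig, assign_periods
from .io import write_chronology, write_counts, write_taxon_meta
from .model import (
    CLASSED_HABITATS,
    ConfigError,
    Chronology,
    CountTable,
    GROUP_AQUATIC,
    GROUP_SPORE,
    GROUP_TERRESTRIAL,
    HABITAT_COMBUSTIBILITY,
    OTHER_HABITAT,
    TaxonMeta,
)

#: habitat order used by the profile rows (six classed habitats + "other")
PROFILE_HABITATS: tuple[str, ...] = CLASSED_HABITATS + (OTHER_HABITAT,)

#: Default per-period expected influx shares over PROFILE_HABITATS.
#: Open (P1) - closed (P2, P3) - open (P4); closed-form expected mean
#: combustibility 3.10 / 2.68 / 2.69 / 3.33 and open-habitat share
#: (grassland + garrigue) 0.40 / 0.14 / 0.16 / 0.40.
DEFAULT_PROFILES: tuple[tuple[float, ...], ...] = (
    (0.02, 0.22, 0.06, 0.10, 0.18, 0.22, 0.20),
    (0.06, 0.12, 0.12, 0.36, 0.06, 0.08, 0.20),
    (0.08, 0.12, 0.10, 0.34, 0.07, 0.09, 0.20),
    (0.02, 0.10, 0.14, 0.14, 0.16, 0.24, 0.20),
)

_FOREST_HABITATS = ("beech_forest", "white_oak_coppice", "green_oak_coppice", "pine_forest")
_EXEMPLAR = {
    "beech_forest": "Fagus",
    "white_oak_coppice": "Quercus pubescens-type",
    "green_oak_coppice": "Quercus ilex-type",
    "pine_forest": "Pinus",
    "garrigue_heathland": "Plantago lanceolata-type",
    "grassland": "Poaceae",
    OTHER_HABITAT: "Alnus",
}
_SPORE_NAMES = (
    "Sporormiella-type",
    "Sordaria-type",
    "Podospora-type",
    "Cercophora-type",
    "Coniochaeta-type",
    "Delitschia-type",
)
_AQUATIC_NAMES = ("Cyperaceae", "Typha latifolia-type", "Myriophyllum", "Nymphaea")


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_samples: int = 80
    #: (old, young) cal BP
    age_range_calBP: tuple[float, float] = (8000.0, 0.0)
    period_boundaries_calBP: Sequence[float] = (6500.0, 4000.0, 1000.0)
    habitat_profiles: Sequence[Sequence[float]] = DEFAULT_PROFILES
    mean_terrestrial_count: float = 450.0
    min_count: int = 92
    spike_added: int = 10000
    expected_spike_counted: int = 500
    volume_cm3: float = 2.0
    deposition_time_yr_per_cm: float = 20.0
    #: expected spore influx (grains cm^-2 yr^-1) =
    #: spore_base_influx + spore_coupling * openness
    spore_base_influx: float = 3.0
    spore_coupling: float = 25.0
    spore_noise_cv: float = 0.6
    n_spore_types: int = 6
    #: pollen productivity multiplier 1 + gain * openness: open, productive
    #: grassland phases deposit more pollen per cm^2 per year
    influx_openness_gain: float = 3.0
    taxa_per_habitat: int = 4
    taxa_per_open_habitat: int = 10
    n_other_taxa: int = 5
    n_aquatic_taxa: int = 2
    mean_aquatic_count: float = 8.0

    def __post_init__(self) -> None:
        profiles = np.asarray(self.habitat_profiles, dtype=float)
        if profiles.shape != (len(self.period_boundaries_calBP) + 1, len(PROFILE_HABITATS)):
            raise ConfigError(
                "habitat_profiles must be one row per period over "
                f"{len(PROFILE_HABITATS)} habitat shares"
            )
        if np.any(np.abs(profiles.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigError("each habitat profile must sum to 1 (within 1e-9)")
        if np.any(profiles < 0):
            raise ConfigError("habitat profiles must be non-negative")
        old, young = self.age_range_calBP
        if old <= young:
            raise ConfigError("age_range_calBP must be (old, young) with old > young")
        if self.spore_coupling < 0 or self.spore_noise_cv < 0 or self.spore_base_influx < 0:
            raise ConfigError(
                "spore_base_influx, spore_coupling and spore_noise_cv must be >= 0"
            )
        self.habitat_profiles = profiles


@dataclass
class GroundTruth:
    """Exact generative quantities for every sample and period."""

    per_sample: pd.DataFrame
    period_means: dict
    profiles: np.ndarray

    def to_dict(self) -> dict:
        return {
            "per_sample": self.per_sample.reset_index().to_dict(orient="list"),
            "period_means": self.period_means,
            "profiles": self.profiles.tolist(),
            "profile_habitats": list(PROFILE_HABITATS),
        }


def expected_combustibility(profile) -> float:
    """Closed-form influx-weighted mean combustibility of a habitat profile."""
    p = np.asarray(profile, dtype=float)
    classes = np.array([HABITAT_COMBUSTIBILITY[h] for h in CLASSED_HABITATS], dtype=float)
    classed = p[: len(CLASSED_HABITATS)]
    return float(classed @ classes / classed.sum())


def openness_fraction(profile) -> float:
    """Share of the profile on open habitats (grassland + garrigue/heathland)."""
    idx = [PROFILE_HABITATS.index("grassland"), PROFILE_HABITATS.index("garrigue_heathland")]
    return float(np.asarray(profile, dtype=float)[idx].sum())


def _taxon_layout(config: SyntheticConfig):
    """Taxon names, habitat assignment and within-habitat weight vectors.

    Forest habitats hold few taxa under a steep rank-abundance curve (one
    dominant tree); open habitats hold many herb taxa under a shallow curve,
    so rarefied richness rises with the landscape's open-habitat share.
    """
    names: list[str] = []
    habitats: list[str] = []
    weights: list[np.ndarray] = []
    for hab in PROFILE_HABITATS:
        if hab in _FOREST_HABITATS:
            k, decay = config.taxa_per_habitat, 0.30
        elif hab == OTHER_HABITAT:
            k, decay = config.n_other_taxa, 0.50
        else:
            k, decay = config.taxa_per_open_habitat, 0.65
        names.append(_EXEMPLAR[hab])
        label = hab.replace("_", " ")
        names += [f"{label} assoc. {j}" for j in range(1, k)]
        habitats += [hab] * k
        w = decay ** np.arange(k)
        weights.append(w / w.sum())
    return names, habitats, np.concatenate(weights)


def generate_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[CountTable, TaxonMeta, Chronology, GroundTruth]:
    """Draw one synthetic dataset; bitwise reproducible under a fixed seed."""
    config = config or SyntheticConfig()
    ss = np.random.SeedSequence(config.seed)
    rng_counts, rng_spike, rng_gamma, rng_poisson, rng_aq = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    old, young = config.age_range_calBP
    n = config.n_samples
    ages = np.linspace(young, old, n)  # top (young) to bottom (old)
    samples = [f"S{i + 1:03d}" for i in range(n)]

    pcfg = PeriodConfig(boundaries_calBP=tuple(config.period_boundaries_calBP))
    periods = assign_periods(ages, pcfg)
    period_index = {lab: i for i, lab in enumerate(pcfg.labels)}

    names, habitats, within_w = _taxon_layout(config)
    hab_idx = np.array([PROFILE_HABITATS.index(h) for h in habitats])

    terr_counts = np.zeros((len(names), n), dtype=int)
    spike_counted = np.zeros(n)
    spore_counts = np.zeros((config.n_spore_types, n), dtype=int)
    aq_counts = np.zeros((config.n_aquatic_taxa, n), dtype=int)
    truth_rows = []

    spore_w = 1.0 / np.arange(1, config.n_spore_types + 1)
    spore_w /= spore_w.sum()

    for j in range(n):
        profile = config.habitat_profiles[period_index[periods[j]]]
        probs = profile[hab_idx] * within_w
        probs = probs / probs.sum()
        total = max(config.min_count, int(rng_counts.poisson(config.mean_terrestrial_count)))
        terr_counts[:, j] = rng_counts.multinomial(total, probs)
        aq_counts[:, j] = rng_aq.poisson(config.mean_aquatic_count, config.n_aquatic_taxa)

        open_frac = openness_fraction(profile)
        # a fixed number of pollen grains is counted per sample, so higher
        # pollen productivity shows up as fewer marker grains encountered
        productivity = 1.0 + config.influx_openness_gain * open_frac
        spike_counted[j] = max(
            1, int(rng_spike.poisson(config.expected_spike_counted / productivity))
        )

        # spore deposition couples to openness on the influx scale; the
        # expected tally follows from the realized marker ratio
        mu_flux = config.spore_base_influx + config.spore_coupling * open_frac
        if config.spore_noise_cv > 0:
            cv2 = config.spore_noise_cv**2
            g = rng_gamma.gamma(shape=1.0 / cv2, scale=cv2)
        else:
            g = 1.0
        mu_count = (
            mu_flux
            * g
            * config.deposition_time_yr_per_cm
            * config.volume_cm3
            * spike_counted[j]
            / config.spike_added
        )
        spore_counts[:, j] = rng_poisson.poisson(mu_count * spore_w)

        truth_rows.append(
            {
                "sample": samples[j],
                "age_calBP": ages[j],
                "period": periods[j],
                "expected_combustibility": expected_combustibility(profile),
                "openness": open_frac,
                "expected_spore_influx": mu_flux,
            }
        )

    spore_names = [
        _SPORE_NAMES[k] if k < len(_SPORE_NAMES) else f"Coprophilous type {k + 1}"
        for k in range(config.n_spore_types)
    ]
    aq_names = [
        _AQUATIC_NAMES[k] if k < len(_AQUATIC_NAMES) else f"Aquatic type {k + 1}"
        for k in range(config.n_aquatic_taxa)
    ]
    all_counts = pd.DataFrame(
        np.vstack([terr_counts, aq_counts, spore_counts]),
        index=names + aq_names + spore_names,
        columns=samples,
    )
    counts = CountTable(
        counts=all_counts,
        spike_counted=pd.Series(spike_counted, index=samples),
        spike_added=pd.Series(float(config.spike_added), index=samples),
        volume_cm3=pd.Series(config.volume_cm3, index=samples),
    )
    meta_df = pd.DataFrame(
        {
            "group": [GROUP_TERRESTRIAL] * len(names)
            + [GROUP_AQUATIC] * len(aq_names)
            + [GROUP_SPORE] * len(spore_names),
            "habitat": habitats + [OTHER_HABITAT] * (len(aq_names) + len(spore_names)),
            "reliable_herbivory_indicator": [False] * (len(names) + len(aq_names))
            + [k < (config.n_spore_types + 1) // 2 for k in range(config.n_spore_types)],
        },
        index=names + aq_names + spore_names,
    )
    meta_df.index.name = "taxon"
    meta = TaxonMeta(table=meta_df)

    depth = (ages - young) / config.deposition_time_yr_per_cm + 10.0
    chron = Chronology(
        table=pd.DataFrame(
            {
                "depth_cm": depth,
                "age_calBP": ages,
                "deposition_time_yr_per_cm": config.deposition_time_yr_per_cm,
            },
            index=pd.Index(samples, name="sample"),
        )
    )

    per_sample = pd.DataFrame(truth_rows).set_index("sample")
    period_means = {
        lab: expected_combustibility(config.habitat_profiles[i])
        for lab, i in period_index.items()
    }
    truth = GroundTruth(
        per_sample=per_sample,
        period_means=period_means,
        profiles=np.asarray(config.habitat_profiles),
    )
    return counts, meta, chron, truth


def write_fixture(dataset, directory: str) -> dict[str, str]:
    """Write a generated dataset as counts/taxa/chronology CSVs plus a
    ground-truth JSON; returns the paths."""
    if not directory:
        raise ConfigError("output directory path is empty")
    counts, meta, chron, truth = dataset
    os.makedirs(directory, exist_ok=True)
    paths = {
        "counts": write_counts(counts, os.path.join(directory, "counts.csv")),
        "taxa": write_taxon_meta(meta, os.path.join(directory, "taxa.csv")),
        "chronology": write_chronology(
            chron, os.path.join(directory, "chronology.csv"), counts=counts
        ),
    }
    gt_path = os.path.join(directory, "ground_truth.json")
    with open(gt_path, "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
    paths["ground_truth"] = gt_path
    return paths
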