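import numpy as np
import pandas as pd
import pytest

from firegraze import (
    Chronology,
    CountTable,
    DiversityConfig,
    SyntheticConfig,
    TaxonMeta,
    diversity_series,
    generate_dataset,
    influx_table,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset (four periods, 80 samples), shared
    read-only across tests."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_influx(default_dataset):
    counts, _meta, chron, _truth = default_dataset
    return influx_table(counts, chron)


@pytest.fixture(scope="session")
def default_diversity(default_dataset, default_influx):
    counts, meta, chron, _truth = default_dataset
    return diversity_series(counts, meta, default_influx, chron, DiversityConfig())


def make_tiny_dataset():
    """Hand-written 5-taxon x 3-sample dataset with known numbers."""
    samples = ["top", "mid", "bot"]
    counts = pd.DataFrame(
        {
            "top": [10, 15, 5, 3, 2],
            "mid": [20, 5, 0, 1, 0],
            "bot": [8, 12, 10, 0, 4],
        },
        index=["Poaceae", "Fagus", "Pinus", "Cyperaceae", "Sporormiella-type"],
    )
    ct = CountTable(
        counts=counts,
        spike_counted=pd.Series([50.0, 100.0, 25.0], index=samples),
        spike_added=pd.Series(10000.0, index=samples),
        volume_cm3=pd.Series(2.0, index=samples),
    )
    meta = TaxonMeta(
        table=pd.DataFrame(
            {
                "group": [
                    "terrestrial_pollen",
                    "terrestrial_pollen",
                    "terrestrial_pollen",
                    "aquatic_pollen",
                    "coprophilous_spore",
                ],
                "habitat": ["grassland", "beech_forest", "pine_forest", "other", "other"],
                "reliable_herbivory_indicator": [False, False, False, False, True],
            },
            index=counts.index,
        )
    )
    chron = Chronology(
        table=pd.DataFrame(
            {
                "depth_cm": [10.0, 20.0, 30.0],
                "age_calBP": [500.0, 3000.0, 7000.0],
                "deposition_time_yr_per_cm": [20.0, 20.0, 103.0],
            },
            index=pd.Index(samples, name="sample"),
        )
    )
    return ct, meta, chron


@pytest.fixture()
def tiny_dataset():
    return make_tiny_dataset()
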