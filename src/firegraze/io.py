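"""Read and write the three input tables as delimited text files.

Default dialect: UTF-8, comma-separated.  ``counts.csv`` holds taxa as rows
and samples as columns (header cell ``taxon``); the transposed orientation
(samples as rows, header cell ``sample``) is auto-detected and may carry the
spike columns inline.  Otherwise the spike data (``spike_counted``,
``spike_added``, ``volume_cm3``) travel as per-sample columns of
``chronology.csv`` or in a separate side table.
"""

from __future__ import annotations

import os
from typing import Optional

import pandas as pd

from .model import (
    Chronology,
    ConfigError,
    CountTable,
    FormatError,
    TaxonMeta,
)

SPIKE_COLUMNS = ("spike_counted", "spike_added", "volume_cm3")


def _read_table(path: str, sep: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FormatError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=sep, encoding="utf-8")
    if df.empty:
        raise FormatError(f"empty table: {path}")
    return df


def read_counts(
    path: str,
    sep: str = ",",
    spike: Optional[pd.DataFrame] = None,
) -> CountTable:
    """Read a count table, auto-detecting orientation.

    ``spike`` is an optional per-sample DataFrame (indexed by sample) with
    the columns ``spike_counted``, ``spike_added`` and ``volume_cm3``; it is
    required unless those columns are embedded in a sample-per-row file.
    """
    df = _read_table(path, sep)
    first = str(df.columns[0]).strip().lower()
    if first == "taxon":
        counts = df.set_index(df.columns[0])
        counts.index.name = "taxon"
    elif first == "sample":
        df = df.set_index(df.columns[0])
        inline = [c for c in SPIKE_COLUMNS if c in df.columns]
        if inline and spike is None:
            spike = df[inline]
        counts = df.drop(columns=inline).T
        counts.index.name = "taxon"
    else:
        raise FormatError(
            f"first header cell must be 'taxon' or 'sample', got {first!r}"
        )
    if spike is None:
        raise ConfigError(
            "spike data not found: supply spike_counted/spike_added/volume_cm3 "
            "columns inline or as a side table"
        )
    missing = [c for c in SPIKE_COLUMNS if c not in spike.columns]
    if missing:
        raise ConfigError(f"spike table lacks column(s) {missing}")
    return CountTable(
        counts=counts,
        spike_counted=spike["spike_counted"],
        spike_added=spike["spike_added"],
        volume_cm3=spike["volume_cm3"],
    )


def read_taxon_meta(path: str, sep: str = ",") -> TaxonMeta:
    df = _read_table(path, sep)
    if "taxon" not in df.columns:
        raise FormatError("taxon metadata must have a 'taxon' column")
    return TaxonMeta(table=df.set_index("taxon"))


def read_chronology(path: str, sep: str = ",") -> Chronology:
    df = _read_table(path, sep)
    if "sample" not in df.columns:
        raise FormatError("chronology must have a 'sample' column")
    df = df.set_index("sample")
    chron_cols = ["depth_cm", "age_calBP", "deposition_time_yr_per_cm"]
    missing = [c for c in chron_cols if c not in df.columns]
    if missing:
        raise FormatError(f"chronology lacks column(s) {missing}")
    return Chronology(table=df[chron_cols])


def read_dataset(
    counts_path: str,
    taxa_path: str,
    chronology_path: str,
    sep: str = ",",
) -> tuple[CountTable, TaxonMeta, Chronology]:
    """Read the full triple; spike columns are pulled from the chronology
    file when the count file does not carry them."""
    chron_df = _read_table(chronology_path, sep)
    if "sample" not in chron_df.columns:
        raise FormatError("chronology must have a 'sample' column")
    chron_df = chron_df.set_index("sample")
    spike = None
    if all(c in chron_df.columns for c in SPIKE_COLUMNS):
        spike = chron_df[list(SPIKE_COLUMNS)]
    counts = read_counts(counts_path, sep=sep, spike=spike)
    meta = read_taxon_meta(taxa_path, sep=sep)
    chron = Chronology(
        table=chron_df[["depth_cm", "age_calBP", "deposition_time_yr_per_cm"]]
    )
    return counts, meta, chron


# --- writers -----------------------------------------------------------------


def write_counts(table: CountTable, path: str, sep: str = ",") -> str:
    out = table.counts.copy()
    out.index.name = "taxon"
    out.to_csv(path, sep=sep, encoding="utf-8")
    return path


def write_taxon_meta(meta: TaxonMeta, path: str, sep: str = ",") -> str:
    out = meta.table.copy()
    out.index.name = "taxon"
    # keep the nullable class column readable as integers
    out["combustibility_class"] = out["combustibility_class"].astype("Int64")
    out.to_csv(path, sep=sep, encoding="utf-8")
    return path


def write_chronology(
    chron: Chronology, path: str, sep: str = ",", counts: Optional[CountTable] = None
) -> str:
    out = chron.table.copy()
    if counts is not None:
        out["spike_counted"] = counts.spike_counted.reindex(out.index)
        out["spike_added"] = counts.spike_added.reindex(out.index)
        out["volume_cm3"] = counts.volume_cm3.reindex(out.index)
    out.index.name = "sample"
    out.to_csv(path, sep=sep, encoding="utf-8")
    return path
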