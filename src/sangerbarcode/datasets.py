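"""Packaged data tables from the Marine Park (Brooklyn) barcoding survey.

Three small tab-separated tables ship with the package:

- ``ant_congruence.tsv`` -- 20 ant samples with their morphological and
  DNA-barcode identifications, for the congruence analysis;
- ``novel_barcodes.tsv`` -- the ledger of 12 barcodes the survey published
  as new database entries, with the closest matching taxon, the rank the
  match supported, and the marker gene;
- ``survey_counts.tsv`` -- the survey's headline tallies (sample totals
  and per-group taxon counts) used for composition and rate arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("sangerbarcode.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype=str, **kwargs)


def load_ant_congruence() -> pd.DataFrame:
    """Morphological vs barcode identifications for 20 ant samples."""
    return _read("ant_congruence.tsv")


def load_novel_barcode_ledger() -> pd.DataFrame:
    """The 12 published novel barcodes with closest taxon, rank and gene."""
    return _read("novel_barcodes.tsv")


def load_survey_counts() -> pd.DataFrame:
    """Headline survey tallies; ``count`` and ``denominator`` are integers."""
    df = _read("survey_counts.tsv")
    df["count"] = df["count"].astype(int)
    df["denominator"] = df["denominator"].astype(int)
    return df


def survey_count(df: pd.DataFrame, group: str, item: str) -> tuple[int, int]:
    """(count, denominator) for one tallied item."""
    row = df[(df["group"] == group) & (df["item"] == item)]
    if len(row) != 1:
        raise KeyError(f"no unique survey count for ({group!r}, {item!r})")
    return int(row["count"].iloc[0]), int(row["denominator"].iloc[0])
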