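"""Congruence of morphological and barcode identifications.

Identification tables name taxa in the conventional shorthand: a full
binomial ("Tetramorium caespitum"), a genus-only call ("Nylanderia sp."),
or an uncertain species comparison ("Monomorium cf. viride").  This module
parses those strings and tallies, per sample, whether the morphologist and
the barcode agree at genus and (where both reach it) species level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .taxonomy import Rank


@dataclass(frozen=True)
class ParsedName:
    genus: str
    epithet: str | None
    rank: Rank
    uncertain: bool = False  # "cf." qualifier

    def __post_init__(self) -> None:
        if (self.rank == Rank.genus) != (self.epithet is None):
            raise ValueError("genus-rank names have no epithet and vice versa")
        if self.uncertain and self.rank != Rank.species:
            raise ValueError("the cf. qualifier applies to species names only")

    def render(self) -> str:
        if self.rank == Rank.genus:
            return f"{self.genus} sp."
        qualifier = "cf. " if self.uncertain else ""
        return f"{self.genus} {qualifier}{self.epithet}"


def parse_taxon_name(text: str) -> ParsedName:
    """Parse "Genus epithet" / "Genus sp." / "Genus cf. epithet"."""
    tokens = text.split()
    if len(tokens) == 2 and tokens[1] in ("sp.", "spp."):
        return ParsedName(genus=tokens[0], epithet=None, rank=Rank.genus)
    if len(tokens) == 2:
        return ParsedName(genus=tokens[0], epithet=tokens[1], rank=Rank.species)
    if len(tokens) == 3 and tokens[1] == "cf.":
        return ParsedName(
            genus=tokens[0], epithet=tokens[2], rank=Rank.species, uncertain=True
        )
    raise ValueError(f"unparseable name: {text!r}")


@dataclass(frozen=True)
class CongruenceRecord:
    sample_id: str
    morph: ParsedName
    barcode: ParsedName
    genus_match: bool
    species_comparable: bool
    species_match: bool | None
    barcode_rank: Rank


def compare_pair(
    sample_id: str, morph: ParsedName, barcode: ParsedName
) -> CongruenceRecord:
    """Compare one sample's morphological and barcode identifications.

    Species agreement ignores the "cf." qualifier: an uncertain species
    call still names an epithet and is compared on it.
    """
    genus_match = morph.genus == barcode.genus
    comparable = morph.rank == Rank.species and barcode.rank == Rank.species
    species_match = (morph.epithet == barcode.epithet) if comparable else None
    return CongruenceRecord(
        sample_id=sample_id,
        morph=morph,
        barcode=barcode,
        genus_match=genus_match,
        species_comparable=comparable,
        species_match=species_match,
        barcode_rank=barcode.rank,
    )


def congruence_summary(records: Sequence[CongruenceRecord]) -> dict[str, int]:
    return {
        "n": len(records),
        "n_genus_match": sum(1 for r in records if r.genus_match),
        "n_barcode_genus_only": sum(
            1 for r in records if r.barcode_rank == Rank.genus
        ),
        "n_species_match": sum(1 for r in records if r.species_match),
    }


def compare_table(df: pd.DataFrame) -> list[CongruenceRecord]:
    """Compare a table with columns sample_id, morphological_id, barcode_id."""
    required = ["sample_id", "morphological_id", "barcode_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"congruence table lacks column(s) {missing}")
    return [
        compare_pair(
            row.sample_id,
            parse_taxon_name(row.morphological_id),
            parse_taxon_name(row.barcode_id),
        )
        for row in df.itertuples(index=False)
    ]


def load_congruence_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
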