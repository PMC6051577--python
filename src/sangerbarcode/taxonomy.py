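"""Taxonomy-linked reference library and rank arithmetic.

The reference library is the pipeline's stand-in for a public sequence
database: a FASTA file of marker sequences plus a tab-separated taxonomy
table that assigns every record a complete Linnaean lineage.  Identification
results escalate to coarser ranks when several equally good hits disagree at
species level, so the library also provides the lowest-common-rank
computation over a set of lineages.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

VALID_MARKERS = ("COI", "rbcL", "ITS")

_WS = re.compile(r"\s+")


def _norm(name: str) -> str:
    """Collapse internal whitespace and strip; names stay case-sensitive."""
    return _WS.sub(" ", name).strip()


class Rank(enum.IntEnum):
    """Linnaean ranks ordered from broadest (kingdom) to finest (species).

    The integer value is the depth: ``Rank.kingdom < Rank.species`` means
    kingdom is *above* (broader than) species.
    """

    kingdom = 0
    phylum = 1
    class_ = 2
    order = 3
    family = 4
    genus = 5
    species = 6

    @property
    def label(self) -> str:
        return "class" if self is Rank.class_ else self.name

    @classmethod
    def from_label(cls, label: str) -> "Rank":
        label = label.strip().lower()
        if label == "class":
            return cls.class_
        try:
            return cls[label]
        except KeyError:
            raise ValueError(f"unknown taxonomic rank: {label!r}") from None


RANKS: tuple[Rank, ...] = tuple(Rank)
RANK_LABELS: tuple[str, ...] = tuple(r.label for r in RANKS)


@dataclass(frozen=True)
class Lineage:
    """A gap-free lineage from kingdom down to a terminal rank.

    ``names[i]`` is the taxon name at depth ``i`` (kingdom first).  The
    terminal rank is implied by the number of names.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.names) <= len(RANKS):
            raise ValueError("lineage must span kingdom to at most species")
        cleaned = tuple(_norm(n) for n in self.names)
        if any(not n for n in cleaned):
            raise ValueError("lineage names must be non-empty (no gaps allowed)")
        object.__setattr__(self, "names", cleaned)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "Lineage":
        names = []
        for label in RANK_LABELS:
            value = mapping.get(label)
            if value is None or not str(value).strip():
                break
            names.append(str(value))
        # any named rank below the first gap is a violation
        deeper = [
            label
            for label in RANK_LABELS[len(names) :]
            if str(mapping.get(label) or "").strip()
        ]
        if deeper:
            raise ValueError(
                f"lineage has a gap above rank(s) {deeper}: {dict(mapping)!r}"
            )
        return cls(tuple(names))

    @property
    def terminal_rank(self) -> Rank:
        return Rank(len(self.names) - 1)

    @property
    def terminal_name(self) -> str:
        return self.names[-1]

    def name_at(self, rank: Rank) -> str | None:
        """Name at ``rank``, or None if the lineage stops above it."""
        return self.names[rank] if rank <= self.terminal_rank else None

    def truncated(self, rank: Rank) -> "Lineage":
        if rank > self.terminal_rank:
            raise ValueError("cannot truncate below the terminal rank")
        return Lineage(self.names[: rank + 1])

    def as_dict(self) -> dict[str, str]:
        return {r.label: n for r, n in zip(RANKS, self.names)}


def lowest_common_rank(lineages: Sequence[Lineage]) -> tuple[Rank, str]:
    """Deepest rank at which every lineage carries the same name.

    Walks kingdom -> species and returns the last rank where all lineages
    agree, together with the shared name.  Raises on an empty list or when
    the lineages do not even share a kingdom.
    """
    if not lineages:
        raise ValueError("lowest_common_rank requires at least one lineage")
    best: tuple[Rank, str] | None = None
    for rank in RANKS:
        names = {lin.name_at(rank) for lin in lineages}
        if len(names) != 1 or None in names:
            break
        best = (rank, next(iter(names)))
    if best is None:
        raise ValueError("lineages share no rank, not even kingdom")
    return best


@dataclass(frozen=True)
class ReferenceRecord:
    ref_id: str
    marker: str
    sequence: str
    lineage: Lineage

    def __post_init__(self) -> None:
        if self.marker not in VALID_MARKERS:
            raise ValueError(f"invalid marker {self.marker!r} for {self.ref_id}")
        seq = self.sequence.upper()
        if set(seq) - set("ACGTN"):
            raise ValueError(f"non-ACGTN characters in reference {self.ref_id}")
        if len(seq) < 100:
            raise ValueError(f"reference {self.ref_id} shorter than 100 bp")
        object.__setattr__(self, "sequence", seq)


@dataclass
class ReferenceLibrary:
    """All reference records plus the taxonomy they span."""

    records: list[ReferenceRecord]
    taxonomy: set[Lineage] = field(default_factory=set)
    total_residues_per_marker: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.ref_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate ref_id(s): {dupes}")
        if not self.taxonomy:
            self.taxonomy = {r.lineage for r in self.records}
        if not self.total_residues_per_marker:
            totals: dict[str, int] = {}
            for r in self.records:
                totals[r.marker] = totals.get(r.marker, 0) + len(r.sequence)
            self.total_residues_per_marker = totals

    def __len__(self) -> int:
        return len(self.records)

    def records_for_marker(self, marker: str) -> list[ReferenceRecord]:
        return [r for r in self.records if r.marker == marker]

    def get(self, ref_id: str) -> ReferenceRecord:
        for r in self.records:
            if r.ref_id == ref_id:
                return r
        raise KeyError(ref_id)


def load_taxonomy_table(taxonomy_path: str | Path) -> dict[str, Lineage]:
    """Read the ``ref_id<TAB>kingdom..species`` taxonomy table."""
    df = pd.read_csv(taxonomy_path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["ref_id", *RANK_LABELS]
    if list(df.columns) != expected:
        raise ValueError(
            f"taxonomy table must have columns {expected}, got {list(df.columns)}"
        )
    lineages: dict[str, Lineage] = {}
    for row in df.itertuples(index=False):
        ref_id = row.ref_id
        if ref_id in lineages:
            raise ValueError(f"duplicate taxonomy row for ref_id {ref_id}")
        mapping = dict(zip(df.columns[1:], row[1:]))
        lineages[ref_id] = Lineage.from_mapping(mapping)
    return lineages


def load_reference_library(
    fasta_path: str | Path, taxonomy_path: str | Path
) -> ReferenceLibrary:
    """Load the reference FASTA (headers ``ref_id|marker``) and taxonomy TSV.

    Every FASTA record must have a taxonomy row; a missing or duplicate
    ``ref_id`` is a hard error naming the offender.
    """
    lineages = load_taxonomy_table(taxonomy_path)
    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        try:
            ref_id, marker = rec.id.split("|", 1)
        except ValueError:
            raise ValueError(
                f"reference FASTA header {rec.id!r} is not 'ref_id|marker'"
            ) from None
        if ref_id in seen:
            raise ValueError(f"duplicate ref_id in FASTA: {ref_id}")
        seen.add(ref_id)
        if ref_id not in lineages:
            raise ValueError(f"no taxonomy row for ref_id {ref_id}")
        records.append(
            ReferenceRecord(ref_id, marker, str(rec.seq), lineages[ref_id])
        )
    if not records:
        raise ValueError("empty reference library")
    return ReferenceLibrary(records)


def write_reference_library(
    library: ReferenceLibrary, fasta_path: str | Path, taxonomy_path: str | Path
) -> None:
    with open(fasta_path, "w") as fh:
        for rec in library.records:
            fh.write(f">{rec.ref_id}|{rec.marker}\n")
            for i in range(0, len(rec.sequence), 80):
                fh.write(rec.sequence[i : i + 80] + "\n")
    rows = []
    for rec in library.records:
        row = {"ref_id": rec.ref_id}
        row.update({l: "" for l in RANK_LABELS})
        row.update(rec.lineage.as_dict())
        rows.append(row)
    pd.DataFrame(rows, columns=["ref_id", *RANK_LABELS]).to_csv(
        taxonomy_path, sep="\t", index=False
    )
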