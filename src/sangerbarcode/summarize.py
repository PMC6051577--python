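"""Biodiversity summaries over a set of identification results.

Produces the survey-style bookkeeping: taxonomic composition tables with
percentages at a chosen rank, species-level identification rates per
group, unique-haplotype counts per marker, and tallies of
native/introduced/invasive status over the distinct taxa observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .consensus import ConsensusBarcode
from .identify import (
    STATUS_EXCLUDED,
    STATUS_IDENTIFIED,
    IdentificationResult,
)
from .taxonomy import Rank

VALID_STATUSES = ("native", "introduced", "invasive")
UNRESOLVED = "unresolved"


def percent(n: int, total: int) -> float:
    """Percentage rounded half-away-from-zero to one decimal place."""
    if total == 0:
        raise ValueError("cannot take a percentage of zero samples")
    if not 0 <= n <= total:
        raise ValueError("numerator must lie in [0, total]")
    x = 100.0 * n / total
    return int(x * 10 + 0.5) / 10 if x >= 0 else -int(-x * 10 + 0.5) / 10


@dataclass
class CompositionTable:
    group: str
    rank: Rank
    rows: list[tuple[str, int, float]]  # (taxon, count, percent)
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["taxon", "count", "percent"])


def composition_table(
    results: Sequence[IdentificationResult],
    rank: Rank,
    group: str = "all",
    group_filter: Callable[[IdentificationResult], bool] | None = None,
) -> CompositionTable:
    """Tally samples per taxon name at ``rank``.

    Samples identified only above ``rank`` (e.g. a family-level assignment
    when tabulating genera) are pooled into an ``unresolved`` row.  Rows
    are sorted largest count first, ties alphabetically.
    """
    pool = [r for r in results if group_filter is None or group_filter(r)]
    if not pool:
        raise ValueError(f"no results in group {group!r}")
    counts: dict[str, int] = {}
    for r in pool:
        lineage = r.lineage
        name = lineage.name_at(rank) if lineage is not None else None
        counts[name or UNRESOLVED] = counts.get(name or UNRESOLVED, 0) + 1
    total = len(pool)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return CompositionTable(
        group=group,
        rank=rank,
        rows=[(name, n, percent(n, total)) for name, n in rows],
        total=total,
    )


def species_level_rate(
    results: Sequence[IdentificationResult],
    group_filter: Callable[[IdentificationResult], bool] | None = None,
) -> tuple[int, int, float]:
    """(n at species rank, group size, percent) for non-excluded samples."""
    pool = [
        r
        for r in results
        if r.status != STATUS_EXCLUDED
        and (group_filter is None or group_filter(r))
    ]
    if not pool:
        raise ValueError("empty group for species_level_rate")
    n = sum(
        1
        for r in pool
        if r.status == STATUS_IDENTIFIED and r.assigned_rank == Rank.species
    )
    return n, len(pool), percent(n, len(pool))


def count_unique_haplotypes(
    consensi: Iterable[ConsensusBarcode],
) -> dict[str, int]:
    """Distinct consensus sequences per marker (exact string identity).

    The per-marker counts sum to the headline haplotype count; the total
    is returned under the key ``"total"``.
    """
    seen: dict[str, set[str]] = {}
    for c in consensi:
        seen.setdefault(c.marker, set()).add(c.sequence.upper())
    out = {marker: len(seqs) for marker, seqs in sorted(seen.items())}
    out["total"] = sum(out.values())
    return out


@dataclass
class StatusLookup:
    """Taxon name (species binomial or bare genus) -> origin status."""

    statuses: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxon, status in self.statuses.items():
            if status not in VALID_STATUSES:
                raise ValueError(
                    f"invalid status {status!r} for taxon {taxon!r}; "
                    f"expected one of {VALID_STATUSES}"
                )

    @classmethod
    def from_csv(cls, path: str | Path) -> "StatusLookup":
        df = pd.read_csv(path, dtype=str)
        if list(df.columns) != ["taxon", "status"]:
            raise ValueError("status lookup must have columns taxon,status")
        statuses: dict[str, str] = {}
        for i, row in df.iterrows():
            taxon = (row["taxon"] or "").strip()
            status = (row["status"] or "").strip()
            if not taxon or status not in VALID_STATUSES:
                raise ValueError(f"malformed status row {i + 2}: {row.to_dict()}")
            statuses[taxon] = status
        return cls(statuses)

    def lookup(self, name: str) -> str:
        """Species name first, then its genus; misses are ``unknown``."""
        name = name.strip()
        if name in self.statuses:
            return self.statuses[name]
        genus = name.split()[0]
        return self.statuses.get(genus, "unknown")


def status_tally(
    results: Sequence[IdentificationResult],
    lookup: StatusLookup,
    group_filter: Callable[[IdentificationResult], bool] | None = None,
) -> dict[str, int]:
    """Counts of native/introduced/invasive/unknown over *distinct* taxa.

    Each distinct assigned taxon name (not each sample) is looked up once;
    excluded samples and samples without an assignment are ignored.
    """
    taxa = {
        r.assigned_name
        for r in results
        if r.status != STATUS_EXCLUDED
        and r.assigned_name
        and (group_filter is None or group_filter(r))
    }
    tally = {"native": 0, "introduced": 0, "invasive": 0, "unknown": 0}
    for taxon in taxa:
        tally[lookup.lookup(taxon)] += 1
    return tally


def marker_group(marker: str) -> Callable[[IdentificationResult], bool]:
    """Group filter by barcoding marker (COI: animals, rbcL: plants, ITS: fungi)."""
    return lambda r: r.marker == marker
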