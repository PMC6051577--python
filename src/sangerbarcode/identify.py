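"""Taxonomic identification of consensus barcodes against the reference library.

Each query is aligned locally (Smith-Waterman, match +1, mismatch -2, gap
open -5, gap extend -2) against every same-marker reference.  The best hit
is the one with the highest percent identity; identity ties are broken by
the lowest e-value, and if several *species* remain tied the assignment is
escalated to the lowest taxonomic rank they share.  A sample is called
``identified`` when the top identity is >= 95% and ``potential_novel``
otherwise; novel candidates are additionally screened (read quality, read
overlap, open reading frame) before they may be published.

E-values follow the Karlin-Altschul form K*m*n*exp(-lambda*S).  They are
used purely to order tied hits; their absolute calibration is irrelevant
here and the constants are fixed in :data:`KARLIN_K`/:data:`KARLIN_LAMBDA`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align
from Bio.Data import CodonTable

from .consensus import ConsensusBarcode
from .qc import SangerRead, flag_low_quality
from .taxonomy import Lineage, Rank, ReferenceLibrary, lowest_common_rank

IDENTITY_THRESHOLD = 95.0
MIN_OVERLAP = 50
KARLIN_K = 0.621
KARLIN_LAMBDA = 1.33

LOCAL_MATCH = 1.0
LOCAL_MISMATCH = -2.0
LOCAL_GAP_OPEN = -5.0  # score of the first gapped column
LOCAL_GAP_EXTEND = -2.0

#: NCBI translation table per marker; ITS is non-coding and never translated.
GENETIC_CODES = {"COI": 5, "rbcL": 1}

#: hits with an e-value above this are not reported (standard BLAST default)
EVALUE_MAX = 10.0

#: a hit must span at least this fraction of the query; ranking hits by
#: percent identity is only meaningful between alignments of comparable
#: extent, otherwise a chance 8-bp perfect match outranks a true homolog
MIN_QUERY_COVERAGE = 0.5

STATUS_IDENTIFIED = "identified"
STATUS_POTENTIAL_NOVEL = "potential_novel"
STATUS_EXCLUDED = "excluded_low_quality"


@dataclass(frozen=True)
class AlignmentHit:
    ref_id: str
    lineage: Lineage
    percent_identity: float
    alignment_length: int
    n_identical: int
    n_mismatch: int
    n_gap_columns: int
    raw_score: float
    bit_score: float
    e_value: float


@dataclass
class IdentificationResult:
    sample_id: str
    marker: str
    assigned_name: str | None
    assigned_rank: Rank | None
    status: str
    top_hits: list[AlignmentHit] = field(default_factory=list)
    tie_escalated: bool = False

    @property
    def top_identity(self) -> float | None:
        return self.top_hits[0].percent_identity if self.top_hits else None

    @property
    def lineage(self) -> Lineage | None:
        """Lineage supporting the assignment, truncated at the assigned rank."""
        if not self.top_hits or self.assigned_rank is None:
            return None
        return self.top_hits[0].lineage.truncated(self.assigned_rank)


@dataclass(frozen=True)
class NoveltyReport:
    sample_id: str
    reads_high_quality: bool
    overlap_sufficient: bool
    translation_ok: bool

    @property
    def publishable(self) -> bool:
        return self.reads_high_quality and self.overlap_sufficient and self.translation_ok


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = LOCAL_MATCH
    aligner.mismatch_score = LOCAL_MISMATCH
    aligner.open_gap_score = LOCAL_GAP_OPEN
    aligner.extend_gap_score = LOCAL_GAP_EXTEND
    return aligner


def evalue(
    raw_score: float,
    query_len: int,
    db_len: int,
    K: float = KARLIN_K,
    lam: float = KARLIN_LAMBDA,
) -> float:
    """Karlin-Altschul expected hit count K*m*n*exp(-lambda*S)."""
    if query_len < 1 or db_len < 1:
        raise ValueError("sequence and database lengths must be >= 1")
    return K * query_len * db_len * math.exp(-lam * raw_score)


def bit_score(raw_score: float, K: float = KARLIN_K, lam: float = KARLIN_LAMBDA) -> float:
    return (lam * raw_score - math.log(K)) / math.log(2.0)


def _identity_counts(a: str, b: str) -> tuple[int, int, int, int]:
    """Per-column tallies over a gapped alignment, excluding N columns.

    Returns (n_identical, n_mismatch, n_gap, n_excluded) where columns in
    which either sequence shows an N are excluded entirely: a masked base
    should neither support nor penalize identity.
    """
    ident = mism = gaps = excl = 0
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            excl += 1
        elif x == "-" or y == "-":
            gaps += 1
        elif x == y:
            ident += 1
        else:
            mism += 1
    return ident, mism, gaps, excl


def align_to_references(
    query: ConsensusBarcode, library: ReferenceLibrary
) -> list[AlignmentHit]:
    """Local alignment of one consensus against every same-marker reference.

    Percent identity is computed over alignment columns excluding those
    containing N in either sequence; hits with raw score <= 0 or an
    e-value above :data:`EVALUE_MAX` are dropped, as are alignments
    spanning less than :data:`MIN_QUERY_COVERAGE` of the query.  The
    returned list is sorted best-first (identity desc, e-value asc,
    ref_id as a stable final key).
    """
    if not query.sequence:
        raise ValueError("cannot identify an empty consensus")
    refs = library.records_for_marker(query.marker)
    if not refs:
        raise ValueError(f"no reference records for marker {query.marker!r}")
    db_len = library.total_residues_per_marker[query.marker]
    aligner = _local_aligner()
    hits: list[AlignmentHit] = []
    for ref in refs:
        aln = aligner.align(query.sequence, ref.sequence)[0]
        score = float(aln.score)
        if score <= 0:
            continue
        e_val = evalue(score, len(query.sequence), db_len)
        if e_val > EVALUE_MAX:
            continue
        a, b = str(aln[0]), str(aln[1])
        query_span = sum(1 for c in a if c != "-")
        if query_span < MIN_QUERY_COVERAGE * len(query.sequence):
            continue
        ident, mism, gaps, excl = _identity_counts(a, b)
        counted = ident + mism + gaps
        pid = 100.0 * ident / counted if counted else 0.0
        hits.append(
            AlignmentHit(
                ref_id=ref.ref_id,
                lineage=ref.lineage,
                percent_identity=pid,
                alignment_length=counted + excl,
                n_identical=ident,
                n_mismatch=mism,
                n_gap_columns=gaps,
                raw_score=score,
                bit_score=bit_score(score),
                e_value=e_val,
            )
        )
    hits.sort(key=lambda h: (-h.percent_identity, h.e_value, h.ref_id))
    return hits


def _round_identity(pid: float) -> float:
    return round(pid, 2)


def _round_evalue(e: float) -> float:
    """Two significant figures, as printed in a BLAST report."""
    return float(f"{e:.1e}")


def select_best_hit(hits: Sequence[AlignmentHit]) -> tuple[str, Rank, bool]:
    """Apply the best-hit decision rule with rank escalation on ties.

    Hits tied on rounded percent identity are re-ranked by rounded e-value;
    if the survivors name more than one species, the assignment escalates
    to the lowest rank their lineages share.
    """
    if not hits:
        raise ValueError("select_best_hit requires at least one hit")
    top_pid = max(_round_identity(h.percent_identity) for h in hits)
    tied = [h for h in hits if _round_identity(h.percent_identity) == top_pid]
    best_e = min(_round_evalue(h.e_value) for h in tied)
    tied = [h for h in tied if _round_evalue(h.e_value) == best_e]
    species = {h.lineage.name_at(Rank.species) for h in tied}
    if len(species) == 1 and None not in species:
        return next(iter(species)), Rank.species, False
    rank, name = lowest_common_rank([h.lineage for h in tied])
    return name, rank, True


def classify_identity(
    top_identity: float | None, threshold: float = IDENTITY_THRESHOLD
) -> str:
    """>= 95% identity -> identified; below it (or no hit) -> potential novel."""
    if top_identity is None:
        return STATUS_POTENTIAL_NOVEL
    return STATUS_IDENTIFIED if top_identity >= threshold else STATUS_POTENTIAL_NOVEL


def identify_sample(
    query: ConsensusBarcode,
    library: ReferenceLibrary,
    threshold: float = IDENTITY_THRESHOLD,
) -> IdentificationResult:
    """Full decision procedure for one consensus barcode."""
    hits = align_to_references(query, library)
    if not hits:
        return IdentificationResult(
            sample_id=query.sample_id,
            marker=query.marker,
            assigned_name=None,
            assigned_rank=None,
            status=STATUS_POTENTIAL_NOVEL,
        )
    name, rank, escalated = select_best_hit(hits)
    status = classify_identity(hits[0].percent_identity, threshold)
    return IdentificationResult(
        sample_id=query.sample_id,
        marker=query.marker,
        assigned_name=name,
        assigned_rank=rank,
        status=status,
        top_hits=hits[:10],
        tie_escalated=escalated,
    )


def translate_and_check(sequence: str, marker: str) -> tuple[int | None, bool]:
    """Find a reading frame free of internal stop codons.

    COI is translated with the invertebrate mitochondrial code and rbcL
    with the standard code; ITS is non-coding, so the check passes
    vacuously.  Frames 0..2 are scanned over the full sequence; a frame
    passes when no codon before the final one is a stop.  Codons
    containing N are not counted as stops.
    """
    if set(sequence) - set("ACGTN"):
        raise ValueError("sequence must be over A,C,G,T,N")
    if len(sequence) < 60:
        raise ValueError("sequence too short to frame-check (< 60 bp)")
    if marker not in GENETIC_CODES:
        return None, True
    table = CodonTable.unambiguous_dna_by_id[GENETIC_CODES[marker]]
    stops = set(table.stop_codons)
    for frame in (0, 1, 2):
        codons = [
            sequence[i : i + 3]
            for i in range(frame, len(sequence) - 2, 3)
        ]
        if not any(c in stops for c in codons[:-1]):
            return frame, True
    return None, False


def novelty_screen(
    result: IdentificationResult,
    fwd: SangerRead,
    rev: SangerRead,
    consensus: ConsensusBarcode,
    min_overlap: int = MIN_OVERLAP,
) -> NoveltyReport:
    """Screen a potential novel barcode before it may be published.

    Requires the original (pre-trim) reads so the quality flags reflect
    the full traces.  Candidates failing any check are downgraded to
    ``excluded_low_quality`` by the caller.
    """
    if result.status != STATUS_POTENTIAL_NOVEL:
        raise ValueError("novelty_screen applies only to potential_novel samples")
    reads_ok = not (flag_low_quality(fwd) or flag_low_quality(rev))
    overlap_ok = consensus.overlap_length >= min_overlap
    _, translation_ok = translate_and_check(consensus.sequence, consensus.marker)
    return NoveltyReport(
        sample_id=result.sample_id,
        reads_high_quality=reads_ok,
        overlap_sufficient=overlap_ok,
        translation_ok=translation_ok,
    )
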