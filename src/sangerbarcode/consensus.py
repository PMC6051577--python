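"""Pairwise merging of forward/reverse Sanger reads into one barcode.

The reverse read is reverse-complemented and aligned to the forward read
with a semi-global alignment (end gaps free), the aligned columns are
resolved base-by-base using the Phred scores, and the amplification
primers (M13-tailed) are trimmed from both ends of the merged sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

from Bio import Align

from .primers import PRIMERS, iupac_reverse_complement, primer_matches
from .qc import SangerRead

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_SCORE = -2.0

Support = Literal["both_agree", "conflict_resolved", "single_read"]


def reverse_complement(bases: str) -> str:
    if set(bases) - set("ACGTN"):
        raise ValueError("reverse_complement expects bases over A,C,G,T,N")
    return bases.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped alignment of two sequences plus per-column tallies."""

    aligned_query: str
    aligned_subject: str
    score: float
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    n_identical: int
    n_mismatch: int
    n_gap_columns: int

    def __len__(self) -> int:
        return len(self.aligned_query)


def _column_counts(a: str, b: str) -> tuple[int, int, int]:
    ident = mism = gaps = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            gaps += 1
        elif x == y:
            ident += 1
        else:
            mism += 1
    return ident, mism, gaps


def _semiglobal_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    if hasattr(aligner, "end_insertion_score"):
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    else:  # Biopython < 1.86 naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def overlap_align(forward: str, reverse_rc: str) -> PairwiseAlignment:
    """Semi-global alignment (end gaps free) of the oriented read pair.

    Scoring: match +1, mismatch -1, gap -2 per gapped column; terminal
    gaps in either sequence are free so the reads may overhang each other.
    """
    if not forward or not reverse_rc:
        raise ValueError("overlap_align requires two non-empty sequences")
    aln = _semiglobal_aligner().align(forward, reverse_rc)[0]
    a, b = str(aln[0]), str(aln[1])
    ident, mism, gaps = _column_counts(a, b)
    return PairwiseAlignment(
        aligned_query=a,
        aligned_subject=b,
        score=float(aln.score),
        query_interval=(0, len(forward)),
        subject_interval=(0, len(reverse_rc)),
        n_identical=ident,
        n_mismatch=mism,
        n_gap_columns=gaps,
    )


@dataclass(frozen=True)
class ConsensusBarcode:
    """Merged, primer-trimmed barcode for one sample.

    ``per_base_support`` records, per consensus position, whether both
    reads agreed there, a conflict was resolved by quality, or only one
    read covered it.
    """

    sample_id: str
    marker: str
    sequence: str
    overlap_length: int
    per_base_support: tuple[Support, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.per_base_support):
            raise ValueError("per_base_support must match sequence length")
        if self.overlap_length > len(self.sequence):
            raise ValueError("overlap_length cannot exceed consensus length")


def build_consensus(
    aln: PairwiseAlignment,
    fwd_quals: Sequence[int],
    rev_quals: Sequence[int],
    sample_id: str = "",
    marker: str = "COI",
) -> ConsensusBarcode:
    """Resolve alignment columns into a consensus sequence.

    Per column: both bases equal -> that base; a conflict -> the base with
    the higher Phred score (a called base always beats an N; an exact
    quality tie between two called bases yields N); one base against a gap
    -> the present base.  ``rev_quals`` must already be in the orientation
    of the reverse-complemented read.
    """
    a, b = aln.aligned_query, aln.aligned_subject
    n_fwd = sum(1 for c in a if c != "-")
    n_rev = sum(1 for c in b if c != "-")
    if len(fwd_quals) != n_fwd or len(rev_quals) != n_rev:
        raise ValueError("quality vectors must match the unaligned read lengths")
    seq: list[str] = []
    support: list[Support] = []
    overlap = 0
    i = j = 0
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            overlap += 1
            qx, qy = fwd_quals[i], rev_quals[j]
            if x == y:
                seq.append(x)
                support.append("both_agree")
            elif x == "N" or y == "N":
                seq.append(y if x == "N" else x)
                support.append("conflict_resolved")
            elif qx == qy:
                seq.append("N")
                support.append("conflict_resolved")
            else:
                seq.append(x if qx > qy else y)
                support.append("conflict_resolved")
            i += 1
            j += 1
        elif x != "-":
            seq.append(x)
            support.append("single_read")
            i += 1
        else:
            seq.append(y)
            support.append("single_read")
            j += 1
    if overlap == 0:
        raise ValueError("no usable overlap between the read pair")
    return ConsensusBarcode(
        sample_id=sample_id,
        marker=marker,
        sequence="".join(seq),
        overlap_length=overlap,
        per_base_support=tuple(support),
    )


def _hamming_ok(primer: str, segment: str, max_mismatch: int) -> bool:
    if len(primer) != len(segment):
        return False
    mism = 0
    for p, s in zip(primer, segment):
        if not primer_matches(p, s):
            mism += 1
            if mism > max_mismatch:
                return False
    return True


def _find_forward_primer(seq: str, primer: str, max_mismatch: int, window: int) -> int:
    """Return the cut position after the forward primer, or 0 if absent.

    Looks for the full primer at any offset within the first ``window``
    bases; failing that, for a primer *suffix* (>= 12 bp) anchored at the
    very start of the sequence, as happens when QC trimming has already
    eaten into the primer.
    """
    lp = len(primer)
    for s in range(0, max(0, min(window, len(seq)) - lp) + 1):
        if _hamming_ok(primer, seq[s : s + lp], max_mismatch):
            return s + lp
    for k in range(lp - 1, 11, -1):
        if k <= len(seq) and _hamming_ok(primer[-k:], seq[:k], max_mismatch):
            return k
    return 0


def remove_primers(
    consensus: ConsensusBarcode, marker: str | None = None, max_mismatch: int = 2
) -> ConsensusBarcode:
    """Trim the tailed forward primer and reverse-primer complement.

    Each end's terminal 60 bases are searched for its primer at up to
    ``max_mismatch`` mismatches (IUPAC-aware, substitutions only); an end
    whose primer is not found is left untouched.
    """
    marker = marker or consensus.marker
    if marker not in PRIMERS:
        raise ValueError(f"no primer pair known for marker {marker!r}")
    fwd_primer, rev_primer = PRIMERS[marker]
    seq = consensus.sequence
    start = _find_forward_primer(seq, fwd_primer, max_mismatch, window=60)
    # the 3' end carries the reverse complement of the reverse primer; a
    # truncated 3' end leaves a *prefix* of that rc anchored at the end
    rc = iupac_reverse_complement(rev_primer)
    rev_seq = seq[::-1]
    rc_rev = rc[::-1]  # searching the reversed sequence for the reversed rc
    cut = _find_forward_primer(rev_seq[: len(rev_seq) - start], rc_rev, max_mismatch, window=60)
    end = len(seq) - cut
    trimmed = seq[start:end]
    support = consensus.per_base_support[start:end]
    return replace(
        consensus,
        sequence=trimmed,
        per_base_support=support,
        overlap_length=sum(1 for s in support if s != "single_read"),
    )


def merge_pair(
    fwd: SangerRead, rev: SangerRead, sample_id: str | None = None
) -> ConsensusBarcode:
    """Orient, align and merge a QC'd read pair (primers still attached)."""
    rev_rc = reverse_complement(rev.bases)
    rev_rc_quals = tuple(reversed(rev.quals))
    aln = overlap_align(fwd.bases, rev_rc)
    return build_consensus(
        aln,
        fwd.quals,
        rev_rc_quals,
        sample_id=sample_id or fwd.sample_id,
        marker=fwd.marker,
    )
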