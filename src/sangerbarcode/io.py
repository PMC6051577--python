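"""Readers and writers for the pipeline's file formats.

Reads are exchanged as Phred+33 FASTQ with ids ``sample_id|marker|F`` /
``...|R``; stage outputs are plain TSV/CSV/JSON so every intermediate can
be inspected with standard tools.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .identify import AlignmentHit, IdentificationResult, NoveltyReport
from .qc import SangerRead, TrimReport


def _parse_read(rec, expected_direction: str) -> SangerRead:
    parts = rec.id.split("|")
    if len(parts) != 3 or parts[2] not in ("F", "R"):
        raise ValueError(
            f"FASTQ id {rec.id!r} is not of the form sample_id|marker|F/R"
        )
    sample_id, marker, tag = parts
    direction = "forward" if tag == "F" else "reverse"
    if direction != expected_direction:
        raise ValueError(
            f"read {rec.id!r} found in the {expected_direction} file"
        )
    return SangerRead(
        sample_id=sample_id,
        direction=direction,
        bases=str(rec.seq).upper(),
        quals=tuple(rec.letter_annotations["phred_quality"]),
        marker=marker,
    )


def read_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> list[tuple[SangerRead, SangerRead]]:
    """Load paired FASTQ files; pairs must appear in the same order."""
    fwd = [_parse_read(r, "forward") for r in SeqIO.parse(str(r1_path), "fastq")]
    rev = [_parse_read(r, "reverse") for r in SeqIO.parse(str(r2_path), "fastq")]
    if len(fwd) != len(rev):
        raise ValueError(
            f"unpaired FASTQ files: {len(fwd)} forward vs {len(rev)} reverse reads"
        )
    for f, r in zip(fwd, rev):
        if f.sample_id != r.sample_id:
            raise ValueError(
                f"read pair out of sync: {f.sample_id!r} vs {r.sample_id!r}"
            )
    return list(zip(fwd, rev))


def write_qc_report(
    reports: Iterable[tuple[SangerRead, TrimReport]], path: str | Path
) -> None:
    rows = [
        {
            "sample_id": read.sample_id,
            "direction": read.direction,
            "mean_phred": round(rep.mean_phred, 2),
            "low_quality": rep.low_quality,
            "kept_start": rep.kept_interval[0],
            "kept_end": rep.kept_interval[1],
            "n_masked": rep.n_masked,
        }
        for read, rep in reports
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_identifications(
    results: Iterable[IdentificationResult], path: str | Path
) -> None:
    rows = []
    for r in results:
        top = r.top_hits[0] if r.top_hits else None
        rows.append(
            {
                "sample_id": r.sample_id,
                "marker": r.marker,
                "assigned_name": r.assigned_name or "",
                "assigned_rank": r.assigned_rank.label if r.assigned_rank else "",
                "status": r.status,
                "top_percent_identity": round(top.percent_identity, 2) if top else "",
                "top_e_value": f"{top.e_value:.2e}" if top else "",
                "tie_escalated": r.tie_escalated,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_novel_candidates(
    entries: Iterable[tuple[IdentificationResult, NoveltyReport, str]],
    fasta_path: str | Path,
    sidecar_path: str | Path,
) -> None:
    """Novel-barcode FASTA plus a ledger of closest taxon, rank and gene."""
    rows = []
    with open(fasta_path, "w") as fh:
        for result, report, sequence in entries:
            if not report.publishable:
                continue
            fh.write(f">{result.sample_id}|{result.marker}\n")
            for i in range(0, len(sequence), 80):
                fh.write(sequence[i : i + 80] + "\n")
            rows.append(
                {
                    "sample_id": result.sample_id,
                    "closest_taxon": result.assigned_name or "",
                    "taxonomic_level": (
                        result.assigned_rank.label if result.assigned_rank else ""
                    ),
                    "gene": result.marker,
                }
            )
    pd.DataFrame(
        rows, columns=["sample_id", "closest_taxon", "taxonomic_level", "gene"]
    ).to_csv(sidecar_path, sep="\t", index=False)
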