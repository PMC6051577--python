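"""End-to-end pipeline: QC -> consensus -> identify -> screen -> summarize.

Every stage writes a plain-text artifact into the output directory, and a
machine-readable manifest records the configuration and per-stage record
counts.  Outputs contain no timestamps, so two runs with the same inputs
and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .congruence import compare_pair, congruence_summary, parse_taxon_name
from .consensus import ConsensusBarcode, merge_pair, remove_primers
from .identify import (
    IDENTITY_THRESHOLD,
    MIN_OVERLAP,
    STATUS_EXCLUDED,
    STATUS_POTENTIAL_NOVEL,
    IdentificationResult,
    NoveltyReport,
    identify_sample,
    novelty_screen,
)
from .io import (
    read_fastq_pairs,
    write_identifications,
    write_novel_candidates,
    write_qc_report,
)
from .qc import (
    DEFAULT_CUTOFF,
    DEFAULT_MAX_N,
    DEFAULT_TRIM_WINDOW,
    DEFAULT_WINDOW,
    qc_read,
)
from .summarize import (
    StatusLookup,
    composition_table,
    count_unique_haplotypes,
    marker_group,
    species_level_rate,
    status_tally,
)
from .taxonomy import Rank, load_reference_library

log = logging.getLogger("sangerbarcode")


@dataclass
class PipelineConfig:
    reads_r1: str
    reads_r2: str
    reference_fasta: str
    taxonomy_tsv: str
    output_dir: str
    metadata_csv: str | None = None
    status_csv: str | None = None
    morphology_tsv: str | None = None
    qc_window: int = DEFAULT_WINDOW
    qc_cutoff: float = DEFAULT_CUTOFF
    trim_window: int = DEFAULT_TRIM_WINDOW
    max_n: int = DEFAULT_MAX_N
    identity_threshold: float = IDENTITY_THRESHOLD
    min_overlap: int = MIN_OVERLAP
    seed: int = 17

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 100:
            raise ValueError("identity threshold must lie in (0, 100]")
        if min(self.qc_window, self.trim_window, self.min_overlap) < 1:
            raise ValueError("window and overlap parameters must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineRun:
    """In-memory view of one pipeline execution."""

    config: PipelineConfig
    results: list[IdentificationResult] = field(default_factory=list)
    consensi: dict[str, ConsensusBarcode] = field(default_factory=dict)
    #: one report per sample classified below the identity threshold,
    #: whether or not it survived the publication screen
    novelty_reports: dict[str, "NoveltyReport"] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


GROUP_NAMES = {"COI": "animals", "rbcL": "plants", "ITS": "fungi"}


def _summaries(results, consensi, lookup: StatusLookup | None) -> dict:
    summary: dict = {"n_samples": len(results)}
    statuses: dict[str, int] = {}
    for r in results:
        statuses[r.status] = statuses.get(r.status, 0) + 1
    summary["status_counts"] = statuses
    summary["haplotypes"] = count_unique_haplotypes(consensi.values())
    groups: dict = {}
    for marker, name in GROUP_NAMES.items():
        pool = [r for r in results if r.marker == marker]
        if not pool:
            continue
        entry: dict = {"n": len(pool)}
        try:
            n, total, pct = species_level_rate(results, marker_group(marker))
            entry["species_level"] = {"n": n, "total": total, "percent": pct}
        except ValueError:
            pass
        for rank in (Rank.family, Rank.genus):
            usable = [r for r in pool if r.status != STATUS_EXCLUDED]
            if usable:
                table = composition_table(usable, rank, group=name)
                entry[f"composition_{rank.label}"] = [
                    {"taxon": t, "count": c, "percent": p} for t, c, p in table.rows
                ]
        if lookup is not None:
            entry["status_tally"] = status_tally(results, lookup, marker_group(marker))
        groups[name] = entry
    summary["groups"] = groups
    if lookup is not None:
        summary["status_tally"] = status_tally(results, lookup)
    return summary


def _barcode_name(result: IdentificationResult) -> str | None:
    """Render an assignment as a comparable taxon-name string, if possible."""
    if result.assigned_name is None or result.assigned_rank is None:
        return None
    if result.assigned_rank == Rank.species:
        return result.assigned_name
    if result.assigned_rank == Rank.genus:
        return f"{result.assigned_name} sp."
    return None


def run_pipeline(config: PipelineConfig) -> PipelineRun:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("loading reference library")
    library = load_reference_library(config.reference_fasta, config.taxonomy_tsv)
    log.info("loaded %d reference records", len(library))
    pairs = read_fastq_pairs(config.reads_r1, config.reads_r2)
    log.info("loaded %d read pairs", len(pairs))

    qc_rows = []
    trimmed_pairs = {}
    raw_pairs = {}
    for fwd, rev in pairs:
        t_fwd, rep_fwd = qc_read(
            fwd,
            window=config.qc_window,
            cutoff=config.qc_cutoff,
            trim_window=config.trim_window,
            max_n=config.max_n,
        )
        t_rev, rep_rev = qc_read(
            rev,
            window=config.qc_window,
            cutoff=config.qc_cutoff,
            trim_window=config.trim_window,
            max_n=config.max_n,
        )
        qc_rows.extend([(fwd, rep_fwd), (rev, rep_rev)])
        trimmed_pairs[fwd.sample_id] = (t_fwd, t_rev)
        raw_pairs[fwd.sample_id] = (fwd, rev)
    write_qc_report(qc_rows, outdir / "qc_report.tsv")
    log.info("QC complete for %d read pairs", len(trimmed_pairs))

    consensi: dict[str, ConsensusBarcode] = {}
    merge_failures: list[str] = []
    for sample_id, (t_fwd, t_rev) in trimmed_pairs.items():
        try:
            merged = merge_pair(t_fwd, t_rev, sample_id=sample_id)
            consensi[sample_id] = remove_primers(merged)
        except ValueError as exc:
            log.warning("consensus failed for %s: %s", sample_id, exc)
            merge_failures.append(sample_id)
    with open(outdir / "consensus.fasta", "w") as fh:
        for sample_id, cons in consensi.items():
            fh.write(f">{sample_id}|{cons.marker}\n{cons.sequence}\n")
    log.info("built %d consensus barcodes", len(consensi))

    results: list[IdentificationResult] = []
    novel_entries = []
    novelty_reports: dict[str, NoveltyReport] = {}
    for sample_id, (fwd, rev) in raw_pairs.items():
        if sample_id not in consensi:
            results.append(
                IdentificationResult(
                    sample_id=sample_id,
                    marker=fwd.marker,
                    assigned_name=None,
                    assigned_rank=None,
                    status=STATUS_EXCLUDED,
                )
            )
            continue
        cons = consensi[sample_id]
        try:
            result = identify_sample(cons, library, config.identity_threshold)
        except ValueError as exc:
            raise RuntimeError(f"identify stage failed for {sample_id}: {exc}")
        if result.status == STATUS_POTENTIAL_NOVEL:
            report = novelty_screen(result, fwd, rev, cons, config.min_overlap)
            novelty_reports[sample_id] = report
            if report.publishable:
                novel_entries.append((result, report, cons.sequence))
            else:
                result.status = STATUS_EXCLUDED
        results.append(result)
    write_identifications(results, outdir / "identifications.tsv")
    write_novel_candidates(
        novel_entries, outdir / "novel_barcodes.fasta", outdir / "novel_barcodes.tsv"
    )
    log.info(
        "identified %d samples (%d novel candidates publishable)",
        len(results),
        len(novel_entries),
    )

    lookup = StatusLookup.from_csv(config.status_csv) if config.status_csv else None
    summary = _summaries(results, consensi, lookup)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    if config.morphology_tsv:
        morph = pd.read_csv(config.morphology_tsv, sep="\t", dtype=str)
        by_sample = {r.sample_id: r for r in results}
        records = []
        for row in morph.itertuples(index=False):
            result = by_sample.get(row.sample_id)
            name = _barcode_name(result) if result else None
            if name is None:
                continue
            records.append(
                compare_pair(
                    row.sample_id,
                    parse_taxon_name(row.morphological_id),
                    parse_taxon_name(name),
                )
            )
        cong = congruence_summary(records)
        with open(outdir / "congruence.json", "w") as fh:
            json.dump(cong, fh, indent=2, sort_keys=True)
        summary["congruence"] = cong

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "counts": {
            "read_pairs": len(pairs),
            "consensus_barcodes": len(consensi),
            "merge_failures": len(merge_failures),
            "identifications": len(results),
            "novel_publishable": len(novel_entries),
            "status_counts": summary["status_counts"],
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineRun(
        config=config,
        results=results,
        consensi=consensi,
        novelty_reports=novelty_reports,
        summary=summary,
        manifest=manifest,
    )
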