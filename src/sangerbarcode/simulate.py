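"""Synthetic barcoding study generator.

Emulates the data a field barcoding survey produces, with the statistical
structure the downstream analysis assumes: a taxonomy-linked reference
library evolved hierarchically (conspecific pairs well above 95% identity,
congeneric pairs well below), specimens drawn from that library or from
novel taxa absent from it, M13-tailed primers on both amplicon ends,
Sanger-like positional quality decay with Phred-governed miscalls, and
optional numt contaminants carrying a frameshift and an in-frame stop.

All randomness flows through one :class:`numpy.random.Generator` seeded
from ``SimulationParams.seed``; a fixed seed reproduces every file
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import reverse_complement
from .primers import PRIMERS, concrete
from .qc import SangerRead
from .taxonomy import (
    Lineage,
    ReferenceLibrary,
    ReferenceRecord,
    write_reference_library,
)

BASES = np.array(list("ACGT"))

#: kingdom and fixed higher ranks per marker (one clade per marker keeps
#: the library small while still exercising rank escalation)
MARKER_CLADES = {
    "COI": ("Animalia", "Arthropodia", "Insectia", "Simuliformes"),
    "rbcL": ("Plantae", "Tracheophytia", "Magnoliopsidia", "Simulales"),
    "ITS": ("Fungi", "Basidiomycotia", "Agaricomycetia", "Simulicales"),
}

#: quality below which the simulator writes an N instead of a base call
N_CALL_QUALITY = 3


@dataclass
class SimulationParams:
    """Study conditions for the synthetic survey.

    The specimen count and marker mix default to the surveyed community
    (187 specimens: 70 animal/COI, 116 plant/rbcL, 1 fungus/ITS); the
    divergence ladder keeps conspecific pairs ~99% identical and
    congeneric pairs ~92%, so the 95% identity rule separates them.
    """

    n_families: int = 3
    genera_per_family: int = 2
    species_per_genus: int = 2
    barcode_length: dict[str, int] = field(
        default_factory=lambda: {"COI": 650, "rbcL": 550, "ITS": 600}
    )
    conspecific_divergence: float = 0.01
    congeneric_divergence: float = 0.08
    confamilial_divergence: float = 0.18
    q_max: int = 50
    q_end: int = 8
    ramp_length: int = 40
    numt_rate: float = 0.0
    novel_taxon_rate: float = 0.1
    n_specimens: int = 187
    marker_weights: dict[str, float] = field(
        default_factory=lambda: {"COI": 70.0, "rbcL": 116.0, "ITS": 1.0}
    )
    seed: int = 17

    def validate(self) -> None:
        if self.n_families < 1 or self.genera_per_family < 1 or self.species_per_genus < 1:
            raise ValueError("taxonomy dimensions must all be >= 1")
        if not (
            self.conspecific_divergence
            < self.congeneric_divergence
            < self.confamilial_divergence
        ):
            raise ValueError(
                "divergences must strictly increase with rank distance "
                "(conspecific < congeneric < confamilial)"
            )
        if not self.conspecific_divergence < 0.05 < self.congeneric_divergence:
            raise ValueError(
                "the 95% identity rule requires conspecific divergence < 0.05 "
                "< congeneric divergence"
            )
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be >= 1")
        if not 0 <= self.novel_taxon_rate <= 1 or not 0 <= self.numt_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if not 0 <= self.q_end <= self.q_max <= 60:
            raise ValueError("need 0 <= q_end <= q_max <= 60")
        for marker, length in self.barcode_length.items():
            if length < 100:
                raise ValueError(f"barcode length for {marker} must be >= 100")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated specimen."""

    sample_id: str
    lineage: Lineage
    marker: str
    is_novel: bool
    is_numt: bool
    barcode: str  # the amplified insert (numt-corrupted when is_numt)


#: stop codons per coding marker (COI: invertebrate mitochondrial code;
#: rbcL: standard code); coding sequences evolve under purifying selection,
#: so the simulator never fixes a substitution that creates a frame-0 stop
STOP_CODONS = {"COI": {"TAA", "TAG"}, "rbcL": {"TAA", "TAG", "TGA"}}


def _random_sequence(
    length: int, rng: np.random.Generator, stops: set[str] | None = None
) -> str:
    arr = np.array(list(rng.choice(BASES, size=length)))
    if stops:
        # repair frame-0 stop codons so the ancestor has an open reading
        # frame, as a real barcode region does
        for i in range(0, length - 2, 3):
            if "".join(arr[i : i + 3]) in stops:
                arr[i] = "C"  # CAA/CAG/CGA are never stops
    return "".join(arr)


def mutate(
    sequence: str,
    rate: float,
    rng: np.random.Generator,
    stops: set[str] | None = None,
) -> str:
    """Substitute a Binomial(L, rate) number of distinct positions.

    With ``stops`` given, substitutions that would create a frame-0 stop
    codon are redrawn (or skipped if every base change creates one),
    emulating purifying selection on a coding region.
    """
    arr = np.array(list(sequence))
    n = rng.binomial(len(arr), rate)
    if n == 0:
        return sequence
    positions = rng.choice(len(arr), size=n, replace=False)
    for p in positions:
        choices = rng.permutation(BASES[BASES != arr[p]])
        for base in choices:
            if stops is not None:
                old = arr[p]
                arr[p] = base
                c = 3 * (p // 3)
                if c + 3 <= len(arr) and "".join(arr[c : c + 3]) in stops:
                    arr[p] = old
                    continue
                break
            arr[p] = base
            break
    return "".join(arr)


def simulate_reference_library(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[ReferenceLibrary, dict[str, str]]:
    """Evolve the reference library hierarchically, one clade per marker.

    Branch lengths are half the target pairwise divergence, so two taxa
    separated at a rank differ by approximately the configured rate.
    """
    params.validate()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    records: list[ReferenceRecord] = []
    ancestors: dict[str, str] = {}
    counter = 0
    for marker in ("COI", "rbcL", "ITS"):
        kingdom, phylum, class_, order = MARKER_CLADES[marker]
        prefix = marker.lower().capitalize()
        stops = STOP_CODONS.get(marker)
        ancestor = _random_sequence(params.barcode_length[marker], rng, stops)
        ancestors[marker] = ancestor
        for fi in range(params.n_families):
            family = f"{prefix}idae{fi}"
            fam_seq = mutate(ancestor, params.confamilial_divergence, rng, stops)
            for gi in range(params.genera_per_family):
                genus = f"{prefix}genus{fi}{gi}"
                gen_seq = mutate(fam_seq, params.confamilial_divergence / 2, rng, stops)
                for si in range(params.species_per_genus):
                    species = f"{genus} simulans{si}"
                    sp_seq = mutate(gen_seq, params.congeneric_divergence / 2, rng, stops)
                    lineage = Lineage(
                        (kingdom, phylum, class_, order, family, genus, species)
                    )
                    records.append(
                        ReferenceRecord(f"REF{counter:04d}", marker, sp_seq, lineage)
                    )
                    counter += 1
    return ReferenceLibrary(records), ancestors


def _quality_ramp(length: int, params: SimulationParams) -> np.ndarray:
    """Linear Phred ramp q_end -> q_max over ramp_length at both ends."""
    pos = np.arange(length, dtype=float)
    up = params.q_end + (params.q_max - params.q_end) * np.minimum(
        pos / max(params.ramp_length, 1), 1.0
    )
    down = params.q_end + (params.q_max - params.q_end) * np.minimum(
        (length - 1 - pos) / max(params.ramp_length, 1), 1.0
    )
    return np.minimum(up, down).round().astype(int)


def _sequencing_read(
    template: str,
    sample_id: str,
    direction: str,
    marker: str,
    params: SimulationParams,
    rng: np.random.Generator,
) -> SangerRead:
    quals = _quality_ramp(len(template), params)
    arr = np.array(list(template))
    p_err = 10.0 ** (-quals / 10.0)
    miscall = rng.random(len(arr)) < p_err
    for p in np.flatnonzero(miscall):
        choices = BASES[BASES != arr[p]]
        arr[p] = rng.choice(choices)
    arr[quals < N_CALL_QUALITY] = "N"
    return SangerRead(
        sample_id=sample_id,
        direction=direction,
        bases="".join(arr),
        quals=tuple(int(q) for q in quals),
        marker=marker,
    )


def _numt_corrupt(barcode: str, rng: np.random.Generator) -> str:
    """Pseudogene copy: an in-frame stop codon plus a 1-bp deletion.

    The stop (TAA, a stop in both the standard and invertebrate
    mitochondrial codes) lands on a frame-0 codon in the middle third;
    the deletion downstream shifts every later frame.
    """
    n_codons = len(barcode) // 3
    stop_codon = rng.integers(n_codons // 3, 2 * n_codons // 3)
    s = stop_codon * 3
    corrupted = barcode[:s] + "TAA" + barcode[s + 3 :]
    del_pos = int(rng.integers(s + 3, len(corrupted)))
    return corrupted[:del_pos] + corrupted[del_pos + 1 :]


def simulate_specimen_reads(
    library: ReferenceLibrary,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[SangerRead, SangerRead]], list[TruthRecord]]:
    """Draw specimens and emit a forward/reverse Sanger read pair for each.

    A specimen is either a conspecific draw from a library species or, at
    ``novel_taxon_rate``, a freshly evolved taxon at congeneric distance
    from its nearest library record (so it cannot reach 95% identity).
    numts replace the amplified template for coding markers (COI, rbcL)
    at ``numt_rate``.  Both reads span the full amplicon, which carries
    the M13-tailed primer on each end.
    """
    params.validate()
    if not library.records:
        raise ValueError("cannot simulate specimens from an empty library")
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    markers = [m for m in params.marker_weights if library.records_for_marker(m)]
    weights = np.array([params.marker_weights[m] for m in markers], dtype=float)
    weights /= weights.sum()
    pairs: list[tuple[SangerRead, SangerRead]] = []
    truths: list[TruthRecord] = []
    for i in range(params.n_specimens):
        sample_id = f"SIM-{i:04d}"
        marker = markers[rng.choice(len(markers), p=weights)]
        refs = library.records_for_marker(marker)
        source = refs[rng.integers(len(refs))]
        stops = STOP_CODONS.get(marker)
        is_novel = bool(rng.random() < params.novel_taxon_rate)
        if is_novel:
            barcode = mutate(source.sequence, params.congeneric_divergence, rng, stops)
            genus = source.lineage.names[5]
            lineage = Lineage(source.lineage.names[:6] + (f"{genus} novellus{i}",))
        else:
            barcode = mutate(source.sequence, params.conspecific_divergence, rng, stops)
            lineage = source.lineage
        is_numt = marker in ("COI", "rbcL") and bool(rng.random() < params.numt_rate)
        template = _numt_corrupt(barcode, rng) if is_numt else barcode
        fwd_primer, rev_primer = (concrete(p) for p in PRIMERS[marker])
        amplicon = fwd_primer + template + reverse_complement(rev_primer)
        fwd = _sequencing_read(amplicon, sample_id, "forward", marker, params, rng)
        rev = _sequencing_read(
            reverse_complement(amplicon), sample_id, "reverse", marker, params, rng
        )
        pairs.append((fwd, rev))
        truths.append(
            TruthRecord(
                sample_id=sample_id,
                lineage=lineage,
                marker=marker,
                is_novel=is_novel,
                is_numt=is_numt,
                barcode=template,
            )
        )
    return pairs, truths


SAMPLING_DATES = (
    "2014-07-14", "2014-07-15", "2014-07-25", "2014-07-28", "2014-07-29",
    "2014-08-04", "2015-08-04", "2015-08-05", "2015-08-10",
)
PARK_LAT, PARK_LON = 40.597, -73.921


def _write_fastq(pairs, path_r1: Path, path_r2: Path) -> None:
    def emit(fh, read: SangerRead) -> None:
        tag = "F" if read.direction == "forward" else "R"
        fh.write(f"@{read.sample_id}|{read.marker}|{tag}\n{read.bases}\n+\n")
        fh.write("".join(chr(q + 33) for q in read.quals) + "\n")

    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for fwd, rev in pairs:
            emit(f1, fwd)
            emit(f2, rev)


def truth_frame(truths: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in truths],
            "marker": [t.marker for t in truths],
            "is_novel": [t.is_novel for t in truths],
            "is_numt": [t.is_numt for t in truths],
            "family": [t.lineage.names[4] for t in truths],
            "genus": [t.lineage.names[5] for t in truths],
            "species": [t.lineage.names[6] for t in truths],
            "barcode": [t.barcode for t in truths],
        }
    )


def write_fixture_bundle(
    output_dir: str | Path, params: SimulationParams | None = None
) -> dict[str, Path]:
    """Simulate a complete study and write every pipeline input.

    Produces the reference FASTA + taxonomy TSV, the paired FASTQ files,
    a sample-metadata CSV (collection date, GPS fix, locality, field
    guess), an origin-status lookup CSV over the library's species, and
    the specimen truth table.  Deterministic for a fixed seed.
    """
    params = params or SimulationParams()
    params.validate()
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    library, _ = simulate_reference_library(params, rng)
    pairs, truths = simulate_specimen_reads(library, params, rng)

    paths = {
        "reference_fasta": outdir / "reference.fasta",
        "taxonomy_tsv": outdir / "taxonomy.tsv",
        "reads_r1": outdir / "reads_R1.fastq",
        "reads_r2": outdir / "reads_R2.fastq",
        "samples_csv": outdir / "samples.csv",
        "status_csv": outdir / "status.csv",
        "truth_csv": outdir / "truth.csv",
    }
    write_reference_library(library, paths["reference_fasta"], paths["taxonomy_tsv"])
    _write_fastq(pairs, paths["reads_r1"], paths["reads_r2"])

    meta_rows = []
    for t in truths:
        field_guess = (
            t.lineage.names[6]
            if rng.random() < 0.7 and not t.is_novel
            else f"{t.lineage.names[5]} sp."
        )
        meta_rows.append(
            {
                "sample_id": t.sample_id,
                "marker": t.marker,
                "collection_date": SAMPLING_DATES[rng.integers(len(SAMPLING_DATES))],
                "latitude": round(PARK_LAT + rng.normal(0, 0.004), 6),
                "longitude": round(PARK_LON + rng.normal(0, 0.004), 6),
                "locality": ("restored", "disturbed")[rng.integers(2)],
                "field_id": field_guess,
            }
        )
    pd.DataFrame(meta_rows).to_csv(paths["samples_csv"], index=False)

    status_rows = []
    species_names = sorted({r.lineage.names[6] for r in library.records})
    for name in species_names:
        if rng.random() < 0.6:
            status = ("native", "introduced", "invasive")[
                rng.choice(3, p=[0.5, 0.3, 0.2])
            ]
            status_rows.append({"taxon": name, "status": status})
    genera = sorted({r.lineage.names[5] for r in library.records})
    for genus in genera:
        if rng.random() < 0.3:
            status_rows.append({"taxon": genus, "status": "native"})
    pd.DataFrame(status_rows, columns=["taxon", "status"]).to_csv(
        paths["status_csv"], index=False
    )
    truth_frame(truths).to_csv(paths["truth_csv"], index=False)
    return paths
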