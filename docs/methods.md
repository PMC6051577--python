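# Methods

This note documents the models, decision rules and numerical choices
behind `sangerbarcode`, and what the synthetic-data generator does and
does not emulate.

## Quality model and read QC

A Phred score Q encodes a base-call error probability 10^(−Q/10); Q20 is
99% accuracy. QC runs three steps in order:

1. **Window masking** (`qc.window_quality_mask`, window = 18, cutoff = 20).
   A position is *called* iff at least one length-18 window containing it
   has arithmetic-mean Phred ≥ 20; reads shorter than the window are
   judged as one whole-read window. Uncalled bases become N; qualities
   are untouched, so the operation is idempotent. Two conventions were
   genuinely open here and are fixed as package choices: the window
   statistic is the mean of Phred scores (not of error probabilities,
   matching common trimming-tool practice), and a position is kept if
   *any* covering window passes — the optimistic union — because the
   all-window rule discards interior high-quality runs adjacent to one
   bad patch.
2. **Low-quality flagging** (`qc.flag_low_quality`): mean Phred of the
   *original* read < 20, computed before any masking or trimming. The
   boundary is exclusive: a mean of exactly 20 is not flagged. Flagged
   reads continue through the pipeline (they can still be identified)
   but bar their sample from novel-barcode publication.
3. **Terminal-N trimming** (`qc.trim_terminal_ns`, window = 12,
   max_n = 1): the kept interval runs from the first window holding at
   most one N to the last such window. Windows are clipped for sequences
   shorter than 12; if no window qualifies the kept interval is empty.

Masking before trimming means low-quality read ends (where Sanger traces
degrade) turn into N runs and are removed, even when the original base
caller wrote concrete bases there.

## Consensus assembly

The reverse read is reverse-complemented (its quality vector reversed)
and aligned to the forward read with a semi-global alignment — end gaps
free on both sequences — scoring match +1, mismatch −1, gap −2 per
column. The alignment engine is Biopython's `PairwiseAligner`; its scores
are verified in the test suite against an independent tabular
dynamic-programming oracle on random string pairs.

Columns are resolved per rule: agreement keeps the base; a conflict keeps
the base with the higher Phred score; an exact quality tie writes N
rather than an IUPAC ambiguity code (downstream identity computation
treats N as neutral, and the alphabet stays {A,C,G,T,N}); a called base
always beats an N, whatever the qualities, because an N is a non-call
rather than contrary evidence. Flanks covered by a single read are kept
and labelled `single_read` in the per-base support track. A pair whose
best alignment has no column with both bases present fails with "no
usable overlap".

**Primer removal.** Amplicons carry M13-tailed primers (M13F(-21)
`TGTAAAACGACGGCCAGT`, M13R(-27) `CAGGAAACAGCTATGAC`; marker cores
LCO1490/HCO2198 for COI, rbcLa-f/rbcLa-rev for rbcL, ITS1F/ITS4 for ITS).
Each end's terminal 60 bases are searched for its primer (the reverse
primer as its reverse complement) by IUPAC-aware Hamming comparison at up
to 2 mismatches, substitutions only — primers sit at read ends, so
indel-tolerant search buys nothing here. Because QC trimming routinely
eats the outermost primer bases, a primer *suffix* of ≥ 12 bases anchored
at the sequence start (and the mirrored prefix at the end) is also
recognized. Read Ns never count as primer mismatches. Absent primers
leave that end untouched; the operation is idempotent.

## Identification

Every consensus is aligned locally (Smith–Waterman: match +1, mismatch
−2, gap open −5 for the first gapped column, extend −2) against every
same-marker reference. Percent identity is computed over alignment
columns, excluding columns containing N in either sequence from both
numerator and denominator, so masked bases neither support nor penalize a
hit; a self-hit is 100% regardless of Ns.

Hits are discarded when (a) the raw score is ≤ 0, (b) the e-value exceeds
10 — the conventional BLAST reporting default — or (c) the alignment
spans less than half the query. Filter (c) is essential once hits are
*ranked by percent identity*: without it, a chance 8-bp perfect match to
an unrelated reference outranks a 99%-identity full-length homolog, an
artifact interactive BLAST use never exposes because of its seeding and
reporting thresholds.

E-values follow the Karlin–Altschul form K·m·n·e^(−λS) with K = 0.621,
λ = 1.33, m the query length and n the total same-marker residue count of
the library. They are ordering devices only; their absolute calibration
is irrelevant to any decision the pipeline makes.

**Best-hit rule.** Keep the hits with maximal percent identity (compared
after rounding to 2 decimals); among those, keep the hits with minimal
e-value (compared at 2 significant figures — both roundings mimic
comparing printed report values and avoid float-equality brittleness).
One surviving species ⇒ species-rank assignment. Several surviving
species ⇒ the assignment escalates to the deepest rank shared by all
surviving lineages (genus, family, … — the full lineage is walked, not
just the class/family/genus levels). The escalation flag is recorded.

**Threshold.** Top identity ≥ 95.0 ⇒ `identified`; < 95.0 or no
surviving hit ⇒ `potential_novel`. The boundary is inclusive at exactly
95.0.

**Novelty screen.** A potential novel barcode is publishable iff
(1) neither read is low-quality, (2) the consensus overlap is ≥ 50 bases
(the package's operationalization of "substantial overlap"; configurable),
and (3) some reading frame over the full sequence is free of internal
stop codons — COI translated with the invertebrate mitochondrial code
(NCBI table 5, where TGA is tryptophan), rbcL with the standard code
(table 1), ITS skipped as non-coding. Codons containing N are never
counted as stops. The frame check is what catches numt pseudogenes: a
frameshift or in-frame stop leaves no clean frame. Candidates failing any
check become `excluded_low_quality`.

## Summaries

Percentages are rounded half-away-from-zero to one decimal
(`summarize.percent`); one convention is applied throughout. Composition
tables count samples per taxon at a chosen rank, pooling samples
identified only above that rank into an `unresolved` row, and sort rows
largest-count-first. Species-level identification rates count
species-rank identified samples over all non-excluded group members.
Haplotypes are distinct consensus strings per marker — exact identity
after uppercasing, no alignment-aware collapsing, which is the simplest
defensible reading and makes the count reproducible. Origin-status
tallies look each *distinct* assigned taxon up by species name first,
then by genus, mapping misses to `unknown`.

## Congruence

Identification strings are parsed with the field's conventions: "Genus
epithet" (species), "Genus sp." (genus only), "Genus cf. epithet"
(species with uncertainty). The "cf." qualifier marks uncertainty but
names an epithet, so species agreement is compared ignoring it — two
"cf." calls of the same epithet agree at species level. Genus agreement
is genus-string equality; species agreement is defined only when both
names reach species rank.

## The synthetic study

`simulate` generates everything downstream stages consume, with all
randomness drawn from a single seeded NumPy generator (fixed seed ⇒
byte-identical files).

- **Reference library.** One clade per marker; a random ancestral
  sequence per marker (650 bp COI, 550 bp rbcL, 600 bp ITS — standard
  barcode lengths) evolved hierarchically into families, genera and
  species by substitution only. Branch lengths are half the target
  pairwise divergence: conspecific 1%, congeneric 8%, confamilial 18% by
  default, so the ≥ 95% identity rule cleanly separates conspecific
  (~99%) from congeneric (~92%) matches. Coding markers evolve under
  purifying selection: a substitution that would create a frame-0 stop
  codon is redrawn, since real COI/rbcL barcodes are open reading frames
  — without this the translation screen would reject everything.
- **Specimens.** 187 by default, mixing markers 70:116:1
  (COI:rbcL:ITS), i.e. an animal-and-plant-dominated community with one
  fungus. Each specimen is a conspecific draw (1% divergence) from a
  random library species or, at rate 0.1, a novel taxon evolved at
  congeneric distance from a library record — guaranteeing it cannot
  reach 95% identity against any reference. numt contaminants (rate 0 by
  default; only meaningful for coding markers) replace the amplified
  template with a pseudogene copy bearing an in-frame TAA stop in the
  middle third plus a 1-bp deletion downstream.
- **Reads.** Amplicon = tailed forward primer + template + reverse
  complement of the tailed reverse primer (primer IUPAC degeneracies
  fixed to one base for simulation). Both reads span the full amplicon —
  typical for Sanger on sub-700-bp amplicons; partial coverage is not
  modelled. Qualities ramp linearly in Phred units from q_end = 8 at the
  ends to q_max = 50 over 40 bases; miscalls occur per base with
  probability 10^(−Q/10); bases below Q3 are written as N.

What the generator does *not* emulate: chromatogram artifacts (dye blobs,
double peaks), indel sequencing errors, chimeras, contamination between
samples, heterozygous ITS copies, or reference libraries with wrong or
incomplete taxonomy. Passing recovery tests therefore demonstrates the
decision logic is implemented correctly under the stated noise model, not
that the pipeline is robust to every pathology of real trace data.

## Problem sizes and tolerances in the test suite

Oracle-equivalence tests run 500 random pairs (alignment, length ≤ 30)
and 1000 random reads (QC windows, length ≤ 100) — small enough that the
brute-force oracles are obviously correct, large enough to hit edge
configurations. The recovery tests run the full default study (187
specimens) and a 25-specimen numt study; at these sizes the pipeline
completes in well under a minute per run on one core. The recovery
thresholds (≥ 90% of clean specimens to true species, 100% of
out-of-library specimens below threshold) are the study conditions the
generator's defaults encode, not tuned values; in practice recovery at
the defaults is 100%.

## Known limitations

- The reference library requires complete lineages; records with unknown
  intermediate ranks are rejected rather than patched. How real
  public-database hits with partial lineages should escalate is left to
  the library builder.
- BLAST is replaced by exhaustive Smith–Waterman, exact but O(nm) per
  pair; the design targets desk-scale libraries (hundreds of records),
  not GenBank-scale search.
- The semi-global merge assumes the two reads overlap in their
  high-quality middles; amplicons much longer than twice the usable read
  length would merge with a gap, which the "no usable overlap" error
  reports rather than repairs.
- E-value constants are fixed, not estimated from the scoring matrix;
  only their ordering role is exercised.
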