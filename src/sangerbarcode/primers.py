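"""PCR primer constants for the three barcoding markers.

All amplification primers carry a universal M13 sequencing tail on the 5'
end: M13F(-21) on the forward primer and M13R(-27) on the reverse primer.
The amplicon therefore starts with the tailed forward primer and ends with
the reverse complement of the tailed reverse primer; both must be trimmed
before identification.
"""

from __future__ import annotations

M13F = "TGTAAAACGACGGCCAGT"
M13R = "CAGGAAACAGCTATGAC"

# marker -> (tailed forward primer, tailed reverse primer), 5'->3'
PRIMERS: dict[str, tuple[str, str]] = {
    # LCO1490 / HCO2198, the Folmer COI pair
    "COI": (
        M13F + "GGTCAACAAATCATAAAGATATTGG",
        M13R + "TAAACTTCAGGGTGACCAAAAAATCA",
    ),
    # rbcLa forward / reverse (R = A/G degeneracy)
    "rbcL": (
        M13F + "ATGTCACCACAAACAGAGACTAAAGC",
        M13R + "GTAAAATCAAGTCCACCRCG",
    ),
    # ITS1F / ITS4 for the fungal ITS region
    "ITS": (
        M13F + "CCGTAGGTGAACCTGCGG",
        M13R + "TCCTCCGCTTATTGATATGC",
    ),
}

# IUPAC degeneracy used when matching primers against called bases
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def primer_matches(primer_char: str, base: str) -> bool:
    """IUPAC-aware match of one primer position against one called base.

    An N in the read is a non-call and cannot contradict the primer, so
    it always matches.
    """
    return base == "N" or base in IUPAC.get(primer_char, "")


_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_reverse_complement(primer: str) -> str:
    """Reverse complement preserving IUPAC degeneracy codes."""
    return primer.translate(_IUPAC_COMPLEMENT)[::-1]


def concrete(primer: str) -> str:
    """Resolve IUPAC degeneracies to a fixed base (first alphabetically).

    Used by the read simulator, which needs a concrete amplicon sequence.
    """
    return "".join(IUPAC[c][0] for c in primer)
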