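"""Codon tables and small sequence helpers.

Non-degenerate site saturation needs exactly one codon per amino acid at
each saturated position.  :data:`PREFERRED_CODON` is a fixed, E. coli
codon-usage-biased choice of one codon per residue; any site may override
it in its own ``codon_for_residue`` map.  Degenerate-codon schemes
(NNK etc.) are kept only for diversity comparisons — the point of the
on-bead split-and-mix method is that it never uses them.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGT")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: One codon per amino acid, biased toward highly used E. coli codons.
PREFERRED_CODON: dict[str, str] = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}

#: Codon counts of common degenerate saturation schemes (for comparison
#: against a non-degenerate one-codon-per-residue build).
DEGENERATE_CODON_COUNTS: dict[str, int] = {
    "NNK": 32,
    "NNS": 32,
    "NNN": 64,
    "VNN": 48,
}

STOP_CODONS = frozenset(standard_dna_table.stop_codons)

#: Codon -> amino acid (stops as '*'), for hot loops.
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TO_AA.update({codon: "*" for codon in STOP_CODONS})


def aa_of(codon: str) -> str:
    """Amino acid (one letter, '*' for stop) encoded by an ACGT codon."""
    return CODON_TO_AA[codon]


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return str(Seq(seq).reverse_complement())


def translate(orf: str) -> str:
    """Translate an in-frame coding sequence (no terminal stop required)."""
    return str(Seq(orf).translate())


def is_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= DNA_ALPHABET


def codon_of(orf: str, aa_position: int) -> str:
    """Codon at a 1-based amino-acid position of an ORF."""
    start = (aa_position - 1) * 3
    return orf[start:start + 3]
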