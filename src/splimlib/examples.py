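"""Synthetic example constructs for tests, documentation and the CLI demo.

Real campaigns start from a cloned ORF; everything here is generated
in-repo so that the toolkit is exercisable without any external data.  The
default example mimics a small three-helix-bundle binder (Affibody-like):
a 58-codon ORF with four fully saturated sites at codons 10, 18, 28 and
35, a T7 promoter/RBS 5' element and a C-terminal fusion stub standing in
for a SpyCatcher-coding region.  All sequences are synthetic stand-ins,
not any published construct.
"""

from __future__ import annotations

import numpy as np

from .codons import PREFERRED_CODON, revcomp
from .design import DEFAULT_ENZYMES, SaturationSite, SaturationScheme

#: T7 promoter + spacer + ribosome binding site (standard motifs).
T7_RBS = "TAATACGACTCACTATAGGGAGACCACAACGGTTTCCCTCTAGAAATAATTTTGTTTAACTTTAAGAAGGAGATATACAT"

#: Synthetic stand-in for a C-terminal fusion-tag coding region + stop.
FUSION_STUB = "GGTAGCGGCAGCGCACATATTGTGATGGTGGATGCCTATAAACCGACCAAATAA"


def _site_free(seq: str, enzymes=DEFAULT_ENZYMES) -> bool:
    return not any(
        probe in seq
        for e in enzymes
        for probe in (e.recognition, revcomp(e.recognition))
    )


def synthetic_orf(n_codons: int, seed: int = 0, enzymes=DEFAULT_ENZYMES,
                  flank_5: str = "", flank_3: str = "") -> str:
    """Random stop-free ORF from the preferred-codon table, rejection-sampled
    until the full construct context contains no enzyme recognition site."""
    rng = np.random.default_rng(seed)
    residues = list(PREFERRED_CODON)
    for _ in range(1000):
        aa_seq = rng.choice(residues, size=n_codons)
        orf = "".join(PREFERRED_CODON[a] for a in aa_seq)
        if _site_free(flank_5 + orf + flank_3, enzymes):
            return orf
    raise RuntimeError("could not sample an enzyme-site-free ORF")


def _with_in_set_wild_type(orf: str, sites) -> str:
    """Rewrite each saturated codon so the wild-type residue belongs to the
    site's residue set (a saturated position always includes its wild type
    among the splits)."""
    from .codons import aa_of

    orf = list(orf)
    for site in sites:
        start = (site.aa_position - 1) * 3
        codon = "".join(orf[start:start + 3])
        if aa_of(codon) not in site.residues:
            orf[start:start + 3] = site.codon_for_residue[site.residues[0]]
    return "".join(orf)


def _sample_scheme(site_positions, n_codons, residues, seed) -> SaturationScheme:
    """Deterministic rejection sampling of a clean, valid scheme."""
    from .design import validate_scheme

    sites = tuple(SaturationSite(p, residues=residues) for p in site_positions)
    for attempt in range(50):
        orf = synthetic_orf(n_codons, seed=seed + 1_000_003 * attempt,
                            flank_5=T7_RBS, flank_3=FUSION_STUB)
        scheme = SaturationScheme(
            orf_sequence=_with_in_set_wild_type(orf, sites),
            sites=sites,
            fixed_5prime=T7_RBS,
            fixed_3prime=FUSION_STUB,
        )
        if _site_free(scheme.reference_construct) and validate_scheme(scheme).ok:
            return scheme
    raise RuntimeError("could not sample a clean scheme")


def example_scheme(
    site_positions: tuple[int, ...] = (10, 18, 28, 35),
    n_codons: int = 58,
    residues: tuple[str, ...] = tuple(PREFERRED_CODON),
    seed: int = 2020,
) -> SaturationScheme:
    """A fully saturated multi-site scheme on a synthetic Affibody-like ORF."""
    return _sample_scheme(site_positions, n_codons, residues, seed)


def three_codon_scheme(seed: int = 7) -> SaturationScheme:
    """Minimal three-site scheme exercising both junction chemistries.

    Sites are spaced so the first junction takes the 4-nt-overhang enzyme
    (two constant codons of room) and the second junction only fits the
    3-nt-overhang enzyme (a single intervening constant codon), mirroring
    the proximal-codon geometry the stability-stuffer design enables.
    """
    return _sample_scheme((5, 8, 10), 16, ("A", "G", "S"), seed)
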