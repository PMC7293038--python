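"""Fragment-set design for split-and-mix on-bead site-saturation libraries.

A library is assembled on beads in ``m`` attachment-rounds, one per
saturated codon, each round split into one reaction per allowed residue.
Build-up runs in the antisense direction: the first (anchor) fragment set
carries the 3'-most saturated codon together with the fixed 3' element and
a DBCO handle for covalent bead coupling; internal rounds add short
synthetic duplexes that each contribute exactly their variant codon (plus
cohesive ends) to the growing construct; the final (terminal) fragment set
carries the 5'-most codon, the fixed 5' element (promoter/RBS) and a FAM
label for monitoring assembly.

Scarlessness is achieved with Type IIs enzymes: every incoming duplex ends
in a disposable "stability stuffer" whose embedded recognition site lets
the next on-bead digestion cut the stuffer off exactly at the junction,
exposing a 5' overhang read straight from the final construct sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .codons import (
    DEGENERATE_CODON_COUNTS,
    PREFERRED_CODON,
    codon_of,
    is_dna,
    revcomp,
    translate,
)


class SchemeError(ValueError):
    """Malformed scheme input (bad characters, inconsistent fields)."""


class DesignError(RuntimeError):
    """A scheme that cannot be decomposed into a physical fragment set."""


class AssemblyError(RuntimeError):
    """In-silico digestion/ligation failed (incompatible ends, bad site)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnzymeDef:
    """A Type IIs restriction enzyme producing 5' overhangs.

    ``spacer`` is the number of bases between the 3' end of the top-strand
    recognition sequence and the top-strand cut; the bottom strand is cut
    ``overhang_length`` bases further, leaving a 5' overhang.
    """

    name: str
    recognition: str
    spacer: int
    overhang_length: int

    def __post_init__(self) -> None:
        if not is_dna(self.recognition):
            raise SchemeError(f"enzyme {self.name}: bad recognition sequence")
        if self.recognition == revcomp(self.recognition):
            raise SchemeError(f"enzyme {self.name}: recognition is palindromic")
        if self.overhang_length < 1 or self.spacer < 0:
            raise SchemeError(f"enzyme {self.name}: bad geometry")

    @property
    def site_footprint(self) -> int:
        """Bases consumed by recognition + spacer on the stuffer side."""
        return len(self.recognition) + self.spacer


ESP3I = EnzymeDef("Esp3I", "CGTCTC", spacer=1, overhang_length=4)
BSPQI = EnzymeDef("BspQI", "GCTCTTC", spacer=1, overhang_length=3)
DEFAULT_ENZYMES = (ESP3I, BSPQI)


@dataclass(frozen=True)
class SaturationSite:
    """One saturated codon: which residues it may take and with which codon."""

    aa_position: int  # 1-based codon index in the ORF
    residues: tuple[str, ...] = tuple(PREFERRED_CODON)
    codon_for_residue: dict[str, str] | None = None

    def __post_init__(self) -> None:
        residues = tuple(dict.fromkeys(self.residues))  # dedupe, keep order
        object.__setattr__(self, "residues", residues)
        if not residues:
            raise SchemeError(f"site {self.aa_position}: empty residue set")
        table = dict(self.codon_for_residue or {})
        for aa in residues:
            codon = table.setdefault(aa, PREFERRED_CODON.get(aa, ""))
            if len(codon) != 3 or not is_dna(codon):
                raise SchemeError(
                    f"site {self.aa_position}: residue {aa!r} has no valid "
                    f"non-degenerate codon ({codon!r})"
                )
            if translate(codon) != aa:
                raise SchemeError(
                    f"site {self.aa_position}: codon {codon} does not encode {aa}"
                )
        object.__setattr__(self, "codon_for_residue", table)

    @property
    def n_splits(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SaturationScheme:
    """Reference ORF, fixed flanks, saturated sites and available enzymes."""

    orf_sequence: str
    sites: tuple[SaturationSite, ...]
    fixed_5prime: str = ""
    fixed_3prime: str = ""
    enzymes: tuple[EnzymeDef, ...] = DEFAULT_ENZYMES

    def __post_init__(self) -> None:
        for label, seq in (
            ("orf_sequence", self.orf_sequence),
            ("fixed_5prime", self.fixed_5prime),
            ("fixed_3prime", self.fixed_3prime),
        ):
            if seq and not is_dna(seq):
                raise SchemeError(f"{label}: non-ACGT characters")
        if not self.orf_sequence or len(self.orf_sequence) % 3:
            raise SchemeError("orf_sequence length must be a positive multiple of 3")
        if not self.sites:
            raise SchemeError("scheme needs at least one saturated site")
        positions = [s.aa_position for s in self.sites]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise SchemeError("site positions must be strictly increasing")
        n_codons = len(self.orf_sequence) // 3
        if positions[0] < 1 or positions[-1] > n_codons:
            raise SchemeError("site position outside ORF")

    @property
    def n_rounds(self) -> int:
        return len(self.sites)

    @property
    def splits_per_round(self) -> list[int]:
        # build order is antisense: round 1 carries the last site
        return [s.n_splits for s in reversed(self.sites)]

    def codon_span(self, site: SaturationSite) -> tuple[int, int]:
        """Construct coordinates (0-based half-open) of a site's codon."""
        start = len(self.fixed_5prime) + (site.aa_position - 1) * 3
        return start, start + 3

    def wild_type_residue(self, site: SaturationSite) -> str:
        return translate(codon_of(self.orf_sequence, site.aa_position))

    @property
    def reference_construct(self) -> str:
        """Full-length wild-type assembly.

        Saturated codons are written with the site's designed codon for the
        wild-type residue (when the wild-type residue is part of the site's
        residue set), so that the reference equals the library member
        carrying wild-type residues everywhere.
        """
        construct = list(self.fixed_5prime + self.orf_sequence + self.fixed_3prime)
        for site in self.sites:
            wt = self.wild_type_residue(site)
            codon = site.codon_for_residue.get(wt)
            if codon is not None:
                start, end = self.codon_span(site)
                construct[start:end] = codon
        return "".join(construct)


@dataclass(frozen=True)
class Junction:
    """A ligation junction between two consecutive attachment-rounds."""

    round_pair: tuple[int, int]      # (earlier round, later round)
    position: int                    # construct coordinate of overhang start
    overhang: str                    # 5' overhang, read from the construct
    enzyme: EnzymeDef                # enzyme whose digestion exposes it


@dataclass(frozen=True)
class FragmentSpec:
    role: str                        # anchor | internal | terminal
    round_index: int                 # 1 = first attached
    site_position: int               # 1-based codon index
    variant_residue: str
    top_strand: str                  # as-synthesised, 5'->3', sense strand
    bottom_strand: str               # as-synthesised, 5'->3' (antisense)
    upstream_overhang: str           # 5'-side junction overhang ('' if none)
    downstream_overhang: str         # 3'-side junction overhang ('' if none)
    stuffer: str                     # removable region ('' if none)
    modifications: frozenset[str] = frozenset()

    @property
    def duplex_span(self) -> int:
        """Number of construct-axis positions covered by either strand."""
        return max(len(self.top_strand), len(self.bottom_strand))


@dataclass(frozen=True)
class LibraryDesign:
    scheme: SaturationScheme
    fragment_sets: tuple[tuple[FragmentSpec, ...], ...]  # index 0 = round 1
    junctions: tuple[Junction, ...]
    reference_construct: str

    @property
    def n_rounds(self) -> int:
        return len(self.fragment_sets)

    def fragment_for(self, round_index: int, residue: str) -> FragmentSpec:
        for frag in self.fragment_sets[round_index - 1]:
            if frag.variant_residue == residue:
                return frag
        raise KeyError(f"round {round_index}: no fragment for residue {residue!r}")


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __bool__(self) -> bool:  # empty report means valid
        return self.ok


# ---------------------------------------------------------------------------
# Diversity arithmetic
# ---------------------------------------------------------------------------

def diversity(splits_per_round: list[int]) -> int:
    """Theoretical library diversity of a split-and-mix build.

    ``n`` splits in each of ``m`` attachment-rounds give ``n**m`` variants;
    with unequal splits the diversity is the product over rounds.
    """
    if not splits_per_round:
        raise ValueError("splits_per_round must be non-empty")
    if any(int(n) != n or n < 1 for n in splits_per_round):
        raise ValueError("splits per round must be positive integers")
    out = 1
    for n in splits_per_round:
        out *= int(n)
    return out


def degenerate_comparison(scheme: SaturationScheme, codon_scheme: str = "NNK") -> float:
    """Fold-excess of codon combinations a degenerate scheme would carry.

    Ratio of ``codons_per_site ** m`` for the degenerate codon (NNK etc.)
    over the non-degenerate library's diversity.  A 4-site full-saturation
    build comes out at 32**4 / 20**4 = 6.55: the degenerate library would
    need ~6.5x more theoretical variants for the same residue coverage.
    """
    try:
        per_site = DEGENERATE_CODON_COUNTS[codon_scheme]
    except KeyError:
        raise ValueError(f"unknown degenerate codon scheme {codon_scheme!r}") from None
    ratio = 1.0
    for site in scheme.sites:
        ratio *= per_site / site.n_splits
    return ratio


# ---------------------------------------------------------------------------
# Junction planning and validation
# ---------------------------------------------------------------------------

def _constant_mask(scheme: SaturationScheme) -> list[bool]:
    mask = [True] * len(scheme.reference_construct)
    for site in scheme.sites:
        start, end = scheme.codon_span(site)
        mask[start:end] = [False] * 3
    return mask


def _plan_junctions(
    scheme: SaturationScheme,
    enzyme_per_junction: list[EnzymeDef] | None = None,
) -> list[Junction]:
    """Place one junction between each pair of consecutive sites.

    Junction ``k`` (between the fragments carrying site ``k`` and site
    ``k+1`` in construct order) is placed flush against the start of site
    ``k+1``'s codon — as close as possible to the earlier-attached fragment
    — so every internal duplex contributes only its own codon as permanent
    double-stranded sequence.  The overhang must fit entirely in constant
    sequence; by default the largest-overhang enzyme that fits is chosen.
    """
    construct = scheme.reference_construct
    m = scheme.n_rounds
    enzymes = sorted(scheme.enzymes, key=lambda e: -e.overhang_length)
    junctions: list[Junction] = []
    for k in range(m - 1):  # construct-order junction between site k and k+1
        left, right = scheme.sites[k], scheme.sites[k + 1]
        gap = scheme.codon_span(right)[0] - scheme.codon_span(left)[1]
        if enzyme_per_junction is not None:
            enzyme = enzyme_per_junction[k]
            if enzyme.overhang_length > gap:
                raise DesignError(
                    f"no junction placement between sites {left.aa_position} and "
                    f"{right.aa_position}: {enzyme.name} needs "
                    f"{enzyme.overhang_length} constant bases, only {gap} available"
                )
        else:
            enzyme = next(
                (e for e in enzymes if e.overhang_length <= gap), None
            )
            if enzyme is None:
                raise DesignError(
                    f"no junction placement possible between sites "
                    f"{left.aa_position} and {right.aa_position}: only {gap} "
                    f"constant bases between their codons"
                )
        pos = scheme.codon_span(right)[0] - enzyme.overhang_length
        overhang = construct[pos:pos + enzyme.overhang_length]
        # rounds: construct fragment k+1 is attached in round m-k, fragment
        # k+2 (construct order) in round m-k-1; the junction joins them.
        round_pair = (m - k - 1, m - k)
        junctions.append(Junction(round_pair, pos, overhang, enzyme))
    return junctions


def validate_scheme(
    scheme: SaturationScheme,
    enzyme_per_junction: list[EnzymeDef] | None = None,
) -> ValidationReport:
    """Check a scheme for physical realisability; empty report means valid.

    Errors: saturated codons closer than one constant codon apart; no
    feasible junction placement; a scheme enzyme's recognition site (either
    strand) inside constant sequence, where it would be cut during build-up;
    internal stop codons in the ORF.  Warnings: self-complementary or
    duplicated junction overhangs (possible self-/cross-ligation).
    """
    report = ValidationReport()
    protein = translate(scheme.orf_sequence)
    if "*" in protein.rstrip("*"):
        report.errors.append("ORF contains an internal stop codon")

    for a, b in itertools.pairwise(scheme.sites):
        if b.aa_position - a.aa_position < 2:
            report.errors.append(
                f"insufficient separation between sites {a.aa_position} and "
                f"{b.aa_position}: at least one constant codon is required"
            )
    if report.errors:
        return report

    construct = scheme.reference_construct
    mask = _constant_mask(scheme)
    for enzyme in scheme.enzymes:
        for probe in (enzyme.recognition, revcomp(enzyme.recognition)):
            start = construct.find(probe)
            while start != -1:
                span = range(start, start + len(probe))
                if all(mask[i] for i in span):
                    report.errors.append(
                        f"{enzyme.name} recognition site at construct position "
                        f"{start} lies in constant sequence and would be cut "
                        f"during assembly"
                    )
                start = construct.find(probe, start + 1)

    try:
        junctions = _plan_junctions(scheme, enzyme_per_junction)
    except DesignError as exc:
        report.errors.append(str(exc))
        return report

    seen: dict[str, tuple[int, int]] = {}
    for junction in junctions:
        if junction.overhang == revcomp(junction.overhang):
            report.warnings.append(
                f"junction {junction.round_pair}: overhang {junction.overhang} "
                f"is self-complementary (self-ligation possible)"
            )
        if junction.overhang in seen:
            report.warnings.append(
                f"junction {junction.round_pair}: overhang {junction.overhang} "
                f"duplicates junction {seen[junction.overhang]}"
            )
        seen.setdefault(junction.overhang, junction.round_pair)
    return report


# ---------------------------------------------------------------------------
# Decomposition into fragment sets
# ---------------------------------------------------------------------------

#: Fixed GC-balanced filler for stability stuffers, screened to contain no
#: recognition site of the built-in enzymes on either strand.
STUFFER_FILLER = "ATGCCATAGCGTGACTGGTTCACTGCAATGGCATCA"

#: Default stuffer length: makes a minimal internal duplex (3 bp codon core,
#: 4 + 3 nt cohesive ends) span 40 positions in total.
DEFAULT_STUFFER_LENGTH = 30


def _make_stuffer(enzyme: EnzymeDef, length: int) -> str:
    """Disposable stuffer ending in ``recognition + spacer`` so that the
    enzyme cuts exactly at the stuffer/construct boundary."""
    tail = enzyme.recognition + "A" * enzyme.spacer
    if length < len(tail):
        length = len(tail)
    stuffer = STUFFER_FILLER[: length - len(tail)] + tail
    return stuffer


def _screen_fragment(top: str, bottom: str, enzymes, expected: dict[str, int]) -> None:
    """Guard against stray recognition sites created at stuffer boundaries."""
    for enzyme in enzymes:
        n = 0
        for strand in (top, bottom):
            for probe in (enzyme.recognition,):
                start = strand.find(probe)
                while start != -1:
                    n += 1
                    start = strand.find(probe, start + 1)
        if n != expected.get(enzyme.name, 0):
            raise DesignError(
                f"fragment contains {n} {enzyme.name} sites, expected "
                f"{expected.get(enzyme.name, 0)}"
            )


def decompose(
    scheme: SaturationScheme,
    enzyme_per_junction: list[EnzymeDef] | None = None,
    stuffer_length: int = DEFAULT_STUFFER_LENGTH,
) -> LibraryDesign:
    """Decompose a validated scheme into per-round fragment sets.

    Returns ``m`` fragment sets in build (antisense) order.  Round 1 is the
    anchor PCR-fragment set (3'-most site, fixed 3' element, DBCO, and a
    stuffer whose embedded Type IIs site exposes the first junction on
    digestion); rounds ``2..m-1`` are internal duplex sets; round ``m`` is
    the terminal PCR-fragment set (5'-most site, fixed 5' element, FAM).
    """
    report = validate_scheme(scheme, enzyme_per_junction)
    if not report.ok:
        raise DesignError("; ".join(report.errors))

    construct = scheme.reference_construct
    m = scheme.n_rounds
    junctions = _plan_junctions(scheme, enzyme_per_junction)
    sets: list[tuple[FragmentSpec, ...]] = []

    # construct-order fragment k (0-based here) is attached in round m-k
    for k in range(m - 1, -1, -1):
        site = scheme.sites[k]
        round_index = m - k
        up = junctions[k - 1] if k > 0 else None       # 5'-side junction
        down = junctions[k] if k < m - 1 else None     # 3'-side junction
        top_start = up.position if up else 0
        top_end = down.position if down else len(construct)
        bot_end = (down.position + down.enzyme.overhang_length
                   if down else len(construct))
        c0, c1 = scheme.codon_span(site)

        frags = []
        for residue in site.residues:
            codon = site.codon_for_residue[residue]
            seg = list(construct[top_start:bot_end])
            seg[c0 - top_start:c1 - top_start] = codon
            seg = "".join(seg)
            seg_top = seg[: top_end - top_start]

            if k == m - 1:  # anchor: blunt PCR product with 5'-side stuffer
                stuffer = _make_stuffer(up.enzyme, stuffer_length) if up else ""
                top = stuffer + seg_top
                bottom = revcomp(top)
                role, mods = "anchor", frozenset({"DBCO-5prime"})
                expected = {up.enzyme.name: 1} if up else {}
            elif k == 0:  # terminal: PCR product, overhang made off-bead
                # enzyme site sits on the bottom strand, 3' of the junction,
                # so off-bead digestion leaves the construct-side piece with
                # a 5' overhang complementary to the on-bead DNA.
                stuffer = ""
                tail = ""
                if down is not None:
                    enz = down.enzyme
                    tail = "A" * enz.spacer + revcomp(enz.recognition)
                    stuffer = tail
                top = seg + tail
                bottom = revcomp(top)
                role, mods = "terminal", frozenset({"FAM-5prime"})
                expected = {down.enzyme.name: 1} if down else {}
            else:  # internal duplex with 5'-side stuffer
                stuffer = _make_stuffer(up.enzyme, stuffer_length)
                top = stuffer + seg_top
                bottom = revcomp(stuffer + seg)
                role, mods = "internal", frozenset({"phosphorylated-5prime"})
                expected = {up.enzyme.name: 1}

            _screen_fragment(top, bottom, scheme.enzymes, expected)
            frags.append(FragmentSpec(
                role=role,
                round_index=round_index,
                site_position=site.aa_position,
                variant_residue=residue,
                top_strand=top,
                bottom_strand=bottom,
                upstream_overhang=up.overhang if up else "",
                downstream_overhang=down.overhang if down else "",
                stuffer=stuffer,
                modifications=mods,
            ))
        sets.append(tuple(frags))

    return LibraryDesign(
        scheme=scheme,
        fragment_sets=tuple(sets),
        junctions=tuple(junctions),
        reference_construct=construct,
    )


# ---------------------------------------------------------------------------
# In-silico assembly (digestion + ligation bookkeeping)
# ---------------------------------------------------------------------------

@dataclass
class _Molecule:
    """A (possibly sticky-ended) duplex on an arbitrary coordinate axis.

    ``bot`` is stored as the reverse complement of the physical bottom
    strand, i.e. aligned to sense coordinates, so two paired regions match
    as plain strings exactly when the strands would hybridise.
    """

    top: str
    bot: str
    top_start: int
    bot_start: int

    @property
    def top_end(self) -> int:
        return self.top_start + len(self.top)

    @property
    def bot_end(self) -> int:
        return self.bot_start + len(self.bot)

    def check_paired(self) -> None:
        lo = max(self.top_start, self.bot_start)
        hi = min(self.top_end, self.bot_end)
        if self.top[lo - self.top_start:hi - self.top_start] != \
                self.bot[lo - self.bot_start:hi - self.bot_start]:
            raise AssemblyError("strands are not complementary where paired")


def _find_cuts(mol: _Molecule, enzyme: EnzymeDef) -> list[tuple[int, int]]:
    """All (top_cut, bot_cut) coordinate pairs for an enzyme, both strands."""
    cuts = []
    start = mol.top.find(enzyme.recognition)
    while start != -1:  # site on top strand: cuts downstream (3'-ward)
        top_cut = mol.top_start + start + enzyme.site_footprint
        cuts.append((top_cut, top_cut + enzyme.overhang_length))
        start = mol.top.find(enzyme.recognition, start + 1)
    probe = revcomp(enzyme.recognition)
    start = mol.bot.find(probe)
    while start != -1:  # site on bottom strand: cuts upstream in sense coords
        bot_cut = mol.bot_start + start - enzyme.spacer
        cuts.append((bot_cut - enzyme.overhang_length, bot_cut))
        start = mol.bot.find(probe, start + 1)
    return cuts


def _digest(mol: _Molecule, enzyme: EnzymeDef) -> tuple[_Molecule, _Molecule]:
    """Cut at the enzyme's unique site, returning (left, right) pieces."""
    cuts = _find_cuts(mol, enzyme)
    if len(cuts) != 1:
        raise AssemblyError(
            f"{enzyme.name}: expected exactly one cut site, found {len(cuts)}"
        )
    top_cut, bot_cut = cuts[0]
    left = _Molecule(
        top=mol.top[: top_cut - mol.top_start],
        bot=mol.bot[: bot_cut - mol.bot_start],
        top_start=mol.top_start,
        bot_start=mol.bot_start,
    )
    right = _Molecule(
        top=mol.top[top_cut - mol.top_start:],
        bot=mol.bot[bot_cut - mol.bot_start:],
        top_start=top_cut,
        bot_start=bot_cut,
    )
    return left, right


def _ligate(left: _Molecule, right: _Molecule) -> _Molecule:
    """Join two duplexes across complementary 5' overhangs."""
    if left.top_end != right.top_start or left.bot_end != right.bot_start:
        raise AssemblyError("ends are not compatible for ligation")
    joined = _Molecule(
        top=left.top + right.top,
        bot=left.bot + right.bot,
        top_start=left.top_start,
        bot_start=left.bot_start,
    )
    joined.check_paired()  # includes the annealed overhang region
    return joined


def _fragment_molecule(frag: FragmentSpec, top_start: int) -> _Molecule:
    """Place an as-synthesised fragment on the construct coordinate axis."""
    # all as-synthesised fragments are blunt at their far end, so the two
    # strands share a start coordinate; any 5' overhang shows up as the
    # bottom strand extending further on the construct axis.
    bot_sense = revcomp(frag.bottom_strand)
    mol = _Molecule(frag.top_strand, bot_sense, top_start, top_start)
    mol.check_paired()
    return mol


def in_silico_assemble(design: LibraryDesign, variant: list[str] | str) -> str:
    """Assemble one library member fragment-by-fragment, in build order.

    ``variant`` gives one residue per site in construct (N- to C-terminal)
    order.  Each round digests the on-bead DNA (removing the previous
    stuffer and exposing the junction overhang) and ligates the selected
    fragment; the terminal fragment is digested off-bead first.  Returns
    the fully double-stranded top strand of the final molecule.
    """
    scheme = design.scheme
    m = design.n_rounds
    variant = list(variant)
    if len(variant) != m:
        raise ValueError(f"variant must name {m} residues")
    for residue, site in zip(variant, scheme.sites):
        if residue not in site.residues:
            raise ValueError(
                f"residue {residue!r} not in site {site.aa_position}'s set"
            )

    # round r attaches construct-order fragment k = m - r (0-based)
    def frag_for_round(r: int) -> FragmentSpec:
        return design.fragment_for(r, variant[m - r])

    anchor = frag_for_round(1)
    anchor_start = (design.junctions[-1].position - len(anchor.stuffer)
                    if m > 1 else 0)
    bead = _fragment_molecule(anchor, anchor_start)

    for r in range(2, m + 1):
        frag = frag_for_round(r)
        k = m - r
        # junctions[k] joins rounds (r-1, r); its enzyme site sits in the
        # stuffer of the previously attached fragment, so on-bead digestion
        # with it trims that stuffer and exposes the junction overhang.
        junction = design.junctions[k]
        _stuffer_piece, bead = _digest(bead, junction.enzyme)
        if frag.role == "internal":
            incoming_start = design.junctions[k - 1].position - len(frag.stuffer)
        else:  # terminal
            incoming_start = 0
        mol = _fragment_molecule(frag, incoming_start)
        if frag.role == "terminal" and frag.stuffer:
            # terminal fragments receive their cohesive end off-bead
            mol, _tail = _digest(mol, junction.enzyme)
        bead = _ligate(mol, bead)

    bead.check_paired()
    if bead.top_start != bead.bot_start or bead.top_end != bead.bot_end:
        raise AssemblyError("final molecule is not fully double-stranded")
    return bead.top


# ---------------------------------------------------------------------------
# Order sheet
# ---------------------------------------------------------------------------

def emit_order_sheet(design: LibraryDesign) -> pd.DataFrame:
    """One row per physical oligo: name, round, split, sequence 5'->3',
    5' modification and phosphorylation requirement.

    Internal duplexes emit a top- and a bottom-strand row whose annealed
    product reproduces the fragment including its cohesive ends.  PCR-made
    fragments (anchor, terminal) likewise emit both strands of the full
    product, with the bead-coupling (DBCO) and monitoring (FAM) labels on
    the appropriate 5' ends.
    """
    rows = []
    for frag_set in design.fragment_sets:
        for frag in frag_set:
            base = f"r{frag.round_index}_{frag.role}_pos{frag.site_position}"
            split = frag.variant_residue
            phos = "phosphorylated-5prime" in frag.modifications
            if frag.role == "anchor":
                top_mod, bot_mod = "", "DBCO"
            elif frag.role == "terminal":
                top_mod, bot_mod = "FAM", ""
            else:
                top_mod = bot_mod = ""
            rows.append({
                "name": f"{base}_{split}_top", "round": frag.round_index,
                "split": split, "strand": "top",
                "sequence": frag.top_strand, "mod5": top_mod, "phos": phos,
            })
            rows.append({
                "name": f"{base}_{split}_bottom", "round": frag.round_index,
                "split": split, "strand": "bottom",
                "sequence": frag.bottom_strand, "mod5": bot_mod, "phos": phos,
            })
    return pd.DataFrame(rows)
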