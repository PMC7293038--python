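"""Stochastic simulation of the split-and-mix bead process, closed-form
sampling calculators, and a synthetic amplicon-read generator.

The bead model: every bead starts densely coated with ``D`` identical DNA
molecules.  Each attachment-round the bead pool is split uniformly at
random over the round's ligation reactions (this fixes one residue of the
bead's genotype), every molecule on the bead independently either advances
(digestion succeeded and the incoming fragment ligated) or becomes
permanently truncated, and a fraction of beads is lost to washing.  All
full-length molecules on one bead encode the same variant — monoclonality
is a property of the construction, not an assumption.

Molecule-state bookkeeping is expectation-scaled by default (``D`` is tens
of millions; per-molecule sampling is switched on automatically below
``exact_molecule_threshold``), while bead counts, split assignments and
bead losses are always sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class BeadExhaustionError(RuntimeError):
    """All beads were lost before the build completed."""


# ---------------------------------------------------------------------------
# Parameters and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimParams:
    """Split-and-mix process parameters.

    Defaults reflect a typical campaign: ~2e7 DNA molecules coupled per
    bead, on-bead digestion efficiency of 0.94 per round, effectively
    complete ligation, and 80% bead retention per round of washing.
    """

    n_beads_start: int
    molecules_per_bead: int = 20_000_000
    p_cut: float = 0.94
    p_lig: float = 1.0
    bead_retention_per_round: float = 0.80
    junction_indel_prob: float = 0.0
    substitution_prob_per_base: float = 0.0
    seed: int = 0
    exact_molecule_threshold: int = 10_000

    def __post_init__(self) -> None:
        for name in ("p_cut", "p_lig", "bead_retention_per_round",
                     "junction_indel_prob", "substitution_prob_per_base"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_beads_start < 1:
            raise ValueError("n_beads_start must be >= 1")


@dataclass
class BeadPopulation:
    """Simulated bead pool after a completed build.

    ``genotypes`` has one row per surviving bead and one column per round
    (split index chosen that round).  ``molecule_tally`` columns are
    ``[full_length, error_bearing, truncated_round_1..m]`` and sum to
    ``molecules_per_bead`` in every row.
    """

    genotypes: np.ndarray            # (n_beads, m) int16
    molecule_tally: np.ndarray       # (n_beads, m + 2) float64
    splits_per_round: tuple[int, ...]
    params: SimParams
    beads_per_round: tuple[int, ...] = ()   # bead count after each round

    @property
    def n_beads(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_rounds(self) -> int:
        return self.genotypes.shape[1]

    @property
    def full_length_fraction(self) -> float:
        """Mean fraction of molecules per bead that completed error-free."""
        d = self.params.molecules_per_bead
        return float(self.molecule_tally[:, 0].mean() / d) if self.n_beads else 0.0

    def variant_codes(self) -> np.ndarray:
        """Mixed-radix encoding of each bead's genotype (0..V-1)."""
        codes = np.zeros(self.n_beads, dtype=np.int64)
        for r, n in enumerate(self.splits_per_round):
            codes = codes * n + self.genotypes[:, r]
        return codes


@dataclass(frozen=True)
class OccupancySummary:
    """Poisson loading of beads (or DNA) into droplets at mean occupancy λ."""

    lam: float
    empty_fraction: float
    single_fraction: float
    monoclonal_fraction_of_occupied: float


# ---------------------------------------------------------------------------
# Split-and-mix simulation
# ---------------------------------------------------------------------------

def run_split_mix(splits_per_round, params: SimParams) -> BeadPopulation:
    """Simulate an ``m``-round build with ``splits_per_round[r]`` splits.

    Deterministic under a fixed ``params.seed``.  Raises
    :class:`BeadExhaustionError` if washing losses consume every bead.
    """
    splits = tuple(int(n) for n in splits_per_round)
    if not splits or any(n < 1 for n in splits):
        raise ValueError("splits_per_round must be positive integers")
    m = len(splits)
    rng = np.random.default_rng(params.seed)
    exact = params.molecules_per_bead <= params.exact_molecule_threshold

    if max(splits) > np.iinfo(np.int16).max:
        raise ValueError("more than 32767 splits in a round is not supported")
    n = params.n_beads_start
    genotypes = np.empty((n, m), dtype=np.int16)
    beads_per_round = []
    d = params.molecules_per_bead
    if exact:
        surviving = np.full(n, d, dtype=np.int64)
        truncated = np.zeros((n, m), dtype=np.int64)

    # expectation-mode running fractions (identical for every bead)
    frac_surviving = 1.0
    frac_trunc = np.zeros(m)

    for r in range(m):
        if n == 0:
            raise BeadExhaustionError(
                f"no beads remaining before round {r + 1}"
            )
        genotypes[:n, r] = rng.integers(0, splits[r], size=n)
        # molecule advancement: round 1 is attachment (ligation-like only),
        # later rounds require digestion then ligation
        p_adv = params.p_lig if r == 0 else params.p_cut * params.p_lig
        if exact:
            advanced = rng.binomial(surviving[:n], p_adv)
            truncated[:n, r] = surviving[:n] - advanced
            surviving[:n] = advanced
        else:
            frac_trunc[r] = frac_surviving * (1.0 - p_adv)
            frac_surviving *= p_adv
        # washing losses
        n_next = int(rng.binomial(n, params.bead_retention_per_round))
        if n_next < n:
            keep = rng.permutation(n)[:n_next]
            genotypes[:n_next] = genotypes[keep]
            if exact:
                surviving[:n_next] = surviving[keep]
                truncated[:n_next] = truncated[keep]
        n = n_next
        beads_per_round.append(n)

    if n == 0:
        raise BeadExhaustionError("no beads remaining after the final round")

    genotypes = genotypes[:n].copy()
    # junction errors can occur at each of the m-1 ligation junctions
    p_clean = (1.0 - params.junction_indel_prob) ** max(m - 1, 0)
    tally = np.empty((n, m + 2), dtype=np.float64)
    if exact:
        complete = surviving[:n]
        clean = rng.binomial(complete, p_clean)
        tally[:, 0] = clean
        tally[:, 1] = complete - clean
        tally[:, 2:] = truncated[:n]
    else:
        tally[:, 0] = d * frac_surviving * p_clean
        tally[:, 1] = d * frac_surviving * (1.0 - p_clean)
        tally[:, 2:] = d * frac_trunc

    return BeadPopulation(
        genotypes=genotypes,
        molecule_tally=tally,
        splits_per_round=splits,
        params=params,
        beads_per_round=tuple(beads_per_round),
    )


def coverage_summary(pop: BeadPopulation, V: int | None = None):
    """Fraction of the theoretical variants carried by at least one bead.

    Returns ``(coverage_fraction, per_variant_bead_counts)``; counts are a
    length-``V`` array indexed by mixed-radix variant code.
    """
    if V is None:
        V = math.prod(pop.splits_per_round)
    if V < 1:
        raise ValueError("V must be >= 1")
    if pop.n_beads == 0:
        return 0.0, np.zeros(V, dtype=np.int64)
    counts = np.bincount(pop.variant_codes(), minlength=V)
    return float((counts > 0).sum() / V), counts


def coverage_closed_form(N: int, V: int) -> float:
    """Expected coverage when ``N`` independent uniform draws sample a
    ``V``-variant library: ``1 - (1 - 1/V)**N``."""
    if V < 1:
        raise ValueError("V must be >= 1")
    if N < 0:
        raise ValueError("N must be >= 0")
    return -math.expm1(N * math.log1p(-1.0 / V)) if V > 1 else (1.0 if N else 0.0)


# ---------------------------------------------------------------------------
# Closed-form calculators
# ---------------------------------------------------------------------------

def poisson_occupancy(lam: float) -> OccupancySummary:
    """Poisson droplet/bead occupancy at mean loading ``lam``.

    ``empty = exp(-λ)``; ``single = λ·exp(-λ)``; the monoclonal fraction of
    occupied compartments is ``single / (1 - empty)`` (→ 1 as λ → 0).
    Keeping ~80% of compartments empty (λ ≈ 0.22) is the classical price of
    mostly-monoclonal random loading.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    empty = math.exp(-lam)
    single = lam * empty
    occupied = -math.expm1(-lam)
    mono = single / occupied if occupied > 0 else 1.0
    return OccupancySummary(lam, empty, single, mono)


def sequencing_depth(n_reads: int, V: int) -> float:
    """Reads per theoretical library member."""
    if V < 1:
        raise ValueError("V must be >= 1")
    return n_reads / V


def expected_bead_count(freq: float, beads_sampled: int) -> float:
    """Expected number of physical beads carrying a variant of given
    library frequency in a sampled bead pool."""
    if not 0.0 <= freq <= 1.0:
        raise ValueError("freq must be in [0, 1]")
    return freq * beads_sampled


def screening_capacity(events_per_second: int, duration_s: int,
                       oversampling: float) -> float:
    """Maximum library diversity screenable in one sorter session:
    total events divided by the oversampling factor."""
    if oversampling <= 0:
        raise ValueError("oversampling must be > 0")
    return events_per_second * duration_s / oversampling


# ---------------------------------------------------------------------------
# Synthetic amplicon reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmpliconSite:
    nt_start: int                   # 0-based start of the codon on the amplicon
    codon_for_residue: dict[str, str]

    @property
    def wild_type_region(self) -> range:
        return range(self.nt_start, self.nt_start + 3)


@dataclass(frozen=True)
class ReadErrorModel:
    """Per-read error injection for the synthetic sequencer.

    ``indel_rate`` is the probability a read receives one 1-bp insertion
    or deletion; ``junction_bias`` multiplies the indel placement weight
    within ±6 bp of each saturated codon, emulating the elevated indel
    incidence near ligation junctions.
    """

    indel_rate: float = 0.0
    subst_rate: float = 0.0
    truncation_rate: float = 0.0
    junction_bias: float = 1.0
    bias_window: int = 6
    #: indels are only injected at least this far from the end of the read
    #: window — a terminal indel is indistinguishable from a truncation
    edge_margin: int = 6


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    genotype: tuple[str, ...]
    indel: tuple[int, str] | None    # (reference position, 'ins'|'del')
    n_substitutions: int
    truncated: bool

    def to_fastq(self, quality_char: str = "I") -> str:
        return (f"@{self.read_id}\n{self.sequence}\n+\n"
                f"{quality_char * len(self.sequence)}\n")


def amplicon_from_scheme(scheme, flank: int = 30):
    """Reference amplicon spanning every saturated codon, with site specs.

    Returns ``(ref_amplicon, amplicon_sites, wild_type_codons)``.  The
    amplicon is the wild-type construct from ``flank`` bases before the
    first saturated codon to ``flank`` bases after the last, mimicking the
    sequencing amplicon a QC run would use.
    """
    construct = scheme.reference_construct
    first = scheme.codon_span(scheme.sites[0])[0]
    last = scheme.codon_span(scheme.sites[-1])[1]
    start = max(first - flank, 0)
    end = min(last + flank, len(construct))
    amplicon = construct[start:end]
    sites = [
        AmpliconSite(scheme.codon_span(s)[0] - start, dict(s.codon_for_residue))
        for s in scheme.sites
    ]
    wt_codons = tuple(
        construct[scheme.codon_span(s)[0]:scheme.codon_span(s)[1]]
        for s in scheme.sites
    )
    return amplicon, sites, wt_codons


def variant_amplicon(amplicon: str, sites, genotype) -> str:
    """Amplicon sequence for one genotype (one residue per site)."""
    seq = list(amplicon)
    for site, residue in zip(sites, genotype):
        codon = site.codon_for_residue[residue]
        seq[site.nt_start:site.nt_start + 3] = codon
    return "".join(seq)


def _indel_weights(amplicon_length: int, read_length: int, sites,
                   model: ReadErrorModel) -> np.ndarray:
    """Placement weights for injected indels, restricted to the part of the
    molecule a read observes (minus the edge margin) and biased toward the
    saturated codons where ligation junctions sit."""
    observable = min(amplicon_length, read_length) - model.edge_margin
    if observable <= model.edge_margin:
        raise ValueError("read window too short for the indel model")
    w = np.ones(observable)
    w[:model.edge_margin] = 0.0  # a leading indel floats outside the span
    for site in sites:
        lo = max(site.nt_start - model.bias_window, 0)
        hi = min(site.nt_start + 3 + model.bias_window, observable)
        w[lo:hi] *= model.junction_bias
    return w / w.sum()


def simulate_reads(
    composition,
    ref_amplicon: str,
    sites,
    n_reads: int,
    error_model: ReadErrorModel | None = None,
    read_length: int = 150,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Draw single-end reads from a library composition.

    ``composition`` maps genotype tuples to (unnormalised) abundances, or
    is ``None`` for the balanced library (uniform independent residues per
    site).  Reads start at the amplicon 5' end and are cropped to
    ``read_length``; errors are injected per ``error_model``.  Output is
    deterministic under ``seed`` and carries constant quality scores.
    """
    model = error_model or ReadErrorModel()
    rng = np.random.default_rng(seed)
    sites = list(sites)

    if composition is not None:
        if isinstance(composition, BeadPopulation):
            raise TypeError(
                "convert a BeadPopulation with composition_from_population()"
            )
        genotypes = list(composition)
        if not genotypes:
            raise ValueError("composition is empty")
        weights = np.asarray([composition[g] for g in genotypes], dtype=float)
        if weights.sum() <= 0:
            raise ValueError("composition weights sum to zero")
        weights = weights / weights.sum()
        choice = rng.choice(len(genotypes), size=n_reads, p=weights)
        drawn = [tuple(genotypes[i]) for i in choice]
    else:
        per_site = [sorted(site.codon_for_residue) for site in sites]
        idx = [rng.integers(0, len(res), size=n_reads) for res in per_site]
        drawn = [tuple(per_site[s][idx[s][i]] for s in range(len(sites)))
                 for i in range(n_reads)]

    weights = _indel_weights(len(ref_amplicon), read_length, sites, model)
    bases = "ACGT"
    reads: list[SimulatedRead] = []
    for i, genotype in enumerate(drawn):
        seq = variant_amplicon(ref_amplicon, sites, genotype)
        n_sub = int(rng.binomial(len(seq), model.subst_rate)) \
            if model.subst_rate > 0 else 0
        if n_sub:
            chars = list(seq)
            for pos in rng.choice(len(chars), size=n_sub, replace=False):
                chars[pos] = bases[(bases.index(chars[pos]) +
                                    int(rng.integers(1, 4))) % 4]
            seq = "".join(chars)
        indel = None
        if model.indel_rate > 0 and rng.random() < model.indel_rate:
            pos = int(rng.choice(len(weights), p=weights))
            if rng.random() < 0.5:
                seq = seq[:pos] + seq[pos + 1:]
                indel = (pos, "del")
            else:
                seq = seq[:pos] + bases[int(rng.integers(0, 4))] + seq[pos:]
                indel = (pos, "ins")
        truncated = False
        if model.truncation_rate > 0 and rng.random() < model.truncation_rate:
            cut = int(rng.integers(20, max(len(seq) // 2, 21)))
            seq = seq[:cut]
            truncated = True
        seq = seq[:read_length]
        reads.append(SimulatedRead(
            read_id=f"read_{i:07d}",
            sequence=seq,
            genotype=genotype,
            indel=indel,
            n_substitutions=n_sub,
            truncated=truncated,
        ))
    return reads


def composition_from_population(pop: BeadPopulation, design_sites) -> dict:
    """Per-variant abundance map (genotype tuple -> bead count)."""
    residue_sets = [list(site.residues) for site in design_sites]
    counts: dict[tuple[str, ...], int] = {}
    for row in pop.genotypes:
        # genotype columns are in build order (antisense); construct order
        # is the reverse
        genotype = tuple(
            residue_sets[s][row[pop.n_rounds - 1 - s]]
            for s in range(pop.n_rounds)
        )
        counts[genotype] = counts.get(genotype, 0) + 1
    return counts


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(read.to_fastq())
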