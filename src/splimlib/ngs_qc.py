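"""Amplicon-sequencing quality control for on-bead saturation libraries.

Given single-end reads over an amplicon that spans every saturated codon,
the pipeline (i) drops low-quality reads, (ii) aligns each read
semi-globally to the reference amplicon and classifies it as full-length,
indel-bearing, truncated or unalignable, (iii) extracts the codon at each
saturated site from full-length reads, and (iv) summarises library
balance, variant coverage, wild-type template carry-through and the
positional indel/substitution landscape.

Alignment uses an affine-gap pairwise aligner (match +1, mismatch -2, gap
open -4, gap extend -1 by default) with free end gaps on the reference
only, so each read must align end-to-end inside the amplicon.  Reads whose
alignment identity falls below a threshold (default 70%) are discarded as
unalignable — this also absorbs spike-in (e.g. PhiX) contamination.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

from .codons import aa_of


@dataclass(frozen=True)
class AlignParams:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    identity_threshold: float = 0.70
    full_reference_coverage: bool = False


@dataclass
class ReadClassification:
    read_id: str
    read_class: str                  # full_length | indel | truncated | unalignable | low_quality
    indel_events: list[tuple[int, str, int]] = field(default_factory=list)
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    extracted_codons: tuple[str, ...] | None = None
    identity: float = 0.0
    ref_span: tuple[int, int] = (0, 0)


@dataclass
class CodonCounts:
    """Per-site codon, per-site amino-acid and joint-variant counts."""

    codon_counts: list[Counter]              # one Counter per site
    aa_counts: pd.DataFrame                  # sites x amino acids
    joint: Counter                           # genotype tuple -> count
    n_counted_reads: int                     # full-length reads counted at all sites

    def aa_frequency_table(self) -> pd.DataFrame:
        totals = self.aa_counts.sum(axis=1)
        return self.aa_counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)


# ---------------------------------------------------------------------------
# Quality filtering
# ---------------------------------------------------------------------------

def read_fastq(path) -> list:
    """Parse a Phred+33 FASTQ file into SeqRecords (errors carry the index)."""
    try:
        return list(SeqIO.parse(str(path), "fastq"))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ ({path}): {exc}") from exc


def quality_filter(records, mean_q_threshold: float = 20.0,
                   min_length: int = 0):
    """Partition records into (kept, discarded) by mean Phred quality and
    minimum length.  The partition is exhaustive."""
    kept, discarded = [], []
    for rec in records:
        quals = rec.letter_annotations.get("phred_quality", [])
        mean_q = statistics.fmean(quals) if quals else 0.0
        if len(rec.seq) >= min_length and mean_q >= mean_q_threshold:
            kept.append(rec)
        else:
            discarded.append(rec)
    return kept, discarded


# ---------------------------------------------------------------------------
# Alignment-based classification
# ---------------------------------------------------------------------------

def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    # free end gaps on the reference: the read floats inside the amplicon
    aligner.end_deletion_score = 0.0
    return aligner


def _align_events(aln, ref: str, read: str):
    """Indel events, substitutions, matches and reference span of one
    alignment."""
    t_blocks, q_blocks = aln.aligned
    indels: list[tuple[int, str, int]] = []
    subs: list[tuple[int, str, str]] = []
    matches = 0
    for i, ((ts, te), (qs, qe)) in enumerate(zip(t_blocks, q_blocks)):
        for t, q in zip(range(ts, te), range(qs, qe)):
            if ref[t] == read[q]:
                matches += 1
            else:
                subs.append((t, ref[t], read[q]))
        if i + 1 < len(t_blocks):
            nts, nqs = t_blocks[i + 1][0], q_blocks[i + 1][0]
            if nts > te:          # reference advances: deletion in the read
                indels.append((te, "del", nts - te))
            if nqs > qe:          # read advances: insertion
                indels.append((te, "ins", nqs - qe))
    span = (int(t_blocks[0][0]), int(t_blocks[-1][1])) if len(t_blocks) else (0, 0)
    return indels, subs, matches, span


def classify_reads(records, reference_amplicon: str, site_starts,
                   params: AlignParams | None = None) -> list[ReadClassification]:
    """Align and classify reads against the reference amplicon.

    ``site_starts`` are 0-based reference coordinates of each saturated
    codon.  ``records`` may be SeqRecords or ``(read_id, sequence)`` pairs.
    """
    params = params or AlignParams()
    ref = str(reference_amplicon).upper()
    starts = [int(s) for s in site_starts]
    for s in starts:
        if s < 0 or s + 3 > len(ref):
            raise ValueError(f"site codon at {s} outside reference")
    aligner = _make_aligner(params)

    out: list[ReadClassification] = []
    for rec in records:
        if isinstance(rec, tuple):
            read_id, seq = rec
        else:
            read_id, seq = rec.id, str(rec.seq)
        seq = seq.upper()
        if not seq:
            out.append(ReadClassification(read_id, "unalignable"))
            continue
        aln = aligner.align(ref, seq)[0]
        indels, subs, matches, span = _align_events(aln, ref, seq)
        identity = matches / len(seq)
        if identity < params.identity_threshold:
            out.append(ReadClassification(read_id, "unalignable",
                                          identity=identity, ref_span=span))
            continue
        if indels:
            out.append(ReadClassification(
                read_id, "indel", indel_events=indels, substitutions=subs,
                identity=identity, ref_span=span))
            continue
        if params.full_reference_coverage:
            covered = span == (0, len(ref))
        else:
            covered = all(span[0] <= s and s + 3 <= span[1] for s in starts)
        if not covered:
            out.append(ReadClassification(
                read_id, "truncated", substitutions=subs,
                identity=identity, ref_span=span))
            continue
        # no gaps: single aligned block, direct coordinate mapping
        t0, q0 = aln.aligned[0][0][0], aln.aligned[1][0][0]
        codons = tuple(seq[q0 + s - t0:q0 + s - t0 + 3] for s in starts)
        out.append(ReadClassification(
            read_id, "full_length", substitutions=subs,
            extracted_codons=codons, identity=identity, ref_span=span))
    return out


def mark_low_quality(discarded) -> list[ReadClassification]:
    """Classification stubs for reads removed by the quality filter."""
    return [ReadClassification(rec.id, "low_quality") for rec in discarded]


# ---------------------------------------------------------------------------
# Codon counting
# ---------------------------------------------------------------------------

def count_codons(classifications, n_sites: int) -> CodonCounts:
    """Accumulate per-site codon counts from full-length reads.

    Codons containing non-ACGT characters are skipped at that site; the
    joint variant table only counts reads with clean codons at every site.
    """
    codon_counts: list[Counter] = [Counter() for _ in range(n_sites)]
    joint: Counter = Counter()
    n_counted = 0
    for cls in classifications:
        if cls.read_class != "full_length" or cls.extracted_codons is None:
            continue
        codons = cls.extracted_codons
        clean = [all(c in "ACGT" for c in codon) for codon in codons]
        for s, (codon, ok) in enumerate(zip(codons, clean)):
            if ok:
                codon_counts[s][codon] += 1
        if all(clean):
            joint[tuple(aa_of(c) for c in codons)] += 1
            n_counted += 1

    aa_rows = []
    for counter in codon_counts:
        aa: Counter = Counter()
        for codon, n in counter.items():
            aa[aa_of(codon)] += n
        aa_rows.append(aa)
    aa_counts = pd.DataFrame(aa_rows).fillna(0.0)
    aa_counts.index = [f"site_{i + 1}" for i in range(n_sites)]
    aa_counts = aa_counts.reindex(sorted(aa_counts.columns), axis=1)
    return CodonCounts(codon_counts, aa_counts, joint, n_counted)


# ---------------------------------------------------------------------------
# QC report
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    read_tallies: dict[str, int]
    read_fractions: dict[str, float]
    aa_frequency: pd.DataFrame
    balance_median: float            # median site x residue frequency
    balance_sd: float                # SD over the same cells
    coverage: float                  # observed / theoretical variants
    n_observed_variants: int
    fold2_fraction: float            # observed variants within 2x of mean
    fold3_fraction: float
    wild_type_fraction: float        # codon-level template carry-through
    wild_type_residue_fraction: float
    indel_profile: np.ndarray        # per reference position, events / read
    substitution_profile: np.ndarray

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "read_tallies": self.read_tallies,
            "read_fractions": self.read_fractions,
            "aa_frequency": {
                site: {aa: float(f) for aa, f in row.items() if f > 0}
                for site, row in self.aa_frequency.iterrows()
            },
            "balance_median": self.balance_median,
            "balance_sd": self.balance_sd,
            "coverage": self.coverage,
            "n_observed_variants": self.n_observed_variants,
            "fold2_fraction": self.fold2_fraction,
            "fold3_fraction": self.fold3_fraction,
            "wild_type_fraction": self.wild_type_fraction,
            "wild_type_residue_fraction": self.wild_type_residue_fraction,
            "indel_profile": [float(x) for x in self.indel_profile],
            "substitution_profile": [float(x) for x in self.substitution_profile],
        }


def read_fate_summary(classifications) -> tuple[dict[str, int], dict[str, float]]:
    """Exhaustive partition counts and fractions over all classified reads."""
    classes = ["full_length", "indel", "truncated", "unalignable", "low_quality"]
    tallies = {c: 0 for c in classes}
    for cls in classifications:
        tallies[cls.read_class] += 1
    total = sum(tallies.values())
    fractions = {c: (n / total if total else 0.0) for c, n in tallies.items()}
    return tallies, fractions


def qc_report(counts: CodonCounts, classifications, V: int,
              wild_type_codons, reference_length: int) -> QCReport:
    """Summary statistics over counted codons and read classifications.

    ``wild_type_codons`` is one codon per site (template codons, used to
    quantify wild-type carry-through).  Balance is the median ± SD over all
    site x residue frequency cells; fold-deviation fractions use the
    arithmetic mean count over *observed* variants, counting a variant as
    within n-fold when ``mean/n <= count <= mean*n``.
    """
    n_observed = len(counts.joint)
    if V < n_observed:
        raise ValueError(f"V={V} smaller than {n_observed} observed variants")

    tallies, fractions = read_fate_summary(classifications)
    freq = counts.aa_frequency_table()
    cells = freq.to_numpy().ravel()
    balance_median = float(np.median(cells)) if cells.size else 0.0
    balance_sd = float(np.std(cells, ddof=1)) if cells.size > 1 else 0.0

    variant_counts = np.array(sorted(counts.joint.values()), dtype=float)
    if variant_counts.size:
        mean = variant_counts.mean()
        fold2 = float(np.mean((variant_counts >= mean / 2)
                              & (variant_counts <= mean * 2)))
        fold3 = float(np.mean((variant_counts >= mean / 3)
                              & (variant_counts <= mean * 3)))
    else:
        fold2 = fold3 = 0.0

    wt_codons = tuple(wild_type_codons)
    wt_residues = tuple(aa_of(c) for c in wt_codons)
    n_wt = n_wt_res = 0
    for cls in classifications:
        if cls.read_class != "full_length" or cls.extracted_codons is None:
            continue
        if cls.extracted_codons == wt_codons:
            n_wt += 1
        if tuple(aa_of(c) if set(c) <= set("ACGT") else "?"
                 for c in cls.extracted_codons) == wt_residues:
            n_wt_res += 1
    denom = counts.n_counted_reads or 1

    indel_profile = np.zeros(reference_length)
    subst_profile = np.zeros(reference_length)
    n_aligned = 0
    for cls in classifications:
        if cls.read_class in ("unalignable", "low_quality"):
            continue
        n_aligned += 1
        for pos, _kind, _length in cls.indel_events:
            if 0 <= pos < reference_length:
                indel_profile[pos] += 1
        for pos, _ref, _alt in cls.substitutions:
            if 0 <= pos < reference_length:
                subst_profile[pos] += 1
    if n_aligned:
        indel_profile /= n_aligned
        subst_profile /= n_aligned

    return QCReport(
        read_tallies=tallies,
        read_fractions=fractions,
        aa_frequency=freq,
        balance_median=balance_median,
        balance_sd=balance_sd,
        coverage=n_observed / V,
        n_observed_variants=n_observed,
        fold2_fraction=fold2,
        fold3_fraction=fold3,
        wild_type_fraction=n_wt / denom,
        wild_type_residue_fraction=n_wt_res / denom,
        indel_profile=indel_profile,
        substitution_profile=subst_profile,
    )
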