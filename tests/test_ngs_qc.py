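"""Read classification, codon counting and QC statistics."""

import math
import random
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from splimlib.ngs_qc import (
    AlignParams,
    CodonCounts,
    ReadClassification,
    _make_aligner,
    classify_reads,
    count_codons,
    mark_low_quality,
    qc_report,
    quality_filter,
    read_fate_summary,
)
from splimlib.simulate import amplicon_from_scheme, simulate_reads, variant_amplicon

from oracles import gotoh_semiglobal_score


def _record(read_id, seq, q=40):
    rec = SeqRecord(Seq(seq), id=read_id, description="")
    rec.letter_annotations["phred_quality"] = [q] * len(seq)
    return rec


# ---------------------------------------------------------------------------
# Quality filter
# ---------------------------------------------------------------------------

def test_high_quality_reads_all_kept():
    records = [_record(f"r{i}", "ACGT" * 10, q=40) for i in range(10)]
    kept, discarded = quality_filter(records)
    assert len(kept) == 10 and not discarded


def test_known_low_quality_fraction_discarded_exactly():
    low = [_record(f"lo{i}", "ACGT" * 10, q=10) for i in range(3)]
    high = [_record(f"hi{i}", "ACGT" * 10, q=35) for i in range(7)]
    kept, discarded = quality_filter(low + high, mean_q_threshold=20)
    assert len(discarded) == 3 and len(kept) == 7
    assert {r.id for r in discarded} == {f"lo{i}" for i in range(3)}
    stubs = mark_low_quality(discarded)
    assert all(s.read_class == "low_quality" for s in stubs)


def test_min_length_filter():
    records = [_record("short", "ACGTACGT"), _record("long", "ACGT" * 20)]
    kept, discarded = quality_filter(records, min_length=20)
    assert [r.id for r in kept] == ["long"]


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def test_error_free_reads_fully_classified_with_exact_codons(scheme4):
    amp, sites, _ = amplicon_from_scheme(scheme4)
    starts = [s.nt_start for s in sites]
    reads = simulate_reads(None, amp, sites, 300, seed=1)
    cls = classify_reads([(r.read_id, r.sequence) for r in reads], amp, starts)
    assert all(c.read_class == "full_length" for c in cls)
    for read, c in zip(reads, cls):
        expected = tuple(sites[i].codon_for_residue[read.genotype[i]]
                         for i in range(4))
        assert c.extracted_codons == expected


def test_seeded_deletion_located_within_one_base(scheme4):
    amp, sites, _ = amplicon_from_scheme(scheme4)
    starts = [s.nt_start for s in sites]
    pos = 40
    read = amp[:pos] + amp[pos + 1:]
    (c,) = classify_reads([("d1", read)], amp, starts)
    assert c.read_class == "indel"
    assert len(c.indel_events) == 1
    event_pos, kind, length = c.indel_events[0]
    assert kind == "del" and length == 1
    assert abs(event_pos - pos) <= 1


def test_seeded_insertion_detected(scheme4):
    amp, sites, _ = amplicon_from_scheme(scheme4)
    starts = [s.nt_start for s in sites]
    read = amp[:50] + "T" + amp[50:]
    (c,) = classify_reads([("i1", read)], amp, starts)
    assert c.read_class == "indel"
    assert any(kind == "ins" for _, kind, _ in c.indel_events)


def test_shuffled_read_is_unalignable(scheme4):
    amp, sites, _ = amplicon_from_scheme(scheme4)
    rng = random.Random(0)
    shuffled = list(amp)
    rng.shuffle(shuffled)
    (c,) = classify_reads([("x", "".join(shuffled))], amp,
                          [s.nt_start for s in sites])
    assert c.read_class == "unalignable"


def test_read_missing_a_site_is_truncated(scheme4):
    amp, sites, _ = amplicon_from_scheme(scheme4)
    starts = [s.nt_start for s in sites]
    read = amp[:starts[-1] - 1]  # ends before the last saturated codon
    (c,) = classify_reads([("t1", read)], amp, starts)
    assert c.read_class == "truncated"


def test_full_reference_coverage_mode(scheme4):
    amp, sites, _ = amplicon_from_scheme(scheme4)
    starts = [s.nt_start for s in sites]
    read = amp[:-5]  # covers all sites but not the full reference
    (default,) = classify_reads([("r", read)], amp, starts)
    (strict,) = classify_reads([("r", read)], amp, starts,
                               AlignParams(full_reference_coverage=True))
    assert default.read_class == "full_length"
    assert strict.read_class == "truncated"


def test_site_outside_reference_raises(scheme4):
    amp, sites, _ = amplicon_from_scheme(scheme4)
    with pytest.raises(ValueError):
        classify_reads([("r", amp)], amp, [len(amp) - 1])


def test_banded_scores_match_exhaustive_dp_oracle():
    """The production aligner's optimal scores agree with an independent
    affine-gap dynamic-programming oracle on small problems."""
    rng = random.Random(42)
    aligner = _make_aligner(AlignParams())
    for _ in range(60):
        n = rng.randint(20, 120)
        m = rng.randint(10, min(n, 60))
        ref = "".join(rng.choice("ACGT") for _ in range(n))
        if rng.random() < 0.6:
            i = rng.randint(0, n - m)
            read = list(ref[i:i + m])
            for _ in range(rng.randint(0, 3)):
                k = rng.randrange(len(read))
                op = rng.choice("sid")
                if op == "s":
                    read[k] = rng.choice("ACGT")
                elif op == "i":
                    read.insert(k, rng.choice("ACGT"))
                elif len(read) > 6:
                    del read[k]
            read = "".join(read)
        else:
            read = "".join(rng.choice("ACGT") for _ in range(m))
        assert aligner.align(ref, read).score == pytest.approx(
            gotoh_semiglobal_score(ref, read))


# ---------------------------------------------------------------------------
# Codon counting
# ---------------------------------------------------------------------------

def test_single_variant_joint_count_equals_full_length_reads(scheme4):
    amp, sites, _ = amplicon_from_scheme(scheme4)
    starts = [s.nt_start for s in sites]
    genotype = ("D", "S", "A", "M")
    reads = simulate_reads({genotype: 1.0}, amp, sites, 150, seed=2)
    cls = classify_reads([(r.read_id, r.sequence) for r in reads], amp, starts)
    counts = count_codons(cls, 4)
    assert counts.joint == Counter({genotype: 150})
    assert counts.n_counted_reads == 150


def test_absent_residue_cell_is_zero(scheme4):
    amp, sites, _ = amplicon_from_scheme(scheme4)
    starts = [s.nt_start for s in sites]
    comp = {("A", "A", "A", "A"): 1.0, ("C", "A", "A", "A"): 1.0}
    reads = simulate_reads(comp, amp, sites, 100, seed=3)
    cls = classify_reads([(r.read_id, r.sequence) for r in reads], amp, starts)
    counts = count_codons(cls, 4)
    table = counts.aa_counts
    assert table.loc["site_2"].drop("A").sum() == 0
    assert "W" not in counts.joint


def test_codon_with_n_base_excluded_from_counts(scheme4):
    amp, sites, _ = amplicon_from_scheme(scheme4)
    starts = [s.nt_start for s in sites]
    read = list(amp)
    read[starts[0] + 1] = "N"
    cls = [ReadClassification(
        "n1", "full_length",
        extracted_codons=tuple(
            "".join(read[s:s + 3]) for s in starts))]
    counts = count_codons(cls, 4)
    assert sum(counts.codon_counts[0].values()) == 0
    assert sum(counts.codon_counts[1].values()) == 1
    assert not counts.joint


# ---------------------------------------------------------------------------
# QC report
# ---------------------------------------------------------------------------

def _uniform_counts(n_sites=2, residues=("A", "C"), per_cell=50):
    codons = {"A": "GCG", "C": "TGC"}
    cls = []
    i = 0
    for a in residues:
        for b in residues:
            for _ in range(per_cell):
                cls.append(ReadClassification(
                    f"u{i}", "full_length",
                    extracted_codons=(codons[a], codons[b])))
                i += 1
    return cls


def test_uniform_counts_give_exact_balance_and_full_coverage():
    cls = _uniform_counts()
    counts = count_codons(cls, 2)
    report = qc_report(counts, cls, V=4, wild_type_codons=("GCG", "GCG"),
                       reference_length=50)
    assert report.balance_median == pytest.approx(0.5)
    assert report.balance_sd == 0.0
    assert report.coverage == 1.0
    assert report.fold2_fraction == 1.0
    assert report.fold3_fraction == 1.0


def test_balance_on_k_uniform_cells_is_exact():
    for k in (2, 4, 5):
        residues = "ACDEF"[:k]
        codons = {"A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT"}
        cls = [ReadClassification(f"r{i}{res}", "full_length",
                                  extracted_codons=(codons[res],))
               for res in residues for i in range(7)]
        counts = count_codons(cls, 1)
        report = qc_report(counts, cls, V=k, wild_type_codons=("GCG",),
                          reference_length=10)
        assert report.balance_median == pytest.approx(1 / k)
        assert report.balance_sd == 0.0


def test_wild_type_fraction_counts_template_reads():
    cls = _uniform_counts(per_cell=25)  # 100 reads, 25 are (A, A)
    counts = count_codons(cls, 2)
    report = qc_report(counts, cls, V=4, wild_type_codons=("GCG", "GCG"),
                       reference_length=50)
    assert report.wild_type_fraction == pytest.approx(0.25)
    assert report.wild_type_residue_fraction == pytest.approx(0.25)


def test_fold_deviation_recovers_generative_dispersion():
    """Sampling a skewed (log-normal) library composition: the reported
    within-2-fold fraction matches the one computed directly from the known
    generative weights."""
    rng = np.random.default_rng(7)
    V = 400
    weights = rng.lognormal(mean=0.0, sigma=0.45, size=V)
    weights /= weights.sum()
    n_reads = 80_000
    draws = rng.multinomial(n_reads, weights)
    genotypes = [(chr(65 + i // 26), chr(65 + i % 26)) for i in range(V)]
    joint = Counter({g: int(n) for g, n in zip(genotypes, draws) if n})
    counts = CodonCounts([], pd.DataFrame(), joint, n_reads)

    expected_counts = weights * n_reads
    mean = expected_counts.mean()
    generative_fold2 = np.mean((expected_counts >= mean / 2)
                               & (expected_counts <= mean * 2))

    report = qc_report(counts, [], V=V, wild_type_codons=(),
                       reference_length=10)
    sigma = math.sqrt(generative_fold2 * (1 - generative_fold2) / V)
    assert 0.5 < generative_fold2 < 0.98  # the fixture is actually skewed
    assert abs(report.fold2_fraction - generative_fold2) <= 4 * sigma


def test_v_smaller_than_observed_is_error():
    cls = _uniform_counts()
    counts = count_codons(cls, 2)
    with pytest.raises(ValueError):
        qc_report(counts, cls, V=3, wild_type_codons=("GCG", "GCG"),
                  reference_length=50)


# ---------------------------------------------------------------------------
# Read fates & invariants
# ---------------------------------------------------------------------------

def test_read_fate_partition_conserves_reads(scheme4):
    amp, sites, _ = amplicon_from_scheme(scheme4)
    starts = [s.nt_start for s in sites]
    from splimlib.simulate import ReadErrorModel
    reads = simulate_reads(None, amp, sites, 800,
                           ReadErrorModel(indel_rate=0.1, subst_rate=0.003,
                                          truncation_rate=0.05), seed=8)
    cls = classify_reads([(r.read_id, r.sequence) for r in reads], amp, starts)
    tallies, fractions = read_fate_summary(cls)
    assert sum(tallies.values()) == 800
    assert sum(fractions.values()) == pytest.approx(1.0)
    assert tallies["indel"] > 0 and tallies["truncated"] > 0


def test_error_free_fixture_has_no_indel_or_truncation(scheme4):
    amp, sites, _ = amplicon_from_scheme(scheme4)
    reads = simulate_reads(None, amp, sites, 100, seed=9)
    cls = classify_reads([(r.read_id, r.sequence) for r in reads], amp,
                         [s.nt_start for s in sites])
    tallies, _ = read_fate_summary(cls)
    assert tallies["indel"] == 0 and tallies["truncated"] == 0


def test_coverage_monotone_in_read_count(scheme4):
    """Observed-variant coverage can only grow as reads accumulate."""
    amp, sites, _ = amplicon_from_scheme(scheme4)
    starts = [s.nt_start for s in sites]
    reads = simulate_reads(None, amp, sites, 1_200, seed=10)
    cls = classify_reads([(r.read_id, r.sequence) for r in reads], amp, starts)
    previous = 0
    for k in (200, 400, 800, 1_200):
        counts = count_codons(cls[:k], 4)
        observed = len(counts.joint)
        assert observed >= previous
        previous = observed
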