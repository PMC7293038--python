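"""Post-screening hit analysis: functional classification of characterised
clones, per-position consensus of improved binders, and input-library
representation lookup for any genotype.

Signals are median fluorescence normalised so the wild-type protein reads
1.0.  Clones below the lower threshold (default 20% of wild-type) are
non-functional false positives; clones above wild-type are improved.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ngs_qc import CodonCounts


@dataclass
class HitRecord:
    clone_id: str
    genotype: tuple[str, ...]
    normalized_signal: float
    label: str = ""                 # nonfunctional | functional | improved


@dataclass
class SiteConsensus:
    modal_residues: tuple[str, ...]  # >1 entry means a tie
    count: int

    @property
    def ambiguous(self) -> bool:
        return len(self.modal_residues) > 1


@dataclass
class ConsensusResult:
    per_site: list[SiteConsensus]
    consensus_genotype: tuple[str, ...]  # '?' marks ambiguous (tied) sites
    input_frequency: float | None = None
    expected_beads: float | None = None


def _round_half_up_percent(x: float) -> int:
    return int(math.floor(100.0 * x + 0.5))


def classify_hits(records, lower: float = 0.20, improved_cut: float = 1.0):
    """Label clones by normalised binding signal.

    ``signal < lower`` -> nonfunctional; ``signal > improved_cut`` ->
    improved; otherwise functional (boundary values inclusive on the
    functional side).  Returns the labelled records plus count and
    integer-percent tallies.
    """
    hits: list[HitRecord] = []
    for rec in records:
        if isinstance(rec, HitRecord):
            clone_id, genotype, signal = rec.clone_id, rec.genotype, rec.normalized_signal
        else:
            clone_id, genotype, signal = rec
        signal = float(signal)
        if signal < 0:
            raise ValueError(f"clone {clone_id}: negative signal {signal}")
        if signal < lower:
            label = "nonfunctional"
        elif signal > improved_cut:
            label = "improved"
        else:
            label = "functional"
        hits.append(HitRecord(clone_id, tuple(genotype), signal, label))

    counts = Counter(h.label for h in hits)
    total = len(hits)
    tallies = {
        label: {
            "count": counts.get(label, 0),
            "percent": _round_half_up_percent(counts.get(label, 0) / total)
            if total else 0,
        }
        for label in ("nonfunctional", "functional", "improved")
    }
    return hits, tallies


def consensus(improved_genotypes) -> ConsensusResult:
    """Per-site modal residue over a set of genotypes.

    Ties are reported explicitly (all tied residues listed, consensus
    marked ``?`` at that site); the result is invariant to input order.
    """
    genotypes = [tuple(g) for g in improved_genotypes]
    if not genotypes:
        raise ValueError("need at least one genotype")
    lengths = {len(g) for g in genotypes}
    if len(lengths) != 1:
        raise ValueError(f"ragged genotype lengths: {sorted(lengths)}")
    (m,) = lengths

    per_site: list[SiteConsensus] = []
    consensus_genotype: list[str] = []
    for s in range(m):
        counter = Counter(g[s] for g in genotypes)
        top = max(counter.values())
        tied = tuple(sorted(res for res, n in counter.items() if n == top))
        per_site.append(SiteConsensus(tied, top))
        consensus_genotype.append(tied[0] if len(tied) == 1 else "?")
    return ConsensusResult(per_site, tuple(consensus_genotype))


def representation(genotype, counts: CodonCounts, beads_sampled: int):
    """Input-library frequency of a genotype and the number of physical
    beads it is expected on in a sampled pool.

    Returns ``(frequency, expected_beads, absent)``; an absent genotype is
    not an error, it reports frequency 0 with the flag set.
    """
    genotype = tuple(genotype)
    total = sum(counts.joint.values())
    n = counts.joint.get(genotype, 0)
    if total == 0 or n == 0:
        return 0.0, 0.0, True
    freq = n / total
    return freq, freq * beads_sampled, False


def enrichment(sorted_counts: CodonCounts, input_counts: CodonCounts,
               pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-site, per-residue log2 enrichment of a sorted pool over input.

    Frequencies are pseudocount-adjusted: ``log2((f_sorted + p') /
    (f_input + p'))`` with ``p' = pseudocount / total``; swapping the
    arguments negates the table.
    """
    a, b = sorted_counts.aa_counts, input_counts.aa_counts
    if list(a.index) != list(b.index):
        raise ValueError("mismatched site sets between pools")
    cols = sorted(set(a.columns) | set(b.columns))
    a = a.reindex(columns=cols, fill_value=0.0)
    b = b.reindex(columns=cols, fill_value=0.0)
    fa = a.div(a.sum(axis=1).replace(0, np.nan), axis=0).fillna(0.0)
    fb = b.div(b.sum(axis=1).replace(0, np.nan), axis=0).fillna(0.0)
    pa = pseudocount / max(float(a.to_numpy().sum()), 1.0)
    pb = pseudocount / max(float(b.to_numpy().sum()), 1.0)
    p = max(pa, pb)
    return np.log2((fa + p) / (fb + p))
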