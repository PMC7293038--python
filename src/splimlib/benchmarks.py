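"""Published reference values for full-scale library QC.

These are dataset-level numbers reported for a real 160,000-member,
4-site on-bead saturation library characterised by deep sequencing (reads
deposited at the ENA under accession PRJEB33942).  Reproducing them
requires the deposited multi-million-read dataset, so they are recorded
here as optional external-validation targets only — nothing desk-scale
computes them, and no test asserts them against simulator output.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ExternalBenchmark:
    name: str
    value: float
    units: str
    description: str
    dataset: str = "ENA PRJEB33942"
    desk_scale: bool = False


EXTERNAL_VALIDATION: tuple[ExternalBenchmark, ...] = (
    ExternalBenchmark(
        "balance_median_percent", 5.1, "%",
        "median per-amino-acid frequency over all site x residue cells",
    ),
    ExternalBenchmark(
        "balance_sd_percent", 0.77, "%",
        "standard deviation over the same site x residue frequency cells",
    ),
    ExternalBenchmark(
        "coverage_percent", 99.3, "%",
        "theoretical library members observed at least once",
    ),
    ExternalBenchmark(
        "fold2_fraction_percent", 88.0, "%",
        "observed variants within 2-fold of the mean variant count",
    ),
    ExternalBenchmark(
        "indel_truncation_read_percent", 13.8, "%",
        "reads carrying insertions, deletions and/or truncations",
    ),
    ExternalBenchmark(
        "wild_type_contamination_percent", 0.25, "%",
        "wild-type template carry-through in the sequenced library",
    ),
)
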