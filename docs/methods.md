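# Methods

## The assembly model

A library member is the construct `fixed_5' + ORF + fixed_3'` with each
saturated codon replaced by that site's designed codon. Build-up is
modelled in the **antisense direction**: the anchor fragment (attached to
the bead first, via a 5'-DBCO handle on its bottom strand) carries the
3'-most saturated codon and the fixed 3' element; each subsequent round
ligates a fragment carrying the next saturated codon toward the 5' end;
the terminal fragment adds the 5'-most codon together with the
promoter/RBS element and a 5'-FAM monitoring label. Building antisense
means any incompletely extended molecule lacks the promoter and is
transcriptionally silent, which is why truncation failures are tolerable
at the molecule level.

Junctions between consecutive fragments are 5' overhangs generated by
Type IIs digestion. The built-in enzymes are Esp3I (CGTCTC, 1-nt spacer,
4-nt overhang) and BspQI (GCTCTTC, 1-nt spacer, 3-nt overhang); custom
enzymes can be supplied as (recognition, spacer, overhang length)
triples. Because Type IIs enzymes cut outside their recognition site, the
overhang sequence is read **directly from the construct** at the junction
position — ligation is scar-free by construction, and the package proves
it per design by re-deriving every variant through explicit in-silico
digestion/ligation and comparing with direct codon substitution.

### Junction placement and enzyme choice

One junction is placed between each pair of consecutive sites, inside
constant sequence only. The junction overhang is placed flush against the
start of the earlier-attached (3'-side) fragment's codon; this maximises
the room left for the next stuffer and makes every internal duplex
contribute only its own codon as permanent double-stranded sequence
whenever the downstream constant gap equals the overhang length. Each
junction uses the largest-overhang enzyme that fits the constant gap
(4-nt Esp3I when at least four constant bases separate the codons, 3-nt
BspQI for the minimum single-constant-codon separation). An explicit
per-junction enzyme list can override this. Schemes whose sites are
directly adjacent (no constant codon between) are rejected: the overhang
would have to span a saturated codon.

### Stability stuffers

Internal duplexes and the anchor carry a disposable stuffer 5' of their
retained sequence: a fixed GC-balanced filler ending in
`recognition + spacer` so that digestion cuts exactly at the
stuffer/construct boundary. The default stuffer length is 30 nt, which
makes a minimal internal duplex (3-bp codon core, 4-nt + 3-nt cohesive
ends) span 40 positions in total — the size regime in which short duplex
ligation substrates are stable. The length is configurable; every
generated fragment is screened so it contains exactly the intended
recognition sites and no strays created at stuffer boundaries. The
terminal fragment instead carries its recognition site 3' of the junction
on the bottom strand and is digested off-bead before the final ligation.

### Validation

`validate_scheme` reports errors for: internal stop codons; saturated
codons without at least one intervening constant codon; infeasible
junction placement; and any scheme enzyme's recognition site (either
strand) lying wholly in constant sequence, where it would be re-cut
during build-up. Recognition sites overlapping a saturated codon are not
flagged (they are variant-dependent); if a particular variant creates
one, the in-silico assembly of that variant fails loudly rather than
silently mis-assembling. Self-complementary or duplicated junction
overhangs are warnings, not errors: each ligation happens in its own
reaction, so cross-talk between junctions is excluded by protocol, but
self-ligation within a reaction remains possible.

## The split-and-mix simulator

Each bead starts with `D` identical molecules (default 2×10⁷, the
coupling stoichiometry at which on-bead DNA remains flow-cytometrically
visible). Per round:

* beads are assigned uniformly at random to that round's splits
  (fixing one genotype position per bead — monoclonality is therefore a
  construction property, and the simulator never violates it);
* every surviving molecule advances with probability `p_lig` in round 1
  (attachment) and `p_cut × p_lig` afterwards (digestion then ligation);
  failures are permanently truncated at that round;
* the bead count decays binomially with retention `r` per round
  (washing losses).

Defaults: `p_cut = 0.94` (measured bulk on-bead digestion efficiency),
`p_lig = 1.0` (solid-phase ligation saturates when enough DNA is
supplied), `r = 0.80` per round — a fitted default back-derived from a
20 M → 8.2 M bead trajectory over four rounds, not an independently
measured constant. With these defaults a 4-round build leaves
`0.94³ ≈ 83 %` of each bead's molecules full length. Junction errors
(probability per ligation, default 0) move completed molecules into an
`error_bearing` tally.

Molecule tallies are expectation-scaled by default (`D` is huge; the
per-bead law of large numbers makes sampling noise negligible) and
switch automatically to exact per-molecule binomial sampling when
`D ≤ 10⁴`. Bead counts, split assignments and bead losses are always
sampled. A single seeded NumPy generator drives each run; identical
seeds give bit-identical populations and FASTQ output.

Closed forms: Poisson occupancy (`empty = e^{−λ}`,
`monoclonal-of-occupied = λe^{−λ}/(1−e^{−λ})`, defined as 1 at λ→0),
coverage `1 − (1 − 1/V)^N`, sequencing depth `reads/V`, expected bead
count `freq × beads`, and screening capacity
`events/s × duration / oversampling`.

## The synthetic read generator

Reads are single-end (default 150 nt, constant Phred 40 quality), drawn
from a per-variant abundance map (or the balanced library when no map is
given), starting at the amplicon 5' end. Errors per read: substitutions
at a per-base rate; with probability `indel_rate` one 1-bp insertion or
deletion; with probability `truncation_rate` a hard truncation. Indel
positions are drawn with weight multiplied by `junction_bias` within
±6 bp of each saturated codon, emulating the elevated indel incidence
near ligation junctions in real libraries.

Indels are only placed inside the read-observable window, excluding a
6-nt margin at either end: an indel in the terminal few bases of a read
is mathematically indistinguishable from a truncation (the optimal
alignment simply ends earlier), so placing errors there would make any
seeded rate unrecoverable by any classifier. This is a deliberate
identifiability choice of the generator, documented here because it means
the generator does *not* emulate terminal sequencing artefacts.

What the generator does not model: paired ends, quality-score decay along
the read, PCR amplification bias and chimeras, polyclonal beads, and
spike-in genomes. Passing the round-trip tests therefore shows that the
pipeline recovers the parameters of this generative model, not that it
reproduces every artefact of a real sequencing run.

## Read QC

Reads below a mean-quality threshold (default Q20) are dropped first.
Each remaining read is aligned to the reference amplicon with an
affine-gap pairwise aligner — match +1, mismatch −2, gap open −4
(the score of a length-1 gap), gap extension −1 — with free end gaps on
the reference only, so the read must align end-to-end inside the
amplicon. Classification: identity (matches / read length) below 70 % →
`unalignable` (this also absorbs spike-in reads); any internal gap →
`indel`; alignment not covering every saturated codon → `truncated`
(a strict full-reference-coverage mode is available); otherwise
`full_length`, with codons extracted at the site coordinates through the
gap-free coordinate map. Codons containing N are excluded from counts
but the read keeps its class.

Report statistics: balance is the median ± SD over all site × residue
frequency cells of the observed amino-acid table; coverage is observed
joint variants over the theoretical diversity; fold-deviation fractions
use the arithmetic mean count over *observed* variants with
`mean/n ≤ count ≤ mean·n` inclusive; wild-type carry-through is counted
at codon level (template codons at every site), with a residue-level
count alongside; positional indel/substitution profiles are events per
aligned read at each reference position.

## Hit analysis

Clones are labelled from signals normalised to wild-type = 1: below 0.20
non-functional, above 1.0 improved, otherwise functional; boundary values
fall on the functional side. Tally percentages round half-up to integers.
The consensus reports, per site, all residues tied for the modal count —
never a silent choice — and marks tied sites `?` in the consensus
genotype. Representation of a genotype is its joint-count frequency and
the expected number of physical beads carrying it in a sampled pool; an
absent genotype reports frequency 0 with an `absent` flag. Enrichment
between a sorted and an input pool is a per-site, per-residue
`log2((f_sorted + p')/(f_input + p'))` with a count-scaled pseudocount,
antisymmetric under swapping the pools.

## Synthetic examples and problem sizes

All fixtures are generated in-repo: a synthetic Affibody-like 58-codon
ORF (rejection-sampled from a fixed E. coli-biased one-codon-per-residue
table until stop- and recognition-site-free in its full construct
context) with four fully saturated sites at codons 10, 18, 28 and 35
behind a T7 promoter/RBS and ahead of a synthetic C-terminal fusion stub;
and a three-codon proximal scheme whose two junctions exercise both the
4-nt and the 3-nt overhang chemistry. The codon table is a documented
default, not any published campaign's table.

Test problem sizes are chosen to keep the suite fast while leaving
statistical tolerances meaningful: the coverage law is checked at
V = 1,000 over 20 seeds at N/V ∈ {0.1, 1, 5, 50}; the full-scale bead
simulation runs 2×10⁷ beads once; the QC round trip uses 10⁵ simulated
150-nt reads from the balanced 20⁴ composition with a 10 % seeded indel
rate, checked at three binomial standard deviations.

## Known limitations

* Junction placement is deterministic (flush to the earlier-attached
  codon); no search over alternative placements for overhang-set
  optimisation (ligation-fidelity optimisation of overhang sets is out of
  scope, as each junction ligates in isolation).
* The aligner reports one optimal alignment; indel positions inside
  homopolymers are placed at the alignment's convention (left-shifted
  relative to the gap), tested to ±1 of the seeded position.
* The simulator treats digestion/ligation failures as independent across
  molecules and rounds; real failure modes (bead clumping, reagent
  carry-over) are correlated.
* Dataset-scale QC benchmarks of a real multi-million-read library
  (balance ≈ 5 %, coverage ≈ 99 %, indel/truncation share ≈ 14 %) are
  recorded in `splimlib.benchmarks` as external-validation targets only;
  nothing desk-scale recomputes them.
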