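# Methods

`ncostmin` analyses the primary transcriptome of a streamlined bacterium
under nitrogen stress from strand-specific 5′-end coverage, and asks
whether the structure of the transcriptome shifts toward products that
cost the cell fewer nitrogen atoms. This note records the models, the
parameters that matter, the simulator's scope, and the numerical choices
made where the design was genuinely open.

## TSS detection

The unit of input is a per-position, per-strand count of read 5′ ends for
two libraries: one enriched for native (5′-triphosphate) transcript starts
and one non-enriched control. A true transcription start appears as a
saw-tooth: a sharp pileup at the start position, decaying downstream, much
stronger in the enriched library.

At a candidate position (enriched count ≥ the noise threshold, default 4)
the detector tests the count difference `d = enriched − control_scaled`
against a Skellam null, `D ~ Skellam(λ_e, λ_c)`, where `λ_e` and `λ_c`
are per-strand background 5′-end densities. The reported p-value is the
upper tail `P(D ≥ d)`, evaluated with the Bessel-based Skellam
implementation in SciPy; a brute-force convolution of two Poisson mass
functions serves as an independent oracle in the test suite (agreement
better than 1e−9 absolute over rates ≤ 20 and counts ≤ 200). Significant
positions (default p < 1e−10) within 5 nt on the same strand are merged
to the position with maximal enriched count (ties to the smaller
coordinate), and calls whose enriched-minus-control difference is below
100 are dropped — the automated analogue of the manual curation step of
dRNA-seq workflows.

**Background estimation.** `λ` per strand is the mean count over
positions at or below the 95th percentile of nonzero counts (zeros
included), floored at 0.01. TSS spikes sit above that percentile and do
not inflate the estimate. The exact windowing used by TSSAR-style tools
is not published; the trimmed mean is this package's documented choice.

**Depth normalization.** Control counts are scaled before both the test
and the curation difference. The default scale is the per-strand ratio of
background rates: background noise tracks sequencing depth while signal
does not, so this estimator remains valid even though enrichment changes
the libraries' total-count composition. Scaling by the ratio of *total*
5′-end counts is available (`depth_norm="total"`) but over-corrects
whenever the enriched library's total is signal-dominated — on an
equal-depth simulated genome it erased a true internal TSS (enriched 464
vs control 62 scaled to a difference of 92, below the curation cutoff).
`depth_norm="none"` reproduces raw-count behavior.

**Classification.** Each retained call receives every positional category
it satisfies over all genes: *primary* (same strand, within 250 nt
upstream of the gene's 5′ end, inclusive of both the window edge and
distance 0), *internal* (inside the gene body, same strand), *antisense*
(inside the gene body, opposite strand), *downstream* (same strand,
strictly < 30 nt past the 3′ end), and *orphan* only when nothing else
applies. "Within 250" is read inclusively and "less than 30" strictly,
following the wording of the respective rules. Primary classification is
anchored at the gene's annotated 5′ end (the translational start when the
annotation carries no explicit TSS). Leaderless starts are primary calls
within 10 nt of the translational start.

## Internal transcription dynamics

For a gene with both a primary and an internal TSS, the internal
transcription ratio in a condition is the 5′-end abundance at the
internal TSS divided by the abundance at the primary TSS, where abundance
integrates a downstream-inclusive window of `w = 5` nt (the merge-range
scale; the integration window behind "read mapping at" a TSS is not
published, and `w` is configurable). Ratios are invariant to global
library depth. Genes whose ratio clears 10% in at least one condition are
retained; the comparison is made at the threshold's stated precision
(two decimals, inclusive), so an estimate fluctuating in the third
decimal around a ratio of exactly 0.10 is not excluded by float noise.

Conditions are compared two ways:

* **Direction.** The fold change `ratio_deplete / ratio_replete` is
  classified as `up_in_deplete`, `up_in_replete`, or `similar`; the
  similar band is fold ∈ [1/1.2, 1.2], chosen so the three-way call is
  total and deterministic (no numeric band is published).
* **Wilcoxon rank-sum test.** The sampling unit is the per-offset
  internal:primary count ratio: for each offset d of the abundance
  window, the internal count at d divided by the primary count at d
  (offsets with a zero primary count are skipped; the test is skipped
  entirely when fewer than 3 offsets are nonzero in both windows).
  Pairing offsets cancels the deterministic saw-tooth decay; a rank test
  on unpaired window counts is dominated by the position effect and is
  both powerless and mis-calibrated (measured: p ∈ [0.07, 1] regardless
  of a four-fold ratio change). Published per-gene rank tests of this
  kind rarely state their sampling unit; this construction is the
  package default. Note the
  resolution limit: an exact two-sided rank-sum on 6+6 observations
  cannot fall below 2/C(12,6) ≈ 2.2e−3, so per-gene significance at much
  smaller thresholds is attainable only with wider windows or more
  granular sampling units. Null calibration was verified by simulation:
  with identical planted ratios, P(p ≤ α) ≤ α at α ∈ {0.01, 0.05, 0.2,
  0.5} (the exact test is discrete, hence conservative; its p-values are
  not literally uniform).

Genes with an internal TSS but no primary TSS are compared directly:
depth-normalized internal abundance in the deprived sample over the
replete sample, with +∞ reported when the replete abundance is zero. A
12 h TSS is *conserved* when a 24 h call exists within the merge range on
the same strand.

## Truncated isoforms and nitrogen accounting

Translation is assumed to initiate at methionine: the truncated isoform
implied by an internal TSS begins at the nearest in-frame ATG at or
downstream (strand-aware) of the TSS; genes with no such Met before the
stop are excluded with a log message. Both isoforms are translated with
the bacterial code (table 11; a GTG/TTG initiator reads as Met at the
annotated start only). Nitrogen is counted per residue as backbone (1 N)
plus side chain: +3 Arg, +2 His, +1 each Lys, Asn, Gln, Trp. Whole-residue
accounting is the default because "mol N per mol protein" budgets are
whole-protein quantities; `side_chain_only=True` gives the alternative.
The saving of a truncation equals the nitrogen of the removed N-terminal
prefix (an exact conservation law, property-tested), and is invariant
under synonymous recoding. Aggregates report both the pooled percent
(100·Σsaving/Σfull) and the mean of per-protein percents, which generally
differ. Optional parallels: carbon atoms per residue, and the ring-N
content of the removed 5′ RNA segment (A=5, G=5, C=3, U=2 per base).

## Motif statistics

**Gly–Gly pairs.** Adjacent in-frame glycine codon pairs act as
Shine–Dalgarno mimics that pause ribosomes. Observed counts of the 16
ordered pairs over {GGT, GGC, GGA, GGG} (never spanning gene boundaries;
CDSs containing ambiguous bases are excluded with a warning) are compared
with an independence null, `E[(a,b)] = P(a)·P(b)·N_adjacent`, built from
genome-wide codon frequencies. Pairs pool into bins by affinity of the
hexamer for the anti-Shine–Dalgarno sequence at the 16S rRNA 3′ terminus.
The shipped table is a heuristic rank, not a thermodynamic computation:
each hexamer is scored by its best ungapped alignment to the SD consensus
AGGAGG (match 1, G opposite template A scored 0.5 for G:U wobble), which
yields three occupied affinity classes — GGT/GGC-initiated (low),
GGG-initiated (mid), GGA-initiated plus GGGGGG (high). Bin edges sit at
midpoints between distinct score levels; any user table (hexamer → score)
can replace it.

**Pyrimidine/purine-rich k-mers.** Every length-k window fully inside a
region (overlaps allowed; optional `collapse` merges overlapping
qualifying windows into maximal runs) counts when its class fraction is
at least the threshold, with the ceiling rule ≥⌈threshold·k⌉ guarded
against float artifacts. The expectation is a binomial composition null,
`N_windows · P(Binomial(k, p̂) ≥ ⌈threshold·k⌉)`, with `p̂` fit on the
same region set by default (`null="genome"` selectable); the published
expectation model is not defined, so this choice is documented rather
than inherited. Enrichment between two region sets or classes uses a
two-sided Fisher's exact test on observed counts against
nearest-integer-rounded expected counts (exact tests need integers; the
rounding is symmetric and degenerate tables report p = 1 with a flag).

**NtcA boxes.** The global nitrogen-stress regulator's binding site is
scanned as an IUPAC-degenerate pattern, default GTA-N8-TAC (the canonical
cyanobacterial box; position-weight-matrix scans can be emulated by
overriding the pattern), on the coding
strand strictly less than 100 bp upstream of each translational start.

## Synthetic data

The generator emulates the experiment's inputs with planted, serialized
truth: an AT-rich genome (default GC 0.31, matching streamlined marine
picocyanobacteria) of ATG-initiated, stop-terminated CDSs drawn i.i.d.
from configurable codon weights, fixed-length intergenic spacers with a
controlled pyrimidine fraction, optional planted NtcA boxes (chance
pattern matches inside scanned upstream windows are scrubbed so planted
sites are exactly the recoverable truth), and an optional pair-depletion
knob that destroys a stated fraction of chosen Gly–Gly adjacencies by
codon swapping (marginal codon counts preserved, so depletion acts purely
on the adjacency). Coverage per library is Poisson around background
noise (default 0.5 per position) plus, at planted TSSs, the TSS mean
(enriched) or mean/enrichment (control, default contrast 10×) with a
geometric downstream tail (decay 0.5 over 5 nt) forming the saw-tooth.
Everything is bit-reproducible for a fixed seed.

Standard fixtures encode the study conditions: 50 genes with primary and
internal TSSs at mean 1000; planted internal:primary ratios
{0.05, 0.1, 0.4, 0.8} with the internal mean held at 1000; an
85-gene fixture partitioned 64/13/8 into up-in-deplete (0.2→0.8),
up-in-replete (0.8→0.2) and similar (0.4/0.4) ratio dynamics; 187
internal-only TSSs with 117 planted three-fold higher under depletion; 81
internal TSSs at 12 h with 72 re-planted at 24 h; and 20 primary TSSs
with 2 leaderless.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real libraries: overdispersed count noise
(negative-binomial behavior of biological replicates), positional biases
of ligation and amplification, processed 5′-monophosphate ends surviving
enrichment, operonic read-through, RNA secondary-structure effects on
coverage, or a realistic genome-wide TSS density. The fixtures establish
correctness and calibration of the inference machinery under its own
model assumptions, not performance on any particular organism.

## Problem sizes and numerical notes

Shipped fixtures use 25–100 kb genomes with 4–187 planted TSSs, chosen so
the full suite and the acceptance script complete in seconds while
leaving wide statistical margins (e.g. detection recall/precision of 1.0
against a 0.95 bound; worst ratio error ~4% against a 10% bound). The
pipeline is a pure function of (inputs, config, seed); reruns are
byte-identical. Degenerate inputs are handled explicitly: all-zero
strands floor the background at 0.01; zero primary abundance routes a
gene to the direct comparison; genes without a downstream Met are
excluded from truncation records; affinity bins with zero expectation are
excluded with a warning; merge ties break toward the smaller coordinate.

## Known limitations

Real dRNA-seq libraries violate the Poisson assumption (overdispersion
inflates the Skellam tail, so the effective false-positive rate exceeds
the nominal p-threshold; the stringent 1e−10 default absorbs much of
this). The anti-SD affinity table is an overridable rank heuristic, not a
hybridization-energy model. The Fisher construction on rounded expected
counts treats a model expectation as if it were a second observed sample.
Reproducing published genome-scale values for a specific organism
additionally requires that organism's genome, annotation, and
supplementary TSS tables as inputs.
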