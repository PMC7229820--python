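# Methods

## Data model and coordinate conventions

All genomic coordinates are BED-native: 0-based, half-open `[start, end)`.
The TSS of a plus-strand gene is `start`; of a minus-strand gene `end - 1`.
Promoter windows are `[tss - flank, tss + flank)` clipped at 0 and always
containing the TSS base. Chromosome names are compared verbatim; a name
present in one input and absent from another is an error, never a silent
drop. Expression matrices are gene × sample tables of FPKM (or TPM after
normalisation; TPM columns must sum to 1e6 within a relative tolerance of
1e-6). Sample identity (genotype ∈ {WT, KO, KO_WT}, day ∈ {0, 3, 6, 12},
replicate) is embedded in the sample id as `GENOTYPE_d<day>_r<rep>`.

## Differential expression

The DE operation is deliberately simple: a gene's fold-change is
`log2((mean_B + c) / (mean_A + c))` on the abundance scale with pseudocount
`c = 0.1`, and its p-value is Welch's unequal-variance t-test on
`log2(value + c)`. This is a stand-in for a full count-model DE method —
the downstream classification consumes only (log2fc, p) pairs, so the
choice of test only affects calibration, not structure. A DE call requires
fold-change > 1.5 **and** P < 0.05, both strict. When both replicate
vectors are constant the t-statistic is undefined; the p-value is set to 1
(no evidence of change), which is the conservative resolution of the 0/0.

With 3-vs-2 replicates and log2 noise 0.25, a planted 4-fold change is
called significant in roughly 86% of draws (the Welch degrees of freedom
are punishing at n = 2); the Monte-Carlo test asserts this measured level.
The two-stage gene classification is deliberately robust to this: grid
placement uses fold-change alone (the grid's cutoff line is a fold-change
line), so dependent-gene recovery does not pay the power penalty twice.
Significance enters only through the `status` column of DE tables.

## Two-stage 9-square classification

Letters are assigned row-major on a 3×3 grid: rows are the y-axis category
(up, neutral, down from top), columns the x-axis category (down, neutral,
up from left), so C is up-on-both, E the centre, F∪I up-on-x-but-not-up-
on-y, A∪D down-on-x-but-not-down-on-y. "Up" on an axis means
fc > cutoff (default log2 1.5), "down" means fc < −cutoff, both strict.
Stage 1 contrasts WT (x) against KO (y) for the day-12-vs-day-0 change;
stage 2 re-tests stage-1 survivors with the rescue (x) against KO (y).
The letter layout and the stage-2 axis orientation are design choices
fixed here and probed exhaustively in the tests (every sign combination
maps to a distinct letter). Invariants: the nine letters partition any
input; raising the cutoff never moves a gene out of E; stage-2 sets are
subsets of stage-1 sets; the up- and down-dependent sets are disjoint.

## Trajectory scaling

Per (gene, genotype), replicates are averaged per timepoint and the four
means scaled affinely to [0, 1]. A constant trajectory maps to all zeros
rather than 0.5 — deterministic and order-preserving for near-constant
rows. "Constant" is judged with a relative tolerance of 1e-9×max|value|,
because the mean of three identical replicates and the mean of two can
differ by a unit in the last place, and dividing by such a span would
amplify pure rounding noise into a fake trajectory.

## Chromatin operations

* **Peak intersection** uses a per-chromosome sweep over the sorted
  intervals with a running prefix-maximum of end coordinates, so nested and
  contained intervals are handled; the overlap criterion is ≥ 1 shared bp.
  Inputs must already be sorted — an unsorted set is an error, not an
  implicit sort. The sweep is checked in the tests against an O(n²)
  all-pairs oracle and against an independent interval library.
* **Reduced peaks**: per-peak signal is the length-weighted mean track
  value over the peak span in each genotype; the peak is "reduced" when
  `log2((KO + 0.1)/(WT + 0.1)) ≤ −1` (KO at most about half of WT). The
  threshold is a config knob (`reduced_log2_cutoff`); calls are monotone in
  it by construction.
* **Binned correlation** is plain Pearson over every genome bin of two
  equally-binned tracks, zeros included (mirroring a binned read-count
  workflow); default bin 10 kb. A constant track is an error, not a NaN.
* **Metagene profiles**: TSS mode samples the track at fixed offsets in
  `[-flank, +flank]` around each TSS (minus-strand genes reversed);
  gene-body mode rescales each body to `genebody_nbins` equal fractions
  with length-weighted means per fraction. Strand-mirror symmetry is exact
  and tested.
* **Quantification resolution.** Two bin sizes coexist deliberately:
  `bin_size_bp` (10 kb) for the genome-wide correlation, and
  `quant_bin_bp` (500 bp) for anything that quantifies signal over
  sub-kilobase features (peak spans, promoter windows, metagene positions).
  Averaging a ~900 bp peak into a 10 kb bin dilutes its signal about
  11-fold, which drags KO/WT log-ratios toward 0 once the pseudocount and
  background enter; 500 bp bins keep peak-scale ratios faithful.
* **Stratification** (TET1-bound vs not): per gene, promoter-window mean
  binding and 5hmC signal and replicate-mean day-0 expression, each as
  `log2((KO + 0.1)/(WT + 0.1))`, averaged within the two groups. Day 0 is
  used because the binding/expression coupling is a naive-state question.
* **Association**: 2×2 Pearson chi-squared with df = 1 and no Yates
  correction (a configurable flag enables it); expected cells below 1 are
  recorded as a warning on the result rather than silently trusted.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
`P[X ≥ k]` for a query of n genes hitting k of a set of K in a universe of
N, with Benjamini–Hochberg adjustment across sets. The tests verify the
tail against exhaustive enumeration of all `C(N, n)` draws for small N.

## The simulator

`simulate_study` / `simulate_all` generate, deterministically per seed
(independent named substreams for genome, expression, chromatin, gene
sets):

* **Genome**: 5000 genes on 2 × 60 Mb chromosomes; lengths U(2, 20) kb,
  spacing ≥ 1 kb, intergenic slack spread by a Dirichlet draw; random
  strands. (60 Mb is the smallest round size that packs 2500 genes per
  chromosome with room left for intergenic background peaks.)
* **Expression**: baseline log2 FPKM ~ N(4, 1.5²); dependent genes ramp
  linearly in time by ±2 log2 units (4-fold) from day 0 to day 12 in WT
  and rescue, flat in KO; null_up/null_down genes (400/300) ramp in all
  three genotypes and exist to make stage 1 do real work; remaining genes
  flat; replicate noise N(0, 0.25²) on log2, then exponentiated.
  Genes whose promoter peak is reduced in KO additionally carry a constant
  −1 log2 shift in KO at every timepoint — this plants the naive-state
  DE × binding-loss association without touching any day12/day0 ratio.
* **Chromatin**: every TET1-bound gene (50%) gets a peak centred on its
  TSS (width U(600, 1200) bp, Gamma(4, 5) signal, mean 20); the KO carries
  the same intervals with signal × U(0.05, 0.45) for the reduced 60%,
  × U(0.8, 1.2) otherwise; a Poisson count (rate 0.2 per gene peak) of
  intergenic background peaks is shared by both genotypes. NONO peaks
  number 15% of TET1 peaks, 85% co-placed on TET1 intervals, the rest
  intergenic avoiding TET1. 5hmC mirrors TET1 with lognormal(0, 0.3)
  multiplicative coupling noise. Tracks paint peak signal into 500 bp bins
  (length-weighted) plus Exp(0.1) background noise per bin.

What the simulator does **not** emulate: read-level sampling noise,
mappability or GC bias, peak-width/shape heterogeneity, correlated
replicate structure, real chromosome coordinates, or any count-based
overdispersion. Passing recovery tests therefore demonstrates that the
pipeline's logic is correct and well-calibrated under its own stated noise
model — not that the stand-in DE test would match a count-model method on
real sequencing data.

## Problem sizes and determinism

The default simulated study (5000 genes, ~3000 peaks per set, 240 k fine
bins, 12 k correlation bins) runs end to end in a few seconds; tests use a
scaled-down 400-gene variant of the same structure except where the
study-condition defaults are themselves under test. All randomness flows
from a single integer seed through named `numpy` substreams; identical
seeds give byte-identical output bundles (checksummed in a manifest), and
the pipeline itself is deterministic given its input files.

## Known limitations

* The Welch stand-in is under-powered at two replicates (see above); a
  count-model DE method would change individual p-values but not the
  fold-change-driven classification.
* "Reduced" peaks are defined by a fixed occupancy-ratio rule, not a
  statistical differential-binding call; the count of reduced peaks is
  therefore a function of the cutoff knob.
* Venn overlap counts are asymmetric by construction (peaks of A hitting
  B vs peaks of B hitting A are both reported); no width harmonisation is
  applied to broad-vs-narrow peak comparisons.
* The ORA route is annotation-agnostic; it does not ship or emulate any
  ontology.
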