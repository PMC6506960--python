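# Methods

This note documents the scientific and numerical choices behind
`cometh`: what each stage computes, the parameters that matter, what the
synthetic generator does and does not emulate, and the known limitations.

## Input model and state assignment

The unit of analysis is one chromosome of one sample: an ordered table
of CpG sites with 1-based forward-strand position, read coverage, and MC
ratio (methylated reads / total reads, in [0, 1], missing when the site
has no reads). Only the forward strand is modeled; reverse-strand
records in input files are dropped with a logged count. Positions must
be strictly increasing — unsorted input is sorted with a warning,
duplicated positions are an error, and a present ratio at a
zero-coverage site is rejected as inconsistent.

States discretize the ratio: A = [0, 0.25), B = [0.25, 0.5),
C = [0.5, 0.75), D = [0.75, 1]. The boundaries are half-open from below
with the upper endpoint closed, so a ratio of exactly 0.25 is B and 1.0
is D. Sites with coverage below `min_coverage` (default 3, i.e. <3X)
are NA regardless of ratio. The threshold is a bias/coverage trade-off:
below 3 reads the empirical ratio takes at most four values and the
state assignment is mostly noise. `min_coverage=0` disables the filter,
which is occasionally useful for low-pass data and for worked examples
with shallow sites.

Forward distances (position[i+1] − position[i], in bp) are attached to
the left member of each adjacent pair and computed for all sites
including NA ones; the last site of a track has none.

Coordinates are 1-based inclusive in the native tables. BED export of
SMRs converts to 0-based half-open with the end extended by 1 bp so the
interval covers the G of the final CpG dinucleotide.

## Analysis 1: state transitions and distance dependence

Adjacent sites form an ordered state pair unless either member is NA;
pairs never bridge an NA site, because "consecutive" means no CpG lies
between the two members — skipping an NA site would silently change the
distance semantics. A pair's distance is the left member's forward
distance.

The marginal 4×4 table conditions percentages on the initial state (row
percentages), matching how transition matrices are read. The
distance-stratified table uses half-open 50-bp bins with an open final
bin (default edges 0, 50, …, 500). For per-bin "percent occurrence" two
denominators are defensible: the bin's total over all 16 pairs, or the
bin's row total for the pair's initial state. The bin-total denominator
is the default (it shows the composition of pairs at each distance); the
row-total variant is available via `denominator="row-total"` /
`--profile-denominator row-total` since it isolates the kernel's
distance dependence from the marginal state composition.

### Chi-squared comparison

For each initial state, samples × terminal-states counts form the
contingency table; the Pearson statistic is evaluated directly from its
cell decomposition (no continuity correction), so the contribution table
(O−E)²/E sums to the statistic exactly (the suite checks this at 1e-9
relative, and agreement with an independent implementation at 1e-10).
Terminal states observed in no sample are dropped from the table before
computing df. p-values come from the upper χ² tail; values that
underflow double precision display as "~0".

The divide-by-n sensitivity scan addresses the large-count problem: with
millions of pairs, trivially small differences give astronomically small
p-values. Counts are divided by each divisor (default 1, 10, 100, 1000)
and rounded half-away-from-zero to the nearest integer before re-testing.
The rounding rule is configurable (`floor`, `none`); with `none` the
statistic obeys X²(O/n) = X²(O)/n exactly, which the suite verifies.
Scan steps whose minimum expected count falls below 5 are flagged as
unreliable; a divisor so large that a whole row rounds to zero yields a
`None` step rather than an error. Pairwise 2×4 follow-up tests run when
the omnibus p falls below α (default 0.05) or unconditionally with
`--force-pairwise`; no multiplicity adjustment is applied by default
(a Benjamini–Hochberg helper is provided). Suspected outlier samples
are removed explicitly via `--exclude` — contribution inspection, not an
automatic rule, decides what is an outlier.

## Analysis 2: similarly methylated regions

SMRs are maximal same-state runs; NA breaks a run (consistent with the
pairing rule; `na_breaks=False` gives NA-transparent runs for
sensitivity analysis). Runs need `min_count` ≥ 2 sites to be reported.
Length is last − first position, which makes the smallest reportable SMR
(adjacent CGCG, same state) exactly 2 bp; the alternative last − first + 1
convention would shift every length by one.

Summaries are six numbers (min, Q1, median, mean, Q3, max) computed
after removing exactly one occurrence of the maximum per (state, metric)
group — count and length are trimmed independently, so the removed
region may differ between the two metrics. Trimming one value rather
than all ties at the maximum keeps the operation well-defined when the
distribution is heavily tied at small values. Quartiles use linear
interpolation between order statistics (R's `summary()` convention,
`numpy.quantile(method="linear")`); the method is configurable. A state
with no regions (or none after trimming) yields an all-NaN sentinel row,
not an error.

The Kruskal–Wallis H is computed on mid-ranks with the tie correction
1 − Σ(t³−t)/(N³−N) always applied: SMR CG counts concentrate on 2 and 3,
and the uncorrected statistic would be materially smaller. p-values use
the χ²(k−1) approximation, adequate at the group sizes this analysis
produces (hundreds to thousands of regions per state); no exact
permutation p-value is offered. When every pooled value is identical
the correction degenerates and H is defined as 0 with p = 1. Pairwise
two-group tests (df = 1) follow the same conditional-on-omnibus workflow
as the chi-squared layer.

## Synthetic track generator

The generator exists to create data with the exact structure the
analysis assumes, plus ground truth. Its latent-state chain uses the
distance-dependent kernel

    T(d) = w·T₀ + (1 − w)·1πᵀ,   w = exp(−d/λ),

the simplest mechanism that yields both a realistic marginal transition
table (T₀ at typical spacings) and co-methylation that decays with
distance (independent π draws at large gaps). Defaults:

- `n_sites` 10,000; `start_position` 10,001.
- Spacing: shifted geometric with minimum 2 bp (adjacent CGCG) and mean
  110 bp, the approximate mean CpG spacing of human chromosome 1
  (~2.28M CpGs over ~249 Mb); or fixed spacing for controlled
  experiments.
- Coverage: zero with probability 0.05 (about 95% of sites in typical
  WGBS tracks have reads), otherwise Poisson with mean 30 truncated at
  ≥ 1 (a typical deep WGBS coverage).
- `base_transition` T₀: the published STL001 spleen matrix; the eight
  published tissue matrices are available for multi-tissue scenarios.
  π defaults to T₀'s stationary distribution, so the chain is started
  at stationarity.
- `decay_length` λ = 1000 bp: co-methylation in human data is strong
  below ~1 kb and largely gone by a few kb.
- Emission: the true ratio is drawn uniformly on the latent state's
  interval ("uniform"). "interior" trims a margin (default 20% of the
  interval width per side) so that, at high coverage, the observed
  state almost surely equals the latent state — the noise-free limit
  used in recovery tests. "beta" draws a scaled Beta(2, 2), bunching
  ratios mid-interval.
- Read sampling: methylated reads ~ Binomial(coverage, true ratio);
  the observed ratio is their fraction, missing at zero coverage.

All draws flow from one `numpy.random.default_rng(seed)` stream, so a
config determines its track byte-for-byte.

What the generator does **not** emulate: CpG density heterogeneity
(islands vs deserts), strand asymmetry, non-CpG methylation, coverage
autocorrelation along the genome, bisulfite conversion failure, and any
dependence of methylation on genomic context. Passing recovery tests
therefore demonstrate that the pipeline measures the modeled
distance-dependent transition structure correctly — not that real
tissues follow the model.

## Verification problem sizes and numerical notes

The validation suite pins its claims at these scales, chosen to make
sampling error small relative to each tolerance while keeping the whole
suite fast:

- Transition-matrix recovery: fixed 20-bp spacing, λ = 10⁶ (the kernel
  is then homogeneous to within exp(−2·10⁻⁵)), 100,000 sites, coverage
  mean 200 with interior emissions, fixed seed. Estimated row
  percentages match T₀ within 2 percentage points per cell; the binding
  constraint is the rare initial state B (~3% of sites, so ~0.9 pp
  standard error per cell at this size).
- Noise-free state agreement: same conditions; ≥ 99% of observed states
  equal the latent state (measured ≈ 99.6%; the residual errors sit
  within a binomial standard deviation of an interval boundary).
- Oracle agreements: SMR segmentation vs a run-length-encoding oracle on
  1,000 random tracks (exact); Kruskal–Wallis vs the scipy reference on
  1,000 random tied datasets (≤ 1e-9 relative); Pearson chi-squared vs
  direct formula evaluation on 1,000 random tables (≤ 1e-10 relative).
- Determinism: two full CLI runs on identical inputs produce
  byte-identical CSV/BED/manifest outputs.

Published-table reproduction: the stored three-spleen-sample count
tables reproduce the published row percentages to two decimals (three
cells in the source tables are printed one hundredth above the exactly
rounded value; the comparison allows that last-digit slack), the four
omnibus statistics X² = 1323.14 (A), 1056.65 (B), 1492.95 (C), 9013.65
(D) with df = 6, and the featured contributions 11.07 (STL001 A→A) and
4666.12 (STL001 D→C). The ÷10/÷100 scaled statistics depend on an
integer-rounding rule the source does not state; with half-away-from-zero
rounding the ÷1000 step reproduces the published 1.64 / p = 0.95 for
state A, and the ÷1 step is exact by construction, but intermediate
steps may differ in the last digit and are not treated as reference
values.

## Limitations

- Single-chromosome tracks by construction; cross-chromosome pairs and
  liftover are out of scope.
- No between-sample co-methylation (WGCNA-style networks), no DMR
  calling, no smoothing or imputation of NA sites, and no genomic
  annotation of SMRs (gene body / promoter / CpG island context).
- The chi-squared layer assumes independent pairs; adjacent pairs share
  a site, so the tests are descriptive comparisons, not calibrated
  inference on dependent data — one reason the sensitivity scan, not the
  raw p-value, carries the interpretation.
- Real-data reproduction of full-chromosome SMR summaries requires the
  original Roadmap tracks, which the package does not download.
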