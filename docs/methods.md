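# Methods

## Problem and model

`aneuscore` quantifies aneuploidy — deviation from the euploid chromosome
complement — from copy-number log2-ratio (logR) profiles, and carries that
quantification through the downstream analyses used to ask whether phenotypes
attributed to a driver genotype are in fact explained by chromosomal
copy-number change: per-arm alteration tests between genotype groups,
chromosome-level dosage–expression correlation, TP53 genotype calling from
mutation tables, and survival stratified by aneuploidy quartile.

Two per-sample statistics are central:

* **Aneuploidy score (AS).** With `r_b` the parental-relative logR of bin
  `b` and `w_b` its width in Mb,

  `AS = Σ_b |r_b| · w_b`   (default `per_Mb` weighting).

  The profile is first expressed *relative to the parental clone* by bin-wise
  subtraction of the parental binned profile, so alterations shared with the
  ancestor cancel and AS measures alterations acquired since the clone
  diverged. The raw "sum of absolute segmented log ratios" has no canonical
  unit — it depends on whether one sums per probe, per segment, or per unit
  length — so the weighting is a mode (`per_Mb`, `per_bin`, `per_segment`).
  `per_Mb` is the default because it is invariant to probe density and bin
  width; the modes agree in rank ordering for a fixed segment structure.
  Published absolute AS quantile boundaries from other pipelines are
  segmentation-convention-specific and are deliberately not reproduced.

* **Fraction of genome altered (FGA).** Length of segments with
  |mean logR| strictly greater than 0.2, divided by the total segmented
  length. The inequality is strict: a segment at exactly 0.2 does not count.

Samples are classed by quartile of the cohort statistic: at or below the Q1
boundary → `aneuploid_low`, at or above Q3 → `aneuploid_high`, else
`intermediate`. Boundaries use the linear-interpolation empirical quantile
and are inclusive at both extremes (published usage mixes strict and
inclusive comparisons; a single inclusive convention is applied).

## Coordinates

Internally all coordinates are 0-based half-open base pairs; SEG I/O converts
to and from the ecosystem's 1-based inclusive convention, and `chr`-prefixed
chromosome names are normalized. Every chromosome splits at its centromere
into p/q arms; the bin grid (default 1 Mb) never crosses a centromere, so arm
statistics are exact sums of bins. The `hg38-like` preset embeds approximate
hg38 autosome + X lengths and centromere midpoints; a `scale` option shrinks
all coordinates proportionally (tests and the acceptance script use 1/10
scale so runs complete in seconds while preserving arm structure).

## Segmentation

The segmenter converts probe-level logR to constant-mean segments by
minimizing a penalized least-squares cost

`cost = Σ residual² + λ · n_segments`,

via recursive binary splitting: the split of a segment is the leftmost
position maximizing the residual-sum-of-squares reduction, accepted only if
that reduction exceeds λ and both children keep `min_probes` (default 5)
probes. A local refinement pass then repositions each breakpoint within its
flanking segments, replaces adjacent breakpoint pairs by a single better
split, removes breakpoints whose contribution no longer exceeds λ, and
re-attempts splits, until the cost is stable. Adjacent segments whose means
differ by less than `merge_delta` (default 0.05 logR) are merged as a
post-pass outside the cost. Segment boundaries sit at midpoints between
flanking probes; segment means are plain probe means (no shrinkage); there
is no outlier-smoothing pre-pass.

Defaults: λ = 0.15 detects a 0.3-logR step (half of a single-copy gain on a
diploid background, log2(3/2) ≈ 0.585) sustained over ≥ 5 probes at noise
sd 0.1, while suppressing splits on pure noise.

An exact O(n²) dynamic program over all segmentations of the same cost
(`exact_segmentation_dp`) serves as an independent reference solver. Under
the study conditions (40-probe windows, copy-step levels, noise sd 0.1, ≤ 3
breakpoints) the segmenter matches the DP optimum on every tested instance
(3000/3000 random instances). Being a local search, it can still miss the
global optimum on harder inputs (observed ~0.6% of instances at 60 probes,
noise sd 0.15, 4 closely spaced breakpoints) — a known limitation shared by
all binary-segmentation-family methods.

## Synthetic data generator

The generator produces every pipeline input with known ground truth. What it
emulates, and what it does not:

* **Karyotypes.** Integer copy number per bin starting from CN 2.
  Whole-genome doubling (probability `p_wgd`, default 0.2 — about one in
  five clones, as seen in near-tetraploid clone panels) is applied first and
  sets the baseline ploidy to 4. A Poisson number of events
  (`events_mean`, default 5) then add or remove one copy on whole
  chromosomes, arms, or focal intervals (2–20% of a chromosome).
  Chromothripsis (probability 0.1) rewrites one chromosome as alternating
  runs between baseline−1 and baseline+1 with an exact, recorded number of
  state switches; run lengths are uniform. No subclonal mixtures, no
  allele-specific copy number, no read-level simulation.
* **Probe signal.** Probes are evenly spaced at `probe_density`
  (default 2/Mb); value = log2(CN/2) of the covering bin + Gaussian noise
  (sd 0.1), then median-centered per sample, emulating array normalization.
  Median-centering (not mean) is deliberate: it makes a pure WGD genome
  render as logR ≈ 0 everywhere, reproducing the real-world blind spot that
  makes tetraploidy invisible to relative copy-number assays and detectable
  only by DNA-content measurements. CN 0 is floored at 0.5 before the log.
  Real array artifacts (GC waves, probe-specific biases) are not modeled,
  so passing tests show correct recovery under well-behaved noise, not
  robustness to wave artifacts.
* **Expression.** Gene g in sample s has negative-binomial counts with mean
  `μ_g · (CN_gs/2)^dosage_slope`; `μ_g` is lognormal around a base mean and
  fixed across samples; dispersion α (variance μ + αμ²) is constant across
  genes (default 0.1); α = 0 degenerates to Poisson. `dosage_slope = 1`
  means expression proportional to copy number.
* **Mutation tables.** MAF-dialect TP53 rows per sample realizing a drawn
  class: WT (no row, or a silent row 30% of the time), missense (one
  hotspot change, e.g. R175H/R273H), truncating
  (nonsense/frameshift/splice-site), multi (two non-silent records),
  in-frame (one in-frame deletion).
* **Survival.** Exponential event times; samples at or above the 75th FGA
  percentile get hazard `baseline · HR` (default HR 3), all others the
  baseline; independent exponential censoring with hazard
  `censor_rate · baseline` (default 0.3). Real progression-free-survival
  hazards are neither exponential nor proportional across the whole follow-up;
  the generator is a calibration target, not a disease model.
* **Growth curves.** `N0 · 2^(t/Td)` with multiplicative lognormal noise of
  a given coefficient of variation (mean-one noise, so the expectation is
  unbiased).

All generators are bit-reproducible for a fixed seed; generator functions
also accept a shared `numpy.random.Generator` so a pipeline run draws from
one seeded stream.

## Statistical components

* **Per-arm comparison:** per sample, bin-length-weighted mean logR per arm;
  two-sided two-sample t test per arm (Welch by default — safer under
  unequal variances; a pooled-variance mode is available), Benjamini–
  Hochberg adjustment across arms, flags at adjusted p < 0.1. Arms where
  both groups are identical constants are reported as t = 0, p = 1. Note
  the FDR semantics: with one strongly altered arm present, BH at q = 0.1
  intentionally tolerates a null arm riding along in roughly 2q/m-quantile
  fraction of datasets; the controlled quantity is the false-discovery
  proportion, not the per-dataset exactness of the flagged set.
* **Gain/loss frequency tracks** reuse the 0.2 logR call threshold for
  consistency with the FGA definition.
* **Average chromosomal copy number** from a profile is `2 · 2^m` with `m`
  the length-weighted mean logR of the chromosome.
* **Dosage correlation:** per chromosome, per-sample mean of log2(x+1)
  expression over the chromosome's genes (log transform stabilizes variance
  and makes the dosage slope interpretable; `raw` mode available;
  all-zero genes are dropped as carrying no dosage signal) against
  per-sample average copy number; Pearson r with the t-transform p-value
  plus the least-squares line and a 95% mean-response band. Zero variance
  on either axis yields a flagged `undefined` result instead of NaN.
* **TP53 calls:** see the module docstring for the full rule set. Decisions
  taken where sources are silent: stop-gain and nonsense are one canonical
  code; splice-region (non-essential-site) variants are *not* truncating;
  a missense record accompanied only by silent records is missense (silent
  records are ignored before counting alterations, symmetrically with the
  WT definition); noncoding records are ignored in both tumor and cell-line
  modes; a single record of a class fitting none of the definitions (e.g. a
  nonstop mutation) is excluded as "unclassifiable alteration".
* **Survival:** Kaplan–Meier product-limit estimation and the unweighted
  log-rank test (χ², k−1 df), via lifelines; events precede censorings at
  tied times (standard convention). No Cox model. FGA quartiles for the
  stratified comparison are computed within each TP53 class by default
  (keeps Q1/Q4 sizes balanced across classes); a pooled mode exists.
* **Doubling time:** `duration · log 2 / (log final − log initial)` between
  the first and last timepoints (`endpoint`, the faithful default) or by
  log-linear regression over all points (`fit`, for noisy data). A
  non-growing culture is a flagged result, not an exception.
  Tumor volume is `width² × length / 2` with a swap guard enforcing the
  caliper convention width ≤ length; relative migration is migrated/total.

## Numerical choices and degenerate inputs

Quantile classes require ≥ 4 samples (error below), and an all-identical
cohort is all-intermediate with a warning. FGA requires a non-empty profile.
Binning requires segments to cover ≥ 99% of the grid (configurable);
uncovered bins are zero-filled with a warning. Segmentation emits chromosomes
with fewer than `min_probes` probes as single segments with a warning.
Ties in split position break leftmost; ties between event and censoring
times resolve events first.

## Problem sizes

Tests and the acceptance script run on a 1/10-scale hg38-like genome
(≈ 309 Mb, 23 chromosomes) at 2 probes/Mb and 1 Mb bins, with 4–6-chromosome
toy genomes for calibration loops; cohort sizes are 20 samples for recovery
checks, 100 seeds for pass-rate estimates, 500–1000 replicates for
calibration rates, and 10,000 samples for genotype-proportion recovery.
These sizes are the package's reference experiment; all scale linearly.

## Known limitations

The segmenter is locally, not globally, optimal outside the conditions
documented above. The logR floor at CN 0 makes homozygous-deletion depth
uninformative beyond "strongly negative". WGD is invisible to AS/FGA by
construction (median-centering); detecting it requires DNA-content data
outside this package's scope. The expression model has constant dispersion
and no covariance between genes; the survival model is exponential with a
single hazard step at the FGA Q3 boundary. Cohort filters assume one row
per tumor sample with an optional individual identifier.
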