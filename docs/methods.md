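# Methods

## The design being modelled

A panel of near-isogenic inbred lines (MIKK-style: derived from a wild
founder population by repeated sib-mating) is sampled with one brain
per line per cell of a 2×2 design — sex (F/M) × season, where season
is a photoperiod treatment (summer-like long days vs winter-like short
days). Because individuals within a line are genetically
near-identical, the between-line variance of a gene's expression
estimates its genetic variance, and four samples per line suffice for
line-level contrasts that an outbred design could not support at this
size.

The analysis set is produced by four filters, in this order: read-level
QC, whole-sample expression outliers, SNP identity check, design
completeness. The removal log records the first rule that fired per
sample. The filters commute on the retained set for fixed cohort
statistics; the order only affects which rule gets credited.

## Synthetic data

The generator draws the focal gene on the natural-log scale,

    y = mu + b_line + beta_season·I(summer) + beta_sex·I(female)
          + g_line·I(summer) + d_line·I(female) + eps,

with `b ~ N(0, σ²_line)`, `g ~ N(0, σ²_line_season)`,
`d ~ N(0, σ²_line_sex)` drawn once per line and `eps` per sample, then
exponentiates so TPM values are strictly positive and the divergence
denominators are safe (`back_transform=False` keeps the log scale).
Drawing `g` and `d` once per line makes some lines genuinely
winter-higher or male-higher, so the divergence stage has true
positives to find.

Defaults are the study conditions: 25 lines × 1 sample per cell
(100 samples); `σ²_line = 0.03`, `σ²_resid = 0.07` so the line
intercept explains exactly 30% of the log-scale variance;
`beta_season = 0.12` (summer-positive, a moderate effect at n = 100);
`beta_sex = 0` (no average sex effect); `σ_line_season = 0.15` and
`σ_line_sex = 0.12`, large enough that line-specific deviations are
detectable against `σ_resid ≈ 0.26`; `mu = 3` (≈ 20 TPM). The SNP
panel defaults to 1377 SNPs, fully homozygous per line
(heterozygosity injectable via `het_rate`), per-SNP alt-allele
frequency uniform on (0.1, 0.9) across lines, read depth
Poisson(30) per sample per SNP with a 0.5% per-read allele error.
Chromosome labels cycle over 1–24 and region labels over a
mostly-exonic cycle so the panel-selection filter (exon, not chrom 2,
depth ≥ 10) is exercised. Swaps replace a configurable fraction of
samples' counts with counts drawn from a uniformly chosen different
line; the swap log is the ground truth tests assert against.

What the generator does **not** emulate: multi-gene correlation
structure (decoy genes are i.i.d.), sequencing-level artefacts behind
the QC metrics (the metrics themselves are simulated as clean and
failures are injected directly in tests), linkage between SNPs, and
any genotype–expression coupling. Passing tests therefore demonstrate
the statistical machinery under the stated generative model, not
robustness to real RNA-seq pathologies.

## SNP identity check

Genotypes are called per site from allele counts: no-call below
`min_site_depth = 5`; an allele whose fraction is ≥ `hom_fraction =
0.9` gives the corresponding homozygous call (comparing each allele's
own fraction keeps the boundary float-exact); otherwise het. The
calling rule and both thresholds are conventions exposed in the
configuration — at RNA-seq depths they are robust, but nothing deeper
is claimed for them. A sample's match proportion against a line is the
fraction of *callable* SNPs whose call equals that line's expected
genotype; using the per-sample callable denominator (not panel size)
avoids penalising low-depth samples for no-calls. The sample is
retained iff `p_assigned − max_line p > −0.005` (strict). Ties at the
maximum are all reported; the decision only uses the maximum value, so
ties and line-column order cannot change it.

## QC and completeness filters

- Strandedness failures are removed outright; unique-mapping below 50%
  is removed strictly (exactly 50% is retained).
- "Unusual GC content" has no standard definition; it is implemented
  as a robust z-score of the per-sample GC summary against the cohort
  median and MAD, threshold 3, and logged as a heuristic.
- Whole-sample outliers: per-sample summary `s = median_genes
  log2(TPM+1)`; removed iff `|s − median(s)|/(1.4826·MAD(s)) > k` with
  `k = 5`. A zero MAD removes nobody. The summary statistic and `k`
  are conventions (config-exposed); the workflow this mirrors does not
  pin them down.
- Completeness: a line is kept iff all four sex×season cells are
  occupied; within each cell exactly one sample survives, chosen as
  the lexicographically smallest sample id so the filter is total and
  deterministic even on inputs the design says should not occur
  (extra samples per cell are logged).

## Variance partition

`fit_linear` is OLS (via statsmodels) with the Gaussian ML
log-likelihood. `fit_mixed` implements the single-random-intercept
model directly by profiling: for a fixed variance ratio
`λ = σ²_line/σ²_resid` the GLS fixed effects and the residual variance
have closed forms (block-wise rank-one corrections of the unweighted
cross-products, since `(I + λJ)⁻¹ = I − λ/(1+λn_i)·J` per group), so
the (restricted) likelihood is a 1-D function of `λ`. That function is
minimised deterministically: a 61-point grid on `log λ ∈ [−15, 15]`
followed by bounded Brent refinement (`xatol = 1e-10`), then compared
against the `λ = 0` boundary; `σ²_line` is truncated at zero when the
boundary wins. No random starts; permutation of rows changes estimates
only within the optimiser tolerance (~1e-8 in the ratio). The
implementation is cross-checked in the tests against the balanced
one-way ANOVA closed form and against statsmodels' MixedLM, which is
never used as the implementation.

Conventions that genuinely had to be chosen:

- **REML vs ML.** Variance components, ICC and R²s are reported from
  REML; AIC comparison and the LRT use ML refits of both models so
  they sit on one likelihood (REML likelihoods of models with
  different fixed or random structure are not comparable). Parameter
  counts: linear `p+1`, mixed `p+2` (AIC conventions differ across
  software; this one counts every estimated variance).
- **Coding.** Treatment coding with reference levels female and
  winter, so a positive season coefficient means summer-higher.
- **R².** Marginal R² = `var(Xβ̂)/(var(Xβ̂)+σ²_line+σ²_resid)`,
  conditional adds `σ²_line` to the numerator; `var(Xβ̂)` is the
  population variance of the fitted fixed predictor.
- **Tests.** Per-term Wald χ² on 1 df (`(β̂/SE)²`), no small-sample df
  correction — for 1-df non-interacting terms this is the Type-II
  test. The random-intercept LRT is referred to χ²₁ without the
  boundary 50:50 mixture correction, which makes it conservative (the
  null rejection rate stays below the nominal 5%; the tests assert
  ≤ 8%).
- **Interaction screen.** The sex×season interaction is fitted first
  and dropped iff its Wald p-value exceeds `alpha = 0.05` (strict);
  under the null this drops it with probability ≈ 1 − alpha.

## Divergence indexes and bootstrap flagging

The indexes are asymmetric relative contrasts with the summer (resp.
female) mean as reference: relabelling the seasons maps an index `v`
to `−v/(1−v)`, not `−v`; a metamorphic test pins that transform.
Indexes with a non-positive reference mean are undefined, logged, and
excluded from the bootstrap input rather than imputed.

The envelope is the percentile bootstrap CI of the **mean** of the
observed index vector: resamples of the same size with replacement,
each resample's mean, empirical percentiles with linear interpolation.
The two index types are resampled independently; nothing joint is
needed for marginal CIs. Flagging is strict (values on a bound count
as within).

Two properties of this procedure are asserted as facts rather than
hidden: (1) at 25 lines its true coverage for a normal mean is ≈ 93%,
slightly under nominal — the usual small-sample undercoverage of
percentile intervals, confirmed against an independent R
implementation; (2) because the envelope tracks the CI of the *mean*,
growing the panel at fixed index dispersion narrows it and drives the
flagged fraction toward one even for exchangeable lines. The procedure
flags deviation from the population mean, not outlier status.

## Problem sizes and numerical conventions

The test suite works at the study's scale (25 lines × 4 samples) and
asserts distributional claims over replicates: 200 seeded datasets for
ICC recovery (mean estimate within ±0.05 of the 0.30 truth) and for
the null LRT rate, 50 seeds for exact swap detection (error rate 1%,
depth 10, discordant lines), and 20 000 index vectors for bootstrap
coverage, where the Monte-Carlo error (±0.18 pp) is small against the
quantity's distance from nominal. Pipeline outputs are written with a
fixed 10-significant-digit float format so identical configurations
reproduce byte-identical files; reading the tables back and refitting
agrees to well within that precision.

## Known limitations

- One random intercept only; no crossed/nested random effects, no
  per-line variance heterogeneity.
- Single-gene inference; no multi-gene error-rate control.
- The GC and MAD outlier criteria are reasonable conventions, not
  recovered definitions; results on real data could be sensitive to
  them.
- The divergence flags inherit the bootstrap-of-the-mean caveats
  above and are best read, as in the underlying design, as
  exploratory.
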