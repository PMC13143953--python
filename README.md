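# mikkexpr

Quantitative-genetics analysis of single-gene brain expression across a
panel of near-isogenic fish lines (the MIKK medaka panel design: each
line is essentially one genotype, replicated across individuals, with
one brain sample per sex × season photoperiod cell). The package takes
a TPM expression table plus sample metadata and answers three
questions:

1. **Is each sample really from the line it is labelled with?**
   A SNP-concordance identity check calls genotypes from per-sample
   allele counts at a panel of high-confidence exonic SNPs and retains
   a sample only if its assigned line's match proportion is within a
   strict threshold of the best-matching line's
   (`p_assigned − p_best > −0.005`).
2. **How much expression variance is genetic (between-line)?**
   A fixed-effects linear model `y ~ season + sex` is compared with a
   linear mixed model adding a line random intercept,
   `y = Xβ + Zb + ε`, `b ~ N(0, σ²_line)`, `ε ~ N(0, σ²_resid)`.
   Reported: multiple R² (linear), marginal/conditional R² and the
   intraclass correlation `ICC = σ²_line / (σ²_line + σ²_resid)`
   (mixed, REML), AIC for both models and the likelihood-ratio test of
   the random intercept (ML, χ² with 1 df), plus per-term Wald χ²
   tests of season and sex.
3. **Which lines diverge from the population trend?**
   Per line, the seasonal index `(mean_summer − mean_winter)/mean_summer`
   and the sexual index `(mean_female − mean_male)/mean_female`; a
   percentile bootstrap (1000 resamples) of the mean of the observed
   indexes gives a 95% envelope, and lines strictly outside it are
   flagged above/below.

Because real data of this kind are rarely public, a first-class
synthetic-data generator reproduces the design's statistical structure
(line random intercept, season/sex effects, line-specific seasonal and
sexual deviations, near-isogenic homozygous SNP panels, injectable
sample swaps), so the full pipeline is testable end to end.

## Worked example

Run the whole pipeline on a synthetic study-scale dataset (25 lines ×
4 samples, line effect ≈30% of log-scale variance, summer-positive
season effect):

```sh
$ mikkexpr run --preset study --seed 1 --out run1
pipeline complete -> run1

$ cat run1/model_comparison.tsv
Model   Random effect   R2      AIC
Linear model    None    0.051   663.6927
Linear mixed-effects model      Medaka line     0.211   662.195

$ mikkexpr divergence --expression run1/expression_analysis.tsv \
    --metadata run1/metadata_analysis.tsv --seed 1
season: 17/25 lines flagged (7 negative)
sex: 15/25 lines flagged (7 negative)
```

Reading the output: the fixed effects alone explain 5.1% of the
variance in `bdnf` expression; adding the line random intercept raises
the explained share to 21.1% (conditional R²) for this replicate, and
the mixed model has the lower AIC. The divergence report flags 17 of
25 lines whose seasonal expression change falls outside the bootstrap
95% CI of the population mean change; the 7 negative ones express more
under the winter photoperiod. Single replicates at this sample size
are noisy — the estimated ICC here is 0.17 against a generative truth
of 0.30 — which is why the statistical guarantees are asserted over
hundreds of replicates in the test suite, not per run.

The run directory also contains the SNP-check report, the per-stage
removal log, per-line and per-condition summary tables
(`mikkexpr report --run-dir run1`), the divergence table with CI
bounds and flags, and a manifest (config hash, seed, version) from
which every number is reproducible; re-running with the same config
and seed reproduces byte-identical outputs.

The same stages are available as library functions
(`mikkexpr.generate_expression`, `run_snp_check`, `qc_filter`,
`mad_outlier_filter`, `completeness_filter`, `analyze_gene`,
`divergence_analysis`) and as the subcommands `simulate`, `snpcheck`,
`filter`, `varpart`, `divergence`, `run`, `report`.

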