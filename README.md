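# pqtlmr

Two-sample Mendelian randomization (MR) for circulating proteins, built
around *cis*-acting protein quantitative trait loci (pQTLs) as genetic
instruments. The package is aimed at genetic epidemiologists who want to
estimate the causal effect of a plasma protein level on one or more disease
outcomes from GWAS summary statistics alone, with the sensitivity analyses
that such an analysis needs to be credible: Steiger directionality
filtering, Bayesian colocalization with an LD check, and a proteome-wide
horizontal-pleiotropy audit.

## The model

Each instrument g is a SNP associated with the protein (the exposure X) at
genome-wide significance inside the *cis* window (±500 kb of the leading
pQTL), strong (F = (β_GX/se_GX)² > 10), common (MAF > 0.05), and
approximately independent of the other instruments after LD clumping at
r² < 0.2. For a single instrument the causal effect of X on an outcome Y is
the Wald ratio

    β_XY = β_GY / β_GX ,   se(β_XY) ≈ se(β_GY) / |β_GX| .

Multiple instruments that remain weakly correlated through LD are combined
by **generalized inverse-variance weighting (gIVW)**: generalized least
squares of β_GY on β_GX without intercept, with weighting covariance
Ω_ij = se_GY,i · se_GY,j · r_ij built from the signed LD correlation r. A
multiplicative random-effects model inflates the standard error by
max(1, √(Q/(k−1))) where Q is the residual heterogeneity statistic.
Multivariable MR generalizes the same GLS to a design matrix with one column
per exposure, giving each protein's direct effect.

Colocalization between the protein and an outcome over the cis region uses
per-SNP Wakefield approximate Bayes factors under a single-causal-variant
assumption, with per-SNP priors p1 = p2 = 1e-4 and p12 = 1e-5; the decision
statistic is PP4/(PP3+PP4) ≥ 0.9, corroborated by an LD check (r² ≥ 0.8
between an instrument and the outcome's lead SNP within ±500 kb).

Because real pQTL and outcome GWAS data are access-controlled, the package
ships an LD-structured synthetic generator (`pqtlmr.synthetic`) that draws
marginal GWAS estimates from MVN(R·b, D·R·D) with known ground truth, so
every stage is testable at desk scale.

## Worked example

The packaged 10-SNP toy region (`pqtlmr.fixtures`) encodes one instance of
every selection rule: an LD shadow, an out-of-window SNP, a sub-threshold
SNP, a rare variant, and a palindromic A/T SNP at MAF 0.45.

```sh
$ pqtlmr select --sumstats exposure.tsv --ld ld.tsv --chrom 9 --anchor-pos 1000000
instruments: rs001 rs003 rs007
total F: 63.75

$ pqtlmr harmonize --exposure exposure.tsv --outcome outcome.tsv
kept	8
flipped	1
dropped_palindromic	1
dropped_incompatible	0

$ pqtlmr mr --exposure exposure.tsv --outcome outcome.tsv --ld ld.tsv \
    --instruments rs001 --instruments rs003
beta=0.2 se=0.0184442 OR=1.2214 CI=(1.1780, 1.2664) p=2.14e-27 n_snps=2 Q=2.116e-30
```

Three candidates pass the cis/p/F/MAF/clump criteria; harmonization then
drops the palindromic rs007 (its MAF of 0.45 is too close to 0.5 to resolve
the strand), leaving two instruments whose Wald ratios both equal 0.2. The
gIVW estimate is therefore exactly 0.2 (odds ratio 1.22 per unit of protein)
with zero heterogeneity (Q ≈ 0). The same analysis runs end-to-end from a
YAML config via `pqtlmr run --config study.yaml`, writing a per-outcome
report (OR, 95% CI, Bonferroni-corrected p, colocalization posteriors
PP0–PP4, conditional H4, LD-check flag) and a run log.

The library surface mirrors the pipeline stages: `read_sumstats` /
`harmonize` (allele orientation), `select_cis_instruments` / `steiger_filter`
(instrument validity), `wald_ratio` / `givw` / `mvmr` / `bonferroni`
(estimation), `coloc_abf` / `ld_check` (colocalization), and
`scan_instruments` / `second_step_mr` / `adjust_with_mvmr` (pleiotropy
audit).

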