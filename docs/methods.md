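# Methods

This note documents the statistical model behind `pqtlmr`, the defaults and
their rationale, the synthetic data the validation rests on, and the
numerical and design choices that were genuinely open.

## Study design

The package implements a *cis*-pQTL two-sample MR pipeline: genetic variants
near a protein-coding gene that associate with the circulating protein level
serve as instruments for the protein, and their associations with a disease
outcome in an independent cohort identify the protein's causal effect under
the usual instrumental-variable assumptions. The pipeline runs one discovery
exposure dataset and optional validation exposure datasets (each selects its
own instruments), a set of outcomes with an optional positive control, and
three sensitivity layers: Steiger filtering against reverse causation,
Bayesian colocalization against confounding by LD, and a proteome-wide scan
for horizontal pleiotropy with multivariable adjustment.

## Harmonization

Exposure and outcome tables are aligned on the exposure's effect allele.
Non-palindromic allele pairs are matched directly or after strand
complement; a swapped orientation negates the outcome beta and complements
its EAF. Palindromic pairs (A/T, C/G) carry no strand information in their
labels, so orientation is inferred from allele frequency: if the minor
allele frequency exceeds 0.42 in either table the variant is dropped
(frequencies that close to 0.5 cannot distinguish the two orientations);
otherwise the orientation minimizing |eaf_exposure − eaf_outcome| is chosen.
The 0.42 cutoff is configurable. Variants present in only one table are
skipped with a logged count — no proxy-variant search is attempted. Indels
and multi-allelic records are rejected at read time; this is a
SNP-instrument pipeline.

## Instrument selection

Candidates must satisfy, simultaneously: chromosome equal to the locus
chromosome and position within the **closed** interval ±500 kb of the
leading pQTL (positions 1-based); p < 5e-8; per-SNP F = (β/se)² > 10;
MAF > 0.05. Greedy p-value-ordered clumping (ties: position, then variant
id) then discards any remaining candidate with r² ≥ 0.2 against an accepted
one, so the retained set is pairwise r² < 0.2. The combined instrument
strength is reported as the mean per-SNP F; a regression-form alternative,
F = (n−k−1)/k · R²/(1−R²) with R² the summed per-SNP variance explained, is
exposed as `total_f_regression` because the combined-F definition used for
published totals is ambiguous.

Because gIVW models the residual LD among instruments explicitly, clumping
at the relatively permissive r² < 0.2 is safe: correlation surviving the
clump enters the weighting covariance rather than biasing the estimate.

## Steiger filtering

A valid instrument should explain more variance of the exposure than of the
outcome. Per instrument and trait, variance explained is approximated from
the Wald z on the trait's analysis scale, r² = z²/(z² + n − 2); the
instrument is kept iff r²_exposure > r²_outcome, with ties removed
(conservative). No liability-scale transformation is applied for binary
outcomes: the z-based form needs neither allele frequency nor prevalence and
is standard. A consequence worth knowing: on the observed log-odds scale,
r² for a strong signal is almost independent of n (z² grows linearly in n,
and r² ≈ z²/n), so the power of the directionality comparison comes from the
effect-size asymmetry of a reverse-causal path (the leaked exposure effect
is attenuated by the outcome-to-exposure coefficient), not from the sample
size ratio itself.

## Estimation

* **Wald ratio** (1 instrument): β_XY = β_GY/β_GX, first-order delta SE
  se_GY/|β_GX|. The second-order form adding β_GY²·se_GX²/β_GX⁴ is available
  (`second_order=True`); with the instrument strengths this pipeline
  enforces (F ≫ 10) the difference is negligible for moderate outcome z.
* **gIVW** (k ≥ 1): GLS without intercept, Ω_ij = se_GY,i·se_GY,j·r_ij,
  β = (xᵀΩ⁻¹x)⁻¹xᵀΩ⁻¹y, naive SE = (xᵀΩ⁻¹x)^{-1/2}. The heterogeneity
  statistic Q = rᵀΩ⁻¹r (r the residuals) drives multiplicative
  random-effects inflation max(1, √(Q/(k−1))); the SE never deflates. With
  k = 1 the estimate reduces to the Wald ratio exactly. Ω is factorized by
  Cholesky; a non-positive-definite Ω (near-duplicate instruments) raises an
  error suggesting stricter clumping rather than silently regularizing.
* **Multivariable MR**: the same GLS with design matrix X (one column per
  exposure), b = (XᵀΩ⁻¹X)⁻¹XᵀΩ⁻¹y, per-exposure SE from the diagonal of
  (XᵀΩ⁻¹X)⁻¹, joint inflation max(1, √(Q/(k−p))). Rank-deficient designs
  and k ≤ p raise errors naming the problem.
* p-values are two-sided from the standard normal; 95% intervals use the
  multiplier 1.959964 and are reported on the odds-ratio scale
  (exp(β ∓ 1.959964·se)); for quantitative outcomes the same fields carry
  exp(β). Multiple testing across outcomes uses plain Bonferroni,
  min(1, p·m), with m at least the number of non-control outcomes.

Because the random-effects factor is floored at 1 while Q fluctuates below
its expectation half the time, the combined test is mildly conservative at
small k — the simulated null rejection rate at α = 0.05 sits near 0.035
rather than 0.050 for k = 2. This is a property of the named estimator, not
a defect.

## Colocalization

Per-SNP evidence is the Wakefield approximate Bayes factor:
log ABF = ½·log(1−r) + z²r/2 with r = W/(V+W), V the squared SE, W the
squared prior effect SD. Prior effect SDs default to 0.15 (quantitative,
per-SD units) and 0.2 (binary, log-odds units) — the framework's
conventional values, configurable per trait since the hypothesis priors
p1 = p2 = 1e-4, p12 = 1e-5 say nothing about effect magnitude. Hypothesis
evidence is accumulated in log space with max-shift: S1, S2, S12 are
log-sum-exp of L1, L2, L1+L2; H3's sum over ordered distinct pairs uses the
identity log(exp(S1+S2) − exp(S12)), falling back to direct pairwise
summation when cancellation approaches machine precision (mass concentrated
on the diagonal), and PP3 is exactly 0 for a single-variant region. The
computation is stable for |z| beyond 50. All five posteriors are always
reported; the decision statistic is PP4/(PP3+PP4) ≥ 0.9. The region is the
closed ±500 kb window around the leading pQTL; variants missing from either
trait are dropped with a logged count.

The LD check complements the Bayesian decision: each instrument is compared
with the outcome's smallest-p variant within ±500 kb (ties broken as in
clumping), passing at r² ≥ 0.8. In the orchestrated pipeline,
colocalization runs for outcomes with Bonferroni-significant discovery MR
and always for the positive control (override: `coloc_all`).

## Pleiotropy audit

Step 1 flags every catalog protein that any audited instrument hits at
p < 5e-8 (the audited exposure itself excluded; the lookup threshold is
configurable since published scans rarely state it). Step 2 runs gIVW of
each flagged protein on each outcome using the protein's own instruments,
Bonferroni-corrected over the attempted pairs; the significance default is
0.05 with 0.01 available, as reported practice varies between the two.
Where a pair passes, the primary exposure's estimate is recomputed by
two-exposure multivariable MR over the union of instruments, yielding its
direct effect. The catalog is a local directory with a TSV manifest — no
remote lookups.

## Synthetic data

The generator emulates one-cohort GWAS summary statistics over a cis
region. Genotypes are parameterized on the standardized (per-SD) scale;
given joint (conditional) effects b and LD correlation R, true marginal
effects are R·b and observed estimates are drawn from MVN(R·b, D·R·D) with
D = diag(se) — the exact sampling covariance of marginal estimates from a
single cohort. Standard errors are closed-form: 1/√n for quantitative
traits; 1/√(n·φ(1−φ)·2·maf(1−maf)) on the log-odds scale for binary traits
with case fraction φ. LD families: AR(1) (r_ij = ρ^|i−j|), uniform blocks,
identity; near-singular requests are diagonally jittered. A `noise=False`
switch emits exact expected marginals for deterministic oracles, and all
seeds are explicit arguments.

Study-level simulation places k instruments evenly over the region with
standardized exposure effect 0.1 (≈1% variance each, genome-wide
significant at the sample sizes used), sets outcome joint effects to
β_XY·b plus optional per-instrument pleiotropy, and can make a share of
instruments outcome-first: the variant receives the effect on the outcome
and the exposure inherits only the leaked share (default leak coefficient
0.5), the configuration Steiger filtering must remove. Default sample sizes
(35,000 exposure; 100,000 outcome, case fraction 0.3) mirror the scale of
contemporary proteome and biobank GWAS.

What the generator does **not** emulate: sample overlap between cohorts,
allele-frequency-dependent LD from real reference panels, imputation
quality, population stratification, winner's-curse selection of the
exposure dataset, or assay-specific protein measurement error. Passing
tests therefore demonstrate correctness of the estimators and decision
rules under the stated sampling model, not robustness to those real-data
complications.

## Validation problem sizes

The acceptance checks use: 100 regions (M ∈ {1, 2, 5, 20, 50}) for
enumeration equivalence of the colocalization posteriors; 200 random
instrument sets (k ≤ 10, AR(1) LD) for GLS equivalence; 1000 replicate
studies (k = 2, LD r = 0.4, binary outcome) for recovery of β_XY = 0.2 and
interval coverage; 2000 null studies for size plus 400 ten-outcome families
for family-wise error; 200 replicates per colocalization scenario (M = 200,
AR(1) ρ = 0.9, distinct causal variants 100 steps apart so their r² is
far below 0.05); and 200 replicates per Steiger direction. These sizes give
Monte-Carlo standard errors comfortably inside the asserted bands.

## Known limitations

* Variant ids must be reconciled across datasets upstream; no rsid aliasing
  or merging is modeled.
* No proxy-instrument search, liftover, or genotype-level input.
* Steiger filtering uses the observed-scale r² for binary traits; a
  liability-scale refinement would need prevalence input.
* The colocalization model assumes at most one causal variant per trait in
  the region; multi-signal fine-mapping extensions are out of scope.
* The pleiotropy catalog is local and static; the audit is only as complete
  as the catalog supplied.
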