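# Methods

`pqtlmr` implements a proteome-wide two-sample Mendelian randomization
(MR) and colocalization workflow for linking genetically predicted
circulating protein levels to reproductive-timing outcomes (age at
menarche, AAM; age at natural menopause, ANM), exercised end to end on
synthetic GWAS summary statistics with known ground truth. This note
records the models, the default parameters and why they were chosen, the
numerical conventions, and the known limitations.

## The causal model and estimators

A cis-pQTL — a variant within 1 Mb of a gene's transcription start site,
associated with the encoded protein's circulating level at p ≤ 5×10⁻⁸ —
serves as an instrumental variable for the protein. With SNP-protein
effect β_x (per allele, protein in SD units) and SNP-outcome effect β_y
(outcome in years), the single-instrument **Wald ratio** β_y/β_x estimates
the causal effect of the protein on the outcome in years per SD. Its
standard error uses the first-order delta method |se_y/β_x| (the
convention of the standard MR tooling, which ignores exposure-side
uncertainty); a second-order option adds the β_y²se_x²/β_x⁴ term.

Multi-instrument estimators operate on a harmonized set of per-SNP
(β_x, β_y) pairs:

- **IVW**: the 1/se_y²-weighted zero-intercept regression of β_y on β_x.
  When Cochran's Q exceeds its degrees of freedom the standard error is
  inflated by √(Q/df) (multiplicative random effects); otherwise fixed
  effects. With one instrument it reduces exactly to the Wald ratio.
- **MR-Egger**: the same regression with an intercept; the slope is the
  pleiotropy-adjusted effect, the intercept a test of directional
  pleiotropy. Residual sd is floored at 1. The intercept is identified
  only when instrument strengths vary across SNPs — with identical
  strengths the observed β_x spread is pure sampling noise and the
  intercept absorbs the causal signal; the synthetic panels used for
  calibration therefore draw per-SNP variance explained from a range.
- **Weighted median**: the median of ratio estimates under cumulative
  (β_x/se_y)² weights; consistent when ≥50% of the weight is on valid
  instruments. Standard error by parametric bootstrap (5,000 draws, fixed
  seed).
- **Weighted mode**: the argmax of a Gaussian-kernel-smoothed weighted
  ratio density; bandwidth is 1.5× a Silverman-style rule on the ratios;
  bootstrap standard error as above.

**Instrument strength** is summarized by R² ≈ 2β²f(1−f) (β on a
standardized phenotype, f the effect-allele frequency) and
F = (R²/k)/((1−R²)/(n−k−1)), with F > 10 the conventional adequacy bound.

**Steiger directionality** compares the variance the instrument explains
in exposure vs outcome (both via 2β²f(1−f) on standardized scales):
TRUE means the exposure explains more, supporting exposure → outcome.
The p-value is a two-sample z-test on Fisher-transformed correlations —
the underlying package internals of the original tooling are not
published, so this classical construction is the package's own choice.

**Power** for a continuous outcome uses the non-centrality
|b|√(nR²) with b the standardized effect (years divided by the outcome
SD in years), n the outcome GWAS size, and two-sided normal rejection at
level α. At the strongest printed operating point (n = 370,000,
R² = 0.771, effect 0.02 years, SD 1.3 years, α = 0.05/1300) this rounds
to 100%.

## Harmonization

Outcome records are re-expressed on the exposure's effect allele: swapped
alleles flip the effect sign and frequency; strand flips are resolved by
complementing; palindromic (A/T, C/G) variants are resolved by allele
frequency, and are flagged ambiguous — and dropped from harmonized sets —
when either frequency lies in [0.42, 0.58], the common default of
harmonization tooling (the band is configurable). Records without an
allele frequency are read but are ineligible for R², Steiger, and
colocalization. Coordinates are 1-based; the cis window is
[tss − 10⁶, tss + 10⁶] inclusive.

## Colocalization

Single-variant colocalization follows the Wakefield approximate Bayes
factor enumeration: per SNP, log ABF = ½log(1−r) + ½z²r with
r = w/(w+se²) and prior effect variance w = 0.15² (a standardized
quantitative-trait prior; configurable). Hypotheses H0–H4 (no
association / trait-1 only / trait-2 only / two distinct causal variants
/ one shared variant) are accumulated entirely in log space, so |z| up to
200 is exact; priors default to p1 = p2 = 10⁻⁴, p12 = 10⁻⁵, the standard
defaults. Analysis is restricted to SNPs with MAF > 0.01 within 1 Mb of
the cis-pQTL. Single-SNP regions can leave the distinct-variant
accumulator non-positive; it is clamped to zero with a warning.

`susie_rss` relaxes the single-causal-variant assumption with a
sum-of-single-effects model on z-scores and an LD matrix: L components
each model one causal effect; per iteration a component computes per-SNP
Bayes factors on residualized z-scores (observation z_j ~ N(λ_j, 1),
prior λ_j ~ N(0, s₀)), with s₀ optimized per component over a log grid by
marginal likelihood; components whose best log marginal Bayes factor is
≤ 0.01 are deactivated, so a null region yields no credible sets. A
credible set is the smallest SNP set reaching 95% posterior mass, kept
when its purity (minimum absolute pairwise LD) is ≥ 0.5. The LD matrix
is ridge-regularized (10⁻⁴ on the diagonal). Convergence is declared when
posterior-mean effects change by < 10⁻³; non-convergence returns the fit
with a flag and warning. `coloc_susie` then runs the H0–H4 enumeration on
every pair of credible-set-bearing components, one per trait — this is
how a region where the protein has two signals and the outcome shares
only one is rescued from an H3 verdict.

`multi_trait_coloc` is an explicitly simplified simultaneous test for
≥3 traits (flagged `simplified-joint-abf` in its output): per-SNP log
ABFs are summed across traits, and the all-shared configuration is
weighed against the null and every all-but-one partition, each
alternative with prior 10⁻⁵. Below a posterior of 0.25 the candidate SNP
is reported as None, the "no simultaneous colocalization" convention.
The full regional-selection algorithm of the multi-trait literature is a
non-goal.

## Mediation and multivariable MR

Two-step network MR estimates a = protein→mediator and b =
mediator→outcome; the indirect effect is a·b with the first-order Sobel
standard error √(a²se_b² + b²se_a²) (the classical test; the second-order
variant adding se_a²se_b² is available behind a flag). The proportion
mediated, indirect/total, is reported unclamped with a warning outside
[0, 1]. Multivariable MR regresses SNP-outcome effects on the matrix of
SNP-exposure effects (weights 1/se_y², no intercept); all-zero exposure
columns are dropped with an undefined (NaN) direct effect so a
one-exposure problem reduces exactly to univariable IVW, and residual
rank deficiency raises an error naming the collinear exposures. The same
residual-sd floor as IVW keeps the two standard-error conventions
identical.

A practical caveat quantified during development: because the exposure
matrix contains *estimated* SNP effects, MVMR coefficients carry an
errors-in-variables attenuation of order k·se_x²/R² (k instruments,
protein GWAS standard error se_x). At a protein GWAS of n ≈ 3,300 this
reaches ~5% of the direct effect; at the deCODE-scale n = 35,559 used as
the mediation-panel default it is ~0.5%. The tests compare Monte-Carlo
means against a closed-form probability-limit oracle,
(TᵀT + N)⁻¹TᵀTβ, that accounts for this.

## The synthetic-GWAS generator

The generator emulates the statistical structure of the study's inputs,
not any real locus. For a cis region of p SNPs with LD correlation matrix
R (AR(1) with coefficient `ld_decay` by default; compound-symmetric
blocks optionally), marginal association z-scores are drawn jointly as

    z ~ N(R·λ, R),

with λ carrying non-centralities √(n·r²/(1−r²)) at causal variants, and
converted to per-allele β/se on a standardized phenotype scale via
se = 1/√(2f(1−f)n) — the scale on which R² ≈ 2β²f(1−f). Exposure,
outcome, and mediator draws are independent given the truth (two-sample
design, no sample overlap). Scenarios: `null`, `shared_causal` (one
variant drives both traits; the outcome's variance explained is
(θ/SD)²·r²), `two_causal_in_ld` (the outcome's causal variant sits
adjacent to the exposure's, so their LD equals `ld_decay`; its
non-centrality defaults to matching the exposure's so neither signal
dominates the H3/H4 contrast), `mediated` (protein → mediator (a) →
outcome (b) plus a direct path), `reverse` (the outcome owns the causal
variant and the protein inherits an attenuated downstream signal, so
Steiger should flag FALSE), and `pleiotropic` (a direct SNP-outcome
effect beyond the exposure path). Ground truth is recorded alongside the
tables. A low-level `simulate_tables` accepts arbitrary per-SNP effect
vectors (mean z = √n·R·β, without the residual-variance shrink, adequate
for small effects) for scenarios outside the enum, such as the two-signal
rescue case.

Defaults are the study conditions: exposure GWAS n = 3,301 (SomaLogic-
scale proteomics), outcome n = 370,000 (the menarche-timing GWAS),
mediator n = 40,000 (childhood adiposity), instrument r² = 0.1,
θ = 0.2 years/SD (inside the printed −0.45…0.46 range of significant
effects), MAF ~ U(0.05, 0.5), 200 SNPs at `ld_decay` 0.9. The mediation
panel defaults to a = 0.2, b = 0.5, direct effect 0.05 years/SD (total
0.15, mediated proportion 2/3 — the regime of the published NEGR1
finding), one cis-pQTL from a deCODE-scale protein GWAS (n = 35,559)
plus 17 mediator instruments, the pediatric-BMI MVMR construction.
The reverse-MR panel uses 172 genome-wide-significant LD-independent
outcome instruments (the AAM count) with per-SNP r² ~ U(2×10⁻⁴, 10⁻³)
(~10% total variance) and an outcome→protein effect of 0.4 SD/SD; at
this strength three of the four MR methods are nominally significant in
most replicates (MR-Egger is near-powerless at these per-SNP strengths),
matching the reverse-causation signature reported for LHB. Traits are
assumed standardized throughout; the source GWAS' phenotype
transformations (e.g. rank-normalization) are not modeled.

What the generator does **not** emulate: real LD panels (no long-range
structure, no allele-frequency–dependent LD), sample overlap between
GWAS, population stratification, winner's curse in instrument discovery,
imputation error, or assay-specific artifacts such as protein-altering
variants distorting aptamer binding. Passing tests therefore demonstrate
correctness of the statistical machinery under its stated assumptions,
not robustness to those real-data phenomena.

## Multiple testing and the screen

The forward screen applies a Bonferroni threshold of α/m with m the
number of distinct proteins actually tested in the run (the study
convention: m = 1271 for AAM gives 3.9×10⁻⁵, m = 1349 for ANM gives
3.7×10⁻⁵). Per protein: instrument selection (proxy fallback at LD
r² > 0.8 when the cis-pQTL is absent from the outcome table; ties broken
by smaller p, then position), Wald MR, Steiger, then colocalization (ABF
and, optionally, the fine-mapped pairwise variant) for MR-significant
proteins. Per-protein failures are logged and skipped, never fatal.
Reverse MR clumps the outcome GWAS greedily (p < 5×10⁻⁸, r² < 0.001) and
runs all four estimators. Reports are TSV/JSON under a run directory
with a manifest; a rerun with the same config and seed is byte-identical.

## Numerical conventions and problem sizes

Two-sided normal tests throughout (no df correction, matching how the
printed Wald p-values behave); p-values are clipped to ≥ 10⁻³⁰⁰ when
written. Wald/IVW/Egger are deterministic; bootstrap standard errors use
a fixed default seed. Monte-Carlo test sizes — 100 replicates for
colocalization scenario recovery, 200 for directionality, 500 for
estimator recovery and mediation, 2,000 for the power cross-check, 5,000
for null calibration, with regions of 3–100 SNPs — were chosen so the
binomial/Monte-Carlo error of each assertion is small relative to its
margin while the whole suite stays quick; the replicate counts per
assertion are stated in the tests.

## Known limitations

- The Wald-ratio mean in the shared-causal scenario is attenuated by
  √((1−r²_x)/(1−r²_y)) (≈ 0.95 at r² = 0.1) relative to θ, a consequence
  of the per-trait residual-variance factor in the non-centrality
  parameterization; it is well inside the recovery tolerance at the
  default conditions but visible at large instrument r².
- `multi_trait_coloc` tests only the all-shared vs leave-one-out
  partitions; configurations with two disjoint shared subsets are folded
  into the nearest partition.
- The weighted-mode bandwidth rule is a fixed multiple of a Silverman
  rule; no cross-validation.
- With fewer than ~5 instruments the bootstrap standard errors of the
  median/mode estimators are themselves noisy; the screen's primary
  estimator is the Wald ratio, as in the study design.
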