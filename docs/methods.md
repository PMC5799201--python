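# Methods

`summr` implements two-sample Mendelian randomisation (MR) on GWAS summary
statistics, shaped around a concrete application — estimating the causal
effect of serum 25-hydroxyvitamin D (25(OH)D) on glioma risk from a
four-SNP instrument and eight outcome cohorts — but usable for any
summary-level exposure/outcome pair with the same structure.

## Data model

Each instrument SNP *k* contributes a pair of estimated associations:

- `X_k` — the per-allele effect on the exposure, with standard error
  `sigma_Xk`, from an exposure GWAS;
- `Y_k` — the per-allele log odds ratio for the outcome, with standard
  error `sigma_Yk`, from an outcome GWAS (per cohort, per outcome subtype).

The causal parameter `beta` is the log-OR for the outcome per unit of
exposure, so `Y_k ≈ beta * X_k` under the instrumental-variable
assumptions (relevance, independence from confounders, and exclusion
restriction: the SNP affects the outcome only through the exposure).

The built-in instrument set consists of rs2282679 (*GC*), rs10741657
(*CYP2R1*), rs12785878 (*DHCR7*) and rs6013897 (*CYP24A1*), with per-allele
effects on 25(OH)D of −0.047, −0.052, −0.056 and −0.027 (SEs 0.013, 0.012,
0.013, 0.015; single-SNP F-statistics 13.38, 18.78, 18.29, 3.13).  The
effect allele is by convention the 25(OH)D-*decreasing* allele, hence the
negative signs.  Positions are GRCh37 and are carried as metadata only.
The exposure-effect scale is the one the source study printed; estimates
are reported per unit of that scale without rescaling.

## Harmonisation

Outcome records are aligned to the exposure's effect allele before
estimation.  Non-palindromic SNPs resolve by allele labels alone: a direct
match is kept, swapped effect/other alleles negate `Y_k`, and a match after
complementing both outcome alleles is a strand flip (with the swap logic
re-applied).  Palindromic SNPs (A/T, C/G) carry no strand information in
their labels, so they are resolved by comparing effect-allele frequencies:
both sides must report a frequency outside `0.5 ± w` (default half-width
`w = 0.08`, conventional MR practice) and the match/flip decision follows
frequency concordance.  Anything else is excluded with a machine-readable
reason (`palindromic_ambiguous`, `allele_mismatch`); nothing is dropped
silently, because the instrument count changes every downstream estimate.
With the built-in instrument set, which carries no allele frequencies, the
palindromic rs6013897 is therefore excluded unless the caller attaches
frequencies — an explicit, visible consequence of the rule rather than a
silent assumption about strand.

Instrument independence is checked against a user-supplied pairwise r²
matrix at a configurable threshold (default 0.001); computing LD from a
reference panel is out of scope.  With no matrix, every pair is reported
"unchecked" with a warning.

After harmonisation the pipeline jointly negates `(X_k, Y_k)` wherever
`X_k < 0`, so estimates read per unit *increase* of the exposure and an
OR below 1 means the exposure is protective.  All three estimators are
invariant to this per-instrument joint negation; it is presentation only.

## Estimators

**IVW.**  The fixed-effects inverse-variance weighted estimate

    beta_hat = sum_k X_k Y_k sigma_Yk^-2 / sum_k X_k^2 sigma_Yk^-2
    se(beta_hat) = sqrt(1 / sum_k X_k^2 sigma_Yk^-2)

equivalently weighted least squares of `Y` on `X` through the origin with
weights `sigma_Y^-2`.  Exposure-side error is ignored; with one SNP the
estimate reduces to the Wald ratio `Y/X` with SE `sigma_Y/|X|`.

**Maximum likelihood.**  The bivariate-normal measurement model

    X_k ~ N(xi_k, sigma_Xk^2),   Y_k ~ N(beta * xi_k, sigma_Yk^2)

independent across and within SNPs, maximised over the K+1 parameters
`(xi_1..xi_K, beta)`.  For fixed `beta` the `xi_k` maximisers are available
in closed form,

    xi_k(beta) = (X_k / sigma_Xk^2 + beta Y_k / sigma_Yk^2)
               / (1 / sigma_Xk^2 + beta^2 / sigma_Yk^2),

so the implementation maximises the one-dimensional profile likelihood in
`beta` (Brent's method, initialised at the IVW estimate, tolerance 1e-12,
up to three jittered restarts on failure).  `se(beta)` is the
`beta`-element of the inverse observed-information matrix at the optimum,
computed analytically by block inversion (the `xi` block is diagonal):

    I_profile = sum_k xi_k^2 / sigma_Yk^2
              - sum_k (Y_k - 2 beta xi_k)^2 / sigma_Yk^4
                      / (1/sigma_Xk^2 + beta^2/sigma_Yk^2)

The analytic route was chosen over a generic quasi-Newton fit with a
finite-difference Hessian because it is exact and remains well-conditioned
in the `sigma_X -> 0` limit, where Hessian entries diverge like
`sigma_X^-2` and finite differencing breaks down; in that limit the MLE
collapses to IVW, which the tests verify to 1e-4.

**MR-Egger.**  Weighted linear regression of `Y` on `X` *with* an
unconstrained intercept, weights `sigma_Y^-2`, after orienting every
instrument so `X_k >= 0` (negating `Y_k` in tandem).  The slope is a
pleiotropy-adjusted causal estimate; the intercept estimates the average
direct (pleiotropic) effect of the instruments on the outcome and tests
the exclusion restriction.  The regression runs through `statsmodels` WLS
with the residual dispersion estimated from the fit, so over-dispersion
from balanced pleiotropy widens the intervals.  P values and CIs use the
normal reference by default, consistent with IVW/MLE; a t reference with
K−2 degrees of freedom is available (`use_t=True`) and is the calibrated
choice at small K — with four instruments the normal reference is visibly
anti-conservative (simulated intercept rejection ~8% at nominal 5%),
which is why the package's own calibration tests use the t option.
MR-Egger needs at least three instruments and, with exactly four, has very
low power and a slope that can swing widely; it is reported as a
sensitivity analysis, not a primary estimate.

All P values are two-sided normal (or t where selected); CIs are 95%
throughout, matching the convention of the motivating analysis.  Display
rounding in TSV reports is 3 decimals for beta/SE and P, 2 for OR and CI
bounds; JSON reports keep full precision.

## Meta-analysis

The causal effect is estimated *within* each outcome cohort and the
cohort-level estimates are pooled by inverse-variance weighting under a
fixed-effect model (`w_i = 1/se_i^2`).  The alternative order — pool the
per-SNP outcome effects across cohorts first, then estimate once — is
implemented behind `pool_snps_first` (default off) for comparison.
MR-Egger follows the same per-cohort-then-pool handling as IVW/MLE, with
slope and intercept pooled separately.  Cochran's Q and I² are computed
and logged as heterogeneity diagnostics but never gate results.  Forest
data (per-cohort OR, CI, normalised weight, plus a summary row) are
exported per method and subtype.

Note one caveat the tests quantify: in two-sample MR a single exposure
GWAS serves every outcome cohort, so the exposure-side sampling error is
*shared* across cohorts while fixed-effect pooling treats the cohort
estimates as independent.  The pooled interval is therefore slightly
narrow; under the paper-like simulation the pooled MLE 95% CI covers the
truth in about 93–94% of replicates rather than 95%.

## Sensitivity analyses and multiple testing

Stratified analysis re-estimates within instrument strata — for the
vitamin D set, the synthesis variants (rs12785878, rs10741657) versus the
transport/catabolism ("metabolism") variants (rs2282679, rs6013897) —
to probe horizontal pleiotropy: discordant stratum estimates suggest a
pathway-specific direct effect.  Exclusion analysis drops named SNPs
(e.g. rs12785878, which is ancestry-associated) and records the shift
against the full-set estimate.  Egger on a stratum of fewer than three
SNPs is marked not-estimable rather than an error.  Bonferroni correction
is `alpha/m` (0.05/3 subtypes = 0.0167, displayed as 0.017).

## Power

The binary-outcome normal approximation: with `N` subjects, case fraction
`K`, and instruments explaining a fraction `r2` of exposure variance,

    |log OR| = (z_{1-alpha/2} + z_{power}) / sqrt(N * r2 * K * (1-K))

and its inverse `power_at_or`.  With 12,488 cases, 18,169 controls,
`r2 = 0.02` and `alpha = 0.05`, the detectable ORs at 80% power are 1.26
and 0.79.  `r2` defaults to 0.02 (the share of 25(OH)D variance the
four-SNP instrument explains) and is configurable; subtype-specific power
needs user-supplied subtype case counts.

## Synthetic data

The generator works at the summary level — the very model the estimators
assume — rather than simulating individual genotypes: per SNP a true
effect `xi_k` is drawn (or fixed from a template instrument set), the
observed `X_k ~ N(xi_k, sigma_Xk^2)` is shared by all cohorts in a
replicate, and per cohort `Y_kc ~ N(beta xi_k + alpha_k, sigma_Ykc^2)`
with `alpha_k` a per-SNP direct (pleiotropic) effect.  Outcome SEs follow
the standard log-OR approximation
`1/sqrt(2 p (1-p) N_c K_c (1-K_c))`, which under the paper-like conditions
puts per-SNP `|Y/sigma_Y|` at order 1 — a weak per-SNP signal, as in the
motivating data, not GWAS-significant hits.  Allele labels (with a
configurable palindromic fraction) and the outcome study's reporting
orientation are scrambled per SNP so harmonisation is genuinely exercised.
Everything is reproducible from a single seed.

Scenario presets fix the study conditions:

- `null` / `causal` — four instruments shaped like the 25(OH)D set
  (`xi` in (−0.06, −0.02), `sigma_X` in (0.012, 0.015)), eight cohorts
  splitting 12,488 cases / 18,169 controls evenly, true beta 0 or
  log(0.62);
- `paper_like` — the four real instrument SNPs (ids, alleles, effects,
  SEs) with fixed realistic effect-allele frequencies (0.28, 0.60, 0.75,
  0.80 — chosen away from 0.5 so the palindromic rs6013897 is
  frequency-resolvable), true beta log(0.62);
- `balanced_pleiotropy` / `directional_pleiotropy` — ten instruments with
  a spread of strengths (|xi| in (0.02, 0.10)) in one combined cohort,
  `alpha_k ~ N(0, 0.02^2)` or `N(0.03, 0.02^2)`.  The sizes were set by an
  a-priori power analysis: the implied Egger intercept SE (~0.024) makes
  the balanced scenario a calibration check and gives the directional
  scenario ~20% rejection, cleanly separable at 500 replicates.

What the generator does **not** emulate: linkage disequilibrium between
instruments, individual-level case-control sampling (log-ORs are normal by
construction, not asymptotically), winner's-curse selection of
instruments, allele-frequency differences between studies, and population
stratification.  Passing simulation tests therefore validate the
estimators and pipeline under their own assumptions; they cannot certify
robustness to those real-data complications.

## Numerical and design choices

- Tables are TSV with a configurable column dialect, since exposure and
  outcome sources rarely share headers; the default dialect matches the
  package's own writers, and reads use pandas' round-trip float parsing so
  write-then-read is lossless.
- Reports serialise to JSON exactly (re-reading reproduces every field)
  and to TSV at display precision; absent sections are written as
  explicitly absent, never dropped.  Provenance records input names, a
  config hash and the seed — no timestamps, so identical config + seed
  gives byte-identical reports.
- Degenerate inputs fail loudly and specifically: non-positive SEs,
  duplicate rsIDs, unknown subtype labels, asymmetric LD matrices, empty
  instrument sets, all-zero exposure effects, Egger on fewer than three or
  collinear instruments.
- An exact-fit Egger regression (zero residual) yields SE 0 and a
  point-mass interval rather than an error.
- Monte-Carlo test sizes (500 replicates for calibration/recovery checks,
  200 for secondary oracles, with a fixed seed sequence) keep the full
  suite around a quarter of a minute while leaving binomial tolerance
  bands meaningful.

## Known limitations

- Only fixed-effect pooling is provided; random-effects meta-analysis and
  robust estimators (weighted median/mode, multivariable MR) are out of
  scope.
- The combined-instrument F-statistic sometimes quoted for allelic scores
  has no single standard definition and is not computed; single-SNP
  F-statistics are.
- LD must be supplied precomputed; there is no reference-panel handling or
  proxy-SNP lookup.
- The exposure-effect scale is taken as printed by the source study;
  estimates are per unit of that scale, not per SD or per nmol/L.
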