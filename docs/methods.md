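# Methods

This note records the models, calibrations and numerical choices behind
`mremploy`, in the spirit of the methods documentation of simulation and
statistics packages: what is assumed, what the defaults mean, and what the
synthetic data do and do not establish about real data.

## The causal model

An exposure X (BMI-like, in kg/m²) affects each outcome Y with effect θ per
unit: a log-odds for binary and ordinal outcomes (logistic / cumulative
logit links), a slope for continuous outcomes. A latent standard-normal
confounder C affects both X and Y; genetic instruments G_j (dosages 0/1/2)
affect X additively and may carry direct ("horizontally pleiotropic")
effects α_j on Y. Two-sample MR assumes the SNP–exposure and SNP–outcome
associations come from non-overlapping samples; the generator honours this
by drawing the exposure GWAS from an independent virtual sample.

## Synthetic-cohort calibration

The generator emulates the aggregate regime of a large working-age cohort
analysed for BMI→employment effects:

- **77 independent instrument SNPs** (no LD; the instrument set is
  post-clumping, so independence is the intended state, and a user-supplied
  r² matrix exercises the clumping path separately).
- **Unweighted-score strength.** `exposure_h2` (default 0.015) is the
  fraction of exposure variance explained by the *unweighted* risk-allele
  score — the quantity a score-validation regression reports — and
  `per_allele_score_effect` (default 0.11) is that regression's slope.
  These two targets jointly fix the exposure SD:
  var(X) = slope² · var(score) / h2, giving ≈ 4.7 kg/m² under defaults,
  close to the BMI SD of adult population cohorts. Per-SNP effect
  magnitudes are drawn on the association z-score scale as a shifted
  lognormal (5.49 + LogNormal(−0.14, 1)), whose implied first-stage F
  statistics at a 300k-sample GWAS span ≈ 30–250 with median ≈ 40–60,
  matching published BMI hit lists; they are then rescaled so the
  frequency-weighted mean per-allele effect equals the slope target. Signs
  are random; the risk allele of a negative-effect SNP is its other allele.
- **Variance budget.** Exposure noise variance is total variance minus the
  genetic, covariate (age, sex) and confounder components; a configuration
  whose structural variance exceeds the total is rejected
  ("infeasible variance budget") rather than silently renormalised.
- **Significance-selected GWAS option.** `generate_exposure_gwas` draws
  β̂_Xj = β_Xj + N(0, σ_Xj) with σ_Xj = sd(X)/√(2p_j q_j n). With
  `selection_p` set (the pipeline default, 5×10⁻⁸) each estimate is drawn
  from the sign-preserving truncated normal conditional on reaching that
  threshold — emulating a *published discovery hit list*, in which every
  SNP passed the scan and the weakest estimates carry winner's curse. The
  unconditional mode remains the default of the function itself so that
  null architectures yield uniform p-values.
- **Pleiotropy.** α_j are none / balanced N(0, sd) / directional
  N(mean, sd), attached to the *exposure-increasing* allele. The
  orientation matters: attached to an arbitrary allele, "directional"
  pleiotropy averages to zero after MR-Egger's non-negative orientation
  and becomes undetectable by construction; risk-allele orientation is the
  convention of MR simulation studies and makes the Egger intercept a
  consistent estimate of the mean direct effect.
- **Outcomes.** Binary via logistic link around a baseline prevalence;
  ordinal via cumulative logit with equal baseline category shares (or
  explicit thresholds); continuous with Gaussian noise; employment status
  as a 5-category multinomial logit (employed, early-retired,
  sick/disabled, caring, unemployed, at realistic base rates) sharing one θ
  across the non-employed contrasts, stored as *sets* of endorsed
  categories so the encoding rules below are exercised.
- **Covariates** (age, sex, assessment centre with 10 levels, 10
  principal-component columns) exist to exercise adjustment plumbing; PCs
  are independent noise by design.

A summary-level companion, `simulate_summary_mr`, draws an
already-harmonised (β̂_X, β̂_Y) pair from the exact summary distribution the
cohort generator induces for a continuous outcome. Replicate studies
(coverage, error control) use it at full problem size — 77 SNPs, GWAS
n = 300,000, outcome n = 50,000, outcome SD 3 — at negligible cost.

## Instrument construction

- QC filters: genome-wide significance (default p ≤ 5×10⁻⁸), minor-allele
  frequency, Hardy–Weinberg p and imputation quality. The latter three have
  no defaults and must be supplied (pass `None` to disable); a per-rule
  rejection ledger is returned, counting a multiply-failing SNP once per
  rule.
- Clumping is greedy on p-value against a user-supplied r² matrix
  (default r²_max 0.001), ties broken by (p, snp_id) for determinism; no
  genomic window, since positions may be absent.
- Harmonisation aligns outcome records to the exposure effect allele,
  recognising swapped and strand-complement reports. Palindromic SNPs are
  resolved by allele frequency unless either frequency lies in
  [0.42, 0.58] (configurable), in which case they are dropped;
  irreconcilable allele pairs are dropped with a logged action, not
  raised.
- The unweighted allele score counts exposure-increasing alleles
  (g or 2−g by the sign of the exposure beta); instrument strength comes
  from nested least-squares fits of exposure ~ score + covariates:
  partial R² = (SSE_reduced − SSE_full)/SSE_reduced, an adjusted variant,
  and the score's 1-df F.

## Regression engine

Linear models by least squares, binary by logistic ML, ordinal by the
proportional-odds cumulative-logit model (statsmodels throughout); Wald
p-values; per-outcome complete-case analysis with n reported. Employment
contrasts are coded employed→0, contrast category→1, both→0 ("employed
takes priority"), neither→missing; the pooled non-employment variable
applies the same priority. Categorical covariates are expanded to dummies
with the most frequent level as reference. Per-SNP outcome scans share one
covariates-only fit as a warm start; the linear family uses the
partialled-out (Frisch–Waugh) closed form, which reproduces the full OLS
fit exactly and vectorises over SNPs. SNPs monomorphic in the analytic
sample yield flagged records excluded downstream. Perfect separation is
flagged (`reliable=False`) rather than raised.

## Estimators and numerics

- Weights are first-order inverse-variance 1/σ²_Y everywhere, so Cochran's
  Q equals the radial formulation Σ w_j (ratio_j − θ̂)² with
  w_j = (β̂_Xj/σ_Yj)². Q′ is the analogous statistic about the standard
  (beta-space) Egger fit; because Egger nests IVW under the same weights,
  Q ≥ Q′ algebraically.
- Multiplicative random effects scale SEs by √(Q/(k−1)) (IVW) or
  √(Q′/(k−2)) (Egger) with **no floor at 1** by default (configurable),
  since the selection framework presumes the unfloored form.
- The Rücker selection is hierarchical: fixed-effects IVW unless Q is
  significant at α (default 0.05); then IVW-MRE unless the 1-df Q − Q′
  intercept test is significant; then Egger, fixed or MRE by Q′. The
  flattened variant (consulting Q − Q′ first) differs only when Q is
  non-significant but Q − Q′ is; the hierarchical form is the canonical
  framework and avoids selecting Egger on data with no heterogeneity to
  explain.
- MR-Egger is fitted after jointly flipping each SNP so β̂_X ≥ 0 — the
  standard convention that makes the intercept interpretable.
- Maximum likelihood profiles the true SNP–exposure effects out of the
  bivariate-normal likelihood in closed form and optimises the 1-D profile
  (Brent); the SE comes from the numerical curvature of the profile
  −2 log-likelihood. As σ_X → 0 it reduces to fixed-effects IVW.
- The weighted median interpolates the inverse-variance-weighted CDF of
  per-SNP ratios at 0.5; its SE is a parametric bootstrap (default 1,000
  resamples) with a mandatory explicit seed.
- Radial outlier detection is a single pass: per-SNP Q contributions about
  the IVW fit referred to χ²₁, flagged below α (default 0.05). Iterating
  to convergence is deliberately not done; one pass plus an
  outlier-excluded refit mirrors the reported workflow.
- All 95% CIs use 1.959964 so CI↔SE conversions round-trip exactly; all
  p-values are normal-based Wald tests, including the Egger intercept
  (not t on k−2 df — immaterial at k ≈ 77, and consistent with the fixed
  CI multiplier).
- I²_GX = (Q_GX − (k−1))/Q_GX with Q_GX the Cochran statistic of the
  exposure betas (weights 1/σ²_X); values below 0.9 flag regression
  dilution risk for Egger; a degenerate Q_GX = 0 is an error, negative
  values are reported as-is.

## Stratified comparisons

Sex differences use z = (b₂ − b₁)/√(se₁² + se₂²) with a two-sided normal
p; SEs may be recovered from printed 95% CIs as (upper − lower)/(2·1.959964).
The age-band test is, by default, a weighted-least-squares regression of
band estimates on band midpoints (weights 1/se²) with an F test of the
slope against the intercept-only model; a band-heterogeneity Cochran Q on
m−1 df is available behind a flag (`method="het_q"`), and with two strata
it reproduces the z-difference p exactly. The same instrument set is used
in every stratum.

## Pipeline

`report.run_pipeline` is a pure function of (config, seeds): simulate or
load inputs → filter (→ clump if LD supplied) → score and strength →
encode outcomes → per outcome: observational regression, per-SNP scan,
harmonise, estimator suite, Q statistics, Rücker selection, I²_GX, radial
outliers, outlier-excluded refit, single-SNP and leave-one-out series →
sex-stratified IVW with Z tests → age-band trend → descriptive table. A
failure in one outcome is isolated; the rest complete. Every stage writes
a structured log line with its seeds and counts, percentages are rounded
half-even to one decimal, and identical configs produce byte-identical
tables.

## Problem sizes used by the test suite and acceptance script

Monte-Carlo checks run on the summary-level simulator at the full emulated
scale (k = 77, GWAS n = 300,000, outcome n = 50,000): 1,000 replicates for
coverage of the selected model, 100 for Egger-intercept recovery, 500–1,000
for type-I error, 1,000 random instances for estimator/oracle equivalence.
Individual-level pipeline tests use deliberately small cohorts
(1,200–6,000 individuals, 12–25 SNPs) — they verify plumbing and
determinism, not statistical calibration. The acceptance script's
end-to-end MR recovery uses a 50,000-person cohort with 77 SNPs.

## Known limitations

- The generator draws SNPs in linkage equilibrium, with no genotype
  missingness, no imputation error, and no participant self-selection or
  dynastic effects; passing tests therefore say nothing about collider
  bias, selection bias or residual population stratification in real
  cohorts. PCs and assessment centre are pure plumbing covariates.
- Exposure–outcome relationships are generated linear on the link scale;
  non-linear effects of the exposure are out of scope.
- The Egger intercept test with multiplicative-random SEs grows mildly
  conservative as the pleiotropy variance exceeds the outcome-side
  sampling variance (the multiplicative form misweights additive
  heterogeneity); near-nominal size holds for moderate pleiotropy.
- Coverage of the Rücker-*selected* model is slightly below the nominal
  95% (≈ 94–96% measured here) because the rare falsely-selected Egger
  fits under-cover conditionally; this is a property of post-selection
  inference, not of the individual estimators.
- Mode-based estimators, MR-PRESSO, multivariable MR, Steiger filtering
  and proxy-SNP lookup are intentionally absent.
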