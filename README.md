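# mremploy

Two-sample Mendelian randomisation (MR) of adiposity on employment-related
outcomes, with a synthetic-cohort simulator so the entire analysis can be
exercised, tested and calibrated without access to restricted
individual-level data.

## The problem

Observational associations between body mass index (BMI) and employment
status — being in paid work, sickness/disability, unemployment, early
retirement, caring for home or family — are confounded and open to reverse
causation (job loss can change weight). MR sidesteps both by using genetic
variants robustly associated with BMI as instruments: genotype is fixed at
conception, so SNP–outcome associations are immune to reverse causation and
largely unconfounded. In the two-sample design, SNP–exposure effects come
from an external GWAS and SNP–outcome effects from a separate cohort, and
the causal effect is estimated from summary statistics alone.

The package is aimed at epidemiologists and biostatisticians who want a
tested, scriptable implementation of this full workflow: instrument QC and
LD clumping, allele scoring and instrument-strength diagnostics,
exposure/outcome harmonisation, the MR estimator suite with model selection
and robustness diagnostics, and stratified (sex, age-band) comparisons.

## The statistics

For SNP *j*, let (β̂_Xj, σ_Xj) and (β̂_Yj, σ_Yj) be the harmonised
SNP–exposure and SNP–outcome effects. The package implements:

- **Wald ratio** θ̂_j = β̂_Yj / β̂_Xj with delta-method SE σ_Yj/|β̂_Xj|.
- **IVW**: weighted regression of β̂_Y on β̂_X through the origin with
  weights w_j = 1/σ²_Yj, i.e. θ̂ = Σw β̂_X β̂_Y / Σw β̂²_X; fixed-effects SE
  from the weight sum, or multiplicative-random-effects SE scaled by
  √(Q/(k−1)).
- **MR-Egger**: the same regression with a free intercept after orienting
  all β̂_X ≥ 0; the slope is the causal estimate and the intercept α̂₀
  estimates average directional pleiotropy (the unbalanced-pleiotropy
  test).
- **Weighted median** of the per-SNP ratios (bootstrap SE) and a
  **maximum-likelihood** estimator that models measurement error on both
  axes.
- **Heterogeneity / model selection**: Cochran's Q about the IVW fit,
  Rücker's Q′ about the Egger fit (Q ≥ Q′ always), and the hierarchical
  Rücker framework choosing among {IVW, Egger} × {fixed, multiplicative
  random}.
- **Diagnostics**: I²_GX for the no-measurement-error assumption, radial
  per-SNP Q contributions for outlier flagging, single-SNP and
  leave-one-out series, and Z/F tests comparing stratified estimates.

## Worked example

The default configuration simulates a cohort of 10,000 with 77 instrument
SNPs whose unweighted allele score explains ~1.5% of exposure variance at
~0.11 exposure units per allele, plus an external exposure GWAS of 300,000.
The `mr` subcommand runs the full pipeline (QC → scoring → scans →
harmonisation → estimator suite → Rücker selection):

```
$ mremploy instruments --seed 7
kept 77 / 77 SNPs; rejections: {'pvalue': 0, 'maf': 0, 'hwe': 0, 'info': 0}
F = 104.6, partial R2 = 0.0172, slope = 0.1154 per allele

$ mremploy mr --seed 7
sick_disabled: ivw_fe estimate +0.0072 (95% CI -0.1923, +0.2067) p=9.43e-01
non_employment: ivw_fe estimate -0.0354 (95% CI -0.1323, +0.0615) p=4.74e-01
tdi: ivw_fe estimate +0.0245 (95% CI -0.1010, +0.1500) p=7.02e-01
income: ivw_fe estimate -0.0654 (95% CI -0.1382, +0.0075) p=7.88e-02
```

All 77 simulated instruments pass the genome-wide significance filter
(p ≤ 5×10⁻⁸); the score-validation regression confirms instrument strength
(F ≫ 10, partial R² ≈ 1.7% here, per-allele slope ≈ 0.115). The MR rows
report, per outcome, the estimator chosen by the Rücker framework — here
fixed-effects IVW throughout, as the synthetic data carry no pleiotropic
heterogeneity — with the causal effect per one exposure unit (log-odds for
the binary/ordinal outcomes, slope for the continuous deprivation index).
At this small demonstration size the CIs are wide and include the simulated
true effects (e.g. θ = 0.038 for `tdi`); the acceptance script below runs
the same machinery at the full emulated scale, where effects of this size
are resolvable. `mremploy strata` adds male/female estimates with the
between-sex Z-difference test, and `mremploy report --outdir out/` writes
every table (descriptives, observational regressions, the MR suite with
diagnostics, stratified comparisons, scatter/forest plot data) as TSV plus
a JSON-lines run log.

Library use mirrors the CLI: `simcohort.generate_cohort`,
`instruments.harmonise`, `mrcore.ivw`, `mrcore.rucker_select`,
`strata.z_difference`, `report.run_pipeline`, etc.

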