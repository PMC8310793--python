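"""Synthetic cohorts and exposure GWAS with two-sample MR structure.

The generator emulates the statistical regime of a large population cohort
analysed for causal effects of BMI on employment-related outcomes:

* ~77 independent instrument SNPs whose *unweighted* allele score explains
  ~1.5% of exposure variance, with a per-allele score slope of ~0.11
  exposure units;
* an exposure (BMI-like, kg/m^2) driven by genotypes, covariates, a latent
  confounder and noise;
* binary / ordinal / continuous outcomes, plus a multi-category employment
  status field, generated from the exposure with a chosen causal effect
  ``theta``, confounding, and optional balanced or directional pleiotropy
  (direct SNP -> outcome effects alpha_j);
* an external exposure GWAS drawn from an independent virtual sample, so the
  exposure and outcome associations never share individuals (two-sample
  design).

Because the aggregate instrument strength and the per-allele slope jointly
determine the exposure variance, the exposure SD is derived rather than set:
``var(X) = slope^2 * var(score) / h2`` (~4.7 under defaults, close to the
BMI SD of real adult cohorts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .instruments import GwasRecord, HarmonisedSet

__all__ = [
    "PleiotropySpec",
    "OutcomeSimSpec",
    "SimConfig",
    "Cohort",
    "default_outcomes",
    "generate_cohort",
    "generate_exposure_gwas",
    "simulate_summary_mr",
    "write_cohort",
    "read_cohort",
]

EMPLOYMENT_CATEGORIES = ("employed", "retired", "sick_disabled", "caring", "unemployed")

# Approximate category shares of a working-age cohort (employed first).
_EMPLOYMENT_BASE_RATES = (0.752, 0.133, 0.051, 0.037, 0.023)

_NON_PALINDROMIC = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


@dataclass(frozen=True)
class PleiotropySpec:
    """Direct SNP -> outcome effects alpha_j.

    ``none``: all zero.  ``balanced``: alpha_j ~ N(0, sd) (mean ignored).
    ``directional``: alpha_j ~ N(mean, sd) — violates the exclusion
    restriction on average, which the Egger intercept should detect.
    """

    mode: str = "none"
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.mode!r}")


@dataclass(frozen=True)
class OutcomeSimSpec:
    """One synthetic outcome.

    ``theta`` is the causal effect of a one-unit exposure increase: log-odds
    for binary/ordinal/employment families, slope for continuous.  Binary
    outcomes use ``prevalence`` as the baseline rate; ordinal outcomes get
    ``category_count`` levels with equal baseline shares unless explicit
    latent ``thresholds`` are given; continuous outcomes add N(0, noise_sd).
    """

    name: str
    family: str
    theta: float
    prevalence: float = 0.1
    category_count: int | None = None
    thresholds: tuple[float, ...] | None = None
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("binary", "ordinal", "continuous", "employment"):
            raise ValueError(f"unknown outcome family {self.family!r}")
        if self.family == "ordinal":
            k = self.category_count
            if self.thresholds is None and (k is None or k < 2):
                raise ValueError("ordinal outcome needs category_count >= 2 or thresholds")


def default_outcomes() -> tuple[OutcomeSimSpec, ...]:
    """Employment status plus deprivation and income, at plausible effects.

    The shared employment log-odds (0.07 per kg/m^2) and the deprivation
    slope (0.038) and income log-odds (-0.024) sit in the range causal
    analyses of BMI on work outcomes report.
    """
    return (
        OutcomeSimSpec("employment_status", "employment", theta=0.07),
        OutcomeSimSpec("tdi", "continuous", theta=0.038, noise_sd=3.0),
        OutcomeSimSpec("income", "ordinal", theta=-0.024, category_count=5),
    )


@dataclass(frozen=True)
class SimConfig:
    n_individuals: int = 10_000
    n_snps: int = 77
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_h2: float = 0.015
    per_allele_score_effect: float = 0.11
    exposure_mean: float = 27.4
    confounder_effects: tuple[float, float] = (1.0, 0.2)
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    outcomes: tuple[OutcomeSimSpec, ...] = field(default_factory=default_outcomes)
    age_effect: float = 0.03      # exposure units per year of age (centred)
    sex_effect: float = 1.0       # exposure units, male vs female
    n_pcs: int = 10
    n_centres: int = 10
    male_fraction: float = 0.545
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.exposure_h2 < 1:
            raise ValueError("exposure_h2 must lie in [0, 1)")
        if self.n_individuals < 2 or self.n_snps < 1:
            raise ValueError("need n_individuals >= 2 and n_snps >= 1")


@dataclass
class Cohort:
    """Individuals x {dosages, exposure, covariates, outcomes}.

    ``snp_effects`` are the true per-SNP exposure effects (per effect-allele
    copy, signed); ``eafs`` the configured effect-allele frequencies.
    """

    data: pd.DataFrame
    snp_ids: list[str]
    snp_alleles: dict[str, tuple[str, str]]
    snp_effects: np.ndarray
    eafs: np.ndarray
    alpha: np.ndarray          # direct SNP->outcome (pleiotropic) effects
    config: SimConfig

    @property
    def mafs(self) -> np.ndarray:
        return np.minimum(self.eafs, 1.0 - self.eafs)


# ---------------------------------------------------------------------------
# true genetic architecture (a deterministic function of the config)
# ---------------------------------------------------------------------------

def _true_snp_params(config: SimConfig):
    """SNP ids, alleles, effect-allele frequencies and true betas.

    The instrument set emulates a *significance-selected* GWAS hit list:
    effect magnitudes are drawn on the association z-score scale as a
    shifted lognormal, 5.49 + LogNormal(-0.14, 1.0), whose implied
    first-stage F quantiles at reference GWAS size (~300k) match a
    BMI-scale hit list — minimum ~30, median ~40, maximum across 77 SNPs
    ~250 — and converted to per-allele betas via the per-SNP
    heterozygosity, then rescaled so the frequency-weighted mean equals
    ``per_allele_score_effect``.  This makes the population regression
    slope of exposure on the unweighted risk-allele score equal to that
    target, and ensures every SNP clears a genome-wide significance filter
    at GWAS sample sizes of a few hundred thousand.  Signs are random; the
    risk allele of a negative-beta SNP is its other allele.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2167]))
    k = config.n_snps
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=k)
    flip = rng.random(k) < 0.5
    eafs = np.where(flip, 1.0 - mafs, mafs)
    het = 2.0 * eafs * (1.0 - eafs)          # per-SNP dosage variance
    z_shape = 5.49 + rng.lognormal(-0.14, 1.0, size=k)
    u = z_shape / np.sqrt(het)                # per-allele magnitude shape
    scale = config.per_allele_score_effect * het.sum() / (u * het).sum()
    signs = np.where(rng.random(k) < 0.5, 1.0, -1.0)
    betas = signs * scale * u
    snp_ids = [f"rs{i + 1:05d}" for i in range(k)]
    allele_idx = rng.integers(0, len(_NON_PALINDROMIC), size=k)
    alleles = {s: _NON_PALINDROMIC[i] for s, i in zip(snp_ids, allele_idx)}
    return snp_ids, alleles, eafs, betas


def _exposure_sd(config: SimConfig, het_sum: float) -> float:
    if config.exposure_h2 <= 0 or config.per_allele_score_effect == 0:
        return 4.8  # genetics-free fallback, BMI-like spread
    var = config.per_allele_score_effect ** 2 * het_sum / config.exposure_h2
    return math.sqrt(var)


def _alpha_vector(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    p = config.pleiotropy
    if p.mode == "none":
        return np.zeros(config.n_snps)
    mean = 0.0 if p.mode == "balanced" else p.mean
    return rng.normal(mean, p.sd, size=config.n_snps)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig) -> Cohort:
    """Simulate the individual-level analytic sample.

    Exposure: ``X = mu + sum_j beta_j g_j + covariate effects + c_x C + e``,
    with the noise variance set so the unweighted score explains
    ``exposure_h2`` of var(X).  Outcomes: each family's link applied to
    ``theta (X - mu) + c_y C + sum_j alpha_j g_j``.
    """
    snp_ids, alleles, eafs, betas = _true_snp_params(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 31]))
    n = config.n_individuals

    g = rng.binomial(2, eafs, size=(n, len(snp_ids))).astype(np.int8)

    age = rng.normal(53.0, 6.6, size=n)
    sex = (rng.random(n) < config.male_fraction).astype(int)   # 1 = male
    centre = rng.integers(0, config.n_centres, size=n)
    pcs = rng.standard_normal((n, config.n_pcs))
    conf = rng.standard_normal(n)

    het_sum = float((2.0 * eafs * (1.0 - eafs)).sum())
    sd_x = _exposure_sd(config, het_sum)
    c_x, c_y = config.confounder_effects
    genetic = g @ betas
    var_struct = (
        float(np.var(genetic))
        + config.age_effect ** 2 * 6.6 ** 2
        + config.sex_effect ** 2 * config.male_fraction * (1 - config.male_fraction)
        + c_x ** 2
    )
    noise_var = sd_x ** 2 - var_struct
    if noise_var <= 0:
        raise ValueError(
            "infeasible variance budget: structural variance "
            f"{var_struct:.3f} >= total exposure variance {sd_x ** 2:.3f} "
            "(lower confounder/covariate effects or exposure_h2)"
        )
    exposure = (
        config.exposure_mean
        + genetic
        + config.age_effect * (age - 53.0)
        + config.sex_effect * sex
        + c_x * conf
        + rng.normal(0.0, math.sqrt(noise_var), size=n)
    )

    alpha = _alpha_vector(config, np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 977])))
    # pleiotropic effects act through the exposure-increasing (risk) allele,
    # so "directional" pleiotropy is directional relative to the exposure
    g_risk = np.where(betas > 0, g, 2 - g)
    direct = g_risk @ alpha
    xc = exposure - config.exposure_mean

    data = pd.DataFrame(g, columns=snp_ids)
    data["age"] = age
    data["sex"] = sex
    data["centre"] = pd.Categorical([f"c{i:02d}" for i in centre])
    for j in range(config.n_pcs):
        data[f"pc{j + 1}"] = pcs[:, j]
    data["confounder"] = conf
    data["exposure"] = exposure

    for spec in config.outcomes:
        eta = spec.theta * xc + c_y * conf + direct
        if spec.family == "binary":
            p = expit(logit(spec.prevalence) + eta)
            data[spec.name] = rng.binomial(1, p)
        elif spec.family == "continuous":
            data[spec.name] = eta + rng.normal(0.0, spec.noise_sd, size=n)
        elif spec.family == "ordinal":
            data[spec.name] = _ordinal_draw(spec, eta, rng)
        elif spec.family == "employment":
            data[spec.name] = _employment_draw(eta, rng)

    return Cohort(data, snp_ids, alleles, betas, eafs, alpha, config)


def _ordinal_draw(spec: OutcomeSimSpec, eta: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    if spec.thresholds is not None:
        cuts = np.asarray(spec.thresholds, dtype=float)
    else:
        k = spec.category_count
        cuts = logit(np.arange(1, k) / k)     # equal baseline shares
    # cumulative logit: P(y <= k) = expit(c_k - eta)
    cum = expit(cuts[None, :] - eta[:, None])
    u = rng.random(len(eta))[:, None]
    return 1 + (u > cum).sum(axis=1)


def _employment_draw(eta: np.ndarray, rng: np.random.Generator) -> pd.Series:
    """Multi-category status via multinomial logit, theta shared across the
    four non-employed contrasts; returns frozenset-valued categories."""
    rates = np.asarray(_EMPLOYMENT_BASE_RATES)
    b0 = np.log(rates[1:] / rates[0])
    scores = np.exp(b0[None, :] + eta[:, None])   # vs employed (score 1)
    denom = 1.0 + scores.sum(axis=1)
    probs = np.hstack([1.0 / denom[:, None], scores / denom[:, None]])
    u = rng.random(len(eta))
    idx = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    cats = [frozenset([EMPLOYMENT_CATEGORIES[i]]) for i in idx]
    return pd.Series(cats, dtype=object)


# ---------------------------------------------------------------------------
# exposure GWAS (independent virtual sample)
# ---------------------------------------------------------------------------

def generate_exposure_gwas(config: SimConfig, n_gwas: int, seed: int,
                           selection_p: float | None = None) -> list[GwasRecord]:
    """Summary statistics for the instrument SNPs from a virtual external
    GWAS of ``n_gwas`` individuals (no overlap with any generated cohort).

    ``se_j = sd(X) / sqrt(2 p_j q_j n_gwas)`` — the standard error of a
    per-allele regression slope — and ``beta_hat_j = beta_j + N(0, se_j)``.

    With ``selection_p`` set, each estimate is drawn conditional on reaching
    that significance level in the direction of the true effect (a
    sign-preserving truncated normal).  This emulates a *published discovery
    hit list*, where every reported SNP passed the scan's threshold and the
    weakest estimates carry winner's curse; it guarantees the whole set
    survives a downstream p-value filter at the same threshold.
    """
    if n_gwas < 2:
        raise ValueError("n_gwas must be >= 2")
    snp_ids, alleles, eafs, betas = _true_snp_params(config)
    het = 2.0 * eafs * (1.0 - eafs)
    sd_x = _exposure_sd(config, float(het.sum()))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5501]))
    se = sd_x / np.sqrt(het * n_gwas)
    z_true = np.abs(betas) / se
    if selection_p is None:
        lo = np.zeros(len(betas))
    else:
        crit = norm.isf(selection_p / 2.0)
        lo = norm.cdf(crit - z_true)   # truncation point for the error term
    u = lo + rng.random(len(betas)) * (1.0 - lo)
    z_hat = z_true + norm.ppf(np.clip(u, 1e-16, 1 - 1e-16))
    signs = np.where(betas == 0, 1.0, np.sign(betas))
    bhat = signs * z_hat * se
    pvals = 2.0 * norm.sf(np.abs(bhat) / se)
    records = []
    for j, s in enumerate(snp_ids):
        ea, oa = alleles[s]
        records.append(
            GwasRecord(s, ea, oa, float(eafs[j]), float(bhat[j]), float(se[j]),
                       float(max(pvals[j], 5e-324)), int(n_gwas))
        )
    return records


# ---------------------------------------------------------------------------
# summary-level two-sample simulator
# ---------------------------------------------------------------------------

def simulate_summary_mr(
    config: SimConfig,
    theta: float,
    n_gwas: int,
    n_outcome: int,
    outcome_sd: float,
    seed: int,
) -> HarmonisedSet:
    """Draw an already-harmonised summary-statistic pair directly.

    Exposure side as in :func:`generate_exposure_gwas`; outcome side
    ``by_j = theta beta_j + alpha_j + N(0, se_yj)`` with
    ``se_yj = outcome_sd / sqrt(2 p_j q_j n_outcome)``.  This is the exact
    summary-level distribution the individual-level generator induces for a
    continuous outcome, and is the fast path for replicate studies
    (coverage, error control) at full problem size.
    """
    snp_ids, _, eafs, betas = _true_snp_params(config)
    het = 2.0 * eafs * (1.0 - eafs)
    sd_x = _exposure_sd(config, float(het.sum()))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 40961]))
    se_x = sd_x / np.sqrt(het * n_gwas)
    bx = betas + rng.normal(0.0, se_x)
    alpha = _alpha_vector(config, np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 977])))
    se_y = outcome_sd / np.sqrt(het * n_outcome)
    # direct effects oriented to the risk allele, as in generate_cohort
    by = theta * betas + np.sign(betas) * alpha + rng.normal(0.0, se_y)
    return HarmonisedSet(list(snp_ids), bx, se_x, by, se_y,
                         {s: "kept" for s in snp_ids})


# ---------------------------------------------------------------------------
# cohort I/O (tab-delimited; status sets joined with ';')
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, path) -> None:
    df = cohort.data.copy()
    for col in df.columns:
        if df[col].dtype == object and len(df) and isinstance(df[col].iloc[0], frozenset):
            df[col] = df[col].map(lambda s: ";".join(sorted(s)))
    df.to_csv(path, sep="\t", index=False)


def read_cohort(path, status_columns: Sequence[str] = ("employment_status",)) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in status_columns:
        if col in df.columns:
            df[col] = df[col].map(
                lambda s: frozenset(str(s).split(";")) if pd.notna(s) and s != "" else frozenset()
            )
    return df
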