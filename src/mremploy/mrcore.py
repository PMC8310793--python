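"""Two-sample Mendelian randomisation estimators and diagnostics.

Given harmonised per-SNP exposure and outcome effects (beta_x, se_x,
beta_y, se_y), this module provides:

* the estimator suite — Wald ratio, inverse-variance-weighted (IVW) with
  fixed or multiplicative-random-effects variance, MR-Egger (slope +
  intercept, the unbalanced-pleiotropy test), the weighted median, and a
  bivariate-normal maximum-likelihood estimator;
* heterogeneity statistics — Cochran's Q about the IVW fit and Rucker's Q'
  about the Egger fit — and the Rucker model-selection framework choosing
  among {IVW, Egger} x {fixed, multiplicative random};
* the I2_GX diagnostic for the no-measurement-error (NOME) assumption;
* radial per-SNP Q contributions for outlier detection;
* single-SNP and leave-one-out sensitivity series.

Conventions: weights are first-order inverse-variance 1/se_y^2 throughout;
Egger is fitted after orienting all exposure betas non-negative; 95% CIs
use 1.959964 so CI <-> SE conversions round-trip exactly; p-values are
normal-based Wald tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from ._util import Z95
from .instruments import HarmonisedSet

__all__ = [
    "MRResult",
    "ModelSelection",
    "NomeStats",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "max_likelihood",
    "q_statistics",
    "rucker_select",
    "i2gx",
    "radial_outliers",
    "sensitivity",
]


@dataclass
class MRResult:
    method: str
    estimate: float
    se: float
    pvalue: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - Z95 * self.se, self.estimate + Z95 * self.se)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def or_ci95(self) -> tuple[float, float]:
        lo, hi = self.ci95
        return (float(np.exp(lo)), float(np.exp(hi)))


@dataclass
class ModelSelection:
    """Cochran's Q, Rucker's Q' and the estimator-family decision."""

    Q: float
    Q_prime: float
    df_Q: int
    df_Qprime: int
    p_Q: float
    p_Qprime: float
    Q_diff: float
    p_Qdiff: float
    chosen: str | None = None
    alpha: float | None = None


@dataclass(frozen=True)
class NomeStats:
    """I2_GX: share of variance in the SNP-exposure estimates not due to
    estimation error.  Below 0.9 the Egger slope suffers noticeable
    regression dilution and its intercept test may over-reject."""

    i2gx: float
    q_gx: float
    threshold_flag: bool


def _wald_p(est: float, se: float) -> float:
    if se == 0:
        return 0.0 if est != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(est) / se))


def _require(hs: HarmonisedSet, k_min: int, what: str) -> None:
    if hs.k < k_min:
        raise ValueError(f"{what} requires >= {k_min} SNPs, got {hs.k}")


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> MRResult:
    """Single-SNP causal estimate beta_y / beta_x, first-order delta SE."""
    if beta_x == 0:
        raise ValueError("wald ratio undefined for beta_x = 0")
    est = beta_y / beta_x
    se = se_y / abs(beta_x)
    return MRResult("wald_ratio", float(est), float(se), _wald_p(est, se), 1)


def ivw(hs: HarmonisedSet, variance_model: str = "fixed",
        mre_floor: bool = False) -> MRResult:
    """Inverse-variance-weighted estimate: weighted regression of beta_y on
    beta_x through the origin, weights 1/se_y^2.

    ``fixed``: SE from the weight sum.  ``multiplicative_random``: SE scaled
    by sqrt(Q/(k-1)); no truncation below 1 unless ``mre_floor``.  A single
    SNP degrades to the Wald ratio.
    """
    _require(hs, 1, "ivw")
    if hs.k == 1:
        r = wald_ratio(hs.beta_x[0], hs.se_x[0], hs.beta_y[0], hs.se_y[0])
        return MRResult(f"ivw_{_vm_tag(variance_model)}", r.estimate, r.se,
                        r.pvalue, 1)
    if np.all(hs.beta_x == 0):
        raise ValueError("all exposure betas are zero")
    w = 1.0 / hs.se_y ** 2
    denom = float(np.sum(w * hs.beta_x ** 2))
    est = float(np.sum(w * hs.beta_x * hs.beta_y) / denom)
    var_fe = 1.0 / denom
    if variance_model == "fixed":
        se = np.sqrt(var_fe)
    elif variance_model == "multiplicative_random":
        q = float(np.sum(w * (hs.beta_y - est * hs.beta_x) ** 2))
        scale = q / (hs.k - 1)
        if mre_floor:
            scale = max(scale, 1.0)
        se = np.sqrt(var_fe * scale)
    else:
        raise ValueError(f"unknown variance_model {variance_model!r}")
    return MRResult(f"ivw_{_vm_tag(variance_model)}", est, float(se),
                    _wald_p(est, se), hs.k)


def _vm_tag(variance_model: str) -> str:
    return {"fixed": "fe", "multiplicative_random": "mre"}[variance_model]


def _oriented(hs: HarmonisedSet) -> tuple[np.ndarray, np.ndarray]:
    """Exposure betas oriented non-negative, flipping (bx, by) jointly."""
    s = np.where(hs.beta_x < 0, -1.0, 1.0)
    return s * hs.beta_x, s * hs.beta_y


def egger(hs: HarmonisedSet, variance_model: str = "fixed",
          constrain_intercept: bool = False) -> MRResult:
    """MR-Egger: weighted regression of beta_y on beta_x with a free
    intercept, after orienting all exposure betas non-negative.

    The slope is the causal estimate; the intercept estimates average
    directional pleiotropy and its Wald test is the unbalanced-pleiotropy
    test.  ``constrain_intercept`` forces the intercept to zero, in which
    case the slope coincides with IVW.
    """
    _require(hs, 3, "egger")
    bx, by = _oriented(hs)
    if np.var(bx) == 0:
        raise ValueError("zero variance in exposure betas; Egger slope undefined")
    w = 1.0 / hs.se_y ** 2
    if constrain_intercept:
        base = ivw(hs, variance_model)
        return MRResult(f"egger_{_vm_tag(variance_model)}", base.estimate,
                        base.se, base.pvalue, hs.k, 0.0, 0.0, 1.0)
    sw, swx = np.sum(w), np.sum(w * bx)
    swx2, swy, swxy = np.sum(w * bx ** 2), np.sum(w * by), np.sum(w * bx * by)
    det = sw * swx2 - swx ** 2
    slope = float((sw * swxy - swx * swy) / det)
    inter = float((swx2 * swy - swx * swxy) / det)
    resid = by - inter - slope * bx
    q = float(np.sum(w * resid ** 2))
    var_slope = sw / det
    var_inter = swx2 / det
    if variance_model == "multiplicative_random":
        scale = q / (hs.k - 2)
        var_slope *= scale
        var_inter *= scale
    elif variance_model != "fixed":
        raise ValueError(f"unknown variance_model {variance_model!r}")
    se, se_i = float(np.sqrt(var_slope)), float(np.sqrt(var_inter))
    return MRResult(f"egger_{_vm_tag(variance_model)}", slope, se,
                    _wald_p(slope, se), hs.k,
                    inter, se_i, _wald_p(inter, se_i))


def weighted_median(hs: HarmonisedSet, n_boot: int = 1000,
                    seed: int | None = None) -> MRResult:
    """Weighted median of per-SNP Wald ratios, inverse-variance weights.

    Consistent when SNPs contributing >= 50% of the weight are valid
    instruments.  SE by parametric bootstrap (explicit seed required for a
    reproducible run).
    """
    _require(hs, 3, "weighted_median")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    est = _wm_point(hs.beta_x, hs.beta_y, hs.se_y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx = hs.beta_x + rng.normal(0.0, hs.se_x)
        by = hs.beta_y + rng.normal(0.0, hs.se_y)
        boots[b] = _wm_point(bx, by, hs.se_y)
    se = float(np.std(boots, ddof=1))
    return MRResult("weighted_median", est, se, _wald_p(est, se), hs.k)


def _wm_point(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> float:
    bx = np.where(bx == 0, 1e-300, bx)
    ratios = by / bx
    w = (bx / sy) ** 2        # inverse variance of the ratio
    order = np.argsort(ratios)
    r, w = ratios[order], w[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return float(np.interp(0.5, cum, r))


def max_likelihood(hs: HarmonisedSet, tol: float = 1e-10) -> MRResult:
    """Bivariate-normal ML estimate of the causal effect.

    Model: bx_j ~ N(xi_j, se_x_j^2), by_j ~ N(theta xi_j, se_y_j^2) with
    the true exposure effects xi_j profiled out in closed form.  Accounts
    for exposure-side measurement error, unlike IVW.  SE from the curvature
    of the profile -2 log-likelihood.
    """
    _require(hs, 1, "max_likelihood")
    if hs.k == 1:
        return wald_ratio(hs.beta_x[0], hs.se_x[0], hs.beta_y[0], hs.se_y[0])
    bx, sx2 = hs.beta_x, hs.se_x ** 2
    by, sy2 = hs.beta_y, hs.se_y ** 2

    def nll2(theta: float) -> float:
        xi = (bx / sx2 + theta * by / sy2) / (1.0 / sx2 + theta ** 2 / sy2)
        return float(np.sum((bx - xi) ** 2 / sx2 + (by - theta * xi) ** 2 / sy2))

    start = ivw(hs).estimate
    res = optimize.minimize_scalar(
        nll2, bracket=(start - 1.0, start, start + 1.0), method="brent",
        options={"xtol": tol, "maxiter": 500},
    )
    if not res.success:
        raise RuntimeError(f"max_likelihood failed to converge: {res}")
    theta = float(res.x)
    h = max(1e-6, 1e-4 * abs(theta))
    curv = (nll2(theta + h) - 2.0 * nll2(theta) + nll2(theta - h)) / h ** 2
    se = float(np.sqrt(2.0 / curv))
    return MRResult("max_likelihood", theta, se, _wald_p(theta, se), hs.k)


# ---------------------------------------------------------------------------
# heterogeneity and model selection
# ---------------------------------------------------------------------------

def q_statistics(hs: HarmonisedSet) -> ModelSelection:
    """Cochran's Q about the IVW fit, Rucker's Q' about the Egger fit.

    Both use first-order weights 1/se_y^2, so Q equals the radial-MR
    formulation sum_j w_j (ratio_j - theta_ivw)^2 with w_j = (bx_j/se_y_j)^2.
    Q >= Q' always (the Egger model nests IVW); Q - Q' is a 1-df test of the
    intercept, i.e. of unbalanced pleiotropy.
    """
    _require(hs, 3, "q_statistics")
    w = 1.0 / hs.se_y ** 2
    th = ivw(hs).estimate
    q = float(np.sum(w * (hs.beta_y - th * hs.beta_x) ** 2))
    e = egger(hs)
    bx, by = _oriented(hs)
    qp = float(np.sum(w * (by - e.intercept - e.estimate * bx) ** 2))
    k = hs.k
    return ModelSelection(
        Q=q, Q_prime=qp, df_Q=k - 1, df_Qprime=k - 2,
        p_Q=float(stats.chi2.sf(q, k - 1)),
        p_Qprime=float(stats.chi2.sf(qp, k - 2)),
        Q_diff=q - qp,
        p_Qdiff=float(stats.chi2.sf(q - qp, 1)),
    )


def rucker_select(ms: ModelSelection, alpha: float = 0.05) -> str:
    """Rucker framework: choose among IVW/Egger x fixed/random.

    The selection is hierarchical.  If Cochran's Q is non-significant at
    ``alpha`` there is no excess heterogeneity to explain and fixed-effects
    IVW is retained.  Given significant Q, the Q - Q' difference (1 df)
    asks whether an unbalanced-pleiotropy intercept accounts for it: if not,
    IVW with multiplicative random effects; if so, the Egger family, with
    fixed or multiplicative-random variance according to Q'.  Deterministic;
    the decision is recorded on the ModelSelection.
    """
    if ms.p_Q >= alpha:
        chosen = "ivw_fe"
    elif ms.p_Qdiff >= alpha:
        chosen = "ivw_mre"
    elif ms.p_Qprime >= alpha:
        chosen = "egger_fe"
    else:
        chosen = "egger_mre"
    ms.chosen = chosen
    ms.alpha = alpha
    return chosen


def fit_method(hs: HarmonisedSet, method: str) -> MRResult:
    """Dispatch an estimator label from :func:`rucker_select`."""
    family, vm = method.rsplit("_", 1)
    variance = {"fe": "fixed", "mre": "multiplicative_random"}[vm]
    return {"ivw": ivw, "egger": egger}[family](hs, variance)


def i2gx(hs: HarmonisedSet) -> NomeStats:
    """I2_GX = (Q_GX - (k-1)) / Q_GX, with Q_GX the Cochran statistic of the
    exposure betas weighted by 1/se_x^2.  Values below 0.9 flag meaningful
    NOME violation; negative values are reported as-is, flagged."""
    _require(hs, 2, "i2gx")
    v = 1.0 / hs.se_x ** 2
    bw = float(np.sum(v * hs.beta_x) / np.sum(v))
    q_gx = float(np.sum(v * (hs.beta_x - bw) ** 2))
    if q_gx == 0:
        raise ValueError("degenerate exposure betas: Q_GX = 0, I2_GX undefined")
    val = (q_gx - (hs.k - 1)) / q_gx
    return NomeStats(float(val), q_gx, bool(val < 0.9))


# ---------------------------------------------------------------------------
# outliers and sensitivity
# ---------------------------------------------------------------------------

def radial_outliers(hs: HarmonisedSet, alpha: float = 0.05):
    """Per-SNP contributions to radial Q about the IVW fit, single pass.

    Contribution q_j = w_j (ratio_j - theta)^2 with w_j = (bx_j/se_y_j)^2;
    a SNP is flagged when its 1-df chi-square tail probability falls below
    ``alpha``.  Returns (flagged snp_ids, contributions array, p array).
    """
    _require(hs, 3, "radial_outliers")
    th = ivw(hs).estimate
    w = (hs.beta_x / hs.se_y) ** 2
    bx = np.where(hs.beta_x == 0, 1e-300, hs.beta_x)
    ratios = hs.beta_y / bx
    contrib = w * (ratios - th) ** 2
    pvals = stats.chi2.sf(contrib, 1)
    flagged = [s for s, p in zip(hs.snp_ids, pvals) if p < alpha]
    return flagged, contrib, pvals


@dataclass
class SensitivityResult:
    single_snp: list[MRResult]
    leave_one_out: list[MRResult]
    loo_excluded: list[str]
    full: MRResult


def sensitivity(hs: HarmonisedSet) -> SensitivityResult:
    """Single-SNP Wald ratios and leave-one-out IVW series.

    No single SNP should move the IVW estimate materially if the causal
    signal is shared across the instrument set.
    """
    _require(hs, 2, "sensitivity")
    singles = [
        wald_ratio(hs.beta_x[j], hs.se_x[j], hs.beta_y[j], hs.se_y[j])
        for j in range(hs.k)
    ]
    loo, excluded = [], []
    for j in range(hs.k):
        mask = np.ones(hs.k, dtype=bool)
        mask[j] = False
        loo.append(ivw(hs.subset(mask)))
        excluded.append(hs.snp_ids[j])
    return SensitivityResult(singles, loo, excluded, ivw(hs))
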