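"""Outcome encoding and the regression engine.

Observational exposure-outcome associations and per-SNP outcome association
scans, with covariate adjustment, for three families: linear (continuous
outcomes), logistic (binary) and proportional-odds cumulative-logit
(ordinal).  All analyses are complete-case per outcome.

Employment status arrives as a per-individual *set* of endorsed categories
(respondents may endorse several).  It is recoded into binary variables
contrasting each non-employed category against being employed, with
"employed" taking priority when both are endorsed, plus a non-employment
variable contrasting any non-employed status against employment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._util import Z95, design_frame
from .instruments import GwasRecord

__all__ = [
    "OutcomeSpec",
    "AssocResult",
    "encode_outcomes",
    "fit_glm",
    "snp_outcome_scan",
    "observational_association",
]

EMPLOYED = "employed"
NON_EMPLOYMENT = "*"  # contrast marker: any non-employed category


@dataclass(frozen=True)
class OutcomeSpec:
    """Analysis outcome definition.

    For ``family='binary'`` with ``contrast_category`` set, the outcome is
    recoded from the raw employment-status sets (``source`` names that
    column); ``contrast_category='*'`` means the pooled non-employment
    contrast.  Otherwise ``name`` refers to an existing cohort column.
    """

    name: str
    family: str
    contrast_category: str | None = None
    source: str = "employment_status"
    levels: tuple | None = None
    extra_covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in ("binary", "ordinal", "continuous"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class AssocResult:
    term: str
    estimate: float
    se: float
    pvalue: float
    n_complete: int
    family: str
    reliable: bool = True
    odds_ratio: float | None = None
    or_ci95: tuple[float, float] | None = None

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - Z95 * self.se, self.estimate + Z95 * self.se)


# ---------------------------------------------------------------------------
# outcome encoding
# ---------------------------------------------------------------------------

def encode_outcomes(raw_status: pd.Series,
                    specs: Sequence[OutcomeSpec]) -> pd.DataFrame:
    """Binary employment contrasts from category-set status fields.

    Per contrast: employed -> 0, contrast category -> 1, both endorsed -> 0
    (employed priority), neither -> missing.  The non-employment contrast
    codes any non-employed endorsement as 1, again with employed priority.
    Empty sets are missing for every employment variable.
    """
    out = {}
    sets = raw_status.map(lambda s: frozenset(s) if s is not None else frozenset())
    for spec in specs:
        if spec.family != "binary" or spec.contrast_category is None:
            continue
        cat = spec.contrast_category
        vals = np.full(len(sets), np.nan)
        for i, s in enumerate(sets):
            if not s:
                continue
            if EMPLOYED in s:
                vals[i] = 0.0
            elif cat == NON_EMPLOYMENT or cat in s:
                vals[i] = 1.0
        out[spec.name] = vals
    return pd.DataFrame(out, index=raw_status.index)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def fit_glm(y: pd.Series, X: pd.DataFrame, family: str,
            start_params: np.ndarray | None = None) -> list[AssocResult]:
    """Fit one regression and return per-term Wald results.

    linear: least squares; binary: logistic maximum likelihood; ordinal:
    proportional-odds cumulative logit (one slope per regressor shifting all
    cumulative splits equally).  Rows with any missing value are dropped;
    perfect separation is flagged (``reliable=False``) rather than raised.
    """
    df = pd.concat([y.rename("__y__"), X], axis=1).dropna()
    n = len(df)
    if n < X.shape[1] + 2:
        raise ValueError(f"only {n} complete cases for {X.shape[1]} parameters")
    yv = df["__y__"]
    Xv = df[X.columns]
    if np.linalg.matrix_rank(sm.add_constant(Xv.to_numpy(float))) < Xv.shape[1] + 1:
        raise ValueError("rank-deficient design matrix")

    reliable = True
    if family == "continuous":
        res = sm.OLS(yv.to_numpy(float), sm.add_constant(Xv)).fit()
        params, bse, pvals = res.params, res.bse, res.pvalues
        terms = ["const", *Xv.columns]
    elif family == "binary":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=RuntimeWarning)
                res = sm.Logit(yv.to_numpy(float), sm.add_constant(Xv)).fit(
                    disp=0, start_params=start_params)
        except (PerfectSeparationError, RuntimeWarning, np.linalg.LinAlgError):
            reliable = False
            res = sm.Logit(yv.to_numpy(float), sm.add_constant(Xv)).fit(
                method="bfgs", maxiter=200, disp=0)
        if not res.mle_retvals.get("converged", True):
            reliable = False
        params, bse, pvals = res.params, res.bse, res.pvalues
        terms = ["const", *Xv.columns]
    elif family == "ordinal":
        mod = OrderedModel(yv.to_numpy(), Xv, distr="logit")
        res = mod.fit(method="bfgs", maxiter=500, gtol=1e-8, disp=0,
                      start_params=start_params)
        if not res.mle_retvals.get("converged", True):
            reliable = False
        kx = Xv.shape[1]
        params = res.params[:kx]
        bse = res.bse[:kx]
        pvals = res.pvalues[:kx]
        terms = list(Xv.columns)
    else:
        raise ValueError(f"unknown family {family!r}")

    params = np.asarray(params, float)
    bse = np.asarray(bse, float)
    pvals = np.asarray(pvals, float)
    return [
        AssocResult(t, float(b), float(s), float(p), n, family, reliable)
        for t, b, s, p in zip(terms, params, bse, pvals)
    ]


def _term(results: list[AssocResult], term: str) -> AssocResult:
    for r in results:
        if r.term == term:
            return r
    raise KeyError(term)


# ---------------------------------------------------------------------------
# per-SNP outcome association scan
# ---------------------------------------------------------------------------

def snp_outcome_scan(
    cohort,
    snp_ids: Sequence[str],
    outcome: str | pd.Series,
    family: str,
    covariates: Sequence[str] = (),
) -> list[GwasRecord]:
    """One outcome regression per instrument SNP (additive dosage coding).

    Emits outcome-side summary records (beta is a log-odds for the
    binary/ordinal families) carrying the dosage-coded effect allele.
    SNPs monomorphic in the analytic sample are emitted flagged and carry
    no usable estimate.  The linear family uses an exact partialled-out
    least-squares path (identical to the full fit, vectorised over SNPs).
    """
    data = cohort.data
    y = data[outcome] if isinstance(outcome, str) else outcome
    Z = design_frame(data, covariates)

    if family == "continuous":
        return _linear_scan(cohort, snp_ids, y, Z)

    # warm start: the 77 fits share their covariate block, so fit the
    # covariates-only model once and start each per-SNP fit from it
    base = pd.concat([y.rename("__y__"), Z], axis=1).dropna()
    start = _null_start(base["__y__"], base[Z.columns], family)

    records = []
    for s in snp_ids:
        g = data[s]
        sub = pd.concat([y.rename("__y__"), g.rename("__g__"), Z], axis=1).dropna()
        if sub["__g__"].nunique() < 2:
            records.append(_mono_record(cohort, s, len(sub)))
            continue
        X = sub[["__g__", *Z.columns]].rename(columns={"__g__": s})
        res = _term(fit_glm(sub["__y__"], X, family, start_params=start), s)
        records.append(_record_from(cohort, s, sub["__g__"], res))
    return records


def _null_start(y: pd.Series, Z: pd.DataFrame, family: str) -> np.ndarray | None:
    """Parameter vector of the covariates-only fit, with a zero slot
    inserted for the dosage term."""
    try:
        if family == "binary":
            null = sm.Logit(y.to_numpy(float), sm.add_constant(Z)).fit(disp=0)
            p = np.asarray(null.params, float)
            return np.concatenate([p[:1], [0.0], p[1:]])  # [const, g, covs]
        if family == "ordinal":
            null = OrderedModel(y.to_numpy(), Z, distr="logit").fit(
                method="bfgs", maxiter=500, gtol=1e-8, disp=0)
            p = np.asarray(null.params, float)
            kz = Z.shape[1]
            return np.concatenate([[0.0], p[:kz], p[kz:]])  # [g, covs, cuts]
    except Exception:
        return None
    return None


def _linear_scan(cohort, snp_ids, y: pd.Series, Z: pd.DataFrame) -> list[GwasRecord]:
    data = cohort.data
    G = data[list(snp_ids)]
    sub = pd.concat([y.rename("__y__"), G, Z], axis=1).dropna()
    n = len(sub)
    yv = sub["__y__"].to_numpy(float)
    Zc = np.hstack([np.ones((n, 1)), sub[Z.columns].to_numpy(float)])
    # residualise y and every dosage column on the covariates (Frisch-Waugh)
    coef_y, *_ = np.linalg.lstsq(Zc, yv, rcond=None)
    ry = yv - Zc @ coef_y
    Gm = sub[list(snp_ids)].to_numpy(float)
    coef_g, *_ = np.linalg.lstsq(Zc, Gm, rcond=None)
    Rg = Gm - Zc @ coef_g
    gg = (Rg * Rg).sum(axis=0)
    df_resid = n - Zc.shape[1] - 1
    records = []
    for j, s in enumerate(snp_ids):
        g = sub[s]
        if g.nunique() < 2:
            records.append(_mono_record(cohort, s, n))
            continue
        beta = float(Rg[:, j] @ ry / gg[j])
        sse = float(ry @ ry) - beta * beta * gg[j]
        se = float(np.sqrt(sse / df_resid / gg[j]))
        tstat = beta / se
        p = float(2.0 * stats.t.sf(abs(tstat), df_resid))
        ea, oa = cohort.snp_alleles[s]
        records.append(GwasRecord(s, ea, oa, float(g.mean() / 2.0), beta, se,
                                  max(p, 5e-324), n))
    return records


def _record_from(cohort, snp_id: str, g: pd.Series, res: AssocResult) -> GwasRecord:
    ea, oa = cohort.snp_alleles[snp_id]
    return GwasRecord(snp_id, ea, oa, float(g.mean() / 2.0), res.estimate,
                      res.se, max(res.pvalue, 5e-324), res.n_complete)


def _mono_record(cohort, snp_id: str, n: int) -> GwasRecord:
    ea, oa = cohort.snp_alleles[snp_id]
    return GwasRecord(snp_id, ea, oa, 0.0, 0.0, 0.0, 1.0, n, monomorphic=True)


# ---------------------------------------------------------------------------
# observational association
# ---------------------------------------------------------------------------

def observational_association(
    cohort,
    outcome: str | pd.Series,
    family: str,
    covariates: Sequence[str] = (),
    exposure_col: str = "exposure",
) -> AssocResult:
    """Exposure-outcome regression with covariate adjustment.

    The exposure term's estimate (log-odds or slope per exposure unit) is
    returned; binary/ordinal results also carry the odds ratio and its 95%
    CI, ``exp(beta -/+ 1.959964 se)``.
    """
    data = cohort.data
    y = data[outcome] if isinstance(outcome, str) else outcome
    X = pd.concat(
        [data[exposure_col].rename(exposure_col), design_frame(data, covariates)],
        axis=1,
    )
    res = _term(fit_glm(y, X, family), exposure_col)
    if family in ("binary", "ordinal"):
        res.odds_ratio = float(np.exp(res.estimate))
        res.or_ci95 = (float(np.exp(res.estimate - Z95 * res.se)),
                       float(np.exp(res.estimate + Z95 * res.se)))
    return res
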