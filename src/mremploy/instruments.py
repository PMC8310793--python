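"""Instrument construction for two-sample Mendelian randomisation.

Summary-statistic QC, LD clumping, exposure/outcome harmonisation, the
unweighted allele score, and instrument-strength diagnostics (F statistic,
partial R^2, per-allele slope).

Genetic instruments for an exposure such as BMI are SNPs robustly associated
with it in an external GWAS.  Before they can be used in MR the association
records must be filtered on significance and quality metrics, pruned to
approximate linkage independence, and aligned so the exposure and outcome
effect sizes refer to the same effect allele.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GwasRecord",
    "HarmonisedSet",
    "StrengthStats",
    "filter_snps",
    "clump",
    "harmonise",
    "allele_score",
    "instrument_strength",
    "read_gwas",
    "write_gwas",
    "read_ld_matrix",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class GwasRecord:
    """One variant's summary association with a trait.

    ``beta`` is the additive effect per copy of ``effect_allele`` (exposure
    units for a continuous trait, log-odds for binary/ordinal).  ``info`` and
    ``hwe_p`` are optional quality metrics (imputation quality and the
    Hardy-Weinberg equilibrium test p-value) used only by :func:`filter_snps`.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int
    info: float | None = None
    hwe_p: float | None = None
    monomorphic: bool = False

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not self.monomorphic and not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be positive, got {self.se}")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    def is_palindromic(self) -> bool:
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele

    def flipped(self) -> "GwasRecord":
        """The same association reported for the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )


@dataclass
class HarmonisedSet:
    """Per-SNP exposure/outcome effect pairs on a common effect allele.

    Arrays cover the *retained* SNPs only; ``actions`` records the
    harmonisation outcome for every SNP considered, including drops.
    """

    snp_ids: list[str]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    actions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta_x = np.asarray(self.beta_x, dtype=float)
        self.se_x = np.asarray(self.se_x, dtype=float)
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        k = len(self.snp_ids)
        for name in ("beta_x", "se_x", "beta_y", "se_y"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} length != number of snp_ids")

    @property
    def k(self) -> int:
        return len(self.snp_ids)

    def subset(self, keep: Sequence[bool] | np.ndarray) -> "HarmonisedSet":
        keep = np.asarray(keep, dtype=bool)
        ids = [s for s, k in zip(self.snp_ids, keep) if k]
        return HarmonisedSet(
            ids, self.beta_x[keep], self.se_x[keep],
            self.beta_y[keep], self.se_y[keep],
            {s: self.actions.get(s, "kept") for s in ids},
        )

    def drop(self, snp_ids: Iterable[str]) -> "HarmonisedSet":
        bad = set(snp_ids)
        return self.subset([s not in bad for s in self.snp_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": self.snp_ids,
                "beta_x": self.beta_x,
                "se_x": self.se_x,
                "beta_y": self.beta_y,
                "se_y": self.se_y,
                "action": [self.actions.get(s, "kept") for s in self.snp_ids],
            }
        )


@dataclass(frozen=True)
class StrengthStats:
    """Instrument-strength summary from the score-validation regression."""

    f_statistic: float
    partial_r2: float
    adjusted_partial_r2: float
    per_allele_slope: float
    slope_se: float
    n: int


# ---------------------------------------------------------------------------
# summary-statistics I/O (tab-delimited dialect: SNP EA OA EAF BETA SE P N)
# ---------------------------------------------------------------------------

_GWAS_COLS = ["SNP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]


def write_gwas(records: Sequence[GwasRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "SNP": r.snp_id, "EA": r.effect_allele, "OA": r.other_allele,
            "EAF": r.eaf, "BETA": r.beta, "SE": r.se, "P": r.pvalue, "N": r.n,
        }
        if r.info is not None:
            row["INFO"] = r.info
        if r.hwe_p is not None:
            row["HWE_P"] = r.hwe_p
        rows.append(row)
    # %.17g keeps the round-trip bit-exact
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gwas(path) -> list[GwasRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _GWAS_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS table {path} missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            GwasRecord(
                snp_id=str(d["SNP"]), effect_allele=str(d["EA"]),
                other_allele=str(d["OA"]), eaf=float(d["EAF"]),
                beta=float(d["BETA"]), se=float(d["SE"]),
                pvalue=float(d["P"]), n=int(d["N"]),
                info=float(d["INFO"]) if "INFO" in d and pd.notna(d["INFO"]) else None,
                hwe_p=float(d["HWE_P"]) if "HWE_P" in d and pd.notna(d["HWE_P"]) else None,
            )
        )
    return out


def read_ld_matrix(path) -> pd.DataFrame:
    """Square r^2 matrix with snp_id header row and index column."""
    ld = pd.read_csv(path, sep="\t", index_col=0)
    if list(ld.index) != list(ld.columns):
        raise ValueError("LD matrix row and column snp_ids differ")
    return ld


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

def filter_snps(
    records: Sequence[GwasRecord],
    *,
    p_max: float = 5e-8,
    maf_min: float | None,
    hwe_p_min: float | None,
    info_min: float | None,
) -> tuple[list[GwasRecord], dict[str, int]]:
    """Apply significance and quality filters; return survivors and a ledger.

    A record must pass every active rule.  ``maf_min``, ``hwe_p_min`` and
    ``info_min`` have no defaults and must be given explicitly; pass ``None``
    to deactivate a rule.  The ledger counts, per rule, how many records that
    rule removed (a record failing several rules is counted once under each).
    """
    ledger = {"pvalue": 0, "maf": 0, "hwe": 0, "info": 0}
    kept: list[GwasRecord] = []
    for r in records:
        ok = True
        if r.pvalue > p_max:
            ledger["pvalue"] += 1
            ok = False
        if maf_min is not None and r.maf < maf_min:
            ledger["maf"] += 1
            ok = False
        if hwe_p_min is not None:
            if r.hwe_p is None:
                raise ValueError(f"{r.snp_id}: hwe_p missing but hwe_p_min is active")
            if r.hwe_p < hwe_p_min:
                ledger["hwe"] += 1
                ok = False
        if info_min is not None:
            if r.info is None:
                raise ValueError(f"{r.snp_id}: info missing but info_min is active")
            if r.info < info_min:
                ledger["info"] += 1
                ok = False
        if ok:
            kept.append(r)
    return kept, ledger


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------

def clump(
    records: Sequence[GwasRecord],
    ld: pd.DataFrame,
    r2_max: float,
    p_max: float | None = None,
) -> list[GwasRecord]:
    """Greedy p-value clumping against a pairwise r^2 matrix.

    Repeatedly keeps the most significant remaining record and discards all
    records in LD (r^2 > ``r2_max``) with it.  Output is sorted by p-value;
    ties broken by snp_id so the result is deterministic and invariant to
    input order.
    """
    if not 0 < r2_max < 1:
        raise ValueError("r2_max must lie in (0, 1)")
    ids = [r.snp_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate snp_id(s) in clump input: {dupes}")
    missing = [s for s in ids if s not in ld.index or s not in ld.columns]
    if missing:
        raise ValueError(f"LD matrix missing entries for: {missing}")

    if p_max is not None:
        records = [r for r in records if r.pvalue <= p_max]
    pool = sorted(records, key=lambda r: (r.pvalue, r.snp_id))
    kept: list[GwasRecord] = []
    while pool:
        lead = pool.pop(0)
        kept.append(lead)
        pool = [r for r in pool if float(ld.loc[lead.snp_id, r.snp_id]) <= r2_max]
    return kept


# ---------------------------------------------------------------------------
# harmonisation
# ---------------------------------------------------------------------------

def _alleles(r: GwasRecord) -> tuple[str, str]:
    return r.effect_allele, r.other_allele


def harmonise(
    exposure: Sequence[GwasRecord],
    outcome: Sequence[GwasRecord],
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonisedSet:
    """Align exposure and outcome records to a common effect allele.

    For each SNP present in both inputs the outcome record is flipped when
    its alleles are reported for the opposite orientation; strand-complement
    reports are recognised.  Palindromic SNPs (A/T, C/G) carry no strand
    information in their allele codes, so orientation is inferred from allele
    frequency — unless either frequency falls inside the ambiguity window, in
    which case the SNP is dropped.  Irreconcilable allele pairs are dropped,
    not raised.
    """
    for recs, side in ((exposure, "exposure"), (outcome, "outcome")):
        ids = [r.snp_id for r in recs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate snp_ids in {side} records")
    out_by_id = {r.snp_id: r for r in outcome}
    lo, hi = palindromic_eaf_window

    snp_ids: list[str] = []
    bx, sx, by, sy = [], [], [], []
    actions: dict[str, str] = {}

    for ex in exposure:
        if ex.snp_id not in out_by_id:
            continue
        oc = out_by_id[ex.snp_id]
        ea_x, oa_x = _alleles(ex)
        ea_y, oa_y = _alleles(oc)
        comp_ea = _COMPLEMENT.get(ea_x)
        comp_oa = _COMPLEMENT.get(oa_x)

        if ex.is_palindromic():
            # allele codes cannot resolve strand; use frequency
            if (ea_y, oa_y) not in {(ea_x, oa_x), (oa_x, ea_x)}:
                action = "dropped_mismatch"
            elif lo <= ex.eaf <= hi or lo <= oc.eaf <= hi:
                action = "dropped_palindromic"
            else:
                concordant = (ex.eaf < 0.5) == (oc.eaf < 0.5)
                action = "kept" if concordant else "flipped"
        elif (ea_y, oa_y) == (ea_x, oa_x):
            action = "kept"
        elif (ea_y, oa_y) == (oa_x, ea_x):
            action = "flipped"
        elif (ea_y, oa_y) == (comp_ea, comp_oa):
            action = "kept"  # strand complement, same orientation
        elif (ea_y, oa_y) == (comp_oa, comp_ea):
            action = "flipped"
        else:
            action = "dropped_mismatch"

        actions[ex.snp_id] = action
        if action.startswith("dropped"):
            continue
        if action == "flipped":
            oc = oc.flipped()
        snp_ids.append(ex.snp_id)
        bx.append(ex.beta)
        sx.append(ex.se)
        by.append(oc.beta)
        sy.append(oc.se)

    return HarmonisedSet(snp_ids, np.array(bx), np.array(sx),
                         np.array(by), np.array(sy), actions)


# ---------------------------------------------------------------------------
# unweighted allele score
# ---------------------------------------------------------------------------

def allele_score(cohort, exposure_records: Sequence[GwasRecord]) -> np.ndarray:
    """Unweighted polygenic score: risk-allele count across instrument SNPs.

    The risk allele of each SNP is its exposure-increasing allele.  With
    dosages coded for the exposure record's effect allele, a SNP contributes
    ``g`` when beta > 0 and ``2 - g`` when beta < 0.  Dosage columns coded
    for the opposite allele are re-oriented first.
    """
    n = len(cohort.data)
    score = np.zeros(n)
    for r in exposure_records:
        if r.beta == 0:
            raise ValueError(f"{r.snp_id}: beta is exactly 0, risk allele undefined")
        if r.snp_id not in cohort.data.columns:
            raise KeyError(f"cohort has no dosage column for {r.snp_id}")
        g = cohort.data[r.snp_id].to_numpy()
        cohort_ea, cohort_oa = cohort.snp_alleles[r.snp_id]
        if (r.effect_allele, r.other_allele) == (cohort_ea, cohort_oa):
            pass
        elif (r.effect_allele, r.other_allele) == (cohort_oa, cohort_ea):
            g = 2 - g
        else:
            raise ValueError(
                f"{r.snp_id}: record alleles {r.effect_allele}/{r.other_allele} "
                f"do not match cohort alleles {cohort_ea}/{cohort_oa}"
            )
        score += g if r.beta > 0 else 2 - g
    return score.astype(int)


# ---------------------------------------------------------------------------
# instrument strength
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    """Expand categorical columns to dummies (most frequent level reference)."""
    parts = [np.ones((len(df), 1))]
    for c in cols:
        col = df[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            ref = col.value_counts().idxmax()
            for lev in sorted(x for x in col.unique() if x != ref):
                parts.append((col == lev).to_numpy(float).reshape(-1, 1))
        else:
            parts.append(col.to_numpy(float).reshape(-1, 1))
    return np.hstack(parts)


def instrument_strength(
    cohort,
    covariate_names: Sequence[str],
    score_col: str = "allele_score",
    exposure_col: str = "exposure",
) -> StrengthStats:
    """Score-validation regression: exposure ~ score + covariates.

    Returns the score's F statistic (1 numerator df), its partial R^2 —
    the share of exposure variance it explains beyond the covariates,
    (SSE_reduced − SSE_full) / SSE_reduced from nested least-squares fits —
    a sample-size-adjusted variant, and the per-allele slope.
    """
    df = cohort.data
    y = df[exposure_col].to_numpy(float)
    X_cov = _design(df, covariate_names)
    rank = np.linalg.matrix_rank(X_cov)
    if rank < X_cov.shape[1]:
        bad = _collinear_columns(X_cov, covariate_names)
        raise ValueError(f"collinear covariates: {bad}")
    s = df[score_col].to_numpy(float).reshape(-1, 1)
    X_full = np.hstack([X_cov, s])

    beta_r, sse_r = _ols_sse(X_cov, y)
    beta_f, sse_f = _ols_sse(X_full, y)
    n, p_full = X_full.shape
    df_resid = n - p_full
    f_stat = (sse_r - sse_f) / (sse_f / df_resid)
    partial = (sse_r - sse_f) / sse_r
    adj_partial = 1.0 - (1.0 - partial) * (n - X_cov.shape[1]) / df_resid
    slope = beta_f[-1]
    xtx_inv = np.linalg.inv(X_full.T @ X_full)
    slope_se = float(np.sqrt(sse_f / df_resid * xtx_inv[-1, -1]))
    return StrengthStats(float(f_stat), float(partial), float(adj_partial),
                         float(slope), slope_se, n)


def _ols_sse(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Crude diagnosis: columns whose removal restores full rank."""
    bad = []
    full_rank = np.linalg.matrix_rank(X)
    for j in range(1, X.shape[1]):  # skip intercept
        sub = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(sub) == full_rank:
            bad.append(names[min(j - 1, len(names) - 1)] if names else str(j))
    return sorted(set(bad))
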