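"""Stratified MR comparisons: sex-difference Z tests and age-band trends.

Stratum-specific MR estimates (e.g. male vs female) obtained from the same
instrument set in non-overlapping strata are compared with a normal
difference test; across three or more age bands a weighted trend F test
asks whether the causal effect varies with age.  Published results often
print only estimates and 95% CIs, so a CI -> SE conversion is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._util import Z95

__all__ = ["StratumComparison", "ci_to_se", "z_difference", "age_trend_test"]


@dataclass(frozen=True)
class StratumComparison:
    labels: tuple[str, str]
    b1: float
    se1: float
    b2: float
    se2: float
    z: float
    pvalue: float


@dataclass(frozen=True)
class TrendTest:
    f_statistic: float
    df_num: int
    df_den: int
    pvalue: float
    slope: float
    method: str


def ci_to_se(lower: float, upper: float, level: float = 0.95) -> float:
    """Standard error implied by a symmetric normal confidence interval:
    ``(upper - lower) / (2 z_{(1+level)/2})``; 1.959964 at the 95% level."""
    if upper <= lower:
        raise ValueError(f"upper ({upper}) must exceed lower ({lower})")
    z = Z95 if level == 0.95 else stats.norm.ppf(0.5 + level / 2.0)
    return (upper - lower) / (2.0 * z)


def z_difference(b1: float, se1: float, b2: float, se2: float,
                 labels: tuple[str, str] = ("stratum1", "stratum2")) -> StratumComparison:
    """Wald test of equality of two independent stratum estimates:
    z = (b2 - b1) / sqrt(se1^2 + se2^2), two-sided normal p."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (b2 - b1) / np.hypot(se1, se2)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return StratumComparison(labels, b1, se1, b2, se2, float(z), p)


def age_trend_test(
    stratum_results: Sequence[tuple[float, float, float]],
    method: str = "wls_trend",
) -> TrendTest:
    """Does the MR estimate vary across age bands?

    ``stratum_results`` is a sequence of (band midpoint, estimate, se).

    ``wls_trend`` (default): weighted least squares of the estimates on the
    band midpoints, weights 1/se^2; F test of the slope against the
    intercept-only model.  ``het_q``: a band-heterogeneity Cochran Q on
    m - 1 df (order-free alternative); with two strata it reproduces the
    two-sided z-difference p exactly.
    """
    m = len(stratum_results)
    if m < 3 and method == "wls_trend":
        raise ValueError("need >= 3 bands for a trend test; use z_difference for 2 strata")
    x = np.array([r[0] for r in stratum_results], float)
    b = np.array([r[1] for r in stratum_results], float)
    se = np.array([r[2] for r in stratum_results], float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / se ** 2

    if method == "het_q":
        bw = np.sum(w * b) / np.sum(w)
        q = float(np.sum(w * (b - bw) ** 2))
        return TrendTest(q, m - 1, 0, float(stats.chi2.sf(q, m - 1)), 0.0, method)
    if method != "wls_trend":
        raise ValueError(f"unknown method {method!r}")

    X1 = np.column_stack([np.ones(m), x])
    sw = np.sqrt(w)
    beta1, *_ = np.linalg.lstsq(X1 * sw[:, None], b * sw, rcond=None)
    rss1 = float(np.sum(w * (b - X1 @ beta1) ** 2))
    bw = np.sum(w * b) / np.sum(w)
    rss0 = float(np.sum(w * (b - bw) ** 2))
    df_den = m - 2
    if rss1 == 0.0:
        f = 0.0 if rss0 <= 0.0 else np.inf
        p = 1.0 if rss0 <= 0.0 else 0.0
    else:
        f = max(rss0 - rss1, 0.0) / (rss1 / df_den)
        p = float(stats.f.sf(f, 1, df_den))
    return TrendTest(float(f), 1, df_den, p, float(beta1[1]), method)
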