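"""Published reference values used for validation.

Two small tables transcribed from a large published UK cohort analysis of
BMI and employment outcomes are embedded here so the package's descriptive
and stratified-comparison machinery can be validated against numbers that
are recomputable from print: category counts for the descriptive table, and
sex-stratified MR estimates with their 95% CIs for the between-sex Wald
test.  These are *inputs* for validation, never substitutes for computed
results.
"""

from __future__ import annotations

# Overall analytic sample size and employment-category counts
# (female, male, overall), with the published overall percentage.
DESCRIPTIVE_COUNTS = {
    "total": {"female": 104945, "male": 125846, "overall": 230791},
    "employed": {"female": 83292, "male": 90303, "overall": 173595,
                 "overall_pct": 75.2},
    "retired": {"female": 6768, "male": 24036, "overall": 30804,
                "overall_pct": 13.3},
    "sick_disabled": {"female": 4978, "male": 6848, "overall": 11826,
                      "overall_pct": 5.1},
    "caring": {"female": 7534, "male": 1080, "overall": 8614,
               "overall_pct": 3.7},
    "unemployed": {"female": 1640, "male": 3558, "overall": 5198,
                   "overall_pct": 2.3},
    "not_in_paid_work": {"female": 20791, "male": 34507, "overall": 55298,
                         "overall_pct": 24.0},
}

# Sex-stratified MR estimates (per 1 kg/m^2): point estimate and 95% CI for
# males and females, plus the published between-sex difference p-value
# (as printed, 2 significant figures in scientific notation).
SEX_STRATA_MR = [
    {
        "outcome": "not_in_paid_employment", "method": "ivw_fe",
        "male": (0.0194, 0.000523, 0.0383),
        "female": (0.0057, -0.0157, 0.0271),
        "published_p": "3.5E-01",
    },
    {
        "outcome": "sick_disabled", "method": "ivw_fe",
        "male": (0.0646, 0.0296, 0.0996),
        "female": (0.1055, 0.0653, 0.146),
        "published_p": "1.3E-01",
    },
    {
        "outcome": "sick_disabled", "method": "ivw_mre",
        "male": (0.0646, 0.0266, 0.103),
        "female": (0.1055, 0.0589, 0.152),
        "published_p": "1.8E-01",
    },
    {
        "outcome": "caring", "method": "ivw_fe",
        "male": (-0.0282, -0.111, 0.0545),
        "female": (-0.0489, -0.0819, -0.016),
        "published_p": "6.5E-01",
    },
    {
        "outcome": "retired", "method": "ivw_fe",
        "male": (0.0073, -0.016, 0.0305),
        "female": (0.0109, -0.0257, 0.0476),
        "published_p": "8.7E-01",
    },
    {
        "outcome": "unemployed", "method": "ivw_fe",
        "male": (-0.0047, -0.0507, 0.0414),
        "female": (0.0330, -0.0348, 0.101),
        "published_p": "3.7E-01",
    },
    {
        "outcome": "tdi", "method": "ivw_fe",
        "male": (0.0331, 0.0116, 0.0546),
        "female": (0.0422, 0.0193, 0.0651),
        "published_p": "5.7E-01",
    },
    {
        "outcome": "hours_worked", "method": "ivw_fe",
        "male": (-0.0110, -0.108, 0.0862),
        "female": (0.0748, -0.0346, 0.184),
        "published_p": "2.5E-01",
    },
    {
        "outcome": "education", "method": "ivw_fe",
        "male": (-0.0254, -0.0396, -0.0113),
        "female": (-0.0256, -0.0412, -0.00998),
        "published_p": "9.9E-01",
    },
    {
        "outcome": "income", "method": "ivw_fe",
        "male": (-0.0192, -0.0337, -0.0046),
        "female": (-0.0295, -0.0457, -0.0133),
        "published_p": "3.5E-01",
    },
]


def format_p(p: float) -> str:
    """Scientific notation with two significant figures, e.g. 1.3E-01."""
    return f"{p:.1E}"
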