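"""Published group summary statistics of the original study cohort.

Pre/post mean and SD of the clinical outcome measures and kinematic
parameters reported for the N = 10 chronic-stroke cohort that motivated
this pipeline.  These printed summaries are *inputs*: the package
recomputes baseline-SD effect sizes from them as worked examples
(``reachkin.stats.cohens_d``), it does not store any effect-size value.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GroupSummary:
    """Printed pre/post group summary for one variable."""

    variable: str
    kind: str  # {clinical, kinematic}
    mean_pre: float
    sd_pre: float
    mean_post: float
    sd_post: float
    improvement_direction: str  # {increase, decrease}


#: clinical outcome measures, N = 10 (points; WMFT_Time in s)
CLINICAL_GROUP_SUMMARIES = {
    "FMA_UE": GroupSummary("FMA_UE", "clinical", 32.20, 9.60, 39.50, 10.01, "increase"),
    "WMFT_Time": GroupSummary("WMFT_Time", "clinical", 32.82, 25.33, 24.04, 23.54, "decrease"),
    "WMFT_FAS": GroupSummary("WMFT_FAS", "clinical", 2.39, 0.64, 2.83, 0.77, "increase"),
    "MAL_AOU": GroupSummary("MAL_AOU", "clinical", 1.19, 0.73, 2.01, 0.86, "increase"),
    "MAL_QOM": GroupSummary("MAL_QOM", "clinical", 1.21, 0.64, 2.05, 0.78, "increase"),
}

#: kinematic parameters, paretic arm, N = 10 (units as in the construct table)
KINEMATIC_GROUP_SUMMARIES = {
    "MT": GroupSummary("MT", "kinematic", 2.41, 0.58, 2.28, 0.69, "decrease"),
    "CurvI": GroupSummary("CurvI", "kinematic", 1.67, 0.69, 1.88, 1.14, "decrease"),
    "Vmax": GroupSummary("Vmax", "kinematic", 55.72, 17.08, 58.44, 16.18, "increase"),
    "TpctVmax": GroupSummary("TpctVmax", "kinematic", 39.11, 12.21, 47.67, 6.13, "increase"),
    "NVP": GroupSummary("NVP", "kinematic", 17.11, 5.27, 15.55, 5.66, "decrease"),
    "LDJ": GroupSummary("LDJ", "kinematic", -18.96, 0.80, -18.60, 1.38, "increase"),
    "ShFE": GroupSummary("ShFE", "kinematic", 18.86, 4.67, 18.61, 7.32, "increase"),
    "ShAA": GroupSummary("ShAA", "kinematic", 25.14, 4.82, 25.90, 8.37, "increase"),
    "ElFE": GroupSummary("ElFE", "kinematic", 38.89, 22.73, 36.84, 19.49, "increase"),
    "Th": GroupSummary("Th", "kinematic", 6.61, 4.07, 6.97, 5.09, "decrease"),
    "TExc": GroupSummary("TExc", "kinematic", 12.83, 7.91, 12.56, 8.68, "decrease"),
}

GROUP_SUMMARIES = {**CLINICAL_GROUP_SUMMARIES, **KINEMATIC_GROUP_SUMMARIES}

#: variables whose printed effect size is consistent with the printed
#: means/SDs to two decimals; the remainder carry upstream rounding and
#: are excluded from the worked-example checks
CONSISTENT_EFFECT_ROWS = (
    "FMA_UE", "WMFT_Time", "MAL_AOU", "MAL_QOM",
    "TpctVmax", "CurvI", "Vmax", "TExc",
)


def recompute_effect_size(variable: str) -> float:
    """Recompute baseline-SD Cohen's d from the printed summaries
    (sign-adjusted so improvement is positive)."""
    from .stats import cohens_d

    s = GROUP_SUMMARIES[variable]
    return cohens_d(s.mean_pre, s.sd_pre, s.mean_post, s.improvement_direction)


def recompute_effect_magnitude(variable: str) -> float:
    """|d| from the printed summaries — the scale on which the study
    tabulates its effect sizes."""
    return abs(recompute_effect_size(variable))
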