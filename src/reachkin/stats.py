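"""Statistical battery relating kinematic parameters to clinical outcomes.

Implements the analyses used to relate reach-to-target kinematics to
upper-extremity clinical outcome measures in a small pre/post
intervention cohort:

* Spearman rank correlations, cross-sectional (pre and post observations
  pooled) and longitudinal (post - pre deltas), against total and
  proximal clinical score variants, with Holm adjustment per grid and
  Hinkle-style magnitude labels.
* Paired pre/post tests by bootstrap (resampling pairs, default B = 1000):
  percentile CI of the mean difference and a studentized (bootstrap-t)
  p-value, which keeps the type-I error near nominal at n = 10 where the
  plain percentile p-value is markedly anticonservative.
* Cohen's d with the pre-intervention SD as denominator, sign-adjusted so
  improvement is positive.
* MCID responder flags and the non-paretic reference band
  (mean +/- 1 SD of the non-paretic aggregates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    InvalidArgumentError,
    UndefinedBandError,
    UndefinedCorrelationError,
    UndefinedEffectSizeError,
)

# ---------------------------------------------------------------- scores

#: clinical measures: direction of improvement
CLINICAL_DIRECTIONS = {
    "FMA_UE": "increase",
    "WMFT_FAS": "increase",
    "WMFT_Time": "decrease",
    "MAL_AOU": "increase",
    "MAL_QOM": "increase",
}

#: measures that also exist in a proximal (shoulder/elbow items) variant
PROXIMAL_MEASURES = ("FMA_UE", "WMFT_FAS", "WMFT_Time")

#: score ranges used for validation: (low, high); None = open
SCORE_RANGES = {
    "FMA_UE": (0.0, 66.0),
    "WMFT_FAS": (0.0, 5.0),
    "WMFT_Time": (0.0, None),
    "MAL_AOU": (0.0, 5.0),
    "MAL_QOM": (0.0, 5.0),
}

#: shipped default minimal clinically important differences (user-editable;
#: points, or seconds for WMFT_Time), drawn from the chronic-stroke
#: rehabilitation literature
DEFAULT_MCID = {
    "FMA_UE": 5.25,
    "WMFT_FAS": 0.37,
    "WMFT_Time": 1.5,
    "MAL_AOU": 0.5,
    "MAL_QOM": 0.5,
}


def validate_clinical(scores: pd.DataFrame) -> pd.DataFrame:
    """Validate a subject/session clinical-scores table in place."""
    needed = {"subject_id", "session"} | set(CLINICAL_DIRECTIONS)
    missing = needed - set(scores.columns)
    if missing:
        raise InvalidArgumentError(f"clinical table misses columns {sorted(missing)}")
    bad_sessions = set(scores["session"]) - {"pre", "post"}
    if bad_sessions:
        raise InvalidArgumentError(f"unknown sessions {sorted(bad_sessions)}")
    for measure, (lo, hi) in SCORE_RANGES.items():
        vals = scores[measure].dropna()
        if (vals < lo).any() or (hi is not None and (vals > hi).any()):
            raise InvalidArgumentError(f"{measure} outside its scale")
    return scores


# ------------------------------------------------------------ primitives

#: cached permutation-null tables of |r_s| per sample size
_NULL_TABLES: dict[int, np.ndarray] = {}
_NULL_M = 200_000
#: largest n for which the Monte-Carlo permutation p-value is used
_NULL_MAX_N = 30


def _null_abs_rs(n: int) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of |r_s| for tie-free samples
    of size n (distribution-free), under a fixed internal seed."""
    table = _NULL_TABLES.get(n)
    if table is None:
        rng = np.random.default_rng(987654321 + n)
        perms = np.argsort(rng.random((_NULL_M, n)), axis=1)
        d2 = ((perms - np.arange(n)) ** 2).sum(axis=1)
        rs = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
        table = np.sort(np.abs(rs))
        _NULL_TABLES[n] = table
    return table


def spearman_null_pvalue(r: float | np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a Spearman correlation from the Monte-Carlo
    permutation null (valid for tie-free data; accurate deep into the
    tail, where the usual t-approximation is liberal)."""
    table = _null_abs_rs(n)
    idx = np.searchsorted(table, np.abs(r) - 1e-12, side="left")
    return (_NULL_M - idx + 1.0) / (_NULL_M + 1.0)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and two-sided p.

    For tie-free samples of n <= 30 the p-value comes from the
    distribution-free permutation null (Monte-Carlo, fixed internal
    seed); otherwise from the usual t-approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise InvalidArgumentError("need >= 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant vector")
    res = sps.spearmanr(x, y)
    n = x.size
    tie_free = (np.unique(x).size == n) and (np.unique(y).size == n)
    if tie_free and n <= _NULL_MAX_N:
        p = float(spearman_null_pvalue(float(res.statistic), n))
    else:
        p = float(res.pvalue)
    return float(res.statistic), p


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)  # step-down monotonicity
    out = np.empty(m)
    out[order] = adj
    return out


def hinkle_label(r_s: float) -> str:
    """Magnitude label for a correlation coefficient: boundaries 0.30 /
    0.50 / 0.70 assigned to the higher class."""
    r = abs(float(r_s))
    if r > 1.0 + 1e-12:
        raise InvalidArgumentError("|r| must be <= 1")
    if r >= 0.70:
        return "high"
    if r >= 0.50:
        return "moderate"
    if r >= 0.30:
        return "low"
    return "negligible"


def cohens_d(
    mean_pre: float,
    sd_pre: float,
    mean_post: float,
    improvement_direction: str = "increase",
) -> float:
    """Standardized pre-to-post change, baseline-SD denominator:
    d = (mean_post - mean_pre) / sd_pre, sign-flipped when a decrease is
    the improvement so that improvement is always positive."""
    if sd_pre <= 0:
        raise UndefinedEffectSizeError("pre-intervention SD must be positive")
    if improvement_direction not in ("increase", "decrease"):
        raise InvalidArgumentError(
            f"unknown improvement_direction {improvement_direction!r}"
        )
    d = (mean_post - mean_pre) / sd_pre
    return -d if improvement_direction == "decrease" else d


def effect_size_label(d: float) -> str:
    """Cohen's conventions: 0.20 / 0.50 / 0.80 = small / medium / large."""
    a = abs(d)
    if a >= 0.80:
        return "large"
    if a >= 0.50:
        return "medium"
    if a >= 0.20:
        return "small"
    return "negligible"


# --------------------------------------------------------- paired tests

@dataclass(frozen=True)
class PairedTestResult:
    """Bootstrap paired-test summary for one variable."""

    variable: str
    level: str  # {group, subject}
    n: int
    mean_pre: float
    sd_pre: float
    mean_post: float
    sd_post: float
    median_pre: float
    iqr_pre: tuple[float, float]
    median_post: float
    iqr_post: tuple[float, float]
    mean_diff: float
    t: float
    p_boot: float
    ci_low: float
    ci_high: float
    d: float
    degenerate: bool = False
    significant_after_holm: Optional[bool] = None


def bootstrap_paired_t(
    pre: Sequence[float],
    post: Sequence[float],
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    variable: str = "",
    level: str = "group",
    improvement_direction: str = "increase",
    ci_level: float = 0.95,
) -> PairedTestResult:
    """Paired pre/post test by bootstrap over pairs.

    Resamples the n paired differences with replacement B times.  Reports
    the percentile CI of the mean difference and a studentized
    (bootstrap-t) two-sided p-value: the bootstrap distribution of the
    centered t statistic is compared against the observed t.  Reproducible
    under a fixed seed.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise InvalidArgumentError("pre and post must be equal-length vectors")
    n = pre.size
    if n < 2:
        raise InvalidArgumentError("need n >= 2 pairs")
    if B < 100:
        raise InvalidArgumentError("need B >= 100 bootstrap samples")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    diff = post - pre
    mean_diff = float(diff.mean())
    sd_pre = float(pre.std(ddof=1))
    sd_diff = float(diff.std(ddof=1))
    q1_pre, med_pre, q3_pre = np.percentile(pre, [25, 50, 75])
    q1_post, med_post, q3_post = np.percentile(post, [25, 50, 75])

    try:
        d = cohens_d(pre.mean(), sd_pre, post.mean(), improvement_direction)
    except UndefinedEffectSizeError:
        d = float("nan")

    if sd_diff == 0.0:
        return PairedTestResult(
            variable=variable, level=level, n=n,
            mean_pre=float(pre.mean()), sd_pre=sd_pre,
            mean_post=float(post.mean()), sd_post=float(post.std(ddof=1)),
            median_pre=float(med_pre), iqr_pre=(float(q1_pre), float(q3_pre)),
            median_post=float(med_post),
            iqr_post=(float(q1_post), float(q3_post)),
            mean_diff=mean_diff, t=float("nan"), p_boot=float("nan"),
            ci_low=mean_diff, ci_high=mean_diff,
            d=0.0 if mean_diff == 0.0 else d, degenerate=True,
        )

    t_obs = mean_diff / (sd_diff / np.sqrt(n))

    idx = rng.integers(0, n, size=(B, n))
    boot = diff[idx]
    boot_mean = boot.mean(axis=1)
    boot_sd = boot.std(axis=1, ddof=1)
    alpha = 1.0 - ci_level
    ci_low, ci_high = np.percentile(
        boot_mean, [100 * alpha / 2, 100 * (1 - alpha / 2)]
    )

    ok = boot_sd > 0
    t_star = (boot_mean[ok] - mean_diff) / (boot_sd[ok] / np.sqrt(n))
    p = float(((np.abs(t_star) >= abs(t_obs)).sum() + 1) / (ok.sum() + 1))

    return PairedTestResult(
        variable=variable, level=level, n=n,
        mean_pre=float(pre.mean()), sd_pre=sd_pre,
        mean_post=float(post.mean()), sd_post=float(post.std(ddof=1)),
        median_pre=float(med_pre), iqr_pre=(float(q1_pre), float(q3_pre)),
        median_post=float(med_post), iqr_post=(float(q1_post), float(q3_post)),
        mean_diff=mean_diff, t=float(t_obs), p_boot=p,
        ci_low=float(ci_low), ci_high=float(ci_high), d=float(d),
    )


def paired_tests_table(
    pre_post: Mapping[str, tuple[np.ndarray, np.ndarray]],
    directions: Mapping[str, str],
    B: int = 1000,
    seed: int = 0,
    level: str = "group",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run bootstrap paired tests for a family of variables and Holm-adjust
    their p-values jointly (one family per table)."""
    rng = np.random.default_rng(seed)
    results = [
        bootstrap_paired_t(
            pre, post, B=B, seed=rng, variable=var, level=level,
            improvement_direction=directions.get(var, "increase"),
        )
        for var, (pre, post) in pre_post.items()
    ]
    rows = pd.DataFrame([r.__dict__ for r in results])
    mask = ~rows["p_boot"].isna()
    adj = np.full(len(rows), np.nan)
    if mask.any():
        adj[mask.to_numpy()] = holm_adjust(rows.loc[mask, "p_boot"].to_numpy())
    rows["p_holm"] = adj
    rows["significant_after_holm"] = rows["p_holm"] < alpha
    rows.loc[~mask, "significant_after_holm"] = False
    rows["effect_label"] = rows["d"].map(
        lambda v: effect_size_label(v) if np.isfinite(v) else "undefined"
    )
    return rows


# ------------------------------------------------------- correlation grid

def correlation_matrix(
    kin_agg: pd.DataFrame,
    clinical: pd.DataFrame,
    scope: str,
    kin_params: Sequence[str],
    measures: Sequence[str] = ("FMA_UE", "WMFT_FAS", "WMFT_Time"),
    alpha: float = 0.05,
    arm: str = "paretic",
) -> pd.DataFrame:
    """Spearman grid between kinematic aggregates and clinical scores.

    ``scope``: 'cross_sectional' pools the pre and post subject-session
    observations (two rows per subject); 'longitudinal' correlates
    per-subject (post - pre) deltas of both sides.  Each grid crosses the
    measures' total and proximal variants with every kinematic parameter;
    Holm adjustment is applied over the whole grid (one family per panel).
    Subjects missing a session are dropped from the longitudinal panel.
    """
    if scope not in ("cross_sectional", "longitudinal"):
        raise InvalidArgumentError(f"unknown scope {scope!r}")
    kin = kin_agg[kin_agg["arm"] == arm] if "arm" in kin_agg.columns else kin_agg
    merged = kin.merge(clinical, on=["subject_id", "session"], how="inner")

    variants = []
    for meas in measures:
        variants.append((meas, "total", meas))
        prox_col = meas + "_prox"
        if meas in PROXIMAL_MEASURES and prox_col in merged.columns:
            variants.append((meas, "proximal", prox_col))

    if scope == "longitudinal":
        counts = merged.groupby("subject_id")["session"].nunique()
        keep = counts[counts == 2].index
        merged = merged[merged["subject_id"].isin(keep)]
        wide = merged.set_index(["subject_id", "session"]).sort_index()
        post = wide.xs("post", level="session")
        pre = wide.xs("pre", level="session")
        numeric = [c for c in wide.columns if wide[c].dtype.kind in "fi"]
        merged = (post[numeric] - pre[numeric]).reset_index()

    cells = []
    for meas, variant, col in variants:
        for param in kin_params:
            try:
                r, p = spearman(merged[param], merged[col])
            except (InvalidArgumentError, UndefinedCorrelationError):
                r, p = float("nan"), float("nan")  # too few / constant pairs
            cells.append(
                {
                    "kinematic": param,
                    "measure": meas,
                    "variant": variant,
                    "scope": scope,
                    "n": int(merged[[param, col]].dropna().shape[0]),
                    "r_s": r,
                    "p_raw": p,
                }
            )
    grid = pd.DataFrame(cells)
    ok = ~grid["p_raw"].isna()
    adj = np.full(len(grid), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = holm_adjust(grid.loc[ok, "p_raw"].to_numpy())
    grid["p_holm"] = adj
    grid["significant"] = grid["p_holm"] < alpha
    grid["label"] = grid["r_s"].map(
        lambda r: hinkle_label(r) if np.isfinite(r) else "undefined"
    )
    return grid


# ------------------------------------------------------ responder / band

def mcid_flags(
    clinical: pd.DataFrame,
    mcid_table: Mapping[str, float] | None = None,
    directions: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject, per-measure MCID flags plus a responder summary.

    A measure is flagged when its direction-aware improvement is >= its
    MCID (boundary inclusive); a responder is a subject with at least one
    flagged measure.  Measures without an MCID entry are skipped.
    """
    mcid_table = dict(DEFAULT_MCID if mcid_table is None else mcid_table)
    directions = dict(CLINICAL_DIRECTIONS if directions is None else directions)
    for k, v in mcid_table.items():
        if v <= 0:
            raise InvalidArgumentError(f"MCID for {k} must be positive")
    wide = clinical.set_index(["subject_id", "session"]).sort_index()
    measures = [m for m in directions if m in clinical.columns]
    rows = []
    for subject in wide.index.get_level_values(0).unique():
        sub = wide.loc[subject]
        if not {"pre", "post"}.issubset(sub.index):
            continue
        for meas in measures:
            if meas not in mcid_table:
                continue
            delta = float(sub.loc["post", meas] - sub.loc["pre", meas])
            improvement = -delta if directions[meas] == "decrease" else delta
            rows.append(
                {
                    "subject_id": subject,
                    "measure": meas,
                    "delta": delta,
                    "improvement": improvement,
                    "mcid": mcid_table[meas],
                    "meets_mcid": improvement >= mcid_table[meas],
                }
            )
    flags = pd.DataFrame(rows)
    if flags.empty:
        return flags, pd.DataFrame(columns=["subject_id", "n_meaningful", "responder"])
    summary = (
        flags.groupby("subject_id")["meets_mcid"]
        .agg(n_meaningful="sum", responder="any")
        .reset_index()
    )
    return flags, summary


def nonparetic_band(values: Sequence[float]) -> tuple[float, float]:
    """Reference band: mean +/- 1 SD of the pooled non-paretic aggregates."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise UndefinedBandError("need >= 2 non-paretic observations")
    m, s = values.mean(), values.std(ddof=1)
    return float(m - s), float(m + s)


def within_band(value: float, band: tuple[float, float]) -> bool:
    """Whether a paretic value falls inside the non-paretic reference band
    (changes inside it are not considered noteworthy)."""
    lo, hi = band
    return bool(lo <= value <= hi)
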