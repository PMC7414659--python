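"""Validation batteries: analytic worked examples, parameter-recovery
batteries on synthetic trials, statistical-calibration simulations, and
end-to-end cohort checks.

Every function recomputes its quantities from scratch by running the
pipeline; nothing is cached or tabulated.  These are the computations
behind the package's reported validation numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import endpoint as ep
from .cohort import (
    CohortConfig,
    expected_spearman,
    linked_clinical_scores,
    simulate_cohort_movements,
)
from .extract import KIN_DIRECTIONS, PARAMETERS, aggregate_profiles, extract_profile
from .minjerk import PEAK_SPEED_FACTOR, min_jerk_profile
from .preprocess import speed_profile
from .published import CONSISTENT_EFFECT_ROWS, recompute_effect_magnitude
from .simulate import SimConfig, synth_joint_trial, synth_reach_trial
from .stats import bootstrap_paired_t, holm_adjust, paired_tests_table, spearman


# ------------------------------------------------- analytic worked examples

def effect_size_examples() -> dict[str, float]:
    """Baseline-SD effect sizes recomputed from the published pre/post
    group summaries (the rows whose printed value is consistent with its
    printed inputs)."""
    return {
        var: recompute_effect_magnitude(var) for var in CONSISTENT_EFFECT_ROWS
    }


def minjerk_suite(
    amplitude: float = 30.0, duration: float = 1.0, sample_rate: float = 1000.0
) -> dict[str, float]:
    """Endpoint parameters of a noiseless, unfiltered sampled minimum-jerk
    reach along a straight 3D chord."""
    t, pos, _ = min_jerk_profile(amplitude, duration, sample_rate)
    direction = np.array([0.4, 0.8, np.sqrt(1 - 0.4**2 - 0.8**2)])
    path = pos[:, None] * direction[None, :]
    speed = speed_profile(path, sample_rate)
    vmax, _ = ep.peak_velocity(speed)
    ldj = ep.log_dimensionless_jerk(speed, sample_rate)

    # rescaled movements sampled with the same number of points
    _, _, speed_a = min_jerk_profile(2 * amplitude, duration, sample_rate)
    ldj_a = ep.log_dimensionless_jerk(speed_a, sample_rate)
    # duration rescale at the same sample count (time axis dilated)
    _, _, speed_t = min_jerk_profile(amplitude, 2 * duration, sample_rate / 2)
    ldj_t = ep.log_dimensionless_jerk(speed_t, sample_rate / 2)
    _, _, speed_0 = min_jerk_profile(amplitude, duration, sample_rate)
    ldj_0 = ep.log_dimensionless_jerk(speed_0, sample_rate)

    return {
        "TpctVmax": ep.time_to_peak_pct(speed),
        "NVP": float(ep.count_velocity_peaks(speed, sample_rate)),
        "CurvI": ep.trajectory_directness(path, phase="outbound"),
        "Vmax": vmax,
        "Vmax_expected": PEAK_SPEED_FACTOR * amplitude / duration,
        "LDJ": ldj,
        "LDJ_amplitude_rescale_diff": abs(ldj_a - ldj_0),
        "LDJ_duration_rescale_diff": abs(ldj_t - ldj_0),
    }


# ------------------------------------------------------ parameter recovery

def nvp_recovery_battery(
    n_trials: int = 200, seed: int = 0
) -> tuple[float, pd.DataFrame]:
    """Noiseless trials with k = 1..4 outbound submovements: fraction
    where the counted velocity peaks equal the generated number."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_trials):
        k = 1 + i % 4
        cfg = SimConfig(
            n_submovements=k,
            movement_duration=float(rng.uniform(1.8, 3.0)),
            path_curvature_gain=float(rng.uniform(0.0, 0.2)),
            marker_noise_sd=0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        target = int(rng.integers(1, 13))
        rec, truth = synth_reach_trial(cfg, target_index=target)
        prof, _ = extract_profile(rec)
        rows.append(
            {"k": k, "true_nvp": truth.true_n_velocity_peaks, "nvp": prof.NVP}
        )
    table = pd.DataFrame(rows)
    rate = float((table["nvp"] == table["true_nvp"]).mean())
    return rate, table


def texc_recovery_battery(
    n_trials: int = 200, noise_sd: float = 0.05, seed: int = 0
) -> tuple[float, pd.DataFrame]:
    """Trunk-excursion recovery under marker noise: |TExc - truth| per
    trial, with injected trunk translations spanning the impaired range."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_trials):
        cfg = SimConfig(
            n_submovements=1 + i % 3,
            trunk_translation=float(rng.uniform(2.0, 12.0)),
            trunk_rotation=float(rng.uniform(0.0, 10.0)),
            marker_noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec, truth = synth_reach_trial(cfg, target_index=int(rng.integers(1, 13)))
        prof, _ = extract_profile(rec)
        rows.append(
            {"true": truth.true_trunk_excursion, "measured": prof.TExc}
        )
    table = pd.DataFrame(rows)
    table["abs_err"] = (table["measured"] - table["true"]).abs()
    return float(table["abs_err"].max()), table


def joint_recovery_battery(
    n_trials: int = 40, seed: int = 0
) -> tuple[float, pd.DataFrame]:
    """Noiseless recovery of *prescribed* joint excursions: trials animate
    the arm from prescribed minimum-jerk angle ramps (static trunk) and
    the battery reports the worst absolute error (deg) of the recovered
    ShFE / ShAA / ElFE ranges against the prescription."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_trials):
        which = i % 3
        exc = {
            "shfe_excursion": float(rng.uniform(10, 45)) if which == 0 else 0.0,
            "shaa_excursion": float(rng.uniform(5, 35)) if which == 1 else 0.0,
            "elfe_excursion": float(rng.uniform(10, 50)) if which == 2 else 0.0,
        }
        rec = synth_joint_trial(
            **exc, elfe_start=float(rng.uniform(30, 60)),
            duration=float(rng.uniform(1.5, 2.5)),
        )
        prof, _ = extract_profile(rec)
        for name, key, measured in (
            ("ShFE", "shfe_excursion", prof.ShFE),
            ("ShAA", "shaa_excursion", prof.ShAA),
            ("ElFE", "elfe_excursion", prof.ElFE),
        ):
            rows.append(
                {
                    "trial": i,
                    "angle": name,
                    "true": exc[key],
                    "measured": measured,
                }
            )
    table = pd.DataFrame(rows)
    table["abs_err"] = (table["measured"] - table["true"]).abs()
    return float(table["abs_err"].max()), table


def reach_roundtrip_battery(
    n_trials: int = 24, seed: int = 0
) -> pd.DataFrame:
    """Round trip simulator inverse kinematics -> marker-based recovery on
    noiseless reach trials spanning all 12 targets.

    Returns a per-trial table of absolute recovery errors for the three
    joint ranges, thorax rotation and torso excursion, together with the
    ShAA projection-conditioning number (small values flag reaches where
    the frontal-plane projection is intrinsically unstable)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_trials):
        cfg = SimConfig(
            n_submovements=1 + i % 2,
            trunk_translation=float(rng.uniform(0.0, 8.0)),
            trunk_rotation=float(rng.uniform(0.0, 8.0)),
            path_curvature_gain=float(rng.uniform(0.0, 0.10)),
            marker_noise_sd=0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec, truth = synth_reach_trial(cfg, target_index=1 + i % 12)
        prof, _ = extract_profile(rec)
        rows.append(
            {
                "trial": i,
                "target": 1 + i % 12,
                "conditioning": truth.shaa_conditioning,
                "err_ShFE": abs(prof.ShFE - truth.true_joint_ranges["ShFE"]),
                "err_ShAA": abs(prof.ShAA - truth.true_joint_ranges["ShAA"]),
                "err_ElFE": abs(prof.ElFE - truth.true_joint_ranges["ElFE"]),
                "err_Th": abs(prof.Th - truth.true_thorax_rotation_range),
                "err_TExc": abs(prof.TExc - truth.true_trunk_excursion),
            }
        )
    return pd.DataFrame(rows)


# -------------------------------------------------- statistical calibration

def bootstrap_type1_error(
    n_replicates: int = 1000, n: int = 10, B: int = 1000,
    alpha: float = 0.05, seed: int = 0,
) -> float:
    """Rejection rate of the bootstrap paired test under a Gaussian null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        pre = rng.normal(size=n)
        post = pre + rng.normal(size=n)  # paired null: no systematic change
        res = bootstrap_paired_t(pre, post, B=B, seed=rng)
        if res.p_boot < alpha:
            rejections += 1
    return rejections / n_replicates


def _spearman_grid_pvalues(
    x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Two-sided Spearman p-values for every column pair (x_j, y_k),
    from the same permutation null the stats module uses."""
    from .stats import spearman_null_pvalue

    n = x.shape[0]
    rx = sps.rankdata(x, axis=0)
    ry = sps.rankdata(y, axis=0)
    rx = (rx - rx.mean(axis=0)) / rx.std(axis=0)
    ry = (ry - ry.mean(axis=0)) / ry.std(axis=0)
    r = rx.T @ ry / n
    return spearman_null_pvalue(r, n)


def holm_familywise_error(
    n_replicates: int = 1000, n: int = 20,
    n_kin: int = 11, n_clin: int = 3,
    alpha: float = 0.05, seed: int = 0,
) -> float:
    """Family-wise error of the Holm-adjusted correlation grid under
    independence (grid sized like the cross-sectional panel)."""
    rng = np.random.default_rng(seed)
    fw = 0
    for _ in range(n_replicates):
        x = rng.normal(size=(n, n_kin))
        y = rng.normal(size=(n, n_clin))
        p = _spearman_grid_pvalues(x, y).ravel()
        if (holm_adjust(p) < alpha).any():
            fw += 1
    return fw / n_replicates


# --------------------------------------------------- end-to-end cohorts

#: scaled-down per-session design used in the replicated cohort batteries
REPLICATE_MOVEMENTS = 12


def null_cohort_battery(
    n_replicates: int = 100,
    n_subjects: int = 10,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, list[int]]:
    """Cohorts with zero injected pre->post kinematic change, run through
    the full pipeline (simulate -> extract -> aggregate -> bootstrap tests
    with Holm): fraction of replicates with *no* Holm-significant group
    kinematic change."""
    rng = np.random.default_rng(seed)
    n_sig = []
    for _ in range(n_replicates):
        cfg = CohortConfig(
            n_subjects=n_subjects,
            movements_per_session=REPLICATE_MOVEMENTS,
            improvement=0.0,
        )
        movements, _ = simulate_cohort_movements(
            cfg, seed=int(rng.integers(0, 2**31 - 1)), arms=("paretic",)
        )
        agg = aggregate_profiles(movements)
        wide = agg.pivot(
            index="subject_id", columns="session", values=list(PARAMETERS)
        )
        tests = paired_tests_table(
            {
                p: (
                    wide[(p, "pre")].to_numpy(dtype=float),
                    wide[(p, "post")].to_numpy(dtype=float),
                )
                for p in PARAMETERS
            },
            KIN_DIRECTIONS,
            B=B,
            seed=int(rng.integers(0, 2**31 - 1)),
            alpha=alpha,
        )
        n_sig.append(int(tests["significant_after_holm"].sum()))
    clean = float(np.mean([s == 0 for s in n_sig]))
    return clean, n_sig


def linked_cohort_battery(
    n_replicates: int = 30,
    n_subjects: int = 20,
    movements: int = 4,
    target_rho: float = 0.7167,
    seed: int = 0,
) -> tuple[float, float, list[float]]:
    """Cohorts with a generated monotone link between movement smoothness
    (LDJ) and the motor-impairment score (FMA-UE): mean recovered
    cross-sectional Spearman correlation versus its generative target."""
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_replicates):
        cfg = CohortConfig(
            n_subjects=n_subjects, movements_per_session=movements
        )
        mov, _ = simulate_cohort_movements(
            cfg, seed=int(rng.integers(0, 2**31 - 1)), arms=("paretic",)
        )
        agg = aggregate_profiles(mov)
        clinical = linked_clinical_scores(
            agg, driver="LDJ", target_rho=target_rho,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        merged = agg.merge(clinical, on=["subject_id", "session"])
        r, _ = spearman(merged["LDJ"], merged["FMA_UE"])
        values.append(r)
    return float(np.mean(values)), expected_spearman(target_rho), values
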