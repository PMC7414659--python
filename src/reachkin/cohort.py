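"""Synthetic cohorts: study-shaped sets of reach trials with ground truth.

Emulates the study design: N subjects, two sessions (pre/post), both arms,
a fixed randomized target order shared across sessions, and per-movement
variability (duration jitter, submovement-schedule jitter, marker noise).
Per-subject impairment is a latent severity in [0, 1] that coherently
drives submovement count, movement slowing, path curvature and trunk
compensation.

Clinical scores can be generated as noisy monotone functions of a
subject's measured kinematics (``linked_clinical_scores``), giving a known
generative rank-correlation target for correlation-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .extract import ExtractionConfig, extract_profile, profiles_to_frame
from .minjerk import staircase_schedule
from .simulate import SimConfig, TrialRecording, synth_reach_trial
from .stats import CLINICAL_DIRECTIONS, PROXIMAL_MEASURES


@dataclass(frozen=True)
class CohortConfig:
    """Design and generative ranges of a synthetic cohort."""

    n_subjects: int = 10
    movements_per_session: int = 36  # 12 targets x repetitions
    sample_rate: float = 120.0
    marker_noise_sd: float = 0.05
    # paretic-arm severity ranges (linear in the latent severity)
    submovements_range: tuple[int, int] = (2, 4)
    duration_range_s: tuple[float, float] = (1.8, 3.2)
    curvature_range: tuple[float, float] = (0.05, 0.25)
    trunk_translation_range_cm: tuple[float, float] = (2.0, 14.0)
    trunk_rotation_range_deg: tuple[float, float] = (2.0, 10.0)
    # non-paretic arm: fast, smooth, little compensation
    nonparetic_duration_s: float = 1.4
    nonparetic_curvature: float = 0.04
    # pre -> post drop of the latent severity (0 = null cohort)
    improvement: float = 0.0
    # within-subject, per-movement jitter
    duration_jitter: float = 0.08
    amplitude_jitter: float = 0.15


@dataclass(frozen=True)
class SubjectTruth:
    """Per-subject generating parameters (paretic arm, pre-intervention)."""

    subject_id: str
    severity: float
    n_submovements: int
    duration_s: float
    curvature: float
    trunk_translation: float
    trunk_rotation: float
    paretic_side: str


def _lerp(rng_pair: tuple[float, float], x: float) -> float:
    lo, hi = rng_pair
    return lo + (hi - lo) * x


def draw_subjects(
    config: CohortConfig, rng: np.random.Generator
) -> list[SubjectTruth]:
    """Draw per-subject severities (0 = mild, 1 = severe) and map them to
    generative parameters; more severe subjects make more submovements,
    move slower, curve more and compensate more with the trunk."""
    subjects = []
    lo_k, hi_k = config.submovements_range
    for i in range(config.n_subjects):
        sev = float(rng.uniform())
        subjects.append(
            SubjectTruth(
                subject_id=f"S{i + 1:02d}",
                severity=sev,
                n_submovements=max(1, int(round(lo_k + (hi_k - lo_k) * sev))),
                duration_s=_lerp(config.duration_range_s, sev),
                curvature=_lerp(config.curvature_range, sev),
                trunk_translation=_lerp(config.trunk_translation_range_cm, sev),
                trunk_rotation=_lerp(config.trunk_rotation_range_deg, sev),
                paretic_side="right" if rng.uniform() < 0.5 else "left",
            )
        )
    return subjects


def _target_order(config: CohortConfig, rng: np.random.Generator) -> list[int]:
    """Fixed randomized target order, shared across sessions and arms."""
    reps = int(np.ceil(config.movements_per_session / 12))
    order: list[int] = []
    for _ in range(reps):
        order.extend(rng.permutation(np.arange(1, 13)).tolist())
    return order[: config.movements_per_session]


def _jittered_schedule(
    k: int, rng: np.random.Generator, amplitude_jitter: float
) -> list[tuple[float, float, float]]:
    base = staircase_schedule(k)
    amps = np.array([a for _, a, _ in base])
    amps = amps * np.exp(rng.normal(0.0, amplitude_jitter, size=k))
    amps = amps / amps.sum()
    return [(onset, float(a), dur) for (onset, _, dur), a in zip(base, amps)]


def iter_cohort_trials(
    config: CohortConfig,
    seed: int = 0,
    arms: tuple[str, ...] = ("paretic", "nonparetic"),
) -> Iterator[TrialRecording]:
    """Deterministic stream of cohort trial recordings."""
    rng = np.random.default_rng(seed)
    subjects = draw_subjects(config, rng)
    order = _target_order(config, rng)
    for subj in subjects:
        for session in ("pre", "post"):
            sev = subj.severity
            if session == "post":
                sev = max(0.0, sev - config.improvement)
            for arm in arms:
                side = subj.paretic_side if arm == "paretic" else (
                    "left" if subj.paretic_side == "right" else "right"
                )
                for target in order:
                    trial_seed = int(rng.integers(0, 2**31 - 1))
                    trng = np.random.default_rng(trial_seed)
                    if arm == "paretic":
                        lo_k, hi_k = config.submovements_range
                        k = max(1, int(round(lo_k + (hi_k - lo_k) * sev)))
                        dur = _lerp(config.duration_range_s, sev)
                        curv = _lerp(config.curvature_range, sev)
                        trunk_t = _lerp(config.trunk_translation_range_cm, sev)
                        trunk_r = _lerp(config.trunk_rotation_range_deg, sev)
                    else:
                        k = 1
                        dur = config.nonparetic_duration_s
                        curv = config.nonparetic_curvature
                        trunk_t, trunk_r = 0.5, 0.5
                    dur *= float(np.exp(trng.normal(0.0, config.duration_jitter)))
                    sim = SimConfig(
                        movement_duration=dur,
                        submovement_schedule=_jittered_schedule(
                            k, trng, config.amplitude_jitter
                        ),
                        path_curvature_gain=curv,
                        trunk_translation=trunk_t,
                        trunk_rotation=trunk_r,
                        marker_noise_sd=config.marker_noise_sd,
                        sample_rate=config.sample_rate,
                        seed=trial_seed,
                    )
                    rec, _ = synth_reach_trial(
                        sim,
                        target_index=target,
                        subject_id=subj.subject_id,
                        session=session,
                        arm=arm,
                        side=side,
                        compute_ground_truth=False,
                    )
                    yield rec


def simulate_cohort_movements(
    config: CohortConfig,
    seed: int = 0,
    arms: tuple[str, ...] = ("paretic", "nonparetic"),
    extraction: Optional[ExtractionConfig] = None,
) -> tuple[pd.DataFrame, list[SubjectTruth]]:
    """Simulate a cohort and run the extraction pipeline on every trial.

    Returns the tidy per-movement parameter table and the per-subject
    generating truths.  Fully deterministic in ``seed``.
    """
    extraction = extraction or ExtractionConfig()
    subjects = draw_subjects(config, np.random.default_rng(seed))
    profiles = [
        extract_profile(rec, extraction)[0]
        for rec in iter_cohort_trials(config, seed, arms)
    ]
    return profiles_to_frame(profiles), subjects


def linked_clinical_scores(
    kin_agg: pd.DataFrame,
    driver: str = "LDJ",
    target_rho: float = 0.7167,
    seed: int = 0,
    arm: str = "paretic",
) -> pd.DataFrame:
    """Clinical scores generated as noisy monotone functions of a measured
    kinematic aggregate.

    The driver parameter's normal scores are mixed with independent
    Gaussian noise at correlation ``target_rho`` and mapped monotonically
    onto each clinical scale; for bivariate-normal latents the expected
    Spearman correlation is (6/pi) asin(rho/2), so the default
    rho = 0.7167 targets r_s = 0.70.  Smoother movement (larger LDJ) maps
    to better scores, direction-aware per measure.
    """
    rng = np.random.default_rng(seed)
    rows = (
        kin_agg[kin_agg["arm"] == arm] if "arm" in kin_agg.columns else kin_agg
    ).reset_index(drop=True)
    vals = rows[driver].to_numpy(dtype=float)
    n = vals.size
    ranks = pd.Series(vals).rank(method="average").to_numpy()
    z = ndtri((ranks - 0.5) / n)  # normal scores of the driver
    out = rows[["subject_id", "session"]].copy()
    scales = {
        "FMA_UE": (21.0, 50.0),
        "WMFT_FAS": (1.0, 4.5),
        "WMFT_Time": (8.0, 70.0),
        "MAL_AOU": (0.3, 3.5),
        "MAL_QOM": (0.3, 3.5),
    }
    for meas, (lo, hi) in scales.items():
        noise = rng.normal(size=n)
        latent = target_rho * z + np.sqrt(1.0 - target_rho**2) * noise
        if CLINICAL_DIRECTIONS[meas] == "decrease":
            latent = -latent
        out[meas] = lo + (hi - lo) * ndtr(latent)
        if meas in PROXIMAL_MEASURES:
            u_prox = ndtr(latent + 0.3 * rng.normal(size=n))
            out[meas + "_prox"] = lo + (hi - lo) * u_prox
    return out


def expected_spearman(rho: float) -> float:
    """Expected Spearman correlation of a bivariate normal with Pearson
    correlation ``rho``: (6/pi) asin(rho/2)."""
    return float(6.0 / np.pi * np.arcsin(rho / 2.0))
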