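"""Per-trial extraction of the eleven kinematic parameters.

Chains filtering -> endpoint speed -> segmentation -> endpoint parameters
(MT, CurvI, Vmax, TpctVmax, NVP, LDJ) and joint/trunk parameters (ShFE,
ShAA, ElFE, Th, TExc) for one recorded reach, and aggregates per-movement
rows to subject-session-arm summaries.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import endpoint as ep
from . import joints
from .markers import endpoint_label
from .preprocess import ReachSegment, detect_reach_bounds, lowpass_filter, speed_profile
from .simulate import TrialRecording, mirror_markers

#: canonical parameter order (matches the reported construct table)
PARAMETERS = (
    "MT", "CurvI", "Vmax", "TpctVmax", "NVP", "LDJ",
    "ShFE", "ShAA", "ElFE", "Th", "TExc",
)

#: parameters where a *decrease* is an improvement
DECREASE_IS_BETTER = ("MT", "CurvI", "NVP", "Th", "TExc")

KIN_DIRECTIONS = {p: ("decrease" if p in DECREASE_IS_BETTER else "increase")
                  for p in PARAMETERS}


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable extraction settings (all surfaced in reports)."""

    cutoff_hz: float = 6.0
    filter_order: int = 4
    threshold_fraction: float = 0.05
    phase: str = "full_cycle"
    nvp_prominence: float = 0.05
    nvp_min_separation_s: float = 0.1
    aggregate_stat: str = "mean"  # or "median"


@dataclass(frozen=True)
class KinematicProfile:
    """The eleven kinematic parameters of one analyzed movement."""

    subject_id: str
    session: str
    arm: str
    target_index: int
    MT: float
    CurvI: float
    Vmax: float
    TpctVmax: float
    NVP: int
    LDJ: float
    ShFE: float
    ShAA: float
    ElFE: float
    Th: float
    TExc: float

    def as_dict(self) -> dict:
        return asdict(self)


def extract_profile(
    recording: TrialRecording,
    config: ExtractionConfig | None = None,
    target_position: np.ndarray | None = None,
) -> tuple[KinematicProfile, ReachSegment]:
    """Compute the eleven parameters for one trial.

    Left-side recordings are mirrored to the canonical right-arm
    convention first; all markers are low-pass filtered before any
    differentiation.
    """
    cfg = config or ExtractionConfig()
    markers = recording.markers
    if recording.side == "left":
        markers = mirror_markers(markers)
        if target_position is not None:
            target_position = np.asarray(target_position, dtype=float).copy()
            target_position[0] = -target_position[0]

    # filter the markers the analysis uses, in one stacked call
    needed = (
        "C7", "T10", "CLAV", "STRN", "RSHO", "LSHO",
        "RELB", "RWRA", "RWRB", endpoint_label("right"),
    )
    stacked = np.concatenate(
        [joints._fill_gaps(markers[label], label) for label in needed], axis=1
    )
    smooth = lowpass_filter(
        stacked, cfg.cutoff_hz, recording.sample_rate, cfg.filter_order
    )
    filt = {
        label: smooth[:, 3 * i : 3 * i + 3] for i, label in enumerate(needed)
    }

    end_label = endpoint_label("right")
    endpoint_pos = filt[end_label]
    speed = speed_profile(endpoint_pos, recording.sample_rate)
    segment = detect_reach_bounds(
        speed,
        threshold_fraction=cfg.threshold_fraction,
        phase=cfg.phase,
        positions=endpoint_pos if cfg.phase == "outbound" else None,
        target=target_position if cfg.phase == "outbound" else None,
    )
    sl = segment.slice()
    seg_speed = speed[sl]
    seg_path = endpoint_pos[sl]

    mt = ep.movement_time(segment, recording.sample_rate)
    curvi = ep.trajectory_directness(seg_path, phase=cfg.phase)
    vmax, _ = ep.peak_velocity(seg_speed)
    tpct = ep.time_to_peak_pct(seg_speed)
    nvp = ep.count_velocity_peaks(
        seg_speed,
        recording.sample_rate,
        cfg.nvp_prominence,
        cfg.nvp_min_separation_s,
    )
    ldj = ep.log_dimensionless_jerk(seg_speed, recording.sample_rate)

    xt, yt, zt = joints.thorax_frame(
        filt["C7"][sl], filt["T10"][sl], filt["CLAV"][sl], filt["STRN"][sl],
        filt["RSHO"][sl], filt["LSHO"][sl],
    )
    humerus = filt["RELB"][sl] - filt["RSHO"][sl]
    fe, aa = joints.shoulder_angles(humerus, xt, yt, zt)
    wrist_mid = 0.5 * (filt["RWRA"][sl] + filt["RWRB"][sl])
    elbow_flex = joints.elbow_flexion_angle(
        filt["RSHO"][sl], filt["RELB"][sl], wrist_mid
    )
    th_series = joints.thorax_rotation(filt["RSHO"][sl], filt["LSHO"][sl], zt[0])

    profile = KinematicProfile(
        subject_id=recording.subject_id,
        session=recording.session,
        arm=recording.arm,
        target_index=recording.target_index,
        MT=mt,
        CurvI=curvi,
        Vmax=vmax,
        TpctVmax=tpct,
        NVP=nvp,
        LDJ=ldj,
        ShFE=joints.angle_range(fe),
        ShAA=joints.angle_range(aa),
        ElFE=joints.angle_range(elbow_flex),
        Th=joints.angle_range(th_series),
        TExc=joints.torso_excursion(filt["CLAV"][sl]),
    )
    return profile, segment


def profiles_to_frame(profiles: list[KinematicProfile]) -> pd.DataFrame:
    """Tidy per-movement parameter table."""
    return pd.DataFrame([p.as_dict() for p in profiles])


def aggregate_profiles(
    movements: pd.DataFrame, statistic: str = "mean"
) -> pd.DataFrame:
    """Per subject-session-arm aggregate of the per-movement table."""
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown aggregation statistic {statistic!r}")
    grouped = movements.groupby(
        ["subject_id", "session", "arm"], as_index=False
    )[list(PARAMETERS)]
    return grouped.mean() if statistic == "mean" else grouped.median()
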