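"""Synthetic reach-to-target trial generator.

Generates motion-capture-like marker trajectories for a seated subject
reaching from a start target to one of twelve clock targets on a vertical
panel and back, with full ground truth for every downstream kinematic
parameter.  The generative model:

* The endpoint (second metacarpal head) follows a spatial path from the
  start position to the target; lateral curvature is an out-of-chord bump
  with a half-sine profile scaled by ``path_curvature_gain``.
* Progress along the path is driven by minimum-jerk submovements: an
  outbound composite of ``n_submovements`` bells, a hold at the target,
  and a single minimum-jerk return.
* Compensatory trunk movement is a translation of the trunk markers along
  the (horizontal) reach direction plus an axial rotation of the shoulder
  line about the vertical through the mid-acromion point, both time-locked
  to path progress.
* Arm markers are placed by a two-link inverse-kinematic chain
  (upper arm: acromion -> lateral epicondyle; forearm+hand: epicondyle ->
  endpoint) with an elbow-below-the-reach-axis swivel convention.
* i.i.d. zero-mean Gaussian noise (sd ``marker_noise_sd``) is added per
  marker, frame and axis after ground truth is extracted.

Output is reproducible: identical (config, geometry, target) give
byte-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import quad

from .errors import InfeasibleConfigurationError, InvalidArgumentError
from .geometry import PanelGeometry
from .markers import SIDE_MARKERS, TRUNK_MARKERS, endpoint_label
from .minjerk import (
    Schedule,
    composed_position_tau,
    composed_speed_tau,
    min_jerk_position_tau,
    min_jerk_speed_tau,
    staircase_schedule,
    validate_schedule,
)

Z_HAT = np.array([0.0, 0.0, 1.0])

#: markers rigidly attached to the trunk
_TRUNK_RIGID = TRUNK_MARKERS + ("RSHO", "LSHO")


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of one synthetic reach trial.

    Lengths in cm, durations in s, ``trunk_rotation`` in degrees.
    ``arm_length`` is the shoulder-to-fist distance (fist closed), i.e. the
    length of the two-link chain: upper arm + forearm + hand.
    """

    arm_length: float = 65.0
    forearm_length: float = 26.0
    hand_length: float = 9.0
    movement_duration: float = 2.0
    hold_s: float = 0.2
    n_submovements: int = 1
    submovement_schedule: Optional[Schedule] = None
    path_curvature_gain: float = 0.0
    trunk_translation: float = 0.0
    trunk_rotation: float = 0.0
    marker_noise_sd: float = 0.0
    sample_rate: float = 120.0
    pad_s: float = 0.3
    panel_distance: Optional[float] = None
    panel_radius: float = 20.0
    shoulder_height: float = 100.0
    shoulder_width: float = 36.0
    seed: int = 0
    #: relative speed threshold defining the ground-truth movement bounds
    truth_threshold: float = 0.05

    def __post_init__(self) -> None:
        if min(self.arm_length, self.forearm_length, self.hand_length) <= 0:
            raise InvalidArgumentError("segment lengths must be positive")
        if self.forearm_length + self.hand_length >= self.arm_length:
            raise InvalidArgumentError(
                "forearm + hand must be shorter than the whole arm"
            )
        if self.sample_rate <= 0:
            raise InvalidArgumentError("sample_rate must be positive")
        if self.movement_duration <= self.hold_s:
            raise InvalidArgumentError(
                "movement_duration must exceed the target hold"
            )
        if self.n_submovements < 1:
            raise InvalidArgumentError("n_submovements must be >= 1")
        if self.path_curvature_gain < 0 or self.marker_noise_sd < 0:
            raise InvalidArgumentError("gains and noise sd must be >= 0")
        if self.trunk_translation < 0 or self.trunk_rotation < 0:
            raise InvalidArgumentError("trunk parameters must be >= 0")
        if self.submovement_schedule is not None:
            validate_schedule(self.submovement_schedule)

    @property
    def upper_arm_length(self) -> float:
        return self.arm_length - self.forearm_length - self.hand_length

    @property
    def reach_length(self) -> float:
        """Length of the simulated two-link chain (upper arm + forearm+hand)."""
        return self.arm_length

    def schedule(self) -> Schedule:
        if self.submovement_schedule is not None:
            return self.submovement_schedule
        return staircase_schedule(self.n_submovements)

    def default_panel_distance(self) -> float:
        """Panel distance such that the farthest target is reachable with
        the arm alone (trunk compensation is injected, never forced)."""
        if self.panel_distance is not None:
            return self.panel_distance
        reach = self.arm_length - 1.0  # 1 cm slack at full extension
        if reach <= self.panel_radius:
            raise InfeasibleConfigurationError(
                "arm too short for the panel radius"
            )
        return float(np.sqrt(reach**2 - self.panel_radius**2))


@dataclass(frozen=True)
class SimGroundTruth:
    """Generating quantities of one synthetic trial, for recovery tests.

    ``true_MT`` is the duration of the movement as defined by the
    measurement convention — the span between the first and last crossings
    of ``truth_threshold`` x peak speed of the *noiseless, continuous*
    endpoint speed profile.  ``true_cycle_duration`` is the commanded
    out-hold-return duration.
    """

    true_MT: float
    true_cycle_duration: float
    movement_start_time: float
    movement_end_time: float
    true_path_length: float
    true_straight_distance: float
    true_curvature_index: float
    true_peak_speed: float
    true_n_velocity_peaks: int
    true_trunk_excursion: float
    true_thorax_rotation_range: float
    true_joint_ranges: dict[str, float] = field(default_factory=dict)
    #: min in-plane fraction of the humerus in the frontal plane over the
    #: movement; small values mean the ShAA projection is ill-conditioned
    shaa_conditioning: float = 1.0


@dataclass
class TrialRecording:
    """Labeled marker trajectories for one reach trial."""

    subject_id: str
    session: str  # {pre, post}
    arm: str  # {paretic, nonparetic}
    side: str  # {right, left}
    target_index: int
    sample_rate: float
    times: np.ndarray  # (n,)
    markers: dict[str, np.ndarray]  # label -> (n, 3) cm

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def endpoint(self) -> np.ndarray:
        return self.markers[endpoint_label(self.side)]


def _rest_skeleton(cfg: SimConfig) -> dict[str, np.ndarray]:
    """Rest positions (right arm tested): tested acromion at the origin of
    x, y; trunk midline toward -x."""
    h = cfg.shoulder_height
    rsho = np.array([0.0, 0.0, h])
    lsho = np.array([-cfg.shoulder_width, 0.0, h])
    m0 = 0.5 * (rsho + lsho)
    return {
        "RSHO": rsho,
        "LSHO": lsho,
        "C7": m0 + np.array([0.0, -6.0, 3.0]),
        "CLAV": m0 + np.array([0.0, 4.0, 1.0]),
        "T10": m0 + np.array([0.0, -8.0, -14.0]),
        "STRN": m0 + np.array([0.0, 6.0, -12.0]),
    }


def _progress_profile(
    t: np.ndarray, cfg: SimConfig, schedule: Schedule
) -> tuple[np.ndarray, np.ndarray]:
    """Path progress w(t) in [0, 1] (0 = start, 1 = target) and its time
    derivative, over the padded trial timeline."""
    t_out = 0.5 * (cfg.movement_duration - cfg.hold_s)
    t_ret = cfg.movement_duration - cfg.hold_s - t_out
    t0 = cfg.pad_s
    t1 = t0 + t_out
    t2 = t1 + cfg.hold_s
    t3 = t2 + t_ret

    w = np.zeros_like(t)
    dw = np.zeros_like(t)

    out = (t >= t0) & (t < t1)
    tau = (t[out] - t0) / t_out
    w[out] = composed_position_tau(schedule, tau)
    dw[out] = composed_speed_tau(schedule, tau) / t_out

    hold = (t >= t1) & (t < t2)
    w[hold] = 1.0

    ret = (t >= t2) & (t <= t3)
    tau_r = (t[ret] - t2) / t_ret
    w[ret] = 1.0 - min_jerk_position_tau(tau_r)
    dw[ret] = -min_jerk_speed_tau(tau_r) / t_ret
    return w, dw


def _path(
    start: np.ndarray, target: np.ndarray, gain: float
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Spatial path P(w) = start + w*chord + gain*L*sin(pi w)*normal."""
    chord = target - start
    length = float(np.linalg.norm(chord))
    if length < 1e-9:
        raise InvalidArgumentError("start and target coincide")
    c_hat = chord / length
    n = np.cross(c_hat, Z_HAT)
    if np.linalg.norm(n) < 1e-6:  # chord vertical: bump out laterally
        n = np.cross(c_hat, np.array([1.0, 0.0, 0.0]))
    n_hat = n / np.linalg.norm(n)
    return chord, n_hat, length, c_hat


def _path_points(
    w: np.ndarray, start: np.ndarray, chord: np.ndarray, n_hat: np.ndarray,
    length: float, gain: float,
) -> np.ndarray:
    return (
        start[None, :]
        + w[:, None] * chord[None, :]
        + (gain * length * np.sin(np.pi * w))[:, None] * n_hat[None, :]
    )


def _path_speed(
    w: np.ndarray, dw: np.ndarray, length: float, gain: float
) -> np.ndarray:
    """|dP/dt| = |dP/dw| * |dw/dt| with |dP/dw| in closed form."""
    dpdw = length * np.sqrt(1.0 + (gain * np.pi * np.cos(np.pi * w)) ** 2)
    return dpdw * np.abs(dw)


def outbound_path_length(length: float, gain: float) -> float:
    """Arc length of one path traversal, by quadrature."""
    val, _ = quad(
        lambda w: np.sqrt(1.0 + (gain * np.pi * np.cos(np.pi * w)) ** 2),
        0.0,
        1.0,
        limit=200,
    )
    return length * float(val)


def _trunk_positions(
    rest: dict[str, np.ndarray],
    w: np.ndarray,
    cfg: SimConfig,
    reach_dir: np.ndarray,
) -> dict[str, np.ndarray]:
    """Trunk markers under translation along the reach direction plus axial
    rotation about the vertical through the (translated) mid-acromion."""
    m0 = 0.5 * (rest["RSHO"] + rest["LSHO"])
    theta = np.deg2rad(cfg.trunk_rotation) * w
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    shift = cfg.trunk_translation * w[:, None] * reach_dir[None, :]
    out: dict[str, np.ndarray] = {}
    for label in _TRUNK_RIGID:
        rel = rest[label] - m0
        rot = np.empty((w.size, 3))
        rot[:, 0] = cos_t * rel[0] - sin_t * rel[1]
        rot[:, 1] = sin_t * rel[0] + cos_t * rel[1]
        rot[:, 2] = rel[2]
        out[label] = m0[None, :] + shift + rot
    return out


def _ik_elbow(
    shoulder: np.ndarray, endpoint: np.ndarray, upper: float, lower: float
) -> np.ndarray:
    """Elbow positions of the two-link chain, elbow swiveled toward the
    component of 'down' perpendicular to the shoulder->endpoint axis."""
    vec = endpoint - shoulder
    d = np.linalg.norm(vec, axis=1)
    if np.any(d > upper + lower - 1e-9) or np.any(d < abs(upper - lower) + 1e-9):
        raise InfeasibleConfigurationError(
            "endpoint outside the reachable annulus of the arm chain "
            f"(distance range {d.min():.2f}..{d.max():.2f} cm, "
            f"links {upper:.1f} + {lower:.1f} cm)"
        )
    a_hat = vec / d[:, None]
    down = -Z_HAT
    r = down[None, :] - (a_hat @ down)[:, None] * a_hat
    r_norm = np.linalg.norm(r, axis=1)
    # near-vertical reach axis: swivel toward -y (toward the body) instead
    bad = r_norm < 1e-8
    if np.any(bad):
        alt = np.array([0.0, -1.0, 0.0])
        r[bad] = alt[None, :] - (a_hat[bad] @ alt)[:, None] * a_hat[bad]
        r_norm = np.linalg.norm(r, axis=1)
    r_hat = r / r_norm[:, None]
    cos_a = (upper**2 + d**2 - lower**2) / (2.0 * upper * d)
    cos_a = np.clip(cos_a, -1.0, 1.0)
    sin_a = np.sqrt(1.0 - cos_a**2)
    return shoulder + upper * (cos_a[:, None] * a_hat + sin_a[:, None] * r_hat)


def _arm_markers(
    shoulder: np.ndarray,
    elbow: np.ndarray,
    endpoint: np.ndarray,
    cfg: SimConfig,
    prefix: str,
) -> dict[str, np.ndarray]:
    """Surface markers of the tested arm from the joint-center chain."""
    lower_vec = endpoint - elbow
    lower_len = np.linalg.norm(lower_vec, axis=1)[:, None]
    f_hat = lower_vec / lower_len
    wrist = elbow + (cfg.forearm_length / (cfg.forearm_length + cfg.hand_length)) * lower_vec
    perp = np.cross(f_hat, Z_HAT)
    pn = np.linalg.norm(perp, axis=1)
    fallback = pn < 1e-8
    if np.any(fallback):
        perp[fallback] = np.cross(f_hat[fallback], np.array([0.0, 1.0, 0.0]))
        pn = np.linalg.norm(perp, axis=1)
    perp /= pn[:, None]
    return {
        prefix + "SHO": shoulder,
        prefix + "UPA": 0.5 * (shoulder + elbow),
        prefix + "ELB": elbow,
        prefix + "FRA": 0.5 * (elbow + wrist),
        prefix + "WRA": wrist + 1.25 * perp,
        prefix + "WRB": wrist - 1.25 * perp,
        prefix + "FIN1": endpoint - 2.0 * perp,
        prefix + "FIN2": endpoint,
    }


def _hanging_arm(shoulder: np.ndarray, cfg: SimConfig, prefix: str) -> dict[str, np.ndarray]:
    """Non-tested arm hanging straight down from its (moving) acromion."""
    u, fh = cfg.upper_arm_length, cfg.forearm_length + cfg.hand_length
    down = np.array([0.0, 0.0, -1.0])
    elbow = shoulder + u * down[None, :]
    hand = elbow + fh * down[None, :]
    wrist = elbow + (cfg.forearm_length / fh) * (hand - elbow)
    side = np.array([1.0, 0.0, 0.0]) * (1.0 if prefix == "R" else -1.0)
    return {
        prefix + "SHO": shoulder,
        prefix + "UPA": 0.5 * (shoulder + elbow),
        prefix + "ELB": elbow,
        prefix + "FRA": 0.5 * (elbow + wrist),
        prefix + "WRA": wrist + 1.25 * side[None, :],
        prefix + "WRB": wrist - 1.25 * side[None, :],
        prefix + "FIN1": hand - 2.0 * side[None, :],
        prefix + "FIN2": hand,
    }


def _threshold_crossings(
    t: np.ndarray, v: np.ndarray, frac: float
) -> tuple[float, float]:
    """First and last crossing times of frac * max(v), linearly refined."""
    vmax = v.max()
    thr = frac * vmax
    above = v >= thr
    idx = np.flatnonzero(above)
    i0, i1 = idx[0], idx[-1]

    def _interp(ia: int, ib: int) -> float:
        if v[ib] == v[ia]:
            return float(t[ib])
        lam = (thr - v[ia]) / (v[ib] - v[ia])
        return float(t[ia] + lam * (t[ib] - t[ia]))

    t_start = _interp(i0 - 1, i0) if i0 > 0 else float(t[0])
    t_end = _interp(i1 + 1, i1) if i1 < t.size - 1 else float(t[-1])
    return t_start, t_end


def _shoulder_angles_truth(
    humerus: np.ndarray, theta: np.ndarray, gimbal_tol: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Flexion/extension and abduction/adduction series of the humerus
    vector in the (commanded) thorax frame; degrees.  Gimbal-adjacent
    frames are NaN, mirroring the analyzer's exclusion rule."""
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # thorax axes under commanded axial rotation: xt = Rz(theta) x, yt = Rz y
    hx = cos_t * humerus[:, 0] + sin_t * humerus[:, 1]
    hy = -sin_t * humerus[:, 0] + cos_t * humerus[:, 1]
    hz = humerus[:, 2]
    scale = np.linalg.norm(humerus, axis=1)
    fe = np.degrees(np.arctan2(hy, -hz))
    aa = np.degrees(np.arctan2(hx, -hz))
    fe[np.hypot(hy, hz) < gimbal_tol * scale] = np.nan
    aa[np.hypot(hx, hz) < gimbal_tol * scale] = np.nan
    return fe, aa


def synth_reach_trial(
    config: SimConfig,
    geometry: Optional[PanelGeometry] = None,
    target_index: int = 12,
    subject_id: str = "S01",
    session: str = "pre",
    arm: str = "paretic",
    side: str = "right",
    compute_ground_truth: bool = True,
) -> tuple[TrialRecording, Optional[SimGroundTruth]]:
    """Simulate one out-and-back reach; returns the recording and, unless
    disabled, its ground truth."""
    if target_index not in range(1, 13):
        raise InvalidArgumentError(
            f"target_index must be 1..12, got {target_index!r}"
        )
    cfg = config
    rest = _rest_skeleton(cfg)
    if geometry is None:
        geometry = PanelGeometry.from_subject(
            rest["RSHO"],
            cfg.default_panel_distance(),
            cfg.forearm_length,
            cfg.panel_radius,
        )
    start = geometry.start_position
    target = geometry.target(target_index)
    chord, n_hat, length, _ = _path(start, target, cfg.path_curvature_gain)

    total = cfg.movement_duration + 2.0 * cfg.pad_s
    n = int(round(total * cfg.sample_rate))
    t = np.arange(n + 1) / cfg.sample_rate
    schedule = cfg.schedule()
    w, dw = _progress_profile(t, cfg, schedule)

    endpoint = _path_points(w, start, chord, n_hat, length, cfg.path_curvature_gain)

    reach_dir = chord.copy()
    reach_dir[2] = 0.0  # trunk lean is horizontal
    if np.linalg.norm(reach_dir) < 1e-9:
        reach_dir = np.array([0.0, 1.0, 0.0])
    reach_dir = reach_dir / np.linalg.norm(reach_dir)

    trunk = _trunk_positions(rest, w, cfg, reach_dir)
    shoulder = trunk["RSHO"]
    upper = cfg.upper_arm_length
    lower = cfg.forearm_length + cfg.hand_length
    elbow = _ik_elbow(shoulder, endpoint, upper, lower)

    markers: dict[str, np.ndarray] = {k: trunk[k] for k in TRUNK_MARKERS}
    markers.update(_arm_markers(shoulder, elbow, endpoint, cfg, "R"))
    markers["RSHO"] = trunk["RSHO"]
    markers.update(_hanging_arm(trunk["LSHO"], cfg, "L"))
    markers["LSHO"] = trunk["LSHO"]

    truth = None
    if compute_ground_truth:
        truth = _ground_truth(cfg, schedule, start, chord, n_hat, length, rest,
                              reach_dir)

    if side == "left":
        markers = mirror_markers(markers)

    if cfg.marker_noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        for label in sorted(markers):
            markers[label] = markers[label] + rng.normal(
                0.0, cfg.marker_noise_sd, size=markers[label].shape
            )

    rec = TrialRecording(
        subject_id=subject_id,
        session=session,
        arm=arm,
        side=side,
        target_index=target_index,
        sample_rate=cfg.sample_rate,
        times=t,
        markers=markers,
    )
    return rec, truth


def mirror_markers(markers: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Reflect the marker set about the sagittal (x = 0) plane, swapping
    left/right labels."""
    out: dict[str, np.ndarray] = {}
    for label, pos in markers.items():
        p = pos.copy()
        p[..., 0] = -p[..., 0]
        if label[0] == "R" and label[1:] in SIDE_MARKERS:
            out["L" + label[1:]] = p
        elif label[0] == "L" and label[1:] in SIDE_MARKERS:
            out["R" + label[1:]] = p
        else:
            out[label] = p
    return out


def _ground_truth(
    cfg: SimConfig,
    schedule: Schedule,
    start: np.ndarray,
    chord: np.ndarray,
    n_hat: np.ndarray,
    length: float,
    rest: dict[str, np.ndarray],
    reach_dir: np.ndarray,
) -> SimGroundTruth:
    """Ground truth from the noiseless generating functions on a dense grid."""
    dense_rate = 10.0 * cfg.sample_rate
    total = cfg.movement_duration + 2.0 * cfg.pad_s
    nd = int(round(total * dense_rate))
    td = np.arange(nd + 1) / dense_rate
    wd, dwd = _progress_profile(td, cfg, schedule)

    speed = _path_speed(wd, dwd, length, cfg.path_curvature_gain)
    t_start, t_end = _threshold_crossings(td, speed, cfg.truth_threshold)

    path_len = outbound_path_length(length, cfg.path_curvature_gain)

    # trunk / thorax truths from the commanded transform
    m0 = 0.5 * (rest["RSHO"] + rest["LSHO"])
    theta = np.deg2rad(cfg.trunk_rotation) * wd
    clav_rel = rest["CLAV"] - m0
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    clav = np.empty((wd.size, 3))
    clav[:, 0] = cos_t * clav_rel[0] - sin_t * clav_rel[1]
    clav[:, 1] = sin_t * clav_rel[0] + cos_t * clav_rel[1]
    clav[:, 2] = clav_rel[2]
    clav += m0[None, :] + cfg.trunk_translation * wd[:, None] * reach_dir[None, :]
    texc = float(np.linalg.norm(clav - clav[0], axis=1).max())

    # joint truths via the same inverse kinematics on the dense grid
    endpoint = _path_points(wd, start, chord, n_hat, length, cfg.path_curvature_gain)
    sho_rel = rest["RSHO"] - m0
    shoulder = np.empty((wd.size, 3))
    shoulder[:, 0] = cos_t * sho_rel[0] - sin_t * sho_rel[1]
    shoulder[:, 1] = sin_t * sho_rel[0] + cos_t * sho_rel[1]
    shoulder[:, 2] = sho_rel[2]
    shoulder += m0[None, :] + cfg.trunk_translation * wd[:, None] * reach_dir[None, :]
    upper = cfg.upper_arm_length
    lower = cfg.forearm_length + cfg.hand_length
    elbow = _ik_elbow(shoulder, endpoint, upper, lower)

    d = np.linalg.norm(endpoint - shoulder, axis=1)
    cos_int = np.clip(
        (upper**2 + lower**2 - d**2) / (2.0 * upper * lower), -1.0, 1.0
    )
    elbow_flex = 180.0 - np.degrees(np.arccos(cos_int))

    fe, aa = _shoulder_angles_truth(elbow - shoulder, theta)
    humerus = elbow - shoulder
    cos_t2, sin_t2 = np.cos(theta), np.sin(theta)
    hx = cos_t2 * humerus[:, 0] + sin_t2 * humerus[:, 1]
    hz = humerus[:, 2]
    conditioning = float(
        (np.hypot(hx, hz) / np.linalg.norm(humerus, axis=1)).min()
    )

    # ranges over the analyzed movement window
    # ranges over the whole commanded movement (pads are static, so they
    # only contribute the rest posture, which is the movement's w = 0 state)
    joint_ranges = {
        "ShFE": float(np.nanmax(fe) - np.nanmin(fe)),
        "ShAA": float(np.nanmax(aa) - np.nanmin(aa)),
        "ElFE": float(elbow_flex.max() - elbow_flex.min()),
    }

    return SimGroundTruth(
        true_MT=t_end - t_start,
        true_cycle_duration=cfg.movement_duration,
        movement_start_time=t_start,
        movement_end_time=t_end,
        true_path_length=path_len,
        true_straight_distance=length,
        true_curvature_index=path_len / length,
        true_peak_speed=float(speed.max()),
        true_n_velocity_peaks=len(schedule) + 1,
        true_trunk_excursion=texc,
        true_thorax_rotation_range=cfg.trunk_rotation,
        true_joint_ranges=joint_ranges,
        shaa_conditioning=conditioning,
    )


def synth_joint_trial(
    shfe_excursion: float = 0.0,
    shaa_excursion: float = 0.0,
    elfe_excursion: float = 0.0,
    elfe_start: float = 40.0,
    duration: float = 2.0,
    sample_rate: float = 120.0,
    pad_s: float = 0.2,
    config: Optional[SimConfig] = None,
    marker_noise_sd: float = 0.0,
    seed: int = 0,
) -> TrialRecording:
    """Animate the arm from *prescribed joint-angle excursions* (static
    trunk), for joint-angle recovery tests.

    Each prescribed angle follows a minimum-jerk ramp from its rest value
    to rest + excursion over ``duration``.  Shoulder angles are the
    projection angles of the humerus in the thorax frame; elbow flexion is
    the angle between the upper-arm and forearm vectors (0 = full
    extension).
    """
    cfg = config or SimConfig()
    rest = _rest_skeleton(cfg)
    n = int(round((duration + 2 * pad_s) * sample_rate))
    t = np.arange(n + 1) / sample_rate
    ramp = min_jerk_position_tau((t - pad_s) / duration)

    fe0, aa0 = 18.0, 12.0  # rest humerus elevation, degrees
    fe = np.deg2rad(fe0 + shfe_excursion * ramp)
    aa = np.deg2rad(aa0 + shaa_excursion * ramp)
    flex = np.deg2rad(elfe_start + elfe_excursion * ramp)

    # humerus direction with prescribed projection angles:
    # FE = atan2(hy, -hz), AA = atan2(hx, -hz) -> h ~ (tan AA, tan FE, -1)
    h = np.stack([np.tan(aa), np.tan(fe), -np.ones_like(fe)], axis=1)
    h /= np.linalg.norm(h, axis=1)[:, None]

    shoulder = np.broadcast_to(rest["RSHO"], (t.size, 3)).copy()
    elbow = shoulder + cfg.upper_arm_length * h

    # flexion about an axis perpendicular to the humerus (thorax-lateral-ish)
    axis = np.cross(h, np.array([0.0, 1.0, 0.0]))
    axis /= np.linalg.norm(axis, axis=1)[:, None]
    f_dir = _rodrigues(h, axis, flex)
    lower = cfg.forearm_length + cfg.hand_length
    endpoint = elbow + lower * f_dir

    markers: dict[str, np.ndarray] = {
        k: np.broadcast_to(rest[k], (t.size, 3)).copy() for k in TRUNK_MARKERS
    }
    markers.update(_arm_markers(shoulder, elbow, endpoint, cfg, "R"))
    markers.update(_hanging_arm(
        np.broadcast_to(rest["LSHO"], (t.size, 3)).copy(), cfg, "L"
    ))
    markers["RSHO"] = shoulder
    markers["LSHO"] = np.broadcast_to(rest["LSHO"], (t.size, 3)).copy()

    if marker_noise_sd > 0:
        rng = np.random.default_rng(seed)
        for label in sorted(markers):
            markers[label] = markers[label] + rng.normal(
                0.0, marker_noise_sd, size=markers[label].shape
            )

    return TrialRecording(
        subject_id="JOINT",
        session="pre",
        arm="paretic",
        side="right",
        target_index=12,
        sample_rate=sample_rate,
        times=t,
        markers=markers,
    )


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rotate row vectors v about row-vector axes by per-row angles."""
    c = np.cos(angle)[:, None]
    s = np.sin(angle)[:, None]
    dot = np.sum(axis * v, axis=1)[:, None]
    return v * c + np.cross(axis, v) * s + axis * dot * (1.0 - c)
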