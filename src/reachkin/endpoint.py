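"""Endpoint-marker kinematic parameters.

Six parameters computed from the endpoint (second metacarpal head)
trajectory of a segmented movement:

* MT       movement time (s)
* CurvI    trajectory directness: traversed path length over the straight
           line between the segment endpoints (>= 1)
* Vmax     peak speed (cm/s)
* TpctVmax time to peak speed, % of movement duration
* NVP      number of velocity peaks (smoothness)
* LDJ      log dimensionless jerk (smoothness):
           LDJ = -ln( (MT^3 / Vmax^2) * integral j(t)^2 dt ),
           with j the second time-derivative of the speed series
           (jerk along the path).  Dimensionless by construction, hence
           invariant to spatial and temporal rescaling of the movement.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import trapezoid
from scipy.signal import find_peaks

from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    NoMovementError,
)
from .preprocess import ReachSegment


def movement_time(segment: ReachSegment, sample_rate: float) -> float:
    """Seconds elapsed between movement onset and end."""
    if sample_rate <= 0:
        raise InvalidArgumentError("sample_rate must be positive")
    return (segment.end_frame - segment.onset_frame) / sample_rate


def _arc_over_chord(path: np.ndarray, tol: float) -> float:
    arc = float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))
    chord = float(np.linalg.norm(path[-1] - path[0]))
    if chord < tol:
        raise InvalidArgumentError(
            "segment endpoints coincide; directness undefined"
        )
    return arc / chord


def trajectory_directness(
    path: np.ndarray, phase: str = "outbound", tol: float = 1e-6
) -> float:
    """Ratio of the traversed path to the straight line joining the
    segment endpoints.

    For an out-and-back movement (``phase='full_cycle'``) the endpoints
    coincide, so directness is computed per half-cycle — split at the
    frame farthest from the start — and averaged.
    """
    path = np.asarray(path, dtype=float)
    if path.shape[0] < 2:
        raise InsufficientDataError("need >= 2 frames")
    if phase == "outbound":
        return _arc_over_chord(path, tol)
    apex = int(np.argmax(np.linalg.norm(path - path[0], axis=1)))
    if apex == 0 or apex == path.shape[0] - 1:
        # degenerate split: fall back to a single leg
        return _arc_over_chord(path, tol)
    out = _arc_over_chord(path[: apex + 1], tol)
    back = _arc_over_chord(path[apex:], tol)
    return 0.5 * (out + back)


def peak_velocity(speed: np.ndarray) -> tuple[float, int]:
    """Global maximum of the speed series and its frame index within the
    segment (ties broken to the earliest frame)."""
    speed = np.asarray(speed, dtype=float)
    if speed.size == 0:
        raise InsufficientDataError("empty segment")
    idx = int(np.argmax(speed))
    return float(speed[idx]), idx


def time_to_peak_pct(speed: np.ndarray) -> float:
    """Time of peak speed from onset as a percentage of movement duration."""
    speed = np.asarray(speed, dtype=float)
    if speed.size < 2:
        raise InsufficientDataError("segment too short")
    _, idx = peak_velocity(speed)
    return 100.0 * idx / (speed.size - 1)


def count_velocity_peaks(
    speed: np.ndarray,
    sample_rate: float,
    min_prominence_fraction: float = 0.05,
    min_separation_s: float = 0.1,
) -> int:
    """Number of local speed maxima with prominence >=
    ``min_prominence_fraction`` x peak speed, at least
    ``min_separation_s`` apart.  At least 1 whenever movement exists."""
    speed = np.asarray(speed, dtype=float)
    if speed.size == 0 or speed.max(initial=0.0) <= 0.0:
        raise NoMovementError("flat or empty speed series")
    vmax = speed.max()
    distance = max(1, int(round(min_separation_s * sample_rate)))
    peaks, _ = find_peaks(
        speed, prominence=min_prominence_fraction * vmax, distance=distance
    )
    return max(1, peaks.size)


def log_dimensionless_jerk(speed: np.ndarray, sample_rate: float) -> float:
    """Log dimensionless jerk of the movement (negative; closer to zero is
    smoother).  Requires >= 7 frames for the third-order differentiation.

    The ideal minimum-jerk reach has LDJ = -ln(720 / 1.875^2) =
    -ln(204.8) ~ -5.32; submovements and corrections drive it more
    negative.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.size < 7:
        raise InsufficientDataError("need >= 7 frames for jerk")
    vmax = speed.max(initial=0.0)
    if vmax <= 0:
        raise NoMovementError("flat speed series")
    dt = 1.0 / sample_rate
    duration = (speed.size - 1) * dt
    accel = np.gradient(speed, dt)
    jerk = np.gradient(accel, dt)
    dlj = duration**3 / vmax**2 * trapezoid(jerk**2, dx=dt)
    return float(-np.log(dlj))
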