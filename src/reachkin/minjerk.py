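"""Minimum-jerk trajectories and submovement composition.

The minimum-jerk point-to-point movement is the quintic

    x(tau) = A * (10 tau^3 - 15 tau^4 + 6 tau^5),   tau = t / T,

the trajectory minimizing integrated squared jerk under rest-to-rest
boundary conditions.  Its speed profile is the symmetric bell

    v(tau) = (A / T) * 30 tau^2 (1 - tau)^2,

peaking at tau = 1/2 with value 1.875 * A / T.  Impaired reaching is
modeled as a sum of time-shifted minimum-jerk submovements, which yields
a speed profile with one local maximum per (sufficiently separated)
submovement.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError

#: peak of 30 tau^2 (1-tau)^2 at tau = 1/2
PEAK_SPEED_FACTOR = 1.875

#: dimensionless jerk of the ideal minimum-jerk movement,
#: integral_0^1 (60 - 360 tau + 360 tau^2)^2 dtau / 1.875^2 = 720 / 1.875^2
MINJERK_DIMENSIONLESS_JERK = 720.0 / PEAK_SPEED_FACTOR**2  # = 204.8

Schedule = Sequence[tuple[float, float, float]]


def min_jerk_position_tau(tau: np.ndarray) -> np.ndarray:
    """Normalized position on [0, 1]; clamped outside the movement window."""
    tau = np.clip(tau, 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def min_jerk_speed_tau(tau: np.ndarray) -> np.ndarray:
    """Normalized speed d(position)/d(tau); zero outside [0, 1]."""
    tau = np.asarray(tau, dtype=float)
    inside = (tau >= 0.0) & (tau <= 1.0)
    t = np.where(inside, tau, 0.0)
    return np.where(inside, 30.0 * t**2 * (1.0 - t) ** 2, 0.0)


def min_jerk_profile(
    amplitude: float, duration: float, sample_rate: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sampled minimum-jerk movement.

    Returns ``(t, position, speed)`` with ``t`` spanning [0, duration]
    inclusive at 1/sample_rate spacing.  Position runs from 0 to
    ``amplitude``; speed is the analytic derivative (cm/s), zero at both
    ends.
    """
    if amplitude <= 0 or duration <= 0 or sample_rate <= 0:
        raise InvalidArgumentError(
            "amplitude, duration and sample_rate must be positive"
        )
    # ceil so the grid always covers [0, duration]: the clamped quintic then
    # ends exactly at the commanded amplitude
    n = int(np.ceil(duration * sample_rate - 1e-9))
    if n < 10:
        raise InvalidArgumentError(
            "need at least 10 samples over the movement "
            f"(got {n} = duration * sample_rate)"
        )
    t = np.arange(n + 1) / sample_rate
    tau = t / duration
    pos = amplitude * min_jerk_position_tau(tau)
    speed = (amplitude / duration) * min_jerk_speed_tau(tau)
    return t, pos, speed


def validate_schedule(schedule: Schedule) -> None:
    """Check submovement-schedule invariants.

    Each entry is ``(onset_fraction, amplitude_fraction, duration_fraction)``
    of the movement window.  Amplitude fractions must sum to 1 and every
    submovement must fit inside the window.
    """
    if len(schedule) < 1:
        raise InvalidArgumentError("schedule must contain >= 1 submovement")
    amps = 0.0
    for onset, amp, dur in schedule:
        if dur <= 0:
            raise InvalidArgumentError("submovement duration must be > 0")
        if amp <= 0:
            raise InvalidArgumentError("submovement amplitude must be > 0")
        if onset < -1e-12 or onset + dur > 1.0 + 1e-9:
            raise InvalidArgumentError(
                f"submovement (onset={onset}, dur={dur}) leaves the window"
            )
        amps += amp
    if abs(amps - 1.0) > 1e-8:
        raise InvalidArgumentError(
            f"amplitude fractions must sum to 1 (got {amps})"
        )


def compose_submovements(
    schedule: Schedule,
    amplitude: float,
    duration: float,
    sample_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose time-shifted minimum-jerk submovements.

    Returns ``(t, position)``; position runs from 0 to ``amplitude``.  With
    submovement overlaps small enough that the component speed bells do not
    merge (disjoint or nearly disjoint windows), the speed profile of the
    composite has exactly ``len(schedule)`` local maxima.
    """
    if amplitude <= 0 or duration <= 0 or sample_rate <= 0:
        raise InvalidArgumentError(
            "amplitude, duration and sample_rate must be positive"
        )
    validate_schedule(schedule)
    n = int(np.ceil(duration * sample_rate - 1e-9))
    t = np.arange(n + 1) / sample_rate
    pos = np.zeros_like(t)
    for onset, amp, dur in schedule:
        tau = (t / duration - onset) / dur
        pos += amplitude * amp * min_jerk_position_tau(tau)
    return t, pos


def composed_position_tau(schedule: Schedule, tau: np.ndarray) -> np.ndarray:
    """Normalized composite position (0 -> 1) at normalized time ``tau``."""
    tau = np.asarray(tau, dtype=float)
    pos = np.zeros_like(tau)
    for onset, amp, dur in schedule:
        pos += amp * min_jerk_position_tau((tau - onset) / dur)
    return pos


def composed_speed_tau(schedule: Schedule, tau: np.ndarray) -> np.ndarray:
    """Normalized composite speed d(position)/d(tau)."""
    tau = np.asarray(tau, dtype=float)
    v = np.zeros_like(tau)
    for onset, amp, dur in schedule:
        v += (amp / dur) * min_jerk_speed_tau((tau - onset) / dur)
    return v


def staircase_schedule(k: int, decay: float = 0.75) -> list[tuple[float, float, float]]:
    """A disjoint ``k``-submovement schedule with geometrically decaying
    amplitudes (a large primary reach followed by smaller corrections).

    Submovements tile the window: onset_i = i/k, duration 1/k each, with a
    small gap (95% of the slot) so speed bells stay separated.
    """
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if k == 1:
        return [(0.0, 1.0, 1.0)]
    raw = np.array([decay**i for i in range(k)])
    amps = raw / raw.sum()
    slot = 1.0 / k
    return [(i * slot, float(amps[i]), 0.95 * slot) for i in range(k)]
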