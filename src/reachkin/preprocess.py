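"""Marker filtering, endpoint speed, and movement segmentation.

Marker trajectories sampled at 120 frames/s are low-pass filtered
(zero-phase 4th-order Butterworth, 6 Hz default) before differentiation;
the movement is then segmented from the endpoint speed profile with a
relative threshold rule (default 5% of peak speed), replacing manual event
verification with a reproducible convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import (
    DegenerateTrialError,
    InsufficientDataError,
    InvalidArgumentError,
    NoMovementError,
)


@dataclass(frozen=True)
class ReachSegment:
    """Frame bounds of one analyzed movement within a trial."""

    onset_frame: int
    end_frame: int
    phase: str  # {outbound, full_cycle}

    def __post_init__(self) -> None:
        if self.onset_frame >= self.end_frame:
            raise InvalidArgumentError("onset_frame must precede end_frame")
        if self.phase not in ("outbound", "full_cycle"):
            raise InvalidArgumentError(f"unknown phase {self.phase!r}")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.onset_frame + 1

    def slice(self) -> slice:
        return slice(self.onset_frame, self.end_frame + 1)


def lowpass_filter(
    series: np.ndarray, cutoff: float, sample_rate: float, order: int = 4
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass along axis 0."""
    if not 0 < cutoff < sample_rate / 2:
        raise InvalidArgumentError(
            f"cutoff must lie in (0, Nyquist) = (0, {sample_rate / 2}); "
            f"got {cutoff}"
        )
    series = np.asarray(series, dtype=float)
    b, a = butter(order, cutoff / (sample_rate / 2.0), btype="low")
    return filtfilt(b, a, series, axis=0)


def speed_profile(positions: np.ndarray, sample_rate: float) -> np.ndarray:
    """Endpoint speed ||dP/dt|| by central differences (one-sided at the
    ends), cm/s."""
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] < 3:
        raise InsufficientDataError("need >= 3 frames to differentiate")
    vel = np.gradient(positions, 1.0 / sample_rate, axis=0)
    return np.linalg.norm(vel, axis=1)


def detect_reach_bounds(
    speed: np.ndarray,
    threshold_fraction: float = 0.05,
    phase: str = "full_cycle",
    positions: np.ndarray | None = None,
    target: np.ndarray | None = None,
    capture_radius: float = 2.0,
) -> ReachSegment:
    """Segment a movement from its speed profile.

    The threshold is ``threshold_fraction`` x peak speed, so segmentation
    is invariant to uniform scaling of the speed series.  The onset is the
    last frame below threshold before the first up-crossing; for
    ``full_cycle`` (out-and-back) the end is the first frame below
    threshold after the last down-crossing, and for ``outbound`` the first
    sub-threshold frame after the outbound peak — if ``positions`` and
    ``target`` are given, additionally requiring the endpoint within
    ``capture_radius`` cm of the target.
    """
    if not 0 < threshold_fraction < 1:
        raise InvalidArgumentError("threshold_fraction must be in (0, 1)")
    if phase not in ("outbound", "full_cycle"):
        raise InvalidArgumentError(f"unknown phase {phase!r}")
    speed = np.asarray(speed, dtype=float)
    vmax = speed.max(initial=0.0)
    if vmax <= 0.0:
        raise NoMovementError("speed profile is identically zero")
    thr = threshold_fraction * vmax
    above = np.flatnonzero(speed >= thr)
    if above.size < 2:
        raise DegenerateTrialError("threshold never crossed for two frames")

    onset = int(max(above[0] - 1, 0))
    if phase == "full_cycle":
        end = int(min(above[-1] + 1, speed.size - 1))
        return ReachSegment(onset, end, phase)

    if positions is not None and target is not None:
        # outbound end: first settle (sub-threshold) within the capture
        # radius of the target after movement onset
        positions = np.asarray(positions, dtype=float)
        near = (
            np.linalg.norm(positions - np.asarray(target)[None, :], axis=1)
            <= capture_radius
        )
        cand = np.flatnonzero((speed < thr) & near)
        cand = cand[cand > onset]
    else:
        # no target known: first sub-threshold frame after the global peak
        peak = int(onset + np.argmax(speed[onset:]))
        cand = np.flatnonzero(speed[peak:] < thr) + peak
    if cand.size == 0:
        raise DegenerateTrialError(
            "no outbound end found (speed never settles near the target)"
        )
    return ReachSegment(onset, int(cand[0]), phase)
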