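"""Target-panel geometry for the reach-to-target task.

A vertical panel faces the seated subject, its center aligned with the
acromion of the tested arm at a distance equal to the subject's arm length
(measured with the fist closed).  Twelve targets sit on the panel in a
clock-like arrangement, 20 cm from the center; an extra start target lies
on the line from the panel center toward the shoulder, at forearm distance
from the center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

X_HAT = np.array([1.0, 0.0, 0.0])
Y_HAT = np.array([0.0, 1.0, 0.0])
Z_HAT = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class PanelGeometry:
    """Positions (cm, world frame) of the panel center, 12 clock targets
    and the start target."""

    center: np.ndarray
    radius: float
    target_positions: dict[int, np.ndarray]
    start_position: np.ndarray
    subject_distance: float

    def __post_init__(self) -> None:
        keys = sorted(self.target_positions)
        if keys != list(range(1, 13)):
            raise InvalidArgumentError("target indices must be exactly 1..12")
        for i, pos in self.target_positions.items():
            r = float(np.linalg.norm(np.asarray(pos) - self.center))
            if abs(r - self.radius) > 1e-6:
                raise InvalidArgumentError(
                    f"target {i} lies at {r:.6f} cm from center, expected "
                    f"{self.radius} cm"
                )

    def target(self, index: int) -> np.ndarray:
        if index not in self.target_positions:
            raise InvalidArgumentError(
                f"target_index must be 1..12, got {index!r}"
            )
        return self.target_positions[index]

    @classmethod
    def from_subject(
        cls,
        shoulder: np.ndarray,
        arm_length: float,
        forearm_length: float,
        radius: float = 20.0,
    ) -> "PanelGeometry":
        """Build the panel for a subject whose tested-arm acromion sits at
        ``shoulder``, facing +Y.

        The panel center is placed ``arm_length`` cm anterior to the
        shoulder; the start target is on the center->shoulder line at
        ``forearm_length`` cm from the center.  Clock target *i* sits at
        angle ``i * 30°`` measured clockwise from 12 o'clock (straight up)
        as seen by the subject.
        """
        if arm_length <= 0 or forearm_length <= 0 or radius <= 0:
            raise InvalidArgumentError("lengths must be positive")
        if forearm_length >= arm_length:
            raise InvalidArgumentError(
                "forearm_length must be smaller than arm_length"
            )
        shoulder = np.asarray(shoulder, dtype=float)
        center = shoulder + arm_length * Y_HAT
        start = center + forearm_length * (shoulder - center) / arm_length
        targets: dict[int, np.ndarray] = {}
        for i in range(1, 13):
            phi = np.deg2rad(30.0 * i)
            # Clockwise as seen by the subject facing +Y: 3 o'clock is the
            # subject's right (+X).
            targets[i] = center + radius * (
                np.sin(phi) * X_HAT + np.cos(phi) * Z_HAT
            )
        return cls(
            center=center,
            radius=radius,
            target_positions=targets,
            start_position=start,
            subject_distance=arm_length,
        )


def default_geometry(
    arm_length: float = 62.0,
    forearm_length: float = 24.0,
    shoulder_height: float = 100.0,
    radius: float = 20.0,
) -> PanelGeometry:
    """Panel for the canonical right-arm subject with the acromion at
    (0, 0, shoulder_height)."""
    shoulder = np.array([0.0, 0.0, shoulder_height])
    return PanelGeometry.from_subject(shoulder, arm_length, forearm_length, radius)
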