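"""Joint-range and trunk-movement parameters from marker positions.

A documented, reproducible replacement for proprietary biomechanical
models: all angles are explicit projection angles in a thorax frame built
from four torso markers, and joints are treated as universal (two-axis)
joints — no axial humeral rotation is computed.

Thorax frame (orthonormal, right-handed):
  * vertical   zt = unit( mid(C7, CLAV) - mid(T10, STRN) )   (up)
  * lateral    xt = inter-acromion line (left -> right acromion),
               orthogonalized against zt
  * anterior   yt = zt x xt

Angles (degrees):
  * elbow flexion  — angle between the upper-arm vector (acromion ->
    lateral epicondyle) and the forearm vector (epicondyle -> midpoint of
    the styloid markers); 0 deg = full extension.
  * shoulder FE / AA — projection angles of the humerus vector in the
    thorax sagittal (yt, zt) and frontal (xt, zt) planes, 0 deg with the
    arm hanging along -zt.
  * thorax rotation — transverse-plane angle of the inter-acromion line
    relative to its orientation at segment onset (the transverse plane is
    the plane perpendicular to the *onset* thorax vertical, which makes
    the measure invariant to a global rotation of the capture volume).
  * torso excursion — maximum displacement of the suprasternal-notch
    (CLAV) marker from its position at segment onset (cm).

Left-arm recordings must be mirrored to the canonical right-arm
convention (see ``reachkin.simulate.mirror_markers``) before calling
these functions, so signs are comparable across sides.
"""

from __future__ import annotations

import numpy as np

from .errors import (
    InsufficientMarkersError,
    InvalidArgumentError,
    InvalidGeometryError,
)

#: fraction of frames a required marker may miss before the segment is
#: rejected (below it, gaps are linearly interpolated)
MISSING_TOLERANCE = 0.10


def _fill_gaps(pos: np.ndarray, label: str) -> np.ndarray:
    """Linearly interpolate NaN frames; reject if too many are missing."""
    pos = np.asarray(pos, dtype=float)
    bad = np.isnan(pos).any(axis=1)
    if not bad.any():
        return pos
    if bad.mean() > MISSING_TOLERANCE:
        raise InsufficientMarkersError(
            f"marker {label}: {bad.mean():.0%} of frames missing "
            f"(tolerance {MISSING_TOLERANCE:.0%})"
        )
    out = pos.copy()
    idx = np.arange(pos.shape[0])
    for ax in range(pos.shape[1]):
        out[bad, ax] = np.interp(idx[bad], idx[~bad], pos[~bad, ax])
    return out


def thorax_frame(
    c7: np.ndarray, t10: np.ndarray, clav: np.ndarray, strn: np.ndarray,
    rsho: np.ndarray, lsho: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame orthonormal thorax axes (xt, yt, zt), each (n, 3)."""
    up = 0.5 * (c7 + clav) - 0.5 * (t10 + strn)
    nz = np.linalg.norm(up, axis=1)
    if np.any(nz < 1e-9):
        raise InvalidGeometryError("degenerate thorax vertical axis")
    zt = up / nz[:, None]
    lat = rsho - lsho
    lat = lat - np.sum(lat * zt, axis=1)[:, None] * zt
    nx = np.linalg.norm(lat, axis=1)
    if np.any(nx < 1e-9):
        raise InvalidGeometryError(
            "acromion line parallel to the thorax vertical"
        )
    xt = lat / nx[:, None]
    yt = np.cross(zt, xt)
    return xt, yt, zt


def elbow_flexion_angle(
    sho: np.ndarray, elb: np.ndarray, wrist_mid: np.ndarray
) -> np.ndarray:
    """Per-frame elbow flexion (deg): angle between the upper-arm and
    forearm vectors; 0 = full extension (collinear chain)."""
    upper = elb - sho
    lower = wrist_mid - elb
    nu = np.linalg.norm(upper, axis=1)
    nl = np.linalg.norm(lower, axis=1)
    if np.any(nu < 1e-9) or np.any(nl < 1e-9):
        raise InvalidGeometryError("zero-length arm segment")
    cosang = np.clip(np.sum(upper * lower, axis=1) / (nu * nl), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def shoulder_angles(
    humerus: np.ndarray,
    xt: np.ndarray,
    yt: np.ndarray,
    zt: np.ndarray,
    gimbal_tol: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame shoulder flexion/extension and abduction/adduction (deg).

    The humerus vector is expressed in the thorax frame; FE is the angle
    of its sagittal-plane projection, AA of its frontal-plane projection,
    both measured from the downward thorax vertical.  Frames where the
    humerus comes within a cone of the decomposition axis (in-plane
    component below ``gimbal_tol`` of the humerus length) have an
    ill-conditioned projection; they are returned as NaN so callers
    exclude them from ranges.
    """
    hx = np.sum(humerus * xt, axis=1)
    hy = np.sum(humerus * yt, axis=1)
    hz = np.sum(humerus * zt, axis=1)
    scale = np.linalg.norm(humerus, axis=1)
    fe = np.degrees(np.arctan2(hy, -hz))
    aa = np.degrees(np.arctan2(hx, -hz))
    fe[np.hypot(hy, hz) < gimbal_tol * scale] = np.nan
    aa[np.hypot(hx, hz) < gimbal_tol * scale] = np.nan
    return fe, aa


def angle_range(series: np.ndarray) -> float:
    """max - min of an angle series, ignoring flagged (NaN) frames."""
    series = np.asarray(series, dtype=float)
    ok = ~np.isnan(series)
    if ok.sum() < 2:
        raise InsufficientMarkersError("too few valid frames for a range")
    return float(np.nanmax(series) - np.nanmin(series))


def thorax_rotation(
    rsho: np.ndarray, lsho: np.ndarray, zt0: np.ndarray | None = None
) -> np.ndarray:
    """Per-frame rotation (deg) of the inter-acromion line relative to its
    orientation at the first frame, in the transverse plane (the plane
    perpendicular to ``zt0``, the onset thorax vertical; world +Z if not
    given)."""
    v = rsho - lsho
    if np.any(np.linalg.norm(v, axis=1) < 1e-9):
        raise InvalidGeometryError("acromion markers coincide")
    if zt0 is None:
        zt0 = np.array([0.0, 0.0, 1.0])
    zt0 = zt0 / np.linalg.norm(zt0)
    vp = v - (v @ zt0)[:, None] * zt0[None, :]
    if np.linalg.norm(vp[0]) < 1e-9:
        raise InvalidGeometryError(
            "acromion line parallel to the transverse-plane normal at onset"
        )
    ref = vp[0]
    cross = np.cross(np.broadcast_to(ref, vp.shape), vp) @ zt0
    dot = vp @ ref
    return np.degrees(np.arctan2(cross, dot))


def torso_excursion(clav: np.ndarray) -> float:
    """Maximum displacement (cm) of the CLAV marker from segment onset."""
    clav = np.asarray(clav, dtype=float)
    if clav.shape[0] < 2:
        raise InvalidArgumentError("need >= 2 frames")
    return float(np.linalg.norm(clav - clav[0], axis=1).max())
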