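"""Translation-corrected gaze kinematics.

The observer in a free-walking VR recording both rotates the eyes and
translates the body, so the angle between consecutive allocentric eye
direction vectors is not a valid eye velocity: a pure body translation with
the gaze locked on a fixed scene point changes the direction vectors without
any eye movement, and a pure translation with a frozen allocentric direction
sweeps the gaze ray across the scene without changing the vectors at all.

The correction works in the scene domain instead.  For two consecutive
samples the shift of the gaze-ray hit points ``v = hit(t2) - hit(t1)`` is
projected onto the plane orthogonal to the viewing direction (orthogonal
rejection), and the angle subtended by that in-plane shift at the observer's
distance from the hit point,

    w(t1) = atan2(||reject(v, eye_dir(t1))||,
                  ||eye_origin(t1) - hit_point(t1)||) / (t2 - t1),

in degrees/second, is the eye's angular velocity irrespective of any
translation: if the hit point does not move, w is exactly zero.

Saccade amplitudes reuse the same construction between the centroids of the
two flanking gaze events, evaluated from the saccade-onset viewpoint and not
divided by time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConfigError
from .io import GazeRecording, GazeSample

__all__ = [
    "VelocitySeries",
    "hit_shift",
    "in_plane_component",
    "angular_velocity_step",
    "angular_velocity",
    "condition_velocity",
    "head_angular_velocity",
    "eye_in_head",
    "head_rotation_matrix",
    "saccade_amplitude",
]

_UNIT_TOL = 1e-6


@dataclass
class VelocitySeries:
    """Per-interval angular velocity, timestamped at the earlier sample.

    ``t[i]`` is the timestamp of the first sample of interval ``i`` (which
    spans samples ``i`` and ``i+1`` of the source recording); ``w`` is in
    degrees/second; ``valid`` marks intervals where both samples were valid
    and carried hit points.  Length is ``n_samples - 1``.
    """

    t: np.ndarray
    w: np.ndarray
    valid: np.ndarray
    dt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.dt is not None:
            self.dt = np.asarray(self.dt, dtype=float)

    def __len__(self) -> int:
        return int(self.t.shape[0])

    @property
    def duration(self) -> float:
        if len(self) == 0:
            return 0.0
        end = self.t[-1] + (self.dt[-1] if self.dt is not None else 0.0)
        return float(end - self.t[0])

    def valid_values(self) -> np.ndarray:
        return self.w[self.valid & np.isfinite(self.w)]


def hit_shift(hit_t1: np.ndarray, hit_t2: np.ndarray) -> np.ndarray:
    """Shift of the hit point between two samples, ignoring the viewpoint."""
    return np.asarray(hit_t2, dtype=float) - np.asarray(hit_t1, dtype=float)


def in_plane_component(v_eye_vec: np.ndarray, eye_vec: np.ndarray) -> np.ndarray:
    """Orthogonal rejection of the hit-point shift from the viewing direction.

    Removes the along-gaze (depth) component of the shift, leaving the part
    that corresponds to a rotation of the eye.  ``eye_vec`` must be unit-norm.
    """
    v = np.asarray(v_eye_vec, dtype=float)
    e = np.asarray(eye_vec, dtype=float)
    if abs(np.linalg.norm(e) - 1.0) > _UNIT_TOL:
        raise ValueError("eye_vec must be unit-norm")
    return v - np.dot(v, e) * e


def angular_velocity_step(s1: GazeSample, s2: GazeSample) -> float:
    """Translation-corrected angular velocity over one sample pair (deg/s)."""
    if s1.hit_point is None or s2.hit_point is None:
        raise ValueError("both samples need hit points")
    dt = s2.t - s1.t
    if dt <= 0:
        raise ValueError("t2 must exceed t1")
    shift = hit_shift(s1.hit_point, s2.hit_point)
    inplane = in_plane_component(shift, s1.eye_dir)
    dist = float(np.linalg.norm(s1.eye_origin - s1.hit_point))
    if dist <= 0:
        raise ValueError("zero distance to hit point")
    ang = np.degrees(np.arctan2(np.linalg.norm(inplane), dist))
    return float(ang / dt)


def angular_velocity(rec: GazeRecording) -> VelocitySeries:
    """Vectorised translation-corrected velocity for a whole recording.

    Intervals where either sample is invalid or lacks a hit point, where the
    observer sits on the hit point, or where the time step is non-positive
    are marked invalid (w = NaN) rather than raising.
    """
    t = rec.t
    dt = np.diff(t)
    h1, h2 = rec.hit_point[:-1], rec.hit_point[1:]
    e = rec.eye_dir[:-1]
    origin = rec.eye_origin[:-1]

    has_hit = rec.has_hit()
    ok = (
        rec.valid[:-1]
        & rec.valid[1:]
        & has_hit[:-1]
        & has_hit[1:]
        & (dt > 0)
    )

    shift = h2 - h1
    # defensive renormalisation: upstream contract is unit directions
    norms = np.linalg.norm(e, axis=1)
    safe = norms > 0
    e = np.where(safe[:, None], e / np.where(safe, norms, 1.0)[:, None], e)
    inplane = shift - np.sum(shift * e, axis=1)[:, None] * e
    dist = np.linalg.norm(origin - h1, axis=1)
    ok &= safe & (dist > 0)

    w = np.full(len(t) - 1, np.nan)
    idx = np.flatnonzero(ok)
    ang = np.degrees(np.arctan2(np.linalg.norm(inplane[idx], axis=1), dist[idx]))
    w[idx] = ang / dt[idx]
    return VelocitySeries(t=t[:-1], w=w, valid=ok, dt=dt)


def condition_velocity(
    vs: VelocitySeries,
    clip: float = 1000.0,
    sg_window: int = 5,
    sg_order: int = 2,
) -> VelocitySeries:
    """Clip biologically impossible velocities, then Savitzky-Golay smooth.

    Values above ``clip`` (default 1000 deg/s) are set to the ceiling before
    smoothing.  Smoothing runs independently on each contiguous valid run so
    invalid intervals never leak into a filter window; runs shorter than the
    window pass through unchanged.  Output is re-clamped to [0, clip] since a
    polynomial fit can overshoot at sharp velocity peaks.
    """
    if sg_window % 2 == 0 or sg_window < sg_order + 1:
        raise ConfigError("sg_window must be odd and exceed sg_order")
    w = vs.w.copy()
    w[vs.valid & (w > clip)] = clip

    out = w.copy()
    n = len(w)
    i = 0
    while i < n:
        if not vs.valid[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and vs.valid[j + 1]:
            j += 1
        if j - i + 1 >= sg_window:
            out[i : j + 1] = savgol_filter(
                w[i : j + 1], sg_window, sg_order, mode="interp"
            )
        i = j + 1
    np.clip(out, 0.0, clip, out=out)
    out[~vs.valid] = np.nan
    return VelocitySeries(t=vs.t, w=out, valid=vs.valid, dt=vs.dt)


def head_angular_velocity(rec: GazeRecording) -> VelocitySeries:
    """Angular velocity of the head direction vector (deg/s)."""
    d = rec.head_dir
    norms = np.linalg.norm(d, axis=1)
    safe = norms > 0
    dn = np.where(safe[:, None], d / np.where(safe, norms, 1.0)[:, None], d)
    dots = np.clip(np.sum(dn[:-1] * dn[1:], axis=1), -1.0, 1.0)
    dt = np.diff(rec.t)
    ok = safe[:-1] & safe[1:] & (dt > 0)
    w = np.full(len(rec) - 1, np.nan)
    w[ok] = np.degrees(np.arccos(dots[ok])) / dt[ok]
    return VelocitySeries(t=rec.t[:-1], w=w, valid=ok, dt=dt)


def head_rotation_matrix(head_dir: np.ndarray, up=(0.0, 1.0, 0.0)) -> np.ndarray:
    """World->head rotation built from the head forward vector and scene up.

    Rows are the head frame's right, up and forward axes expressed in world
    coordinates, so ``R @ v_world`` is ``v`` in head coordinates.
    """
    fwd = np.asarray(head_dir, dtype=float)
    fwd = fwd / np.linalg.norm(fwd)
    upv = np.asarray(up, dtype=float)
    right = np.cross(upv, fwd)
    nr = np.linalg.norm(right)
    if nr < 1e-12:
        raise ValueError("head direction is parallel to the up axis")
    right /= nr
    true_up = np.cross(fwd, right)
    return np.stack([right, true_up, fwd])


def eye_in_head(eye_dir_world: np.ndarray, head_rotation: np.ndarray) -> np.ndarray:
    """Express a world-frame eye direction in the head frame (unit norm)."""
    R = np.asarray(head_rotation, dtype=float)
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
        raise ValueError("head_rotation must be orthonormal")
    v = R @ np.asarray(eye_dir_world, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero eye direction")
    return v / n


def saccade_amplitude(
    prev_centroid: np.ndarray,
    next_centroid: np.ndarray,
    eye_origin_at_onset: np.ndarray,
    eye_vec_at_onset: np.ndarray,
) -> float:
    """Saccade amplitude between flanking gaze centroids, in degrees.

    Same geometric construction as the per-interval velocity — in-plane
    component of the centroid shift over the distance to the first centroid —
    but evaluated from the saccade-onset viewpoint and not divided by time.
    """
    c1 = np.asarray(prev_centroid, dtype=float)
    c2 = np.asarray(next_centroid, dtype=float)
    origin = np.asarray(eye_origin_at_onset, dtype=float)
    e = np.asarray(eye_vec_at_onset, dtype=float)
    n = np.linalg.norm(e)
    if n == 0:
        return float("nan")
    e = e / n
    shift = c2 - c1
    inplane = shift - np.dot(shift, e) * e
    dist = float(np.linalg.norm(origin - c1))
    if dist <= 0:
        return float("nan")
    return float(np.degrees(np.arctan2(np.linalg.norm(inplane), dist)))
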