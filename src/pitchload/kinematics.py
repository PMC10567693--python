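"""Anatomical coordinate systems, joint angles and event detection.

Builds segment-fixed frames for the hand, forearm, upper arm and thorax from
six throwing-arm bony landmarks plus four trunk markers, decomposes the elbow
rotation with the floating-axis (joint coordinate system) convention
(flexion/extension - ab/adduction - pronation/supination) and the shoulder
with a y-x-y Euler sequence (plane of elevation - negative elevation - axial
rotation), and locates the instant of maximal external shoulder rotation
(MER).

Conventions
-----------
* Global frame: z up, gravity along -z.  Left-handed throwers are mirrored
  (x -> -x) before any frame construction so a single right-handed sign
  convention serves both.
* Segment bases are stored as ``(n, 3, 3)`` arrays whose *columns* are the
  local x, y, z axes expressed in the global frame (local -> global maps).
* y is the longitudinal axis pointing from distal to proximal; z is the
  orthogonalized flexion/radial axis (lateral for the right arm); x = y x z.
* Angles are computed and stored in radians, unwrapped along time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

ARM_LANDMARKS = (
    "third_proximal_interphalangeal",
    "ulna_styloid",
    "radius_styloid",
    "lateral_humeral_epicondyle",
    "medial_humeral_epicondyle",
    "acromion",
)
TRUNK_LANDMARKS = ("suprasternal_notch", "c7", "xiphoid", "t8")
ALL_LANDMARKS = ARM_LANDMARKS + TRUNK_LANDMARKS

SEGMENTS = ("hand", "forearm", "upper_arm", "thorax")

#: maximum marker gap (samples) bridged by linear interpolation
MAX_GAP_SAMPLES = 5

#: default zero-phase low-pass cutoff applied to marker positions (Hz);
#: free parameter, not a claim about any particular capture pipeline
DEFAULT_MARKER_CUTOFF = 12.0

_DEGENERATE_TOL = 1e-8


class KinematicsError(ValueError):
    """Invalid marker data or degenerate geometry."""


class GapError(KinematicsError):
    """Marker gap too long to interpolate; the pitch is invalid."""


class GimbalError(KinematicsError):
    """Sustained proximity to a rotation-decomposition singularity."""


# ---------------------------------------------------------------------------
# marker trial container
# ---------------------------------------------------------------------------


@dataclass
class MarkerTrial:
    """Named 3D landmark trajectories for one pitch at the mocap rate."""

    time: np.ndarray
    landmarks: dict[str, np.ndarray]
    handedness: str = "right"
    pitch_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))

    def validate(self, require: tuple[str, ...] = ALL_LANDMARKS) -> None:
        if self.handedness not in ("right", "left"):
            raise KinematicsError(f"unknown handedness {self.handedness!r}")
        if self.time.ndim != 1 or self.time.size < 2:
            raise KinematicsError("time must be a 1-D series of >= 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise KinematicsError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise KinematicsError("time must be uniformly sampled")
        missing = [name for name in require if name not in self.landmarks]
        if missing:
            raise KinematicsError(f"missing landmarks: {missing}")
        for name, xyz in self.landmarks.items():
            xyz = np.asarray(xyz)
            if xyz.shape != (self.time.size, 3):
                raise KinematicsError(
                    f"landmark {name!r} has shape {xyz.shape}, "
                    f"expected {(self.time.size, 3)}"
                )

    def has_gaps(self) -> bool:
        return any(
            not np.all(np.isfinite(xyz)) for xyz in self.landmarks.values()
        )


def fill_gaps(trial: MarkerTrial, max_gap: int = MAX_GAP_SAMPLES) -> MarkerTrial:
    """Linearly interpolate marker gaps of at most ``max_gap`` samples.

    Longer gaps (or gaps touching the trial boundary) raise :class:`GapError`
    and invalidate the pitch.
    """
    filled: dict[str, np.ndarray] = {}
    t = trial.time
    for name, xyz in trial.landmarks.items():
        xyz = np.asarray(xyz, dtype=float).copy()
        bad = ~np.all(np.isfinite(xyz), axis=1)
        if not bad.any():
            filled[name] = xyz
            continue
        runs = _bool_runs(bad)
        for start, stop in runs:  # stop exclusive
            if stop - start > max_gap or start == 0 or stop == len(bad):
                raise GapError(
                    f"landmark {name!r}: gap of {stop - start} samples at "
                    f"[{start}, {stop}) exceeds the {max_gap}-sample limit "
                    "or touches the trial boundary"
                )
        good = ~bad
        for axis in range(3):
            xyz[bad, axis] = np.interp(t[bad], t[good], xyz[good, axis])
        filled[name] = xyz
    return MarkerTrial(t, filled, trial.handedness, trial.pitch_id)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def mirror_trial(trial: MarkerTrial) -> MarkerTrial:
    """Mirror marker x-coordinates about the sagittal (y-z) plane."""
    landmarks = {}
    for name, xyz in trial.landmarks.items():
        xyz = np.asarray(xyz, dtype=float).copy()
        xyz[:, 0] = -xyz[:, 0]
        landmarks[name] = xyz
    hand = "right" if trial.handedness == "left" else "left"
    return MarkerTrial(trial.time, landmarks, hand, trial.pitch_id)


def smooth_markers(
    trial: MarkerTrial, cutoff: float | None = DEFAULT_MARKER_CUTOFF
) -> MarkerTrial:
    """Zero-phase 4th-order Butterworth low-pass on every marker coordinate."""
    if cutoff is None:
        return trial
    rate = trial.rate
    if cutoff >= rate / 2:
        raise KinematicsError("cutoff must be below the Nyquist frequency")
    sos = butter(2, cutoff, btype="low", fs=rate, output="sos")
    landmarks = {
        name: sosfiltfilt(sos, np.asarray(xyz, dtype=float), axis=0)
        for name, xyz in trial.landmarks.items()
    }
    return MarkerTrial(trial.time, landmarks, trial.handedness, trial.pitch_id)


# ---------------------------------------------------------------------------
# numerical differentiation
# ---------------------------------------------------------------------------


def differentiate(series: np.ndarray, rate: float, order: int = 1) -> np.ndarray:
    """Differentiate a uniformly sampled series.

    Second-order central differences in the interior, one-sided second-order
    stencils at the ends.  ``order=2`` applies the operator twice.
    """
    series = np.asarray(series, dtype=float)
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if series.shape[0] < 3:
        raise KinematicsError("series shorter than the difference stencil")
    out = np.gradient(series, 1.0 / rate, axis=0, edge_order=2)
    if order == 2:
        out = np.gradient(out, 1.0 / rate, axis=0, edge_order=2)
    return out


def angular_velocity(basis: np.ndarray, rate: float) -> np.ndarray:
    """Angular velocity (rad/s, global frame) from a basis series.

    Extracted from the skew-symmetric part of ``R' R^T``.
    """
    basis = np.asarray(basis, dtype=float)
    rdot = np.gradient(basis, 1.0 / rate, axis=0, edge_order=2)
    omega_hat = rdot @ np.transpose(basis, (0, 2, 1))
    # anti-symmetrize to suppress numerical drift
    omega_hat = 0.5 * (omega_hat - np.transpose(omega_hat, (0, 2, 1)))
    return np.stack(
        [omega_hat[:, 2, 1], omega_hat[:, 0, 2], omega_hat[:, 1, 0]], axis=1
    )


# ---------------------------------------------------------------------------
# segment frames
# ---------------------------------------------------------------------------


@dataclass
class SegmentFrames:
    """Per-sample anatomical frames and rigid-body kinematics.

    ``bases[s]`` has shape ``(n, 3, 3)`` with columns = local axes in the
    global frame.  ``points`` carries the (smoothed) joint centres used by
    the inverse dynamics: ``shoulder``, ``elbow_centre``, ``wrist_centre``,
    ``hand_distal``.
    """

    time: np.ndarray
    rate: float
    origins: dict[str, np.ndarray]
    bases: dict[str, np.ndarray]
    ang_vel: dict[str, np.ndarray]
    ang_acc: dict[str, np.ndarray]
    points: dict[str, np.ndarray]

    def validate(self) -> None:
        for seg, basis in self.bases.items():
            rtr = np.transpose(basis, (0, 2, 1)) @ basis
            err = np.abs(rtr - np.eye(3)).max()
            if err > 1e-9:
                raise KinematicsError(
                    f"{seg}: basis not orthonormal (max |R^T R - I| = {err:.2e})"
                )
            if np.any(np.linalg.det(basis) < 0):
                raise KinematicsError(f"{seg}: basis not right-handed")


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    small = norm[..., 0] < _DEGENERATE_TOL
    if np.any(small):
        idx = int(np.argmax(small))
        raise KinematicsError(
            f"degenerate geometry for {what} at sample {idx} "
            "(collinear or coincident landmarks)"
        )
    return v / norm


def _frame_from_long_axis(
    y_raw: np.ndarray, temp: np.ndarray, seg: str
) -> np.ndarray:
    """Right-handed basis: y = unit long axis, z = temp orthogonalized, x = y x z."""
    y = _unit(y_raw, f"{seg} longitudinal axis")
    z = temp - np.sum(temp * y, axis=-1, keepdims=True) * y
    z = _unit(z, f"{seg} reference axis")
    x = np.cross(y, z)
    return np.stack([x, y, z], axis=-1)


def build_segment_frames(
    trial: MarkerTrial,
    marker_cutoff: float | None = DEFAULT_MARKER_CUTOFF,
    max_gap: int = MAX_GAP_SAMPLES,
) -> SegmentFrames:
    """Anatomical frames for hand, forearm, upper arm and thorax.

    Gap filling, left/right mirroring and marker smoothing are applied before
    frame construction.  The elbow joint centre is the midpoint of the
    humeral epicondyles; the wrist centre the midpoint of the styloids.
    """
    trial.validate()
    if trial.handedness == "left":
        trial = mirror_trial(trial)
    if trial.has_gaps():
        trial = fill_gaps(trial, max_gap=max_gap)
    trial = smooth_markers(trial, cutoff=marker_cutoff)

    lm = {k: np.asarray(v, dtype=float) for k, v in trial.landmarks.items()}
    pip3 = lm["third_proximal_interphalangeal"]
    uls = lm["ulna_styloid"]
    rds = lm["radius_styloid"]
    lhe = lm["lateral_humeral_epicondyle"]
    mhe = lm["medial_humeral_epicondyle"]
    acr = lm["acromion"]

    elbow_centre = 0.5 * (lhe + mhe)
    wrist_centre = 0.5 * (uls + rds)
    radial = rds - uls  # radial (lateral for the right arm in neutral)
    epi_line = lhe - mhe  # medial -> lateral

    bases = {
        "hand": _frame_from_long_axis(wrist_centre - pip3, radial, "hand"),
        "forearm": _frame_from_long_axis(elbow_centre - uls, radial, "forearm"),
        "upper_arm": _frame_from_long_axis(acr - elbow_centre, epi_line, "upper_arm"),
    }

    ijn = lm["suprasternal_notch"]
    c7 = lm["c7"]
    px = lm["xiphoid"]
    t8 = lm["t8"]
    up = 0.5 * (ijn + c7) - 0.5 * (px + t8)
    fwd = ijn - c7
    y_t = _unit(up, "thorax longitudinal axis")
    x_t = fwd - np.sum(fwd * y_t, axis=-1, keepdims=True) * y_t
    x_t = _unit(x_t, "thorax forward axis")
    z_t = np.cross(x_t, y_t)
    bases["thorax"] = np.stack([x_t, y_t, z_t], axis=-1)

    origins = {
        "hand": wrist_centre,
        "forearm": uls,
        "upper_arm": elbow_centre,
        "thorax": ijn,
    }
    points = {
        "shoulder": acr,
        "elbow_centre": elbow_centre,
        "wrist_centre": wrist_centre,
        "hand_distal": pip3,
    }

    rate = trial.rate
    ang_vel = {s: angular_velocity(b, rate) for s, b in bases.items()}
    ang_acc = {s: differentiate(w, rate, order=1) for s, w in ang_vel.items()}

    frames = SegmentFrames(
        time=trial.time,
        rate=rate,
        origins=origins,
        bases=bases,
        ang_vel=ang_vel,
        ang_acc=ang_acc,
        points=points,
    )
    frames.validate()
    return frames


# ---------------------------------------------------------------------------
# rotation decompositions
# ---------------------------------------------------------------------------


def compose_zxy(a: float, b: float, c: float) -> np.ndarray:
    """R = Rz(a) @ Rx(b) @ Ry(c) (intrinsic z-x'-y'')."""
    return _rot_z(a) @ _rot_x(b) @ _rot_y(c)


def compose_yxy(a: float, b: float, c: float) -> np.ndarray:
    """R = Ry(a) @ Rx(b) @ Ry(c) (intrinsic y-x'-y'')."""
    return _rot_y(a) @ _rot_x(b) @ _rot_y(c)


def _rot_x(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def euler_zxy(R: np.ndarray) -> np.ndarray:
    """Angles (a, b, c) with R = Rz(a) Rx(b) Ry(c); vectorized over leading axes."""
    R = np.asarray(R, dtype=float)
    b = np.arcsin(np.clip(R[..., 2, 1], -1.0, 1.0))
    a = np.arctan2(-R[..., 0, 1], R[..., 1, 1])
    c = np.arctan2(-R[..., 2, 0], R[..., 2, 2])
    return np.stack([a, b, c], axis=-1)


def euler_yxy(R: np.ndarray) -> np.ndarray:
    """Angles (a, b, c) with R = Ry(a) Rx(b) Ry(c); vectorized over leading axes."""
    R = np.asarray(R, dtype=float)
    b = np.arccos(np.clip(R[..., 1, 1], -1.0, 1.0))
    a = np.arctan2(R[..., 0, 1], R[..., 2, 1])
    c = np.arctan2(R[..., 1, 0], -R[..., 1, 2])
    return np.stack([a, b, c], axis=-1)


# ---------------------------------------------------------------------------
# joint angles
# ---------------------------------------------------------------------------


@dataclass
class JointAngleSeries:
    """Unwrapped elbow and shoulder joint angles in radians.

    ``elbow`` columns: flexion/extension, ab/adduction (floating axis),
    pronation/supination.  ``shoulder`` columns: plane of elevation,
    negative elevation, axial rotation (y-x-y Euler).
    """

    time: np.ndarray
    elbow: np.ndarray
    shoulder: np.ndarray
    gimbal_flags: np.ndarray = field(default=None)


def joint_angles(
    frames: SegmentFrames,
    gimbal_tol: float = 1e-3,
    max_gimbal_run: int = 3,
) -> JointAngleSeries:
    """Elbow (floating-axis JCS) and shoulder (y-x-y) joint angles.

    The elbow decomposition is built geometrically: e1 = upper-arm flexion
    axis (local z), e3 = forearm longitudinal axis (local y), floating axis
    e2 = e3 x e1 / ||e3 x e1||, which is orthogonal to both body-fixed axes
    by construction.  Samples closer than ``gimbal_tol`` to a singularity are
    interpolated if isolated; runs longer than ``max_gimbal_run`` raise.
    """
    r_ua = frames.bases["upper_arm"]
    r_fa = frames.bases["forearm"]
    r_th = frames.bases["thorax"]

    e1 = r_ua[:, :, 2]  # upper-arm z: flexion axis
    e3 = r_fa[:, :, 1]  # forearm y: pronation axis
    cross = np.cross(e3, e1)
    cross_norm = np.linalg.norm(cross, axis=1)
    elbow_singular = cross_norm < gimbal_tol
    e2 = cross / np.maximum(cross_norm, _DEGENERATE_TOL)[:, None]

    x_ua, y_ua = r_ua[:, :, 0], r_ua[:, :, 1]
    x_fa, z_fa = r_fa[:, :, 0], r_fa[:, :, 2]
    flexion = np.arctan2(np.sum(e2 * y_ua, axis=1), np.sum(e2 * x_ua, axis=1))
    abduction = np.arcsin(np.clip(np.sum(e1 * e3, axis=1), -1.0, 1.0))
    pronation = np.arctan2(np.sum(e2 * z_fa, axis=1), np.sum(e2 * x_fa, axis=1))
    elbow = np.stack([flexion, abduction, pronation], axis=1)

    r_sh = np.transpose(r_th, (0, 2, 1)) @ r_ua
    shoulder = euler_yxy(r_sh)
    shoulder_singular = np.abs(np.sin(shoulder[:, 1])) < gimbal_tol

    elbow = _patch_singular(elbow, elbow_singular, "elbow", max_gimbal_run, frames.time)
    shoulder = _patch_singular(
        shoulder, shoulder_singular, "shoulder", max_gimbal_run, frames.time
    )

    elbow = np.unwrap(elbow, axis=0)
    shoulder = np.unwrap(shoulder, axis=0)
    return JointAngleSeries(
        time=frames.time,
        elbow=elbow,
        shoulder=shoulder,
        gimbal_flags=elbow_singular | shoulder_singular,
    )


def _patch_singular(
    angles: np.ndarray,
    singular: np.ndarray,
    joint: str,
    max_run: int,
    time: np.ndarray,
) -> np.ndarray:
    if not singular.any():
        return angles
    for start, stop in _bool_runs(singular):
        if stop - start > max_run or start == 0 or stop == len(singular):
            raise GimbalError(
                f"{joint}: sustained gimbal proximity over samples "
                f"[{start}, {stop})"
            )
    out = np.unwrap(angles, axis=0)
    good = ~singular
    for k in range(out.shape[1]):
        out[singular, k] = np.interp(time[singular], time[good], out[good, k])
    return out


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------


@dataclass
class EventSet:
    mer_index: int
    mer_time: float
    flags: tuple[str, ...] = ()


def detect_mer(angles: JointAngleSeries) -> EventSet:
    """Instant of maximal external shoulder rotation.

    External rotation is the negative axial-rotation direction for a
    (mirrored-to-)right-handed thrower, so MER is the minimum of the
    unwrapped axial-rotation series; ties resolve to the earliest sample.
    """
    axial = angles.shoulder[:, 2]
    if axial.size == 0:
        raise KinematicsError("empty axial rotation series")
    idx = int(np.argmin(axial))
    flags: tuple[str, ...] = ()
    if idx in (0, axial.size - 1):
        warnings.warn(
            "MER extremum on the trial boundary; pitch likely truncated",
            stacklevel=2,
        )
        flags = ("mer_on_boundary",)
    return EventSet(mer_index=idx, mer_time=float(angles.time[idx]), flags=flags)
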