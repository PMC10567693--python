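"""Shared fixtures and independent oracle builders.

The marker builders here construct trials directly from geometry (not via
the synthetic module's motion program) so tests of the kinematics/dynamics
chain do not depend on the code path they are checking.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pitchload.kinematics import MarkerTrial

RATE = 120.0

TRUNK_BASE = {
    "suprasternal_notch": np.array([0.0, 0.0, 1.45]),
    "c7": np.array([0.0, -0.08, 1.47]),
    "xiphoid": np.array([0.0, 0.03, 1.27]),
    "t8": np.array([0.0, -0.08, 1.29]),
}


def make_static_trial(
    pose: dict[str, np.ndarray], n: int = 30, rate: float = RATE
) -> MarkerTrial:
    """Constant-in-time trial from a single pose (all landmarks required)."""
    t = np.arange(n) / rate
    landmarks = {k: np.tile(np.asarray(v, float), (n, 1)) for k, v in pose.items()}
    return MarkerTrial(t, landmarks)


def canonical_arm_pose(
    forearm_dir: np.ndarray | None = None,
    flexion_axis: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """A well-conditioned right-arm pose; directions may be overridden."""
    if forearm_dir is None:
        forearm_dir = np.array([0.1, 0.95, 0.25])
    if flexion_axis is None:
        flexion_axis = np.array([0.9, -0.1, 0.3])
    u = np.asarray(forearm_dir, float)
    u = u / np.linalg.norm(u)
    z = np.asarray(flexion_axis, float)
    z = z - (z @ u) * u
    z = z / np.linalg.norm(z)

    p_s = np.array([0.2, 0.0, 1.5])
    p_e = p_s + np.array([0.30, 0.05, -0.12])
    p_w = p_e + 0.27 * u
    pip3 = p_w + 0.20 * u
    pose = {
        "acromion": p_s,
        "lateral_humeral_epicondyle": p_e + 0.035 * z,
        "medial_humeral_epicondyle": p_e - 0.035 * z,
        "radius_styloid": p_w + 0.025 * z,
        "ulna_styloid": p_w - 0.025 * z,
        "third_proximal_interphalangeal": pip3,
    }
    pose.update(TRUNK_BASE)
    return pose


def random_rigid_pose(rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Canonical pose under a random rigid motion (always valid geometry)."""
    pose = canonical_arm_pose(
        forearm_dir=rng.normal(size=3), flexion_axis=rng.normal(size=3)
    )
    q = Rotation.random(rng=rng).as_matrix()
    tr = rng.uniform(-0.5, 0.5, 3)
    return {k: q @ v + tr for k, v in pose.items()}


def make_pendulum_trial(
    theta: np.ndarray,
    rate: float = RATE,
    l_fa: float = 0.27,
    l_h: float = 0.20,
) -> MarkerTrial:
    """Forearm+hand swinging about a fixed global-x axis through the elbow;
    upper arm static vertical.  ``theta`` measured from straight down, in the
    global y-z plane."""
    n = theta.size
    t = np.arange(n) / rate
    p_s = np.array([0.0, 0.0, 1.8])
    p_e = p_s + np.array([0.0, 0.0, -0.34])
    u = np.stack([np.zeros(n), np.sin(theta), -np.cos(theta)], axis=1)
    p_w = p_e + l_fa * u
    pip3 = p_w + l_h * u
    zax = np.tile(np.array([1.0, 0.0, 0.0]), (n, 1))
    landmarks = {
        "acromion": np.tile(p_s, (n, 1)),
        "lateral_humeral_epicondyle": np.tile(p_e, (n, 1)) + 0.035 * zax,
        "medial_humeral_epicondyle": np.tile(p_e, (n, 1)) - 0.035 * zax,
        "radius_styloid": p_w + 0.025 * zax,
        "ulna_styloid": p_w - 0.025 * zax,
        "third_proximal_interphalangeal": pip3,
    }
    for k, v in TRUNK_BASE.items():
        landmarks[k] = np.tile(v + np.array([0.0, -0.05, -0.35]), (n, 1))
    return MarkerTrial(t, landmarks)


def gravitational_elbow_moment(frames, anthro, g=np.array([0.0, 0.0, -9.81])):
    """Closed-form static elbow moment: the joint moment balancing gravity
    on the forearm+hand, taken about the elbow centre.  Independent of the
    Newton-Euler recursion."""
    p_e = frames.points["elbow_centre"][0]
    p_w = frames.points["wrist_centre"][0]
    pip3 = frames.points["hand_distal"][0]
    m_f = anthro.segment_mass("forearm")
    m_h = anthro.segment_mass("hand")
    com_f = p_e + anthro.segments["forearm"].com_fraction * (p_w - p_e)
    com_h = p_w + anthro.segments["hand"].com_fraction * (pip3 - p_w)
    return -np.cross(com_f - p_e, m_f * g) - np.cross(com_h - p_e, m_h * g)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
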