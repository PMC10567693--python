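"""Segment inertial scaling and top-down Newton-Euler inverse dynamics.

Net elbow force and torque are propagated from the free (hand) end in the
global frame, the elbow torque is then expressed in the elbow anatomical
frame (origin at the midpoint of the humeral epicondyles) and its component
along the floating (ab/adduction) axis is reported as the signed external
valgus torque.  The scalar per-pitch outcome is the quadratic-refined peak
of that component near MER.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import EventSet, SegmentFrames, differentiate

GRAVITY = np.array([0.0, 0.0, -9.81])

#: adjusted segment inertia fractions (male), after De Leva's revision of the
#: Zatsiorsky-Seluyanov gamma-scanner tables.  Per segment: mass fraction of
#: body mass; COM position as a fraction of segment length from the proximal
#: end; radii of gyration about the sagittal, transverse and longitudinal
#: axes as fractions of segment length.
DE_LEVA_MALE = {
    "hand": {"mass": 0.0061, "com": 0.7900, "rg": (0.628, 0.513, 0.401)},
    "forearm": {"mass": 0.0162, "com": 0.4574, "rg": (0.276, 0.265, 0.121)},
    "upper_arm": {"mass": 0.0271, "com": 0.5772, "rg": (0.285, 0.269, 0.158)},
}

TABLES = {"de_leva_male": DE_LEVA_MALE}

# Sign chosen so that a positive value is an *external valgus* torque
# (loading the medial elbow) for a right-handed thrower after mirroring.
VALGUS_SIGN = 1.0


class DynamicsError(ValueError):
    pass


@dataclass
class SegmentParams:
    mass_fraction: float
    com_fraction: float
    rg_fractions: tuple[float, float, float]  # sagittal, transverse, longitudinal


@dataclass
class AnthroParams:
    """Body-level anthropometrics plus per-segment scaling fractions."""

    body_mass: float
    body_height: float
    segments: dict[str, SegmentParams]
    table_id: str = "de_leva_male"

    def segment_mass(self, segment: str) -> float:
        return self.segments[segment].mass_fraction * self.body_mass


def scale_segments(
    body_mass: float, body_height: float, table_id: str = "de_leva_male"
) -> AnthroParams:
    """Segment inertial parameters from body mass and height.

    Segment masses are fractions of body mass; COM positions and radii of
    gyration are fractions of the measured segment lengths (taken from the
    marker data at analysis time, so only the fractions are stored here).
    """
    if not np.isfinite(body_mass) or body_mass <= 0:
        raise DynamicsError(f"body_mass must be positive, got {body_mass}")
    if not np.isfinite(body_height) or body_height <= 0:
        raise DynamicsError(f"body_height must be positive, got {body_height}")
    try:
        table = TABLES[table_id]
    except KeyError:
        raise DynamicsError(
            f"unknown table {table_id!r}; available: {sorted(TABLES)}"
        ) from None
    segments = {
        seg: SegmentParams(row["mass"], row["com"], tuple(row["rg"]))
        for seg, row in table.items()
    }
    return AnthroParams(body_mass, body_height, segments, table_id)


@dataclass
class TorqueSeries:
    """Elbow net force (global) and net torque (elbow anatomical frame)."""

    time: np.ndarray
    force: np.ndarray  # (n, 3) N, global frame
    torque_anatomical: np.ndarray  # (n, 3) N*m on (flexion, floating, pronation)
    valgus: np.ndarray  # (n,) signed external valgus component, N*m
    torque_global: np.ndarray  # (n, 3) N*m

    def validate(self) -> None:
        for name in ("force", "torque_anatomical", "valgus"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise DynamicsError(f"non-finite values in {name}")


# chain from the free end inward: (segment, proximal point, distal point)
_CHAIN = (
    ("hand", "wrist_centre", "hand_distal"),
    ("forearm", "elbow_centre", "wrist_centre"),
)


def newton_euler_topdown(
    frames: SegmentFrames,
    anthro: AnthroParams,
    gravity: np.ndarray = GRAVITY,
) -> TorqueSeries:
    """Propagate Newton-Euler force/moment balances from the hand to the elbow.

    For each segment, in the global frame::

        F_prox = m a_com - m g - F_dist
        M_prox = I w' + w x (I w) - M_dist
                 - (r_prox - r_com) x F_prox - (r_dist - r_com) x F_dist

    where ``F_dist``/``M_dist`` is the load applied by the more distal
    segment (zero at the hand).  The elbow torque is the moment exerted on
    the forearm at the elbow centre, re-expressed on the elbow joint
    coordinate axes (flexion axis, floating axis, pronation axis).
    """
    gravity = np.asarray(gravity, dtype=float)
    for seg in ("hand", "forearm", "upper_arm"):
        if seg not in frames.bases:
            raise DynamicsError(f"frames missing segment {seg!r}")
        if seg not in frames.ang_vel or seg not in frames.ang_acc:
            raise DynamicsError(f"frames missing derivative series for {seg!r}")
    frames.validate()
    rate = frames.rate
    n = frames.time.size

    f_dist = np.zeros((n, 3))
    m_dist = np.zeros((n, 3))
    f_prox = np.zeros((n, 3))
    m_prox = np.zeros((n, 3))

    for seg, prox_name, dist_name in _CHAIN:
        params = anthro.segments[seg]
        mass = params.mass_fraction * anthro.body_mass
        r_prox = frames.points[prox_name]
        r_dist = frames.points[dist_name]
        length = float(np.mean(np.linalg.norm(r_dist - r_prox, axis=1)))
        r_com = r_prox + params.com_fraction * (r_dist - r_prox)
        a_com = differentiate(r_com, rate, order=2)

        rg = np.asarray(params.rg_fractions) * length
        # local principal inertia: (sagittal, transverse) -> x, z; longitudinal -> y
        i_local = np.diag(mass * np.array([rg[0] ** 2, rg[2] ** 2, rg[1] ** 2]))
        basis = frames.bases[seg]
        i_glob = basis @ i_local @ np.transpose(basis, (0, 2, 1))
        omega = frames.ang_vel[seg]
        alpha = frames.ang_acc[seg]

        f_prox = mass * (a_com - gravity) - f_dist
        h_dot = np.einsum("nij,nj->ni", i_glob, alpha) + np.cross(
            omega, np.einsum("nij,nj->ni", i_glob, omega)
        )
        m_prox = (
            h_dot
            - m_dist
            - np.cross(r_prox - r_com, f_prox)
            - np.cross(r_dist - r_com, f_dist)
        )
        # reaction applied by this segment on the next proximal one
        f_dist = -f_prox
        m_dist = -m_prox

    # elbow anatomical axes from the joint coordinate system
    e1 = frames.bases["upper_arm"][:, :, 2]  # flexion axis
    e3 = frames.bases["forearm"][:, :, 1]  # pronation axis
    e2 = np.cross(e3, e1)
    e2 = e2 / np.linalg.norm(e2, axis=1, keepdims=True)

    torque_anat = np.stack(
        [
            np.sum(m_prox * e1, axis=1),
            np.sum(m_prox * e2, axis=1),
            np.sum(m_prox * e3, axis=1),
        ],
        axis=1,
    )
    valgus = VALGUS_SIGN * torque_anat[:, 1]
    series = TorqueSeries(
        time=frames.time,
        force=f_prox,
        torque_anatomical=torque_anat,
        valgus=valgus,
        torque_global=m_prox,
    )
    series.validate()
    return series


@dataclass
class PeakTorque:
    value: float
    time: float
    fit_window_indices: tuple[int, ...]
    flags: tuple[str, ...] = ()


def peak_valgus(
    torque: TorqueSeries,
    events: EventSet,
    search_window: float = 0.05,
) -> PeakTorque:
    """Quadratic-refined peak external valgus torque near MER.

    The discrete maximum of the valgus component is located within
    ``+/- search_window`` seconds of MER; a 2nd-order polynomial is fitted by
    least squares to the five samples centred on it and the vertex is
    returned when it lies inside the fit span with negative curvature,
    otherwise the discrete maximum is returned flagged.
    """
    t = torque.time
    v = torque.valgus
    if v.size < 5:
        raise DynamicsError("need at least 5 samples for peak refinement")
    lo = np.searchsorted(t, events.mer_time - search_window, side="left")
    hi = np.searchsorted(t, events.mer_time + search_window, side="right")
    if hi - lo < 1:
        raise DynamicsError("empty peak search window around MER")
    idx = lo + int(np.argmax(v[lo:hi]))

    if idx < 2 or idx > v.size - 3:
        return PeakTorque(
            value=float(v[idx]),
            time=float(t[idx]),
            fit_window_indices=(idx,),
            flags=("peak_on_boundary",),
        )

    window = np.arange(idx - 2, idx + 3)
    tw = t[window] - t[idx]  # centre for conditioning
    coeffs = np.polyfit(tw, v[window], 2)
    a, b, _ = coeffs
    span = tw[-1] - tw[0]
    curv_tol = 1e-8 * max(1.0, abs(float(v[idx]))) / span**2
    if a < -curv_tol:
        t_vertex = -b / (2 * a)
        if tw[0] <= t_vertex <= tw[-1]:
            value = float(np.polyval(coeffs, t_vertex))
            return PeakTorque(
                value=value,
                time=float(t_vertex + t[idx]),
                fit_window_indices=tuple(int(i) for i in window),
            )
    return PeakTorque(
        value=float(v[idx]),
        time=float(t[idx]),
        fit_window_indices=tuple(int(i) for i in window),
        flags=("no_refinement",),
    )
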