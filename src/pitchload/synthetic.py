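"""Synthetic pitch-session generator with known ground truth.

Every downstream stage (frames, angles, MER, inverse dynamics, EMG
summaries, synchronization, windows, mixed models) is testable without real
recordings: sessions of block-structured fastball pitches are generated for
multiple pitchers with per-pitcher random intercepts and slopes in torque
magnitude/variability and muscle activity, EMG bursts spanning the 150 ms
pre-MER window, and device clock offsets between the signal and mocap
timebases.

The throwing-arm motion is a smooth parameterized program built from
``sin^4`` basis bumps (twice continuously differentiable, so numerical
differentiation is well behaved): the trunk translates forward with a single
acceleration bump peaking ~50 ms before MER, the shoulder is held abducted
while its axial rotation dips to an extreme exactly at ``mer_time``, and the
elbow is held flexed at 90 deg.  With that geometry the elbow's floating
(ab/adduction) axis coincides with the humeral long axis, so the axial
acceleration reversal at MER loads the valgus axis directly.  The mapping
from a requested true peak valgus torque to the motion amplitude has no
convenient closed form for the 3-segment chain and is instead calibrated
numerically per participant by running the actual inverse-dynamics pipeline
over an amplitude grid.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, sosfiltfilt

from . import dynamics, kinematics
from .emg import SignalTrial
from .kinematics import MarkerTrial

# geometry constants (m); segment lengths as fractions of body height
UPPER_ARM_FRACTION = 0.186
FOREARM_FRACTION = 0.146
HAND_FRACTION = 0.108
EPICONDYLE_WIDTH = 0.07
WRIST_WIDTH = 0.05

TRUNK_ACCEL_AMP = 30.0  # m/s^2, forward trunk acceleration bump
TRUNK_BUMP_WIDTH = 0.2  # s
FOOT_CONTACT_LEAD = 0.05  # s before MER
ROTATION_BUMP_WIDTH = 0.3  # s, shoulder axial-rotation dip
AUC_WINDOW = 0.150  # s
EMD = 0.050  # s
SIN4_MEAN = 0.375  # mean of sin^4 over its support


class GenerationError(ValueError):
    pass


class CalibrationError(GenerationError):
    pass


# ---------------------------------------------------------------------------
# smooth basis
# ---------------------------------------------------------------------------


def sin4_bump(t: np.ndarray, centre: float, width: float) -> np.ndarray:
    """C^2 unit bump sin^4(pi (t - t0) / width) supported on [t0, t0 + width]."""
    t = np.asarray(t, dtype=float)
    t0 = centre - width / 2
    phase = (t - t0) / width
    out = np.zeros_like(t)
    inside = (phase > 0) & (phase < 1)
    out[inside] = np.sin(np.pi * phase[inside]) ** 4
    return out


def _double_integral(series: np.ndarray, rate: float) -> np.ndarray:
    from scipy.integrate import cumulative_trapezoid

    v = cumulative_trapezoid(series, dx=1.0 / rate, initial=0.0)
    return cumulative_trapezoid(v, dx=1.0 / rate, initial=0.0)


# ---------------------------------------------------------------------------
# session specification
# ---------------------------------------------------------------------------


@dataclass
class SessionSpec:
    """Parameters of a synthetic multi-pitcher session.

    Distributional defaults are placeholders chosen to keep the
    parameter-recovery harness well conditioned (no population values are
    published for the emulated protocol); sessions of 60-110 pitches in
    10-pitch blocks mirror its structure.
    """

    n_participants: int = 3
    pitches_per_participant: int = 60
    block_size: int = 10
    mocap_rate: float = 120.0
    emg_rate: float = 2000.0
    participant_anthro: list[tuple[float, float]] | None = None
    torque_intercept_mean: float = 40.0
    torque_intercept_sd: float = 8.0
    torque_slope_mean: float = 0.0
    torque_slope_sd: float = 0.04
    torque_residual_sd: float = 2.0
    variability_slope_sd: float = 0.01
    fpm_intercept_mean: float = 0.08
    fpm_intercept_sd: float = 0.02
    fpm_slope_mean: float = 0.0
    fpm_slope_sd: float = 0.0008
    cci_intercept_mean: float = 0.045
    cci_intercept_sd: float = 0.01
    cci_slope_mean: float = 0.0
    cci_slope_sd: float = 0.0003
    ball_speed_mean: float = 67.0
    ball_speed_sd: float = 4.0
    ball_speed_residual_sd: float = 1.0
    emg_residual_frac: float = 0.05
    device_offset_range: tuple[float, float] = (-0.5, 0.5)
    dropout_prob: float = 0.0
    mer_time: float = 0.6
    mer_jitter: float = 0.02
    duration: float = 1.0
    emg_noise: bool = False
    rng_seed: int = 0

    def validate(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name in ("participant_anthro",):
                continue
            if isinstance(value, (int, float)) and not np.isfinite(value):
                raise GenerationError(f"spec field {f.name!r} is not finite")
        if self.n_participants < 1:
            raise GenerationError("n_participants must be >= 1")
        if self.pitches_per_participant < self.block_size:
            raise GenerationError(
                "pitches_per_participant must be >= block_size"
            )
        if self.mocap_rate <= 0 or self.emg_rate <= 0:
            raise GenerationError("sampling rates must be positive")
        for name in (
            "torque_intercept_sd",
            "torque_slope_sd",
            "torque_residual_sd",
            "variability_slope_sd",
            "fpm_intercept_sd",
            "fpm_slope_sd",
            "cci_intercept_sd",
            "cci_slope_sd",
            "ball_speed_sd",
            "ball_speed_residual_sd",
        ):
            if getattr(self, name) < 0:
                raise GenerationError(f"spec field {name!r} must be >= 0")
        lo, hi = self.device_offset_range
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
            raise GenerationError("device_offset_range must be finite (lo, hi)")
        if not 0 <= self.dropout_prob < 1:
            raise GenerationError("dropout_prob must be in [0, 1)")
        if self.participant_anthro is not None:
            if len(self.participant_anthro) != self.n_participants:
                raise GenerationError(
                    "participant_anthro length must equal n_participants"
                )
            for mass, height in self.participant_anthro:
                if mass <= 0 or height <= 0:
                    raise GenerationError(
                        "participant_anthro entries must be positive"
                    )


@dataclass
class GroundTruth:
    """Lossless record of every draw behind a generated session."""

    participants: pd.DataFrame
    pitches: pd.DataFrame
    spec: SessionSpec = None


# ---------------------------------------------------------------------------
# truth model (fast path: no marker realization)
# ---------------------------------------------------------------------------


def generate_outcome_table(
    spec: SessionSpec, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Per-pitch true outcome values from the random-effects truth model.

    For pitch p of participant j the torque truth is

        torque_jp = (b0 + u0_j) + (b1 + u1_j) * p + e_jp,
        e_jp ~ N(0, sd_jp),  sd_jp = max(sigma_e + v1_j * p, 0.05 * sigma_e)

    where p (the 1-based pitch index) is the trend predictor; window means
    computed over any 10 consecutive pitches then carry the same slope per
    window number.  EMG AUC and ball-speed truths follow the analogous
    intercept+slope models, clipped to be positive.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)

    n, p_count = spec.n_participants, spec.pitches_per_participant
    if spec.participant_anthro is not None:
        anthro = list(spec.participant_anthro)
    else:
        masses = np.clip(rng.normal(79.4, 9.2, n), 55.0, 110.0)
        heights = np.clip(rng.normal(1.91, 0.05, n), 1.70, 2.10)
        anthro = list(zip(masses, heights))

    participants = pd.DataFrame(
        {
            "participant": [f"P{j + 1:02d}" for j in range(n)],
            "body_mass": [a[0] for a in anthro],
            "body_height": [a[1] for a in anthro],
            "torque_intercept": rng.normal(
                spec.torque_intercept_mean, spec.torque_intercept_sd, n
            ),
            "torque_slope": rng.normal(
                spec.torque_slope_mean, spec.torque_slope_sd, n
            ),
            "variability_slope": rng.normal(0.0, spec.variability_slope_sd, n),
            "fpm_intercept": rng.normal(
                spec.fpm_intercept_mean, spec.fpm_intercept_sd, n
            ),
            "fpm_slope": rng.normal(spec.fpm_slope_mean, spec.fpm_slope_sd, n),
            "cci_intercept": rng.normal(
                spec.cci_intercept_mean, spec.cci_intercept_sd, n
            ),
            "cci_slope": rng.normal(spec.cci_slope_mean, spec.cci_slope_sd, n),
            "ball_speed_intercept": rng.normal(
                spec.ball_speed_mean, spec.ball_speed_sd, n
            ),
        }
    )

    lo, hi = spec.device_offset_range
    rows = []
    for j in range(n):
        part = participants.iloc[j]
        for p in range(1, p_count + 1):
            sd = max(
                spec.torque_residual_sd + part["variability_slope"] * p,
                0.05 * spec.torque_residual_sd if spec.torque_residual_sd > 0 else 0.0,
            )
            torque = (
                part["torque_intercept"]
                + part["torque_slope"] * p
                + rng.normal(0.0, sd)
            )
            # keep physically realizable targets inside the calibration range
            torque = float(np.clip(torque, 3.0, 150.0))
            fpm = part["fpm_intercept"] + part["fpm_slope"] * p
            fpm *= 1.0 + rng.normal(0.0, spec.emg_residual_frac)
            cci = part["cci_intercept"] + part["cci_slope"] * p
            cci *= 1.0 + rng.normal(0.0, spec.emg_residual_frac)
            rows.append(
                {
                    "participant": part["participant"],
                    "pitch_number": p,
                    "block": (p - 1) // spec.block_size + 1,
                    "trend_index": p,
                    "true_peak_valgus": torque,
                    "fpm_auc": max(float(fpm), 1e-4),
                    "cci_auc": max(float(cci), 1e-4),
                    "ball_speed": part["ball_speed_intercept"]
                    + rng.normal(0.0, spec.ball_speed_residual_sd),
                    "mer_time": spec.mer_time
                    + rng.uniform(-spec.mer_jitter, spec.mer_jitter),
                    "device_offset": rng.uniform(lo, hi),
                    "valid": bool(rng.random() >= spec.dropout_prob),
                }
            )
    pitches = pd.DataFrame(rows)
    return GroundTruth(participants=participants, pitches=pitches, spec=spec)


# ---------------------------------------------------------------------------
# kinematic program -> marker trajectories
# ---------------------------------------------------------------------------

# thorax basis columns (x fwd, y up, z right-lateral) in the global frame
# with forward = +Y, up = +Z, right = +X
_R_THORAX = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
_SHOULDER_OFFSET = np.array([-0.05, -0.03, 0.20])  # thorax-local


def pitch_markers(
    amplitude: float,
    mer_time: float,
    body_height: float,
    rate: float = 120.0,
    duration: float = 1.0,
    trunk_accel_amp: float = TRUNK_ACCEL_AMP,
    pitch_id: str = "",
) -> MarkerTrial:
    """Marker trajectories for one pitch of the parameterized motion program.

    ``amplitude`` (rad) scales the shoulder axial-rotation dip whose extreme
    falls exactly at ``mer_time``; ``amplitude = 0`` with
    ``trunk_accel_amp = 0`` yields a static arm (the pure-gravity case).
    """
    if not np.isfinite(amplitude):
        raise GenerationError("amplitude must be finite")
    if rate <= 0:
        raise GenerationError("rate must be positive")
    if body_height <= 0:
        raise GenerationError("body_height must be positive")

    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate

    l_ua = UPPER_ARM_FRACTION * body_height
    l_fa = FOREARM_FRACTION * body_height
    l_h = HAND_FRACTION * body_height

    # trunk forward translation from an analytic acceleration bump
    tc = mer_time - FOOT_CONTACT_LEAD
    acc = trunk_accel_amp * sin4_bump(t, tc, TRUNK_BUMP_WIDTH)
    s = _double_integral(acc, rate)
    p_t = np.zeros((n, 3))
    p_t[:, 1] = s  # forward = +Y
    p_t[:, 2] = 1.40  # suprasternal-notch height

    # shoulder axial rotation: dip to -amplitude at mer_time
    c = -amplitude * sin4_bump(t, mer_time, ROTATION_BUMP_WIDTH)

    cos_c, sin_c = np.cos(c), np.sin(c)
    # humeral basis columns for a = 0, b = -pi/2, axial rotation c(t)
    x_ua = np.stack([np.zeros(n), cos_c, -sin_c], axis=1)
    y_ua = np.tile(np.array([-1.0, 0.0, 0.0]), (n, 1))
    z_ua = np.stack([np.zeros(n), sin_c, cos_c], axis=1)

    p_s = p_t + _R_THORAX @ _SHOULDER_OFFSET
    p_e = p_s - l_ua * y_ua

    # elbow flexed 90 deg: forearm long axis along x_ua, z_fa = z_ua
    fa_dir = x_ua  # elbow -> wrist
    p_w = p_e + l_fa * fa_dir
    pip3 = p_w + l_h * fa_dir

    landmarks = {
        "acromion": p_s.copy(),
        "lateral_humeral_epicondyle": p_e + 0.5 * EPICONDYLE_WIDTH * z_ua,
        "medial_humeral_epicondyle": p_e - 0.5 * EPICONDYLE_WIDTH * z_ua,
        "radius_styloid": p_w + 0.5 * WRIST_WIDTH * z_ua,
        "ulna_styloid": p_w - 0.5 * WRIST_WIDTH * z_ua,
        "third_proximal_interphalangeal": pip3,
        "suprasternal_notch": p_t.copy(),
        "c7": p_t + _R_THORAX @ np.array([-0.08, 0.02, 0.0]),
        "xiphoid": p_t + _R_THORAX @ np.array([0.03, -0.18, 0.0]),
        "t8": p_t + _R_THORAX @ np.array([-0.08, -0.16, 0.0]),
    }
    return MarkerTrial(t, landmarks, handedness="right", pitch_id=pitch_id)


class TorqueCalibration:
    """Numeric map from true peak valgus torque to motion amplitude.

    Built once per participant by running the full marker -> frames ->
    inverse-dynamics -> peak pipeline over an amplitude grid and inverting
    the resulting monotone peak curve with a PCHIP interpolant.
    """

    def __init__(
        self,
        body_mass: float,
        body_height: float,
        rate: float = 120.0,
        duration: float = 1.0,
        mer_time: float = 0.6,
        amplitudes: np.ndarray | None = None,
    ) -> None:
        self.anthro = dynamics.scale_segments(body_mass, body_height)
        self.rate = rate
        self.duration = duration
        if amplitudes is None:
            amplitudes = np.linspace(0.1, 2.8, 8)
        peaks = np.array(
            [
                self._pipeline_peak(a, mer_time, body_height)
                for a in amplitudes
            ]
        )
        if not np.all(np.diff(peaks) > 0):
            raise CalibrationError(
                "pipeline peak torque is not monotone in motion amplitude"
            )
        self.amplitudes = amplitudes
        self.peaks = peaks
        self._inverse = PchipInterpolator(peaks, amplitudes)

    def _pipeline_peak(
        self, amplitude: float, mer_time: float, body_height: float
    ) -> float:
        trial = pitch_markers(
            amplitude, mer_time, body_height, self.rate, self.duration
        )
        frames = kinematics.build_segment_frames(trial)
        angles = kinematics.joint_angles(frames)
        events = kinematics.detect_mer(angles)
        torque = dynamics.newton_euler_topdown(frames, self.anthro)
        return dynamics.peak_valgus(torque, events).value

    def amplitude_for(self, true_peak_torque: float) -> float:
        if not np.isfinite(true_peak_torque):
            raise GenerationError("true_peak_torque must be finite")
        if not (self.peaks[0] <= true_peak_torque <= self.peaks[-1]):
            raise CalibrationError(
                f"target torque {true_peak_torque:.2f} N*m outside the "
                f"calibrated range [{self.peaks[0]:.2f}, {self.peaks[-1]:.2f}]"
            )
        return float(self._inverse(true_peak_torque))


def generate_pitch_markers(
    true_peak_torque: float,
    mer_time: float,
    anthro: tuple[float, float],
    rate: float = 120.0,
    duration: float = 1.0,
    calibration: TorqueCalibration | None = None,
    pitch_id: str = "",
) -> MarkerTrial:
    """Markers for one pitch whose inverse-dynamics peak valgus torque is
    ``true_peak_torque`` (within calibration interpolation error).

    ``anthro`` is ``(body_mass kg, body_height m)``.  Pass a shared
    :class:`TorqueCalibration` when generating many pitches for the same
    participant to avoid repeated calibration runs.
    """
    body_mass, body_height = anthro
    if body_mass <= 0 or body_height <= 0:
        raise GenerationError("anthro mass and height must be positive")
    if calibration is None:
        calibration = TorqueCalibration(
            body_mass, body_height, rate=rate, duration=duration, mer_time=mer_time
        )
    amplitude = calibration.amplitude_for(true_peak_torque)
    return pitch_markers(
        amplitude, mer_time, body_height, rate, duration, pitch_id=pitch_id
    )


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------


def _bandlimited_carrier(
    n: int, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian carrier band-limited to 25-500 Hz."""
    white = rng.standard_normal(n)
    high = min(500.0, 0.45 * rate)
    sos = butter(2, [25.0, high], btype="bandpass", fs=rate, output="sos")
    carrier = sosfiltfilt(sos, white)
    return carrier / np.std(carrier)


def generate_pitch_signals(
    emg_truth: dict[str, float],
    mer_time: float,
    offset: float,
    rate: float = 2000.0,
    duration: float = 1.0,
    pad: float = 0.8,
    noise: bool = False,
    rng: np.random.Generator | None = None,
    trunk_accel_amp: float = TRUNK_ACCEL_AMP,
    accel_noise_sd: float = 0.02,
    pitch_id: str = "",
) -> SignalTrial:
    """EMG + accelerometer channels for one pitch in the device clock.

    ``emg_truth`` holds target AUC values (normalized*s) under keys
    ``fpm_auc`` and ``cci_auc``; bursts are sin^4 envelopes supported exactly
    on the EMD-compensated 150 ms analysis window, so the noise-free
    rectified-filtered AUC equals the target up to filter distortion.  The
    accelerometer trace is the trunk forward acceleration delayed by
    ``offset``; the device clock reads mocap time + offset.
    """
    if rate <= 0:
        raise GenerationError("rate must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    fpm_auc = float(emg_truth.get("fpm_auc", 0.0))
    cci_auc = float(emg_truth.get("cci_auc", 0.0))
    if fpm_auc < 0 or cci_auc < 0:
        raise GenerationError("EMG truth AUCs must be >= 0")

    n = int(round((duration + 2 * pad) * rate)) + 1
    t = -pad + np.arange(n) / rate  # device clock

    # analysis window in the device clock
    win_centre = mer_time - EMD - AUC_WINDOW / 2 + offset
    burst = sin4_bump(t, win_centre, AUC_WINDOW)

    fpm_amp = fpm_auc / (SIN4_MEAN * AUC_WINDOW)
    # equal biceps/triceps amplitudes: CCI = 2 * envelope, AUC = 2*amp*mean*W
    bt_amp = cci_auc / (2.0 * SIN4_MEAN * AUC_WINDOW)

    channels: dict[str, np.ndarray] = {}
    for name, amp in (("FPM", fpm_amp), ("BIC", bt_amp), ("TRI", bt_amp)):
        env = amp * burst
        if noise:
            carrier = _bandlimited_carrier(n, rate, rng)
            raw = env * carrier * np.sqrt(np.pi / 2.0)
            raw += 1e-5 * rng.standard_normal(n)
        else:
            raw = env
        channels[name] = raw

    tc = mer_time - FOOT_CONTACT_LEAD
    accel = trunk_accel_amp * sin4_bump(t - offset, tc, TRUNK_BUMP_WIDTH)
    if accel_noise_sd > 0:
        accel = accel + accel_noise_sd * rng.standard_normal(n)
    channels["accel_z"] = accel

    return SignalTrial(time=t, channels=channels, pitch_id=pitch_id)


def generate_mvc_trials(
    rate: float = 2000.0,
    n_repeats: int = 3,
    noise: bool = False,
    rng: np.random.Generator | None = None,
) -> dict[str, list[np.ndarray]]:
    """MVC recordings per channel: 3 s plateaus of unit amplitude.

    With the unit plateau the MVC envelope reference is 1.0 V, so normalized
    envelopes coincide numerically with the generated burst amplitudes.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    ramp = 0.25
    hold = 3.0
    n = int(round((2 * ramp + hold) * rate)) + 1
    t = np.arange(n) / rate
    env = np.ones(n)
    up = t < ramp
    env[up] = np.sin(np.pi * t[up] / (2 * ramp)) ** 4
    down = t > ramp + hold
    env[down] = np.sin(np.pi * (t[-1] - t[down]) / (2 * ramp)) ** 4
    out: dict[str, list[np.ndarray]] = {}
    for name in ("FPM", "BIC", "TRI"):
        trials = []
        for _ in range(n_repeats):
            if noise:
                carrier = _bandlimited_carrier(n, rate, rng)
                trials.append(env * carrier * np.sqrt(np.pi / 2.0))
            else:
                trials.append(env.copy())
        out[name] = trials
    return out


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------


def generate_session(
    spec: SessionSpec,
) -> tuple[list[MarkerTrial], list[SignalTrial], GroundTruth]:
    """One MarkerTrial and one SignalTrial per pitch, plus the ground truth.

    Identical specs (including seed) reproduce byte-identical output.
    Pitches marked invalid by the dropout model carry a marker gap longer
    than the pipeline's interpolation limit, exercising its gap handling.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    truth = generate_outcome_table(spec, rng=rng)

    marker_trials: list[MarkerTrial] = []
    signal_trials: list[SignalTrial] = []
    for _, part in truth.participants.iterrows():
        targets = truth.pitches[
            truth.pitches["participant"] == part["participant"]
        ]
        lo = min(float(targets["true_peak_valgus"].min()), 5.0)
        hi = float(targets["true_peak_valgus"].max())
        cal = TorqueCalibration(
            part["body_mass"],
            part["body_height"],
            rate=spec.mocap_rate,
            duration=spec.duration,
            mer_time=spec.mer_time,
            amplitudes=_amplitude_grid(lo, hi),
        )
        for _, pitch in targets.iterrows():
            pid = f"{part['participant']}_p{int(pitch['pitch_number']):03d}"
            trial = generate_pitch_markers(
                float(pitch["true_peak_valgus"]),
                float(pitch["mer_time"]),
                (part["body_mass"], part["body_height"]),
                rate=spec.mocap_rate,
                duration=spec.duration,
                calibration=cal,
                pitch_id=pid,
            )
            if not pitch["valid"]:
                _inject_gap(trial, rng)
            marker_trials.append(trial)
            pad = max(abs(spec.device_offset_range[0]),
                      abs(spec.device_offset_range[1])) + 0.3
            signal_trials.append(
                generate_pitch_signals(
                    {
                        "fpm_auc": float(pitch["fpm_auc"]),
                        "cci_auc": float(pitch["cci_auc"]),
                    },
                    mer_time=float(pitch["mer_time"]),
                    offset=float(pitch["device_offset"]),
                    rate=spec.emg_rate,
                    duration=spec.duration,
                    pad=pad,
                    noise=spec.emg_noise,
                    rng=rng,
                    pitch_id=pid,
                )
            )
    return marker_trials, signal_trials, truth


def _amplitude_grid(torque_lo: float, torque_hi: float) -> np.ndarray:
    # generous fixed grid; the calibration rejects out-of-range targets
    del torque_lo, torque_hi
    return np.linspace(0.05, 2.8, 8)


def _inject_gap(trial: MarkerTrial, rng: np.random.Generator) -> None:
    n = trial.n_samples
    start = int(rng.integers(10, max(11, n - 25)))
    length = int(kinematics.MAX_GAP_SAMPLES + 5)
    trial.landmarks["radius_styloid"][start : start + length] = np.nan


def generate_window_series(
    n_participants: int,
    n_windows: int,
    intercept_mean: float,
    intercept_sd: float,
    slope_mean: float,
    slope_sd: float,
    residual_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Window series drawn directly from the mixed-model truth:

        y_wj = (b0 + u0_j) + (b1 + u1_j) * w + e_wj,  e iid normal.

    Unlike :func:`generate_outcome_table` + moving windows, the residuals
    here are independent across windows, matching the assumptions of the
    chi-square likelihood-ratio reference; use this to validate the fitting
    and selection machinery itself (type-I error, coverage).
    """
    u0 = rng.normal(intercept_mean, intercept_sd, n_participants)
    u1 = rng.normal(slope_mean, slope_sd, n_participants)
    w = np.arange(1, n_windows + 1, dtype=float)
    rows = []
    for j in range(n_participants):
        y = u0[j] + u1[j] * w + rng.normal(0.0, residual_sd, n_windows)
        rows.append(
            pd.DataFrame(
                {
                    "participant": f"P{j + 1:02d}",
                    "window_number": w.astype(int),
                    "y": y,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def degenerate_spec(spec: SessionSpec) -> SessionSpec:
    """Copy of ``spec`` with all between/within variance switched off."""
    return replace(
        spec,
        torque_intercept_sd=0.0,
        torque_slope_sd=0.0,
        torque_residual_sd=0.0,
        variability_slope_sd=0.0,
    )
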