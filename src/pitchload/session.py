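"""Device synchronization and per-participant moving-window assembly.

The EMG/accelerometer device and the motion-capture system run on separate
clocks; each pitch is aligned on the peak forward linear acceleration of the
trunk, seen by both devices.  Valid per-pitch outcomes are then collapsed to
10-pitch moving-window means and standard deviations, advancing one pitch at
a time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emg import SignalTrial
from .kinematics import SegmentFrames, differentiate

#: outcomes summarized by the window mean
MAGNITUDE_OUTCOMES = ("peak_valgus", "fpm_auc", "cci_auc", "ball_speed")

DEFAULT_MAX_OFFSET = 2.0  # s
DEFAULT_MIN_QUALITY = 3.0  # peak prominence ratio threshold


class SessionError(ValueError):
    pass


@dataclass
class SyncResult:
    pitch_id: str
    offset: float  # s, device clock minus mocap clock
    method_quality: float
    valid: bool
    reason: str = ""


def trunk_forward_acceleration(frames: SegmentFrames) -> np.ndarray:
    """Trunk forward acceleration from mocap: double-differentiated thorax
    origin projected on the thorax forward (local x) axis."""
    acc = differentiate(frames.origins["thorax"], frames.rate, order=2)
    fwd = frames.bases["thorax"][:, :, 0]
    return np.sum(acc * fwd, axis=1)


def _peak_quality(trace: np.ndarray) -> float:
    spread = float(np.std(trace))
    if spread == 0.0:
        return 0.0
    return float((np.max(trace) - np.median(trace)) / spread)


def _refined_peak_time(time: np.ndarray, trace: np.ndarray) -> float:
    """Sub-sample peak location by parabolic interpolation around the argmax.

    Needed because the mocap grid (~8 ms) is far coarser than the device
    grid; a symmetric acceleration peak between samples would otherwise
    alias into the offset estimate.
    """
    idx = int(np.argmax(trace))
    if idx == 0 or idx == trace.size - 1:
        return float(time[idx])
    y0, y1, y2 = trace[idx - 1], trace[idx], trace[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # flat or non-concave neighbourhood
        return float(time[idx])
    shift = 0.5 * (y0 - y2) / denom
    dt = float(time[1] - time[0])
    return float(time[idx] + np.clip(shift, -1.0, 1.0) * dt)


def synchronize(
    signal: SignalTrial,
    mocap_time: np.ndarray,
    trunk_accel_mocap: np.ndarray,
    max_offset: float = DEFAULT_MAX_OFFSET,
    min_quality: float = DEFAULT_MIN_QUALITY,
) -> SyncResult:
    """Clock offset between the signal device and the mocap system.

    ``offset = t_peak(accelerometer) - t_peak(mocap trunk acceleration)``;
    adding it to a mocap-clock event time (e.g. MER) maps the event into the
    device timebase.  Pitches whose acceleration peak is not prominent in
    either trace are flagged unsynchronized.
    """
    if "accel_z" not in signal.channels:
        raise SessionError("signal trial has no accel_z channel")
    accel = np.asarray(signal.channels["accel_z"], dtype=float)
    trunk = np.asarray(trunk_accel_mocap, dtype=float)
    mocap_time = np.asarray(mocap_time, dtype=float)

    # suppress sensor noise before peak picking; the trunk acceleration
    # bump lives well below 50 Hz
    rate = signal.rate
    if rate > 200.0 and accel.size > 30:
        from scipy.signal import butter, sosfiltfilt

        sos = butter(2, 50.0, btype="low", fs=rate, output="sos")
        accel = sosfiltfilt(sos, accel)

    q_dev = _peak_quality(accel)
    q_moc = _peak_quality(trunk)
    quality = min(q_dev, q_moc)
    if quality < min_quality:
        return SyncResult(
            signal.pitch_id, np.nan, quality, False, "low_peak_prominence"
        )

    t_dev = _refined_peak_time(signal.time, accel)
    t_moc = _refined_peak_time(mocap_time, trunk)
    offset = t_dev - t_moc
    if abs(offset) > max_offset:
        return SyncResult(signal.pitch_id, offset, quality, False, "offset_out_of_range")
    return SyncResult(signal.pitch_id, offset, quality, True)


# ---------------------------------------------------------------------------
# moving windows
# ---------------------------------------------------------------------------

PITCH_COLUMNS = (
    "participant",
    "pitch_number",
    "block",
    "valid",
    "peak_valgus",
    "fpm_auc",
    "cci_auc",
    "ball_speed",
)


def moving_windows(
    results: pd.DataFrame,
    window: int = 10,
    step: int = 1,
    outcomes: tuple[str, ...] = MAGNITUDE_OUTCOMES,
    mode: str = "consecutive_valid",
) -> pd.DataFrame:
    """10-pitch moving-window statistics per participant.

    Parameters
    ----------
    results
        Per-pitch table with at least ``participant``, ``pitch_number``,
        ``valid`` and the outcome columns; sorted or sortable by
        ``pitch_number`` within participant.
    mode
        ``"consecutive_valid"`` (default) forms windows over the sequence of
        valid pitches, skipping invalid ones; ``"strict"`` breaks windows at
        any invalid pitch so every window covers ``window`` consecutive
        recorded pitches.

    Returns
    -------
    Tidy frame with columns ``participant, window_number, outcome, mean, sd,
    n_in_window``; every window contains exactly ``window`` valid pitches and
    window numbers are 1-based per participant.
    """
    if window < 2:
        raise SessionError("window must be >= 2")
    if step < 1:
        raise SessionError("step must be >= 1")
    if mode not in ("consecutive_valid", "strict"):
        raise SessionError(f"unknown mode {mode!r}")
    required = {"participant", "pitch_number", "valid"} | set(outcomes)
    missing = required - set(results.columns)
    if missing:
        raise SessionError(f"results table missing columns: {sorted(missing)}")

    rows = []
    for participant, group in results.groupby("participant", sort=True):
        group = group.sort_values("pitch_number")
        if group["pitch_number"].duplicated().any():
            raise SessionError(
                f"duplicate pitch_number for participant {participant!r}"
            )
        valid = group[group["valid"].astype(bool)]
        if mode == "consecutive_valid":
            segments = [valid]
        else:
            breaks = (~group["valid"].astype(bool)).cumsum()
            segments = [seg for _, seg in valid.groupby(breaks.loc[valid.index])]
        w_num = 0
        for seg in segments:
            n = len(seg)
            for start in range(0, n - window + 1, step):
                w_num += 1
                chunk = seg.iloc[start : start + window]
                for outcome in outcomes:
                    vals = chunk[outcome].to_numpy(dtype=float)
                    rows.append(
                        {
                            "participant": participant,
                            "window_number": w_num,
                            "outcome": outcome,
                            "mean": float(np.mean(vals)),
                            "sd": float(np.std(vals, ddof=1)),
                            "n_in_window": window,
                        }
                    )
        if w_num == 0:
            import warnings

            warnings.warn(
                f"participant {participant!r}: fewer than {window} valid "
                "pitches; no windows formed",
                stacklevel=2,
            )
    return pd.DataFrame(
        rows,
        columns=["participant", "window_number", "outcome", "mean", "sd", "n_in_window"],
    )


def outcome_series(
    windows: pd.DataFrame, outcome: str, statistic: str = "mean"
) -> pd.DataFrame:
    """Long-format (participant, window_number, y) series for one modelled
    outcome; ``statistic="sd"`` selects the within-window variability."""
    if statistic not in ("mean", "sd"):
        raise SessionError("statistic must be 'mean' or 'sd'")
    sub = windows[windows["outcome"] == outcome]
    if sub.empty:
        raise SessionError(f"no windows for outcome {outcome!r}")
    out = sub[["participant", "window_number", statistic]].rename(
        columns={statistic: "y"}
    )
    return out.reset_index(drop=True)
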