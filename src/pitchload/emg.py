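"""Surface EMG processing: linear envelope, MVC normalization, CCI, AUC.

The linear envelope is the full-wave-rectified signal passed through a
zero-phase low-pass Butterworth filter (2nd-order design applied forward and
backward, i.e. 4th-order effective attenuation with zero lag).  Envelopes are
normalized to the maximum filtered-envelope value observed across the MVC
trials of the same channel.  The per-sample biceps-triceps co-contraction
index is

    CCI_i = (EMG_low_i / EMG_high_i) * (EMG_low_i + EMG_high_i)

with the high = 0 case defined as 0 by continuous extension.  Per-pitch
summaries integrate the envelope (trapezoid rule) over a 150 ms window ending
at MER after shifting by the 50 ms electromechanical delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

EMG_CHANNELS = ("FPM", "BIC", "TRI")

DEFAULT_ENVELOPE_CUTOFF = 20.0  # Hz
DEFAULT_EMD = 0.050  # s, electromechanical delay
DEFAULT_AUC_WIDTH = 0.150  # s


class EmgError(ValueError):
    pass


@dataclass
class SignalTrial:
    """Raw device signals for one pitch: three EMG channels + accelerometer.

    ``time`` is in the device (EMG) clock, which may be offset from the
    mocap clock; synchronization resolves the offset.
    """

    time: np.ndarray
    channels: dict[str, np.ndarray]
    pitch_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)

    @property
    def rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))

    def validate(self) -> None:
        dt = np.diff(self.time)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise EmgError("time must be strictly increasing and uniform")
        for name, series in self.channels.items():
            if np.asarray(series).shape != self.time.shape:
                raise EmgError(f"channel {name!r} length mismatch")


def linear_envelope(
    raw: np.ndarray, rate: float, cutoff: float = DEFAULT_ENVELOPE_CUTOFF
) -> np.ndarray:
    """Full-wave rectification followed by zero-phase Butterworth low-pass."""
    raw = np.asarray(raw, dtype=float)
    if rate < 2 * cutoff:
        raise EmgError(f"sampling rate {rate} Hz below 2x cutoff {cutoff} Hz")
    if raw.size <= 12:  # 3x the effective filter order's state length
        raise EmgError("series too short for stable zero-phase filtering")
    sos = butter(2, cutoff, btype="low", fs=rate, output="sos")
    # clamp the small zero-phase undershoot; envelopes are nonnegative
    return np.maximum(sosfiltfilt(sos, np.abs(raw)), 0.0)


@dataclass
class EnvelopeSeries:
    time: np.ndarray
    envelopes: dict[str, np.ndarray]  # normalized, dimensionless
    mvc_reference: dict[str, float]  # V
    flags: dict[str, tuple[str, ...]] = field(default_factory=dict)


def mvc_reference(
    mvc_trials: list[np.ndarray], rate: float, noise_floor: float = 1e-9
) -> float:
    """Normalization reference: max of the linear envelope over all MVC trials."""
    if not mvc_trials:
        raise EmgError("at least one MVC trial is required")
    ref = max(float(np.max(linear_envelope(trial, rate))) for trial in mvc_trials)
    if ref <= noise_floor:
        raise EmgError(
            f"MVC reference {ref:.3e} V at or below the noise floor "
            f"({noise_floor:.3e} V); bad MVC recording"
        )
    return ref


def mvc_normalize(
    trial: SignalTrial,
    mvc_trials: dict[str, list[np.ndarray]],
    cutoff: float = DEFAULT_ENVELOPE_CUTOFF,
    noise_floor: float = 1e-9,
) -> EnvelopeSeries:
    """MVC-normalized linear envelopes for every EMG channel of a pitch.

    Values above 1 are permitted (dynamic contractions can exceed MVC) and
    flagged per channel.
    """
    rate = trial.rate
    envelopes: dict[str, np.ndarray] = {}
    refs: dict[str, float] = {}
    flags: dict[str, tuple[str, ...]] = {}
    for channel in EMG_CHANNELS:
        if channel not in trial.channels:
            raise EmgError(f"trial missing EMG channel {channel!r}")
        if channel not in mvc_trials:
            raise EmgError(f"no MVC trials for channel {channel!r}")
        ref = mvc_reference(mvc_trials[channel], rate, noise_floor=noise_floor)
        env = linear_envelope(trial.channels[channel], rate, cutoff=cutoff) / ref
        envelopes[channel] = env
        refs[channel] = ref
        flags[channel] = ("exceeds_mvc",) if np.max(env) > 1.0 else ()
    return EnvelopeSeries(trial.time, envelopes, refs, flags)


def cci(bic: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Per-sample co-contraction index (low/high) * (low + high).

    Symmetric in its arguments; defined as 0 where the larger input is 0.
    """
    bic = np.asarray(bic, dtype=float)
    tri = np.asarray(tri, dtype=float)
    if np.any(bic < 0) or np.any(tri < 0):
        raise EmgError("CCI inputs must be nonnegative normalized envelopes")
    low = np.minimum(bic, tri)
    high = np.maximum(bic, tri)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(high > 0, (low / np.where(high > 0, high, 1.0)) * (low + high), 0.0)
    return out


def windowed_auc(
    time: np.ndarray,
    series: np.ndarray,
    mer_time: float,
    emd: float = DEFAULT_EMD,
    width: float = DEFAULT_AUC_WIDTH,
) -> float:
    """Trapezoid AUC over the EMD-compensated pre-MER window.

    The envelope is shifted forward by ``emd`` (activity at recorded time t
    represents force at t + emd), so the integral runs over recorded samples
    in ``[mer_time - width - emd, mer_time - emd]``.  Window edges snap to
    the nearest sample.
    """
    time = np.asarray(time, dtype=float)
    series = np.asarray(series, dtype=float)
    rate = 1.0 / float(np.mean(np.diff(time)))
    start = mer_time - width - emd
    stop = mer_time - emd
    i0 = int(round((start - time[0]) * rate))
    i1 = int(round((stop - time[0]) * rate))
    if i0 < 0 or i1 >= time.size:
        raise EmgError(
            f"AUC window [{start:.4f}, {stop:.4f}] s outside trial span "
            f"[{time[0]:.4f}, {time[-1]:.4f}] s "
            f"(deficit {max(0.0, time[0] - start) + max(0.0, stop - time[-1]):.4f} s)"
        )
    return float(np.trapezoid(series[i0 : i1 + 1], time[i0 : i1 + 1]))


@dataclass
class EmgSummary:
    fpm_auc: float
    cci_auc: float
    window: tuple[float, float]
    cci_series: np.ndarray
    flags: tuple[str, ...] = ()


def summarize_pitch(
    envelopes: EnvelopeSeries,
    mer_time_device: float,
    emd: float = DEFAULT_EMD,
    width: float = DEFAULT_AUC_WIDTH,
) -> EmgSummary:
    """FPM AUC and biceps-triceps CCI AUC for one pitch.

    ``mer_time_device`` is MER expressed in the device (EMG) clock, i.e.
    after applying the synchronization offset.
    """
    cci_series = cci(envelopes.envelopes["BIC"], envelopes.envelopes["TRI"])
    fpm = windowed_auc(
        envelopes.time, envelopes.envelopes["FPM"], mer_time_device, emd, width
    )
    cci_auc = windowed_auc(envelopes.time, cci_series, mer_time_device, emd, width)
    flags = tuple(
        f"{ch}_{fl}" for ch, fls in envelopes.flags.items() for fl in fls
    )
    return EmgSummary(
        fpm_auc=fpm,
        cci_auc=cci_auc,
        window=(mer_time_device - width, mer_time_device),
        cci_series=cci_series,
        flags=flags,
    )
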