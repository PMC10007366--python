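"""Pulse rate and SpO2 from detected peaks and dual-channel PPG statistics.

Pulse rate is the beat count over the analysis window scaled to one minute
(for the default 30 s buffer: count x 2).  SpO2 follows the classical
ratio-of-ratios method: each channel's pulsatile (AC) and baseline (DC)
components give R = (AC_red/DC_red) / (AC_ir/DC_ir), which maps to an
oxygen-saturation percentage through a quadratic calibration curve
SpO2 = a*R^2 + b*R + c.

The default calibration (a=-45.060, b=30.354, c=94.845) is the published
reference curve for this sensor family; devices are expected to re-calibrate
against a clinical oximeter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import peaks as _peaks
from . import signal_core as _sc
from .peaks import PeakList
from .signal_core import InvalidConfigError, PPGSignal

__all__ = [
    "ChannelStats",
    "SpO2Calibration",
    "VitalsResult",
    "InsufficientBeatsError",
    "UndefinedRatioError",
    "pulse_rate",
    "channel_ac_dc",
    "ratio_of_ratios",
    "spo2_from_r",
    "measure_spo2",
]


class InsufficientBeatsError(ValueError):
    """Fewer detected beats than the operation requires."""


class UndefinedRatioError(ValueError):
    """Ratio-of-ratios undefined (non-positive DC or zero IR pulsation)."""


@dataclass(frozen=True)
class ChannelStats:
    """Pulsatile (AC) and baseline (DC) components of one optical channel."""

    ac: float
    dc: float
    channel: str

    def __post_init__(self) -> None:
        if self.dc <= 0:
            raise UndefinedRatioError(f"{self.channel} DC must be positive")
        if self.ac < 0:
            raise InvalidConfigError(f"{self.channel} AC must be non-negative")


@dataclass(frozen=True)
class SpO2Calibration:
    """Quadratic ratio-of-ratios calibration: SpO2 = a*R^2 + b*R + c (%)."""

    a: float = -45.060
    b: float = 30.354
    c: float = 94.845


@dataclass(frozen=True)
class VitalsResult:
    pulse_rate_bpm: float
    window_s: float
    n_peaks: int
    spo2_pct: float | None = None
    quality: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.pulse_rate_bpm <= 250:
            raise InvalidConfigError("pulse rate outside [0, 250] bpm")
        if self.spo2_pct is not None and not 0 <= self.spo2_pct <= 100:
            raise InvalidConfigError("SpO2 outside [0, 100] %")


def pulse_rate(peaks: PeakList, window_s: float = 30.0) -> VitalsResult:
    """Beats per minute from the beat count in one contiguous window.

    bpm = count * (60 / window_s); with the default 30 s buffer this is the
    device's "count times two" rule.  Zero detected beats yields 0 bpm with
    a low-quality flag rather than an error.
    """
    if window_s <= 0:
        raise InvalidConfigError("window_s must be positive")
    count = len(peaks)
    bpm = count * (60.0 / window_s)
    flags = () if count else ("no_beats_detected",)
    return VitalsResult(pulse_rate_bpm=bpm, window_s=window_s, n_peaks=count,
                        quality=flags)


def channel_ac_dc(
    signal: PPGSignal,
    window: int | None = None,
    filt: _sc.FIRFilter | None = None,
    hr_max_bpm: float = 220.0,
    theta: float = 0.5,
    m: int = 5,
) -> ChannelStats:
    """AC/DC decomposition of one channel for the ratio-of-ratios.

    DC is the mean of the trailing moving-average trend (the same moving
    average used for DC removal, kept instead of subtracted) over the
    post-warm-up span.  AC is the mean per-beat peak-to-trough excursion of
    the band-passed signal, where the trough is the minimum between
    consecutive systolic peaks.
    """
    if window is None:
        window = _sc.dc_window_length(signal.fs)
    if filt is None:
        filt = _sc.design_bandpass(signal.fs)

    trend = _sc._trailing_moving_average(signal.samples, window)
    detrended = _sc.remove_dc(signal, window)
    filtered = _sc.apply_fir(detrended, filt)
    if filtered.valid_from >= len(filtered):
        raise InsufficientBeatsError(
            "signal shorter than the preprocessing warm-up; no beats observable"
        )
    pk = _peaks.detect_peaks(filtered, hr_max_bpm=hr_max_bpm, theta=theta, m=m)
    dc = float(np.mean(trend[filtered.valid_from:]))
    if len(pk) < 2:
        # A truly pulseless channel (e.g. constant offset) has zero AC by
        # definition; anything else genuinely lacks beats.
        residual = np.ptp(filtered.samples[filtered.valid_from:])
        if residual <= 1e-9 * max(1.0, abs(dc)):
            return ChannelStats(ac=0.0, dc=dc, channel=signal.channel)
        raise InsufficientBeatsError(
            f"need >= 2 detected beats for AC estimation, found {len(pk)}"
        )

    x = filtered.samples
    excursions = []
    for j in range(len(pk) - 1):
        a, b = pk.indices[j], pk.indices[j + 1]
        trough = float(np.min(x[a:b + 1]))
        excursions.append(float(x[a]) - trough)
    ac = float(np.mean(excursions))
    return ChannelStats(ac=max(ac, 0.0), dc=dc, channel=signal.channel)


def ratio_of_ratios(red: ChannelStats, ir: ChannelStats) -> float:
    """R = (AC_red / DC_red) / (AC_ir / DC_ir)."""
    if red.dc <= 0 or ir.dc <= 0:
        raise UndefinedRatioError("DC components must be positive")
    if ir.ac <= 0:
        raise UndefinedRatioError("IR channel has no pulsatile component")
    return (red.ac / red.dc) / (ir.ac / ir.dc)


def spo2_from_r(R: float, calib: SpO2Calibration = SpO2Calibration()) -> float:
    """Oxygen saturation (%) from the ratio-of-ratios, clamped to [0, 100]."""
    if R < 0:
        raise UndefinedRatioError("R must be non-negative")
    raw = calib.a * R * R + calib.b * R + calib.c
    return float(min(100.0, max(0.0, raw)))


def measure_spo2(
    red: PPGSignal,
    ir: PPGSignal,
    calib: SpO2Calibration = SpO2Calibration(),
    window: int | None = None,
) -> dict:
    """Full dual-channel SpO2 pipeline; returns R, SpO2 and per-channel stats."""
    if red.fs != ir.fs:
        raise InvalidConfigError("red and IR channels must share a sampling rate")
    red_stats = channel_ac_dc(red, window=window)
    ir_stats = channel_ac_dc(ir, window=window)
    R = ratio_of_ratios(red_stats, ir_stats)
    return {
        "R": R,
        "spo2_pct": round(spo2_from_r(R, calib), 1),
        "red": {"ac": red_stats.ac, "dc": red_stats.dc},
        "ir": {"ac": ir_stats.ac, "dc": ir_stats.dc},
    }
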