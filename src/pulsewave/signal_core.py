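"""Core PPG signal containers and shared preprocessing.

The pulse-rate, SpO2, and stress pipelines all start from the same two
preprocessing stages applied to a buffered photoplethysmogram (PPG):

1. DC removal — a moving average (trailing window, as a streaming device
   computes it) is subtracted from a delayed copy of the input so that the
   average window is centred on the sample it corrects.
2. Band-pass FIR filtering — an equiripple (Parks–McClellan / Remez)
   linear-phase band-pass spanning the physiological pulse band, 0.7–3.5 Hz
   (30–210 bpm), removes residual baseline drift and high-frequency noise.

Both stages are causal; warm-up samples (where the moving average or the
filter has not yet seen a full window) are flagged via ``PPGSignal.valid_from``
and excluded from downstream statistics, and the FIR group delay is reported
so peak indices can be mapped back to raw-signal coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "PPGSignal",
    "FIRFilter",
    "AcquisitionConfig",
    "InvalidConfigError",
    "InsufficientDataError",
    "FilterDesignError",
    "effective_rate",
    "dc_window_length",
    "remove_dc",
    "design_bandpass",
    "apply_fir",
    "group_delay_samples",
]

CHANNELS = ("green", "red", "ir")


class InvalidConfigError(ValueError):
    """Raised for acquisition/config parameters that violate their invariants."""


class InsufficientDataError(ValueError):
    """Raised when a signal is too short for the requested operation."""


class FilterDesignError(ValueError):
    """Raised when an FIR band-pass specification is infeasible."""


@dataclass(frozen=True)
class PPGSignal:
    """A uniformly sampled optical waveform from one LED channel.

    ``valid_from`` marks the first sample index that is past all causal
    warm-up transients accumulated so far (0 for a raw signal); downstream
    peak detection ignores samples before it.
    """

    samples: np.ndarray
    fs: float
    channel: str = "green"
    t0: float = 0.0
    valid_from: int = 0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise InvalidConfigError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 1:
            raise InvalidConfigError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise InvalidConfigError("samples must all be finite")
        if self.channel not in CHANNELS:
            raise InvalidConfigError(
                f"channel must be one of {CHANNELS}, got {self.channel!r}"
            )
        if not 0 <= self.valid_from <= samples.size:
            raise InvalidConfigError("valid_from outside signal bounds")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds (t0-based)."""
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class FIRFilter:
    """Linear-phase (type I) FIR band-pass filter taps plus design metadata."""

    coefficients: np.ndarray
    fs: float
    f_low: float
    f_high: float
    n_taps: int
    passband_ripple: float = float("nan")
    stopband_ripple: float = float("nan")

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coeffs)
        if self.n_taps != coeffs.size:
            raise FilterDesignError("n_taps does not match coefficient count")
        if self.n_taps % 2 != 1:
            raise FilterDesignError("n_taps must be odd (linear-phase type I)")
        if not np.allclose(coeffs, coeffs[::-1], atol=1e-9):
            raise FilterDesignError("coefficients must be symmetric (linear phase)")
        if not (0 < self.f_low < self.f_high < self.fs / 2):
            raise FilterDesignError(
                "band edges must satisfy 0 < f_low < f_high < fs/2"
            )

    @property
    def group_delay(self) -> int:
        """Group delay in samples: (n_taps - 1) / 2 for a type-I filter."""
        return (self.n_taps - 1) // 2

    def response_at(self, freqs_hz) -> np.ndarray:
        """Magnitude response |H(f)| at the given frequencies (Hz)."""
        w = 2 * np.pi * np.atleast_1d(np.asarray(freqs_hz, dtype=float)) / self.fs
        _, h = sps.freqz(self.coefficients, worN=w)
        return np.abs(h)

    def to_json(self) -> str:
        return json.dumps(
            {
                "fs": self.fs,
                "f_low": self.f_low,
                "f_high": self.f_high,
                "n_taps": self.n_taps,
                "coefficients": self.coefficients.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FIRFilter":
        d = json.loads(text)
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            fs=d["fs"],
            f_low=d["f_low"],
            f_high=d["f_high"],
            n_taps=d["n_taps"],
        )


@dataclass(frozen=True)
class AcquisitionConfig:
    """Sensor acquisition settings: native rate, on-chip averaging, buffer span.

    Defaults reproduce the device configuration: 200 Hz native sampling with
    4-sample averaging gives an effective 50 Hz stream, and a 30 s buffer of
    1500 samples.
    """

    window_s: float = 30.0
    fs_native: float = 200.0
    avg_factor: int = 4

    def __post_init__(self) -> None:
        if self.fs_native <= 0:
            raise InvalidConfigError("fs_native must be positive")
        if not (isinstance(self.avg_factor, int) and self.avg_factor >= 1):
            raise InvalidConfigError("avg_factor must be an integer >= 1")
        if self.window_s <= 0:
            raise InvalidConfigError("window_s must be positive")

    @property
    def fs_effective(self) -> float:
        return self.fs_native / self.avg_factor

    @property
    def buffer_length(self) -> int:
        n = self.fs_effective * self.window_s
        return int(round(n))


def effective_rate(cfg: AcquisitionConfig) -> float:
    """Effective sampling rate after on-chip sample averaging.

    With the default 200 Hz native rate and 4-sample averaging this is
    200/4 = 50 Hz, and the 30 s buffer holds exactly 1500 samples.
    """
    return cfg.fs_effective


def dc_window_length(fs: float, max_ibi_s: float = 1.0) -> int:
    """Moving-average window for DC removal: smallest power of two spanning
    at least one maximal heartbeat.

    At 50 Hz with a 1 s maximal interbeat interval this is 64 samples — a
    power of two so an embedded target can divide by bit shift.
    """
    if fs <= 0:
        raise InvalidConfigError("fs must be positive")
    if not (0 < max_ibi_s <= 3):
        raise InvalidConfigError("max_ibi_s must lie in (0, 3]")
    target = math.ceil(fs * max_ibi_s)
    window = 1
    while window < target:
        window *= 2
    return window


def _trailing_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    # Running mean over the trailing `window` samples, no padding: for
    # n < window-1 the partial window is averaged (warm-up, flagged upstream).
    csum = np.cumsum(x)
    out = np.empty_like(x)
    out[:window] = csum[:window] / np.arange(1, min(window, x.size) + 1)
    if x.size > window:
        out[window:] = (csum[window:] - csum[:-window]) / window
    return out


def remove_dc(signal: PPGSignal, window: int) -> PPGSignal:
    """Subtract a trailing moving average from the delayed input.

    The input is delayed by floor(window/2) samples so that the trailing
    average window is (approximately) centred on the sample it is subtracted
    from, minimising phase distortion of the trend estimate.  The first
    ``window - 1`` samples are warm-up and are flagged via ``valid_from``;
    output length equals input length.
    """
    if window < 1:
        raise InvalidConfigError("window must be >= 1")
    x = signal.samples
    if x.size < window:
        raise InsufficientDataError(
            f"signal has {x.size} samples; DC removal needs at least {window}"
        )
    delay = window // 2
    trend = _trailing_moving_average(x, window)
    delayed = np.concatenate([np.full(delay, x[0]), x[:-delay] if delay else x])
    out = delayed - trend
    warmup = window - 1
    return replace(
        signal,
        samples=out,
        valid_from=min(x.size, max(signal.valid_from, warmup)),
    )


def design_bandpass(
    fs: float,
    f_low: float = 0.7,
    f_high: float = 3.5,
    n_taps: int = 111,
    transition: float = 0.3,
) -> FIRFilter:
    """Design an equiripple linear-phase band-pass FIR via the
    Parks–McClellan (Remez exchange) algorithm.

    The passband spans the physiological pulse band [f_low, f_high]
    (defaults 0.7–3.5 Hz, i.e. 42–210 bpm fundamentals); ``transition``
    is the half-width of each transition band.  Achieved pass/stop ripples
    are measured on a dense frequency grid and stored on the result.
    """
    if n_taps % 2 != 1:
        raise FilterDesignError("n_taps must be odd")
    if f_low - transition <= 0:
        raise FilterDesignError(
            f"lower transition band starts at {f_low - transition:.3f} Hz <= 0"
        )
    if f_high + transition >= fs / 2:
        raise FilterDesignError(
            f"upper transition band ends at {f_high + transition:.3f} Hz >= "
            f"Nyquist ({fs / 2:.3f} Hz)"
        )
    if f_low + transition >= f_high - transition:
        raise FilterDesignError("transition bands overlap: passband is empty")

    bands = [
        0.0,
        f_low - transition,
        f_low + transition,
        f_high - transition,
        f_high + transition,
        fs / 2,
    ]
    taps = sps.remez(n_taps, bands, [0.0, 1.0, 0.0], fs=fs)
    # Remez can return taps that are symmetric only to solver precision.
    taps = 0.5 * (taps + taps[::-1])

    grid = np.arange(0.0, fs / 2 + 1e-9, 0.01)
    filt = FIRFilter(taps, fs, f_low, f_high, n_taps)
    mag = filt.response_at(grid)
    in_pass = (grid >= f_low + transition) & (grid <= f_high - transition)
    in_stop = (grid <= f_low - transition) | (grid >= f_high + transition)
    pass_ripple = float(np.max(np.abs(mag[in_pass] - 1.0)))
    stop_ripple = float(np.max(mag[in_stop]))
    return replace(filt, passband_ripple=pass_ripple, stopband_ripple=stop_ripple)


def apply_fir(signal: PPGSignal, filt: FIRFilter) -> PPGSignal:
    """Causal FIR convolution; output length equals input length.

    The filtered signal lags the input by the group delay
    (``n_taps - 1) / 2`` samples); peak indices found on the output can be
    re-aligned to raw coordinates by subtracting ``filt.group_delay``.
    Warm-up grows by ``n_taps - 1`` samples.
    """
    if filt.fs != signal.fs:
        raise InvalidConfigError(
            f"filter designed for {filt.fs} Hz but signal is {signal.fs} Hz"
        )
    y = sps.lfilter(filt.coefficients, [1.0], signal.samples)
    warmup = signal.valid_from + filt.n_taps - 1
    return replace(signal, samples=y, valid_from=min(signal.samples.size, warmup))


def group_delay_samples(filt: FIRFilter) -> int:
    """Group delay of a linear-phase FIR in samples."""
    return filt.group_delay
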