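"""Ground-truthed synthetic PPG and PRV data.

Nothing here models hemodynamics; the generator's only job is to emit
signals with the features the processing pipeline keys on, together with
exact ground truth, so that peak detection, vitals, feature extraction and
the stress classifier are all testable without hardware or dataset
downloads.

* A beat train draws interbeat intervals from a truncated normal
  distribution restricted to the physiological 273–2000 ms range
  (220–30 bpm).
* Each beat renders as a dominant systolic Gaussian bump plus a smaller,
  delayed diastolic bump; a DC offset, slow sinusoidal baseline wander,
  white noise and optional motion-artifact bursts are added on top.  The
  exact systolic apex sample of every beat is returned as ground truth.
* Dual red/IR channels share one beat train; the red pulsatile amplitude is
  scaled so the analytic ratio-of-ratios equals a prescribed target.
* Labeled PRV datasets draw per-window IBI series from class-specific
  regimes (stress = shorter mean IBI, reduced RMSSD — the direction of
  sympathetic activation) with per-subject offsets, and run the *real*
  feature extractor on each series.

All generators are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as spstats

from .prv import IBISeries, correct_ectopic, extract_features
from .signal_core import InvalidConfigError, PPGSignal
from .stress_model import LabeledDataset

__all__ = [
    "BeatTrain",
    "WaveformParams",
    "RegimeSpec",
    "IBI_MIN_MS",
    "IBI_MAX_MS",
    "generate_beat_train",
    "render_ppg",
    "render_dual_channel",
    "generate_labeled_dataset",
]

# Physiological interbeat-interval range: 220 bpm down to 30 bpm.
IBI_MIN_MS = 273.0
IBI_MAX_MS = 2000.0


@dataclass(frozen=True)
class BeatTrain:
    """Beat times (s) and the IBI sequence (ms) that produced them."""

    times_s: np.ndarray
    ibis_ms: np.ndarray
    mean_bpm: float
    ibi_sd_ms: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        ibi = np.asarray(self.ibis_ms, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "ibis_ms", ibi)
        if t.size and np.any(np.diff(t) <= 0):
            raise InvalidConfigError("beat times must be strictly increasing")
        if not np.allclose(np.diff(t) * 1000.0, ibi, atol=1e-6):
            raise InvalidConfigError("IBIs must equal successive beat-time diffs")


@dataclass(frozen=True)
class WaveformParams:
    """Morphology and nuisance parameters for one rendered channel.

    Widths are Gaussian standard deviations (s).  The diastolic bump is a
    fraction of the systolic amplitude (< 1: the systolic peak is the first
    and highest of the cardiac cycle), delayed by roughly the time to the
    reflected-wave peak.
    """

    systolic_amplitude: float = 1.0
    systolic_width_s: float = 0.045
    diastolic_ratio: float = 0.35
    diastolic_delay_s: float = 0.25
    diastolic_width_s: float = 0.08
    dc_offset: float = 100.0
    wander_amplitude: float = 0.5
    wander_freq_hz: float = 0.25
    noise_sd: float = 0.02
    artifact_rate_per_s: float = 0.0
    artifact_magnitude: float = 5.0

    def __post_init__(self) -> None:
        if self.systolic_width_s <= 0 or self.diastolic_width_s <= 0:
            raise InvalidConfigError("widths must be positive")
        if self.systolic_amplitude < 0 or self.artifact_magnitude < 0:
            raise InvalidConfigError("amplitudes must be non-negative")
        if not 0 <= self.diastolic_ratio < 1:
            raise InvalidConfigError(
                "diastolic ratio must be in [0, 1): systolic peak dominates"
            )


@dataclass(frozen=True)
class RegimeSpec:
    """Per-class IBI regimes for labeled-dataset generation (ms)."""

    baseline_mean_ibi: float = 850.0
    baseline_ibi_sd: float = 50.0
    baseline_rmssd: float = 45.0
    stress_mean_ibi: float = 700.0
    stress_ibi_sd: float = 30.0
    stress_rmssd: float = 22.0

    def __post_init__(self) -> None:
        if not self.stress_mean_ibi < self.baseline_mean_ibi:
            raise InvalidConfigError("stress regime must shorten the mean IBI")
        if not self.stress_rmssd < self.baseline_rmssd:
            raise InvalidConfigError("stress regime must reduce RMSSD")


def typical_ibi_sd(mean_bpm: float) -> float:
    """IBI spread (ms) typical at a given mean heart rate.

    Beat-to-beat variability shrinks as heart rate rises (vagal withdrawal
    during exercise or tachycardia); the anchor points below interpolate
    that trend so clean test trains stay physiologically plausible across
    the supported rate range.
    """
    return float(
        np.interp(mean_bpm, [40.0, 60.0, 100.0, 160.0, 180.0],
                  [45.0, 40.0, 25.0, 12.0, 8.0])
    )


def generate_beat_train(
    mean_bpm: float,
    ibi_sd_ms: float,
    duration_s: float,
    seed: int,
) -> BeatTrain:
    """Beat times from truncated-normal IBIs on [273, 2000] ms."""
    if not 30 <= mean_bpm <= 220:
        raise InvalidConfigError("mean_bpm must lie in [30, 220]")
    if duration_s <= 0:
        raise InvalidConfigError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    mean_ibi = 60000.0 / mean_bpm
    # Draw generously, then trim to the duration.
    n_draw = int(np.ceil(duration_s * 1000.0 / IBI_MIN_MS)) + 2
    if ibi_sd_ms == 0:
        ibis = np.full(n_draw, mean_ibi)
    else:
        a = (IBI_MIN_MS - mean_ibi) / ibi_sd_ms
        b = (IBI_MAX_MS - mean_ibi) / ibi_sd_ms
        ibis = spstats.truncnorm.rvs(
            a, b, loc=mean_ibi, scale=ibi_sd_ms, size=n_draw, random_state=rng
        )
    t0 = 0.15  # first apex slightly after the window start
    times = t0 + np.concatenate([[0.0], np.cumsum(ibis[:-1]) / 1000.0])
    keep = times < duration_s
    times = times[keep]
    return BeatTrain(
        times_s=times,
        ibis_ms=np.diff(times) * 1000.0,
        mean_bpm=mean_bpm,
        ibi_sd_ms=ibi_sd_ms,
    )


def render_ppg(
    train: BeatTrain,
    params: WaveformParams = WaveformParams(),
    fs: float = 50.0,
    seed: int = 0,
    duration_s: float | None = None,
    channel: str = "green",
) -> tuple[PPGSignal, np.ndarray]:
    """Render a beat train into a sampled PPG waveform.

    Returns ``(signal, true_peak_indices)`` where the indices are the exact
    samples nearest each systolic apex.  With noise, wander and artifacts
    disabled the signal's local maxima coincide with those samples.
    """
    if fs < 25:
        raise InvalidConfigError("fs must be >= 25 Hz")
    if duration_s is None:
        duration_s = float(train.times_s[-1]) + 1.0 if train.times_s.size else 1.0
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for tb in train.times_s:
        x += params.systolic_amplitude * np.exp(
            -0.5 * ((t - tb) / params.systolic_width_s) ** 2
        )
        x += (params.systolic_amplitude * params.diastolic_ratio) * np.exp(
            -0.5 * ((t - tb - params.diastolic_delay_s) / params.diastolic_width_s) ** 2
        )
    x += params.dc_offset
    if params.wander_amplitude:
        x += params.wander_amplitude * np.sin(2 * np.pi * params.wander_freq_hz * t)
    rng = np.random.default_rng(seed)
    if params.noise_sd:
        x += rng.normal(0.0, params.noise_sd, size=n)
    if params.artifact_rate_per_s > 0:
        n_bursts = rng.poisson(params.artifact_rate_per_s * duration_s)
        for _ in range(n_bursts):
            center = rng.uniform(0, duration_s)
            width = rng.uniform(0.1, 0.5)
            sign = rng.choice([-1.0, 1.0])
            x += sign * params.artifact_magnitude * np.exp(
                -0.5 * ((t - center) / width) ** 2
            )
    true_idx = np.round(train.times_s * fs).astype(int)
    true_idx = true_idx[(true_idx >= 0) & (true_idx < n)]
    return PPGSignal(samples=x, fs=fs, channel=channel), true_idx


def render_dual_channel(
    train: BeatTrain,
    params_red: WaveformParams,
    params_ir: WaveformParams,
    target_R: float,
    fs: float = 50.0,
    seed: int = 0,
    duration_s: float | None = None,
) -> tuple[PPGSignal, PPGSignal]:
    """Red/IR channel pair whose analytic ratio-of-ratios equals ``target_R``.

    Both channels share the beat train and the pulse shape (widths, delays
    from ``params_red``); the red pulsatile amplitude is rescaled so that
    (AC_red/DC_red) / (AC_ir/DC_ir) = target_R exactly in the prescription.
    Because the shapes match, any shape-dependent attenuation of the
    measurement pipeline cancels in the ratio.
    """
    if target_R <= 0:
        raise InvalidConfigError("target_R must be positive")
    shape = {
        "systolic_width_s": params_red.systolic_width_s,
        "diastolic_ratio": params_red.diastolic_ratio,
        "diastolic_delay_s": params_red.diastolic_delay_s,
        "diastolic_width_s": params_red.diastolic_width_s,
    }
    a_red = (
        target_R
        * params_ir.systolic_amplitude
        * params_red.dc_offset
        / params_ir.dc_offset
    )
    params_red = replace(params_red, systolic_amplitude=a_red, **shape)
    params_ir = replace(params_ir, **shape)
    red, _ = render_ppg(train, params_red, fs, seed=seed, duration_s=duration_s,
                        channel="red")
    ir, _ = render_ppg(train, params_ir, fs, seed=seed + 1, duration_s=duration_s,
                       channel="ir")
    return red, ir


def _ar1_ibis(
    rng: np.random.Generator,
    n: int,
    mean_ms: float,
    sd_ms: float,
    rmssd_ms: float,
) -> np.ndarray:
    # AR(1) with stationary sd = sd_ms and successive-difference RMS =
    # rmssd_ms: var(diff) = 2 sd^2 (1 - rho)  =>  rho = 1 - rmssd^2/(2 sd^2).
    rho = 1.0 - rmssd_ms**2 / (2.0 * sd_ms**2)
    rho = float(np.clip(rho, -0.99, 0.99))
    z = np.empty(n)
    z[0] = rng.normal()
    innov = rng.normal(size=n - 1) * np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        z[i] = rho * z[i - 1] + innov[i - 1]
    return np.clip(mean_ms + sd_ms * z, IBI_MIN_MS, IBI_MAX_MS)


def generate_labeled_dataset(
    n_subjects: int = 15,
    windows_per_subject_per_class: int = 20,
    regime: RegimeSpec = RegimeSpec(),
    imbalance: float | None = None,
    seed: int = 0,
    window_s: float = 30.0,
    subject_sd_ms: float = 30.0,
) -> LabeledDataset:
    """Labeled PRV feature rows from per-subject, per-class IBI regimes.

    Every window draws an AR(1) IBI series matched to the class regime's
    mean, spread and RMSSD, shifted by a per-subject offset, then runs the
    real ectopic correction and feature extractor.  ``imbalance`` (if given)
    is the target baseline-class fraction, achieved by generating fewer
    stress windows (e.g. 0.64 reproduces a 64/36 split).  Subject ids are
    recorded for group-aware splits.
    """
    if n_subjects < 4:
        raise InvalidConfigError("need at least 4 subjects")
    rng = np.random.default_rng(seed)
    n_base = windows_per_subject_per_class
    if imbalance is None:
        n_stress = n_base
    else:
        if not 0 < imbalance < 1:
            raise InvalidConfigError("imbalance must be a fraction in (0, 1)")
        n_stress = max(1, int(round(n_base * (1.0 - imbalance) / imbalance)))

    rows, labels, subjects = [], [], []
    for subj in range(n_subjects):
        offset = rng.normal(0.0, subject_sd_ms)
        rmssd_scale = float(np.exp(rng.normal(0.0, 0.10)))
        for label, n_windows, mean_ibi, sd, rmssd in (
            (0, n_base, regime.baseline_mean_ibi, regime.baseline_ibi_sd,
             regime.baseline_rmssd),
            (1, n_stress, regime.stress_mean_ibi, regime.stress_ibi_sd,
             regime.stress_rmssd),
        ):
            mean_subj = float(np.clip(mean_ibi + offset, IBI_MIN_MS + 50,
                                      IBI_MAX_MS - 200))
            for _ in range(n_windows):
                n_beats = max(4, int(round(window_s * 1000.0 / mean_subj)))
                ibis = _ar1_ibis(rng, n_beats - 1, mean_subj, sd,
                                 rmssd * rmssd_scale)
                series = correct_ectopic(IBISeries(ibis, window_s))
                feats = extract_features(series, n_peaks=n_beats)
                rows.append(feats.to_array())
                labels.append(label)
                subjects.append(subj)
    return LabeledDataset(
        np.vstack(rows), np.asarray(labels, dtype=int), np.asarray(subjects)
    )
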