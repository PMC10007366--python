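"""Interbeat intervals and ultra-short-term pulse-rate-variability features.

Interbeat intervals (IBIs) are the temporal differences of successive
systolic-peak locations, in milliseconds.  Ectopic (premature/aberrant)
beats produce outlier IBIs that distort variability statistics; they are
corrected by a single Z-score pass replacing outliers with the window
median.  From the corrected series a fixed 6-feature vector is extracted —
mean IBI, IBI standard deviation, peak count, RMSSD, excess kurtosis and
skewness — which is the classifier's input contract.

Moment conventions: population (n-denominator) standard deviation, Fisher
(excess) kurtosis, Fisher–Pearson skewness — the defaults of the usual
scientific-Python toolchain.  Zero-variance windows yield kurtosis and
skewness of 0 by convention so the classifier input stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .peaks import PeakList
from .signal_core import InsufficientDataError

__all__ = [
    "IBISeries",
    "PRVFeatureVector",
    "FEATURE_NAMES",
    "ibis_from_peaks",
    "correct_ectopic",
    "extract_features",
]

FEATURE_NAMES = (
    "mean_ibi",
    "std_ibi",
    "no_of_peaks",
    "rmssd",
    "kurtosis_ibi",
    "skewness_ibi",
)


@dataclass(frozen=True)
class IBISeries:
    """Successive interbeat intervals in milliseconds."""

    intervals_ms: np.ndarray
    window_s: float = 30.0

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals_ms, dtype=float)
        object.__setattr__(self, "intervals_ms", iv)
        if iv.size and np.any(iv <= 0):
            raise ValueError("all intervals must be positive")

    def __len__(self) -> int:
        return self.intervals_ms.size


@dataclass(frozen=True)
class PRVFeatureVector:
    """The frozen 6-feature PRV vector (order is a serialization contract)."""

    mean_ibi: float
    std_ibi: float
    no_of_peaks: int
    rmssd: float
    kurtosis_ibi: float
    skewness_ibi: float
    quality: tuple[str, ...] = ()

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.mean_ibi,
                self.std_ibi,
                float(self.no_of_peaks),
                self.rmssd,
                self.kurtosis_ibi,
                self.skewness_ibi,
            ]
        )


def ibis_from_peaks(peaks: PeakList) -> IBISeries:
    """IBIs (ms) from successive systolic-peak sample indices."""
    if len(peaks) < 2:
        raise InsufficientDataError(
            f"need >= 2 peaks for interbeat intervals, got {len(peaks)}"
        )
    ms = np.diff(peaks.indices) / peaks.fs * 1000.0
    return IBISeries(ms)


def correct_ectopic(ibis: IBISeries, z_cutoff: float = 3.0) -> IBISeries:
    """Replace outlier intervals (|z| > cutoff) with the window median.

    Mean and standard deviation (population convention) are computed once
    over the input window; replacement happens in a single pass with no
    re-estimation.  A zero-spread window has no outliers by construction.
    """
    if len(ibis) < 3:
        raise InsufficientDataError("ectopic correction needs >= 3 intervals")
    x = ibis.intervals_ms
    mu = float(np.mean(x))
    sd = float(np.std(x))  # population (n) convention
    if sd == 0.0:
        return IBISeries(x.copy(), ibis.window_s)
    med = float(np.median(x))
    z = np.abs((x - mu) / sd)
    out = np.where(z > z_cutoff, med, x)
    return IBISeries(out, ibis.window_s)


def extract_features(ibis: IBISeries, n_peaks: int) -> PRVFeatureVector:
    """The 6-feature ultra-short-term PRV vector from a corrected IBI series.

    rmssd = sqrt(mean(diff(ibis)^2)); kurtosis is excess (normal -> 0);
    both higher moments are the biased (population) estimators.
    """
    if len(ibis) < 3:
        raise InsufficientDataError("feature extraction needs >= 3 intervals")
    x = ibis.intervals_ms
    mean_ibi = float(np.mean(x))
    std_ibi = float(np.std(x))
    diffs = np.diff(x)
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    quality: tuple[str, ...] = ()
    if std_ibi == 0.0:
        kurt, skew = 0.0, 0.0
        quality = ("zero_variance_ibis",)
    else:
        kurt = float(spstats.kurtosis(x, fisher=True, bias=True))
        skew = float(spstats.skew(x, bias=True))
    return PRVFeatureVector(
        mean_ibi=mean_ibi,
        std_ibi=std_ibi,
        no_of_peaks=int(n_peaks),
        rmssd=rmssd,
        kurtosis_ibi=kurt,
        skewness_ibi=skew,
        quality=quality,
    )
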