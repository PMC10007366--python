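"""Streaming systolic-peak detection on the filtered PPG.

Detection mimics the embedded implementation: every incoming sample is
compared with the preceding ``k`` samples (the rising-edge span at the
maximal supported heart rate), and a candidate local maximum is emitted when
the signal's monotony flips from rising to falling at a sample that exceeds
all ``k`` predecessors.  A second stage selects systolic peaks from the
candidates by (a) enforcing the minimum inter-peak distance implied by a
220 bpm ceiling and (b) rejecting candidates whose amplitude falls below a
fraction of the running median of recently accepted peaks — which removes
diastolic bumps and noise blips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signal_core import FIRFilter, InvalidConfigError, PPGSignal

__all__ = [
    "PeakList",
    "search_range",
    "min_peak_distance",
    "detect_local_maxima",
    "select_systolic",
    "detect_peaks",
    "realign_to_raw",
]


@dataclass(frozen=True)
class PeakList:
    """Accepted systolic peak positions (0-based sample indices, ascending)."""

    indices: np.ndarray
    fs: float
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        amp = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "amplitudes", amp)
        if idx.size != amp.size:
            raise InvalidConfigError("indices and amplitudes must align")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise InvalidConfigError("peak indices must be strictly increasing")
        if not np.all(np.isfinite(amp)):
            raise InvalidConfigError("peak amplitudes must be finite")
        if self.fs <= 0:
            raise InvalidConfigError("fs must be positive")

    def __len__(self) -> int:
        return self.indices.size

    def times(self) -> np.ndarray:
        return self.indices / self.fs


def search_range(fs: float, hr_max_bpm: float = 220.0) -> int:
    """Rising-edge span in samples at the maximal heart rate.

    At the shortest physiological interbeat interval (60/hr_max seconds) the
    rise from trough to systolic peak occupies roughly half a beat, so
    k = ceil((fs * 60/hr_max) / 2).  At 50 Hz with a 220 bpm ceiling this is
    7 samples.
    """
    if fs <= 0 or hr_max_bpm <= 0:
        raise InvalidConfigError("fs and hr_max_bpm must be positive")
    return max(1, math.ceil(fs * 60.0 / hr_max_bpm / 2.0))


def min_peak_distance(fs: float, hr_max_bpm: float = 220.0) -> int:
    """Minimum admissible spacing between systolic peaks, in samples."""
    if fs <= 0 or hr_max_bpm <= 0:
        raise InvalidConfigError("fs and hr_max_bpm must be positive")
    return max(1, math.floor(fs * 60.0 / hr_max_bpm))


def detect_local_maxima(signal: PPGSignal, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Streaming candidate detection.

    Emits index ``n`` when sample ``n`` strictly exceeds each of its ``k``
    predecessors and the monotony changes from rising to falling at ``n``
    (confirmed one sample later, as a streaming device would).  Candidates
    inside the warm-up region (``signal.valid_from``) are suppressed.
    Returns ``(indices, amplitudes)``.
    """
    if k < 1:
        raise InvalidConfigError("k must be >= 1")
    x = signal.samples
    idx: list[int] = []
    rising = False
    for n in range(1, x.size):
        if x[n] > x[n - 1]:
            rising = True
        elif x[n] < x[n - 1]:
            if rising:
                apex = n - 1
                lo = max(0, apex - k)
                if apex >= signal.valid_from and apex - lo >= 1 and np.all(
                    x[lo:apex] < x[apex]
                ):
                    idx.append(apex)
            rising = False
    indices = np.asarray(idx, dtype=int)
    return indices, x[indices] if indices.size else np.empty(0)


def select_systolic(
    candidates: np.ndarray,
    amplitudes: np.ndarray,
    fs: float,
    hr_max_bpm: float = 220.0,
    theta: float = 0.5,
    m: int = 5,
) -> PeakList:
    """Pick systolic peaks from local-maxima candidates.

    Two rules, applied to candidates in ascending order:

    * amplitude gate — a candidate below ``theta`` times the running median
      of the last ``m`` accepted peak amplitudes is rejected (diastolic
      bump / noise);
    * spacing — within any cluster closer than ``floor(fs * 60 / hr_max_bpm)``
      samples, only the largest-amplitude candidate survives (earlier index
      wins ties).
    """
    candidates = np.asarray(candidates, dtype=int)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if candidates.size and np.any(np.diff(candidates) <= 0):
        raise InvalidConfigError("candidates must be strictly ascending")
    d_min = min_peak_distance(fs, hr_max_bpm)

    kept_idx: list[int] = []
    kept_amp: list[float] = []
    for i, a in zip(candidates, amplitudes):
        if kept_idx:
            recent = kept_amp[-m:]
            if a < theta * float(np.median(recent)):
                continue
        if kept_idx and i - kept_idx[-1] < d_min:
            if a > kept_amp[-1]:  # tie keeps the earlier index
                kept_idx[-1] = int(i)
                kept_amp[-1] = float(a)
            continue
        kept_idx.append(int(i))
        kept_amp.append(float(a))
    return PeakList(np.asarray(kept_idx, dtype=int), fs, np.asarray(kept_amp))


def detect_peaks(
    filtered: PPGSignal,
    hr_max_bpm: float = 220.0,
    theta: float = 0.5,
    m: int = 5,
) -> PeakList:
    """Candidate detection + systolic selection in one call."""
    k = search_range(filtered.fs, hr_max_bpm)
    cand, amp = detect_local_maxima(filtered, k)
    return select_systolic(cand, amp, filtered.fs, hr_max_bpm, theta, m)


def realign_to_raw(peaks: PeakList, filt: FIRFilter) -> PeakList:
    """Map peak indices from filtered-signal to raw-signal coordinates by
    subtracting the FIR group delay.  Indices that would become negative
    (deep inside warm-up) are dropped."""
    shifted = peaks.indices - filt.group_delay
    keep = shifted >= 0
    return PeakList(shifted[keep], peaks.fs, peaks.amplitudes[keep])
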