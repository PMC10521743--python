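"""Pan-Tompkins QRS detection.

The classic stage chain: 5-15 Hz band-pass, five-point derivative,
squaring, 150 ms moving-window integration, then adaptive dual-threshold
peak picking with a 200 ms refractory period and a search-back pass at
1.66x the running RR estimate.  Detections are finally refined to the
local maximum of the raw signal within +-50 ms, so downstream slicing
anchors at the true R maximum.

All stage constants follow the original 1985 design; the band-pass is a
zero-phase forward-backward biquad and the integrator window is centred,
so no group-delay compensation is needed at the refinement step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import ECGRecord

__all__ = ["RPeakList", "pan_tompkins", "rr_intervals"]

REFRACTORY_S = 0.2
INTEGRATION_WINDOW_S = 0.15
SEARCHBACK_FACTOR = 1.66
REFINE_WINDOW_S = 0.05


@dataclass(frozen=True)
class RPeakList:
    """Detected R-peak sample indices (strictly increasing) and their fs."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=np.int64))
        if self.indices.ndim != 1:
            raise ValueError("indices must be 1-D")
        if self.indices.size and (np.any(np.diff(self.indices) <= 0) or self.indices[0] < 0):
            raise ValueError("indices must be strictly increasing and non-negative")

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.fs


def _preprocess(x: np.ndarray, fs: float) -> np.ndarray:
    """Band-pass, derivative, square, centred moving-window integration."""
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    # five-point derivative (1/8)(2x[n] + x[n-1] - x[n-3] - 2x[n-4]), zero-centred
    kernel = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) * (fs / 8.0)
    deriv = np.convolve(filtered, kernel, mode="same")
    squared = deriv**2
    win = max(int(round(INTEGRATION_WINDOW_S * fs)), 1)
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")
    return integrated


def _adaptive_pick(integrated: np.ndarray, fs: float) -> list[int]:
    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(integrated, distance=refractory)
    if cand.size == 0:
        return []

    # threshold warm-up from the first 2 s of the integrated signal
    warm = integrated[: int(2 * fs)]
    spki = 0.25 * float(np.max(warm)) if warm.size else 0.0
    npki = 0.5 * float(np.mean(warm)) if warm.size else 0.0

    accepted: list[int] = []
    rr_history: list[float] = []
    noise_peaks: list[int] = []

    def threshold1() -> float:
        return npki + 0.25 * (spki - npki)

    last = None
    for idx in cand:
        peak = integrated[idx]
        # search-back: if the gap since the last beat exceeds 1.66x the
        # running RR, re-examine skipped candidates at half threshold
        if last is not None and rr_history:
            rr_avg = float(np.mean(rr_history[-8:]))
            if (idx - last) > SEARCHBACK_FACTOR * rr_avg * fs:
                for nidx in [j for j in noise_peaks if last < j < idx]:
                    if integrated[nidx] > 0.5 * threshold1() and nidx - last >= int(
                        round(REFRACTORY_S * fs)
                    ):
                        accepted.append(nidx)
                        rr_history.append((nidx - last) / fs)
                        spki = 0.25 * integrated[nidx] + 0.75 * spki
                        last = nidx
                noise_peaks = [j for j in noise_peaks if j > idx]
        if peak > threshold1():
            if last is None or idx - last >= int(round(REFRACTORY_S * fs)):
                accepted.append(idx)
                if last is not None:
                    rr_history.append((idx - last) / fs)
                last = idx
                spki = 0.125 * peak + 0.875 * spki
            else:
                npki = 0.125 * peak + 0.875 * npki
        else:
            noise_peaks.append(idx)
            npki = 0.125 * peak + 0.875 * npki
    return accepted


def pan_tompkins(record: ECGRecord) -> RPeakList:
    """Detect R-peaks in a record.

    Requires at least 2 s of signal at fs >= 100 Hz.  A record in which no
    QRS-like activity is found yields an empty :class:`RPeakList` rather
    than an error; detections on noise-only input may be spurious by
    contract.  Detections are invariant to a constant signal offset.
    """
    if record.fs < 100.0:
        raise ValueError(f"sampling rate {record.fs} Hz too low (need >= 100 Hz)")
    if record.duration_s < 2.0:
        raise ValueError("record shorter than 2 s")
    fs = record.fs
    x = record.samples - np.mean(record.samples)  # offset invariance
    integrated = _preprocess(x, fs)
    if not np.any(integrated > 0):
        return RPeakList(np.empty(0, dtype=np.int64), fs)
    raw_detections = _adaptive_pick(integrated, fs)
    if not raw_detections:
        return RPeakList(np.empty(0, dtype=np.int64), fs)

    # refine to the raw-signal local maximum within +-50 ms
    half = int(round(REFINE_WINDOW_S * fs))
    refined = []
    for idx in raw_detections:
        lo = max(idx - half, 0)
        hi = min(idx + half + 1, x.size)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    # enforce the refractory period after refinement (keep the larger peak)
    keep: list[int] = []
    for idx in refined:
        if keep and idx - keep[-1] < int(round(REFRACTORY_S * fs)):
            if x[idx] > x[keep[-1]]:
                keep[-1] = int(idx)
        else:
            keep.append(int(idx))
    return RPeakList(np.asarray(keep, dtype=np.int64), fs)


def rr_intervals(rpeaks: RPeakList) -> np.ndarray:
    """RR intervals in seconds: first differences of the peak indices / fs."""
    if len(rpeaks) < 2:
        raise ValueError("need at least 2 R-peaks to form RR intervals")
    return np.diff(rpeaks.indices) / rpeaks.fs
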