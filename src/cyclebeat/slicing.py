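"""Slicing a record into subsequences for encoding.

Three strategies: random slices of 1.5-4.0 s, slices of the same random
lengths anchored at detected R-peaks, and single-heartbeat extraction
where each slice spans exactly one RR interval ``[r_k, r_{k+1})`` —
half-open, so consecutive beats tile the inter-peak signal without
overlap.  All strategies are pure functions of (record, rpeaks, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .io import ECGRecord
from .rpeaks import RPeakList

__all__ = [
    "SliceKind",
    "Slice",
    "slice_random",
    "slice_rpeak_aligned",
    "extract_heartbeats",
    "SLICE_DURATION_RANGE_S",
    "BEAT_RR_RANGE_S",
]

SLICE_DURATION_RANGE_S = (1.5, 4.0)
BEAT_RR_RANGE_S = (0.3, 2.0)


class SliceKind(str, Enum):
    RANDOM = "RANDOM"
    RPEAK_ALIGNED = "RPEAK_ALIGNED"
    HEARTBEAT = "HEARTBEAT"


@dataclass
class Slice:
    """A timed subsequence (s_j, t_j) of one record.

    ``times`` are seconds relative to the slice start (``times[0] == 0``).
    """

    values: np.ndarray
    times: np.ndarray
    record_id: str
    start_index: int
    kind: SliceKind

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.values.shape != self.times.shape or self.values.ndim != 1:
            raise ValueError("values and times must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise ValueError("empty slice")
        if self.times[0] != 0.0 or (self.times.size > 1 and np.any(np.diff(self.times) <= 0)):
            raise ValueError("times must start at 0 and be strictly increasing")

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])


def _make_slice(record: ECGRecord, start: int, stop: int, kind: SliceKind) -> Slice:
    values = record.samples[start:stop]
    times = (np.arange(start, stop) - start) / record.fs
    return Slice(values=values, times=times, record_id=record.record_id,
                 start_index=int(start), kind=kind)


def slice_random(record: ECGRecord, n_slices: int, seed: int = 0) -> list[Slice]:
    """Extract ``n_slices`` slices at uniformly random starts.

    Durations are uniform in [1.5, 4.0] s, truncated to fit the record.
    """
    if record.duration_s < SLICE_DURATION_RANGE_S[1]:
        raise ValueError(
            f"record shorter than {SLICE_DURATION_RANGE_S[1]} s; cannot take random slices"
        )
    if n_slices < 0:
        raise ValueError("n_slices must be non-negative")
    rng = np.random.default_rng(seed)
    n = record.samples.size
    out = []
    for _ in range(n_slices):
        start = int(rng.integers(0, n - int(SLICE_DURATION_RANGE_S[0] * record.fs)))
        dur = float(rng.uniform(*SLICE_DURATION_RANGE_S))
        stop = min(start + int(round(dur * record.fs)), n)
        out.append(_make_slice(record, start, stop, SliceKind.RANDOM))
    return out


def slice_rpeak_aligned(
    record: ECGRecord, rpeaks: RPeakList, n_slices: int, seed: int = 0
) -> list[Slice]:
    """Extract slices that always start exactly at a detected R-peak.

    The starting peak is chosen uniformly among peaks followed by at least
    1.5 s of signal; durations are uniform in [1.5, 4.0] s as for random
    slicing, truncated to the record end.
    """
    if n_slices < 0:
        raise ValueError("n_slices must be non-negative")
    n = record.samples.size
    min_len = int(SLICE_DURATION_RANGE_S[0] * record.fs)
    eligible = rpeaks.indices[rpeaks.indices + min_len <= n]
    if eligible.size == 0:
        raise ValueError("no R-peak with >= 1.5 s of signal after it")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_slices):
        start = int(eligible[rng.integers(0, eligible.size)])
        dur = float(rng.uniform(*SLICE_DURATION_RANGE_S))
        stop = min(start + int(round(dur * record.fs)), n)
        out.append(_make_slice(record, start, stop, SliceKind.RPEAK_ALIGNED))
    return out


def extract_heartbeats(
    record: ECGRecord, rpeaks: RPeakList, return_rejected: bool = False
):
    """One slice per consecutive R-peak pair, spanning ``[r_k, r_{k+1})``.

    Beats whose RR interval falls outside [0.3, 2.0] s are dropped (the
    rejection count is available via ``return_rejected``) — a guard
    against detector glitches feeding implausible cycles downstream.
    Fewer than two peaks yields an empty list with a warning.
    """
    if len(rpeaks) < 2:
        warnings.warn("fewer than 2 R-peaks; no heartbeats extracted", stacklevel=2)
        return ([], 0) if return_rejected else []
    out = []
    rejected = 0
    for a, b in zip(rpeaks.indices[:-1], rpeaks.indices[1:]):
        rr = (b - a) / record.fs
        if not BEAT_RR_RANGE_S[0] <= rr <= BEAT_RR_RANGE_S[1]:
            rejected += 1
            continue
        out.append(_make_slice(record, int(a), int(b), SliceKind.HEARTBEAT))
    return (out, rejected) if return_rejected else out
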