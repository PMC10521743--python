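"""Cyclic latent trajectories and their parameterisations.

A d-dimensional latent trajectory traces the unit circle in its first two
coordinates and holds time-constant shape coefficients in the rest:

* full variant (``full``):   l(t) = (cos 2*pi*f(t - tau), sin 2*pi*f(t - tau), b3..bd)
* pace variant (``pace``):  l(t) = (cos 2*pi*f*t,         sin 2*pi*f*t,         b3..bd)
  (no shift tau — inputs are R-peak aligned, so every slice starts at the
  same point of the cycle)
* shape variant (``shape``): l(t) = (cos 2*pi*t, sin 2*pi*t, b3..bd)
  (no pace either — t is the cycle phase in [0, 1], produced by
  time-normalising a single heartbeat)

The stored embedding therefore has d, d-1 and d-2 numbers respectively,
while the trajectory always lives in d dimensions.  ``f`` is in Hz
(cycles per second), so heart rate in bpm is ``60 * f``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "Variant",
    "TrajectoryParams",
    "latent_trajectory",
    "trajectory_period",
    "rmse",
]


class Variant(str, Enum):
    FULL = "full"      # frequency + shift + shape
    PACE = "pace"    # frequency + shape (R-peak aligned inputs)
    SHAPE = "shape"  # shape only (phase-normalised single beats)


@dataclass(frozen=True, eq=False)
class TrajectoryParams:
    """Embedding of one slice: variant tag plus its stored numbers.

    ``b`` holds the shape coefficients (b_3 ... b_d), so the latent
    dimension is ``d = len(b) + 2`` for every variant; the number of
    *stored* parameters is d (full), d-1 (pace) or d-2 (shape).
    """

    variant: Variant
    b: np.ndarray
    f: Optional[float] = None
    tau: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "b", np.asarray(self.b, dtype=np.float64))
        object.__setattr__(self, "variant", Variant(self.variant))
        if self.b.ndim != 1 or self.b.size < 1:
            raise ValueError("b must be a 1-D vector with at least one entry (d >= 3)")
        if self.variant in (Variant.FULL, Variant.PACE):
            if self.f is None or not np.isfinite(self.f) or self.f <= 0:
                raise ValueError(f"variant {self.variant.value} requires f > 0")
        elif self.f is not None:
            raise ValueError("shape variant stores no frequency")
        if self.variant is Variant.FULL:
            if self.tau is None or not np.isfinite(self.tau):
                raise ValueError("full variant requires a finite shift tau")
        elif self.tau is not None:
            raise ValueError(f"variant {self.variant.value} stores no shift")

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrajectoryParams):
            return NotImplemented
        return (self.variant is other.variant and self.f == other.f
                and self.tau == other.tau and np.array_equal(self.b, other.b))

    @property
    def d(self) -> int:
        """Latent-space dimension."""
        return int(self.b.size) + 2

    @property
    def n_stored(self) -> int:
        """Number of stored embedding parameters (d / d-1 / d-2)."""
        return {Variant.FULL: self.d, Variant.PACE: self.d - 1, Variant.SHAPE: self.d - 2}[
            self.variant
        ]

    def to_vector(self) -> np.ndarray:
        """Flatten to the stored parameter vector (f, [tau], b...)."""
        head = {
            Variant.FULL: [self.f, self.tau],
            Variant.PACE: [self.f],
            Variant.SHAPE: [],
        }[self.variant]
        return np.concatenate([np.asarray(head, dtype=np.float64), self.b])

    @classmethod
    def from_vector(cls, variant: Variant, vec: np.ndarray) -> "TrajectoryParams":
        vec = np.asarray(vec, dtype=np.float64)
        variant = Variant(variant)
        if variant is Variant.FULL:
            return cls(variant, b=vec[2:], f=float(vec[0]), tau=float(vec[1]))
        if variant is Variant.PACE:
            return cls(variant, b=vec[1:], f=float(vec[0]))
        return cls(variant, b=vec)


def latent_trajectory(params: TrajectoryParams, t) -> np.ndarray:
    """Evaluate the latent trajectory l(t).

    ``t`` may be a scalar or an array of times (seconds; cycle phase for
    the shape variant).  Returns shape ``(..., d)``; the first two
    coordinates lie on the unit circle, the remaining ``d - 2`` are the
    time-constant shape coefficients.
    """
    t = np.asarray(t, dtype=np.float64)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    if params.variant is Variant.FULL:
        angle = 2.0 * np.pi * params.f * (t - params.tau)
    elif params.variant is Variant.PACE:
        angle = 2.0 * np.pi * params.f * t
    else:
        angle = 2.0 * np.pi * t
    out = np.empty(t.shape + (params.d,), dtype=np.float64)
    out[..., 0] = np.cos(angle)
    out[..., 1] = np.sin(angle)
    out[..., 2:] = params.b
    return out


def trajectory_period(params: TrajectoryParams) -> float:
    """Period of the cyclic trajectory: 1/f, or 1.0 for the shape variant
    (one heartbeat is one unit of phase)."""
    if params.variant is Variant.SHAPE:
        return 1.0
    return 1.0 / float(params.f)


def rmse(s: np.ndarray, s_hat: np.ndarray) -> float:
    """Root-mean-square error between a signal and its reconstruction (mV)."""
    s = np.asarray(s, dtype=np.float64)
    s_hat = np.asarray(s_hat, dtype=np.float64)
    if s.shape != s_hat.shape or s.ndim != 1 or s.size == 0:
        raise ValueError("s and s_hat must be equal-length non-empty vectors")
    return float(np.sqrt(np.mean((s - s_hat) ** 2)))
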