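"""Autoencoding slices onto cyclic latent trajectories.

The encoder maps a slice to trajectory parameters (pace f, shift tau,
shape coefficients b — which of these exist depends on the variant); the
decoder f_D maps a point of the latent trajectory to a sample value, so a
slice is reconstructed as ``s_hat(t) = f_D(l(t))`` on any time grid.
Training minimises the mean over slices of the per-slice mean squared
reconstruction error, which weights short and long slices equally.

Input handling per variant:

* full / pace variants consume slices on their own clock: the encoder
  sees the slice resampled to a fixed grid spanning ``max_len_s`` seconds
  (zero beyond the slice end) together with the slice duration, and the
  trajectory is evaluated at times in seconds from the slice start.
* the shape variant consumes single heartbeats only, time-normalised to
  cycle phase in [0, 1): the encoder sees the beat resampled onto a phase
  grid, and the trajectory is evaluated at phases.  A beat and the same
  beat uniformly time-stretched therefore produce the same embedding.

No filtering or amplitude normalisation is applied to the inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._autodiff import Adam, Tensor, concat
from .slicing import Slice, SliceKind
from .trajectory import TrajectoryParams, Variant, latent_trajectory, rmse

__all__ = ["EncoderConfig", "CyclicAutoencoder", "train", "encode", "reconstruct"]

_F_FLOOR_HZ = 0.1  # frequency head is softplus(x) + floor, keeping f > 0


@dataclass
class EncoderConfig:
    """Training configuration for one autoencoder."""

    variant: str = "pace"
    d: int = 16
    max_len_s: Optional[float] = None  # default: 2.0 for beats, 4.0 for slices
    hidden_widths: tuple[int, ...] = (64, 64)
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 30
    seed: int = 0


def _xavier(rng: np.random.Generator, n_in: int, n_out: int) -> Tensor:
    scale = np.sqrt(2.0 / (n_in + n_out))
    return Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)


def _zeros(n: int) -> Tensor:
    return Tensor(np.zeros((1, n)), requires_grad=True)


class CyclicAutoencoder(BaseEstimator, TransformerMixin):
    """Scikit-learn style estimator learning cyclic latent trajectories.

    Parameters
    ----------
    variant : {"full", "pace", "shape"}
        Trajectory parameterisation.  ``full`` learns frequency, shift and
        shape; ``pace`` drops the shift (R-peak-aligned inputs); ``shape``
        drops the frequency too (phase-normalised heartbeats).
    d : int
        Latent-space dimension (>= 3); the stored embedding has d, d-1 or
        d-2 numbers depending on the variant.
    max_len_s : float, optional
        Pad/crop horizon in seconds for the full/pace variants; defaults
        to 2.0 when fitting heartbeats and 4.0 otherwise.
    hidden_widths, decoder_widths : tuple of int
        Hidden-layer widths of the encoder MLP and the decoder f_D.
    n_grid : int
        Number of points of the fixed input grid the encoder sees.
    n_loss_points : int
        Number of sample points per slice the reconstruction loss uses.
    learning_rate, batch_size, epochs, random_state
        Optimisation settings (Adam); fully reproducible from
        ``random_state`` in single-threaded execution.

    Attributes
    ----------
    training_log_ : list of float
        Mean per-slice reconstruction RMSE (mV) after each epoch.
    """

    def __init__(self, variant: str = "pace", d: int = 16, max_len_s: Optional[float] = None,
                 hidden_widths: tuple[int, ...] = (64, 64),
                 decoder_widths: tuple[int, ...] = (64, 64), n_grid: int = 64,
                 n_loss_points: int = 48, closure_weight: float = 0.25,
                 learning_rate: float = 1e-3, batch_size: int = 64,
                 epochs: int = 30, random_state: int = 0):
        self.variant = variant
        self.d = d
        self.max_len_s = max_len_s
        self.hidden_widths = hidden_widths
        self.decoder_widths = decoder_widths
        self.n_grid = n_grid
        self.n_loss_points = n_loss_points
        self.closure_weight = closure_weight
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    @classmethod
    def from_config(cls, config: EncoderConfig) -> "CyclicAutoencoder":
        return cls(variant=config.variant, d=config.d, max_len_s=config.max_len_s,
                   hidden_widths=tuple(config.hidden_widths),
                   learning_rate=config.learning_rate, batch_size=config.batch_size,
                   epochs=config.epochs, random_state=config.seed)

    # ------------------------------------------------------------------
    def _validate(self, slices: Sequence[Slice]) -> Variant:
        variant = Variant(self.variant)
        if self.d < 3:
            raise ValueError("latent dimension d must be >= 3")
        if variant is Variant.SHAPE:
            if any(s.kind is not SliceKind.HEARTBEAT for s in slices):
                raise ValueError("shape variant requires HEARTBEAT slices only")
        return variant

    def _resolved_max_len(self, slices: Sequence[Slice]) -> float:
        if self.max_len_s is not None:
            return float(self.max_len_s)
        if slices and all(s.kind is SliceKind.HEARTBEAT for s in slices):
            return 2.0
        return 4.0

    def _featurize(self, s: Slice) -> np.ndarray:
        """Resample one slice onto the encoder's fixed input grid."""
        dur = s.times[-1] if s.times[-1] > 0 else 1.0 / max(len(s.times), 1)
        if self.variant_ is Variant.SHAPE:
            grid = np.linspace(0.0, 1.0, self.n_grid, endpoint=False)
            return np.interp(grid, s.times / dur, s.values)
        grid = np.linspace(0.0, self.max_len_s_, self.n_grid, endpoint=False)
        vals = np.interp(grid, s.times, s.values, right=0.0)
        vals[grid > s.times[-1]] = 0.0
        return np.concatenate([vals, [dur]])

    def _loss_points(self, s: Slice) -> tuple[np.ndarray, np.ndarray]:
        """(times, targets) the reconstruction loss is evaluated at."""
        k = min(self.n_loss_points, len(s.values))
        idx = np.unique(np.round(np.linspace(0, len(s.values) - 1, k)).astype(int))
        t = s.times[idx]
        if self.variant_ is Variant.SHAPE:
            dur = s.times[-1] if s.times[-1] > 0 else 1.0
            t = t / dur
        vals = s.values[idx]
        if idx.size < self.n_loss_points:  # pad by repeating the last point
            pad = self.n_loss_points - idx.size
            t = np.concatenate([t, np.full(pad, t[-1])])
            vals = np.concatenate([vals, np.full(pad, vals[-1])])
        return t, vals

    # ------------------------------------------------------------------
    def _init_weights(self, n_in: int, rng: np.random.Generator) -> None:
        enc, dims = [], [n_in, *self.hidden_widths]
        for a, b in zip(dims[:-1], dims[1:]):
            enc.append((_xavier(rng, a, b), _zeros(b)))
        h = dims[-1]
        self._enc_layers = enc
        self._head_b = (_xavier(rng, h, self.d - 2), _zeros(self.d - 2))
        self._head_f = (_xavier(rng, h, 1), _zeros(1)) if self.variant_ is not Variant.SHAPE else None
        self._head_tau = (_xavier(rng, h, 1), _zeros(1)) if self.variant_ is Variant.FULL else None
        dec, ddims = [], [self.d, *self.decoder_widths, 1]
        for a, b in zip(ddims[:-1], ddims[1:]):
            dec.append((_xavier(rng, a, b), _zeros(b)))
        self._dec_layers = dec

    @property
    def _params(self) -> list[Tensor]:
        out = []
        for w, b in self._enc_layers + self._dec_layers:
            out += [w, b]
        for head in (self._head_b, self._head_f, self._head_tau):
            if head is not None:
                out += list(head)
        return out

    def _encode_batch(self, X: Tensor) -> tuple[Tensor, Optional[Tensor], Optional[Tensor]]:
        h = X
        for w, b in self._enc_layers:
            h = (h @ w + b).tanh()
        bw, bb = self._head_b
        b_coef = h @ bw + bb
        f = tau = None
        if self._head_f is not None:
            fw, fb = self._head_f
            f = (h @ fw + fb).softplus() + _F_FLOOR_HZ
        if self._head_tau is not None:
            tw, tb = self._head_tau
            tau = h @ tw + tb
        return b_coef, f, tau

    def _decode(self, latent: Tensor) -> Tensor:
        h = latent
        for i, (w, b) in enumerate(self._dec_layers):
            h = h @ w + b
            if i < len(self._dec_layers) - 1:
                h = h.tanh()
        return h

    def _forward_loss(self, X: np.ndarray, T: np.ndarray, S: np.ndarray,
                      D: Optional[np.ndarray] = None) -> tuple[Tensor, np.ndarray]:
        """Reconstruction (+ cycle-closure) loss of a batch.

        ``D`` carries, for heartbeat slices, the cycle duration in seconds
        (0 for other slice kinds).  A heartbeat spans exactly one cycle,
        but the reconstruction error alone leaves the pace scale free: any
        f = c/T with c <= 1 traces the same family of arcs.  The closure
        term ``2 - 2 cos(2 pi f T)`` vanishes only when the latent
        trajectory closes over the beat, pinning c = 1.
        """
        B, K = T.shape
        b_coef, f, tau = self._encode_batch(Tensor(X))
        t = Tensor(T)
        if self.variant_ is Variant.SHAPE:
            angle = t * (2.0 * np.pi)
        elif self.variant_ is Variant.FULL:
            angle = (t - tau) * f * (2.0 * np.pi)
        else:
            angle = t * f * (2.0 * np.pi)
        cos = angle.cos().reshape(B, K, 1)
        sin = angle.sin().reshape(B, K, 1)
        shape = b_coef.reshape(B, 1, self.d - 2).expand((B, K, self.d - 2))
        latent = concat([cos, sin, shape], axis=-1).reshape(B * K, self.d)
        s_hat = self._decode(latent).reshape(B, K)
        diff = s_hat - Tensor(S)
        loss = (diff * diff).mean()
        if (D is not None and f is not None and self.closure_weight > 0
                and np.any(D > 0)):
            angle_t = Tensor(D[:, None]) * f * (2.0 * np.pi)
            closure = ((1.0 - angle_t.cos()) * 2.0).mean()
            loss = loss + closure * self.closure_weight
        per_slice = np.sqrt(np.mean(diff.data**2, axis=1))
        return loss, per_slice

    # ------------------------------------------------------------------
    def fit(self, slices: Sequence[Slice], y=None) -> "CyclicAutoencoder":
        """Train encoder and decoder on a list of slices."""
        slices = list(slices)
        self.variant_ = self._validate(slices)
        if len(slices) < self.batch_size:
            raise ValueError(
                f"need at least batch_size={self.batch_size} slices, got {len(slices)}"
            )
        self.max_len_s_ = self._resolved_max_len(slices)
        too_long = [s for s in slices if self.variant_ is not Variant.SHAPE
                    and s.duration_s > self.max_len_s_]
        if too_long:
            raise ValueError("slice longer than max_len_s; increase the horizon")

        X = np.stack([self._featurize(s) for s in slices])
        TS = [self._loss_points(s) for s in slices]
        T = np.stack([t for t, _ in TS])
        S = np.stack([v for _, v in TS])
        # cycle durations: closure applies to heartbeat slices only, where
        # one slice is known to span exactly one cardiac cycle
        D = np.array([
            s.duration_s if s.kind is SliceKind.HEARTBEAT else 0.0 for s in slices
        ])

        rng = np.random.default_rng(self.random_state)
        self._init_weights(X.shape[1], rng)
        opt = Adam(self._params, lr=self.learning_rate)
        n = len(slices)
        self.training_log_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_rmse = np.empty(n)
            pos = 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                loss, per_slice = self._forward_loss(X[idx], T[idx], S[idx], D[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_rmse[pos : pos + idx.size] = per_slice
                pos += idx.size
            self.training_log_.append(float(np.mean(epoch_rmse)))
        return self

    # ------------------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "_enc_layers"):
            raise ValueError("autoencoder is not fitted")

    def encode(self, s: Slice) -> TrajectoryParams:
        """Embed one slice; deterministic given the trained weights."""
        self._check_fitted()
        if self.variant_ is Variant.SHAPE and s.kind is not SliceKind.HEARTBEAT:
            raise ValueError("shape variant encodes HEARTBEAT slices only")
        if self.variant_ is not Variant.SHAPE and s.duration_s > self.max_len_s_:
            raise ValueError(f"slice of {s.duration_s:.2f} s exceeds max_len_s={self.max_len_s_}")
        x = self._featurize(s)[None, :]
        b_coef, f, tau = self._encode_batch(Tensor(x))
        return TrajectoryParams(
            variant=self.variant_,
            b=b_coef.data[0],
            f=float(f.data[0, 0]) if f is not None else None,
            tau=float(tau.data[0, 0]) if tau is not None else None,
        )

    def transform(self, slices: Sequence[Slice]) -> np.ndarray:
        """Embed slices; rows are flattened stored-parameter vectors."""
        self._check_fitted()
        return np.stack([self.encode(s).to_vector() for s in slices])

    def reconstruct(self, params: TrajectoryParams, times: np.ndarray) -> np.ndarray:
        """Evaluate ``f_D(l(t))`` on an arbitrary time grid."""
        self._check_fitted()
        times = np.asarray(times, dtype=np.float64)
        latent = latent_trajectory(params, times).reshape(-1, self.d)
        return self._decode(Tensor(latent)).data.reshape(times.shape)

    def reconstruction_rmse(self, s: Slice) -> float:
        """Encode-then-reconstruct RMSE of one slice on its own samples."""
        params = self.encode(s)
        t = s.times
        if self.variant_ is Variant.SHAPE:
            dur = s.times[-1] if s.times[-1] > 0 else 1.0
            t = t / dur
        return rmse(s.values, self.reconstruct(params, t))

    # ------------------------------------------------------------------
    def save(self, path: str) -> None:
        """Single-file checkpoint: weights plus configuration."""
        self._check_fitted()
        arrays = {f"p{i}": p.data for i, p in enumerate(self._params)}
        meta = dict(self.get_params(), variant_=self.variant_.value,
                    max_len_s_=self.max_len_s_,
                    training_log_=getattr(self, "training_log_", []))
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str) -> "CyclicAutoencoder":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            training_log = meta.pop("training_log_")
            variant_ = meta.pop("variant_")
            max_len_s_ = meta.pop("max_len_s_")
            meta["hidden_widths"] = tuple(meta["hidden_widths"])
            meta["decoder_widths"] = tuple(meta["decoder_widths"])
            model = cls(**meta)
            model.variant_ = Variant(variant_)
            model.max_len_s_ = max_len_s_
            model.training_log_ = training_log
            n_in = model.n_grid + (0 if model.variant_ is Variant.SHAPE else 1)
            model._init_weights(n_in, np.random.default_rng(0))
            for i, p in enumerate(model._params):
                p.data = data[f"p{i}"]
        return model


# ---------------------------------------------------------------------------
# functional wrappers


def train(slices: Sequence[Slice], config: EncoderConfig) -> CyclicAutoencoder:
    """Train an autoencoder on slices per the given configuration."""
    return CyclicAutoencoder.from_config(config).fit(slices)


def encode(model: CyclicAutoencoder, s: Slice) -> TrajectoryParams:
    return model.encode(s)


def reconstruct(model: CyclicAutoencoder, params: TrajectoryParams,
                times: np.ndarray) -> np.ndarray:
    return model.reconstruct(params, times)
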