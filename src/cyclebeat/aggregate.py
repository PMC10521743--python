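"""Collapsing a sequence of per-slice embeddings into one record embedding.

Two aggregation functions: coordinate-wise averaging of the stored
parameter vectors (order-invariant, a deliberate information bottleneck)
and a bidirectional LSTM read in temporal order (order-sensitive),
trained end-to-end with a softmax classifier head since no
aggregation-only objective exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._autodiff import Adam, Tensor, concat, softmax_cross_entropy
from .trajectory import TrajectoryParams, Variant

__all__ = [
    "AggregationMethod",
    "EmbeddingSequence",
    "RecordEmbedding",
    "aggregate_mean",
    "LSTMAggregator",
    "train_rnn_aggregator",
    "aggregate_rnn",
]


class AggregationMethod(str, Enum):
    MEAN = "MEAN"
    RNN = "RNN"


@dataclass
class EmbeddingSequence:
    """Ordered per-slice embeddings of one record (uniform variant and d)."""

    record_id: str
    embeddings: list[TrajectoryParams]

    def __post_init__(self) -> None:
        if not self.embeddings:
            raise ValueError("embedding sequence must be non-empty")
        v0, d0 = self.embeddings[0].variant, self.embeddings[0].d
        if any(e.variant is not v0 or e.d != d0 for e in self.embeddings):
            raise ValueError("all embeddings must share variant and latent dimension")

    @property
    def variant(self) -> Variant:
        return self.embeddings[0].variant

    @property
    def d(self) -> int:
        return self.embeddings[0].d

    def matrix(self) -> np.ndarray:
        """Stacked stored-parameter vectors, one row per slice in order."""
        return np.stack([e.to_vector() for e in self.embeddings])


@dataclass(frozen=True)
class RecordEmbedding:
    """A single vector representing one record, with its provenance."""

    vector: np.ndarray
    method: AggregationMethod


def aggregate_mean(seq: EmbeddingSequence) -> RecordEmbedding:
    """Coordinate-wise mean of the flattened embeddings.

    Permutation-invariant; the mean of n copies of one embedding is that
    embedding.  The frequency, shift and shape entries are averaged
    jointly as one vector.
    """
    return RecordEmbedding(vector=seq.matrix().mean(axis=0), method=AggregationMethod.MEAN)


def _as_matrix(seq) -> np.ndarray:
    if isinstance(seq, EmbeddingSequence):
        return seq.matrix()
    m = np.asarray(seq, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] == 0:
        raise ValueError("sequence must be a non-empty (n, e) matrix")
    return m


class LSTMAggregator(BaseEstimator, ClassifierMixin):
    """LSTM aggregation trained jointly with a softmax classifier head.

    Reads each record's embedding sequence in temporal order (and in
    reverse when ``bidirectional``); the record embedding is the
    concatenation of the final hidden states, passed through a small
    fully connected head for classification.  Sequences longer than
    ``max_seq_len`` are uniformly subsampled.
    """

    def __init__(self, hidden_size: int = 32, bidirectional: bool = True,
                 head_width: int = 32, epochs: int = 40, learning_rate: float = 1e-2,
                 max_seq_len: int = 512, random_state: int = 0):
        self.hidden_size = hidden_size
        self.bidirectional = bidirectional
        self.head_width = head_width
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.max_seq_len = max_seq_len
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _init_weights(self, e: int, n_classes: int, rng: np.random.Generator) -> None:
        h = self.hidden_size

        def mk(n_in, n_out):
            return Tensor(rng.normal(0.0, np.sqrt(2.0 / (n_in + n_out)), (n_in, n_out)),
                          requires_grad=True)

        def cell():
            return {g: (mk(e, h), mk(h, h), Tensor(np.zeros((1, h)), requires_grad=True))
                    for g in "ifgo"}

        self._cells = [cell()]
        if self.bidirectional:
            self._cells.append(cell())
        emb_dim = h * len(self._cells)
        self._w1 = mk(emb_dim, self.head_width)
        self._b1 = Tensor(np.zeros((1, self.head_width)), requires_grad=True)
        self._w2 = mk(self.head_width, n_classes)
        self._b2 = Tensor(np.zeros((1, n_classes)), requires_grad=True)

    @property
    def _params(self) -> list[Tensor]:
        out = []
        for cell in self._cells:
            for g in "ifgo":
                out += list(cell[g])
        out += [self._w1, self._b1, self._w2, self._b2]
        return out

    def _run_direction(self, cell, X: np.ndarray, mask: np.ndarray, reverse: bool) -> Tensor:
        B, T, _ = X.shape
        h = Tensor(np.zeros((B, self.hidden_size)))
        c = Tensor(np.zeros((B, self.hidden_size)))
        steps = range(T - 1, -1, -1) if reverse else range(T)
        for t in steps:
            x_t = Tensor(X[:, t, :])
            m = Tensor(mask[:, t : t + 1])
            gates = {}
            for g in "ifgo":
                w, u, b = cell[g]
                z = x_t @ w + h @ u + b
                gates[g] = z.tanh() if g == "g" else z.sigmoid()
            c_new = gates["f"] * c + gates["i"] * gates["g"]
            h_new = gates["o"] * c_new.tanh()
            keep = 1.0 - m
            c = c_new * m + c * keep
            h = h_new * m + h * keep
        return h

    def _forward(self, X: np.ndarray, mask: np.ndarray) -> Tensor:
        hs = [self._run_direction(cell, X, mask, reverse=(i == 1))
              for i, cell in enumerate(self._cells)]
        return hs[0] if len(hs) == 1 else concat(hs, axis=-1)

    def _pack(self, sequences) -> tuple[np.ndarray, np.ndarray]:
        mats = [_as_matrix(s) for s in sequences]
        e = mats[0].shape[1]
        if any(m.shape[1] != e for m in mats):
            raise ValueError("all sequences must share embedding dimension (variant/d)")
        mats = [
            m if m.shape[0] <= self.max_seq_len
            else m[np.round(np.linspace(0, m.shape[0] - 1, self.max_seq_len)).astype(int)]
            for m in mats
        ]
        T = max(m.shape[0] for m in mats)
        X = np.zeros((len(mats), T, e))
        mask = np.zeros((len(mats), T))
        for i, m in enumerate(mats):
            X[i, : m.shape[0]] = m
            mask[i, : m.shape[0]] = 1.0
        return X, mask

    # ------------------------------------------------------------------
    def fit(self, sequences: Sequence, labels) -> "LSTMAggregator":
        """Joint training of the LSTM and the classifier head."""
        y = np.asarray(labels)
        if len(sequences) != y.shape[0]:
            raise ValueError("number of sequences and labels must match")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        X, mask = self._pack(sequences)
        rng = np.random.default_rng(self.random_state)
        self._init_weights(X.shape[2], self.classes_.size, rng)
        opt = Adam(self._params, lr=self.learning_rate)
        self.training_log_ = []
        for _ in range(self.epochs):
            emb = self._forward(X, mask)
            logits = (emb @ self._w1 + self._b1).tanh() @ self._w2 + self._b2
            loss = softmax_cross_entropy(logits, y_idx)
            opt.zero_grad()
            loss.backward()
            opt.step()
            self.training_log_.append(float(loss.data))
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "_cells"):
            raise ValueError("aggregator is not fitted")

    def embed(self, seq) -> RecordEmbedding:
        """Record embedding of one sequence (deterministic at inference)."""
        self._check_fitted()
        X, mask = self._pack([seq])
        emb = self._forward(X, mask)
        return RecordEmbedding(vector=emb.data[0].copy(), method=AggregationMethod.RNN)

    def predict_proba(self, sequences: Sequence) -> np.ndarray:
        self._check_fitted()
        X, mask = self._pack(sequences)
        emb = self._forward(X, mask)
        logits = ((emb @ self._w1 + self._b1).tanh() @ self._w2 + self._b2).data
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, sequences: Sequence) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(sequences), axis=1)]


def train_rnn_aggregator(sequences: Sequence, labels, **kwargs) -> LSTMAggregator:
    """Train an LSTM aggregator (with classifier head) on labelled sequences."""
    return LSTMAggregator(**kwargs).fit(sequences, labels)


def aggregate_rnn(aggregator: LSTMAggregator, seq) -> RecordEmbedding:
    """Aggregate one sequence with a trained LSTM aggregator."""
    return aggregator.embed(seq)
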