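"""Classifier head, evaluation protocol, beat windows and noise scoring.

The classifier head is a small fully connected softmax network over
record (or window) embeddings.  Evaluation follows the binary
AF-vs-non-AF protocol: sensitivity, specificity, PPV, F1, accuracy at a
0.5 decision threshold plus rank-based AUC, reported as mean +- std over
stratified 10-fold cross-validation with hyperparameters held fixed
across folds.

Also here: sliding 30-beat windows with the three window-labelling
strategies (middle / majority / threshold), the reconstruction-error
noise score, and heart-rate timelines from per-beat pace parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .aggregate import EmbeddingSequence
from .autoencoder import CyclicAutoencoder
from .io import ECGRecord
from .rpeaks import pan_tompkins
from .slicing import extract_heartbeats
from .trajectory import Variant

__all__ = [
    "WindowStrategy",
    "BeatWindow",
    "MetricReport",
    "train_classifier",
    "evaluate_binary_af",
    "cross_validate",
    "label_window",
    "make_windows",
    "noise_score",
    "noise_scores",
    "heart_rate_timeline",
    "WINDOW_SIZE",
]

WINDOW_SIZE = 30


class WindowStrategy(str, Enum):
    MIDDLE = "MIDDLE"
    MAJORITY = "MAJORITY"
    THRESHOLD = "THRESHOLD"


@dataclass
class BeatWindow:
    """30 consecutive annotated heartbeats with their window label."""

    embeddings: np.ndarray  # (30, e)
    af_flags: np.ndarray  # (30,) booleans
    label: bool

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        self.af_flags = np.asarray(self.af_flags, dtype=bool)
        if self.af_flags.size != WINDOW_SIZE or self.embeddings.shape[0] != WINDOW_SIZE:
            raise ValueError(f"a beat window holds exactly {WINDOW_SIZE} beats")


@dataclass
class MetricReport:
    """Per-metric (mean, std) over folds, at the given decision threshold.

    ``auc`` is ``None`` when undefined (single-class fold labels).
    """

    f1: tuple[float, float]
    sensitivity: tuple[float, float]
    specificity: tuple[float, float]
    ppv: tuple[float, float]
    auc: Optional[tuple[float, float]]
    accuracy: tuple[float, float]
    threshold: float = 0.5

    def as_dict(self) -> dict:
        out = {}
        for name in ("f1", "sensitivity", "specificity", "ppv", "auc", "accuracy"):
            val = getattr(self, name)
            out[name] = None if val is None else {"mean": val[0], "std": val[1]}
        out["threshold"] = self.threshold
        return out


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    hidden_layer_sizes: tuple[int, ...] = (64, 32),
    max_iter: int = 400,
    seed: int = 0,
) -> MLPClassifier:
    """Fit the fully connected softmax classifier head.

    Works for the 4-class record task and the binary window task alike;
    probabilities from ``predict_proba`` sum to 1 per row.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("embedding and label counts must match")
    clf = MLPClassifier(hidden_layer_sizes=hidden_layer_sizes, max_iter=max_iter,
                        random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on tiny desk-scale fits
        clf.fit(X, y)
    return clf


def evaluate_binary_af(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricReport:
    """Single-fold binary AF-vs-non-AF metrics.

    ``probabilities`` are AF-class probabilities in [0, 1] (for a 4-class
    head, pass its AF softmax component); ``labels`` are booleans with
    True = AF.  Threshold metrics use the given decision threshold; AUC is
    the rank statistic over all positive/negative pairs.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=bool)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("probabilities and labels must be equal-length vectors")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pred = p >= threshold
    tp = int(np.sum(pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    acc = (tp + tn) / y.size
    f1 = 2 * ppv * sens / (ppv + sens) if ppv + sens else 0.0
    auc = (float(roc_auc_score(y, p)), 0.0) if 0 < y.sum() < y.size else None
    return MetricReport(
        f1=(f1, 0.0), sensitivity=(sens, 0.0), specificity=(spec, 0.0),
        ppv=(ppv, 0.0), auc=auc, accuracy=(acc, 0.0), threshold=threshold,
    )


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    af_label=1,
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
    make_classifier: Optional[Callable[[], object]] = None,
) -> MetricReport:
    """Stratified k-fold cross-validation of the binary AF evaluation.

    ``y`` may be multi-class; the AF probability is the softmax component
    of ``af_label`` and all other classes count as non-AF.  Folds are
    near-equal-sized, stratified by class, each used once for testing;
    hyperparameters are identical across folds.  Reports per-metric mean
    and standard deviation over the k folds.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if k > y.shape[0]:
        raise ValueError(f"k={k} exceeds the number of items {y.shape[0]}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports: list[MetricReport] = []
    for train_idx, test_idx in skf.split(X, y):
        if make_classifier is None:
            clf = train_classifier(X[train_idx], y[train_idx], seed=seed)
        else:
            clf = make_classifier()
            clf.fit(X[train_idx], y[train_idx])
        proba = clf.predict_proba(X[test_idx])
        classes = list(clf.classes_)
        af_p = proba[:, classes.index(af_label)] if af_label in classes else np.zeros(
            test_idx.size
        )
        fold_reports.append(
            evaluate_binary_af(af_p, y[test_idx] == af_label, threshold=threshold)
        )

    def agg(name: str):
        vals = [getattr(r, name) for r in fold_reports]
        if name == "auc":
            vals = [v for v in vals if v is not None]
            if not vals:
                return None
        means = np.array([v[0] for v in vals])
        return (float(means.mean()), float(means.std()))

    return MetricReport(
        f1=agg("f1"), sensitivity=agg("sensitivity"), specificity=agg("specificity"),
        ppv=agg("ppv"), auc=agg("auc"), accuracy=agg("accuracy"), threshold=threshold,
    )


def label_window(
    af_flags: Sequence[bool],
    strategy: WindowStrategy = WindowStrategy.MAJORITY,
    p: float = 0.8,
    middle_index: int = WINDOW_SIZE // 2,
    strict: bool = False,
) -> bool:
    """Label a 30-beat window from its per-beat AF flags.

    MAJORITY: AF iff at least 15 of 30 beats are AF.  MIDDLE: the flag of
    the beat at ``middle_index`` (default 15, 0-based — no true centre
    exists for an even window; index 14 available via the argument).
    THRESHOLD: AF iff the AF fraction reaches ``p`` (non-strict ``>=`` by
    default so p=0.8 is attainable at exactly 24/30; ``strict`` switches
    to ``>``).
    """
    flags = np.asarray(af_flags, dtype=bool)
    if flags.size != WINDOW_SIZE:
        raise ValueError(f"expected exactly {WINDOW_SIZE} flags, got {flags.size}")
    strategy = WindowStrategy(strategy)
    count = int(flags.sum())
    if strategy is WindowStrategy.MAJORITY:
        return count >= WINDOW_SIZE // 2
    if strategy is WindowStrategy.MIDDLE:
        return bool(flags[middle_index])
    frac = count / WINDOW_SIZE
    return frac > p if strict else frac >= p


def make_windows(
    embeddings: np.ndarray,
    af_flags: Sequence[bool],
    stride: int = 1,
    strategy: WindowStrategy = WindowStrategy.MAJORITY,
    p: float = 0.8,
) -> list[BeatWindow]:
    """Sliding 30-beat windows over one record's beats.

    ``embeddings`` is the (n_beats, e) matrix of per-beat embeddings in
    source order and ``af_flags`` the matching per-beat annotations.
    Fewer than 30 beats yields an empty list with a warning.
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    flags = np.asarray(af_flags, dtype=bool)
    if emb.shape[0] != flags.size:
        raise ValueError("embeddings and af_flags must have matching lengths")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if flags.size < WINDOW_SIZE:
        warnings.warn("fewer than 30 annotated beats; no windows produced", stacklevel=2)
        return []
    out = []
    for start in range(0, flags.size - WINDOW_SIZE + 1, stride):
        w_flags = flags[start : start + WINDOW_SIZE]
        out.append(
            BeatWindow(
                embeddings=emb[start : start + WINDOW_SIZE],
                af_flags=w_flags,
                label=label_window(w_flags, strategy=strategy, p=p),
            )
        )
    return out


def noise_score(model: CyclicAutoencoder, record: ECGRecord) -> float:
    """Mean per-heartbeat reconstruction RMSE of a record (mV).

    The score is an anomaly statistic for the noise class: a model
    trained on clean beats reconstructs regular records well and noise
    poorly.  A record with no extractable beats scores ``inf`` (ranked
    most anomalous); being a mean, the score is duration-invariant for
    stationary signals.
    """
    rpeaks = pan_tompkins(record)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beats = extract_heartbeats(record, rpeaks)
    beats = [b for b in beats if b.duration_s <= model.max_len_s_] \
        if model.variant_ is not Variant.SHAPE else beats
    if not beats:
        return float("inf")
    return float(np.mean([model.reconstruction_rmse(b) for b in beats]))


def noise_scores(model: CyclicAutoencoder, records: Sequence[ECGRecord]) -> np.ndarray:
    """Noise scores for a dataset; beat-free records get the maximum
    observed finite score."""
    raw = np.array([noise_score(model, r) for r in records])
    finite = raw[np.isfinite(raw)]
    if finite.size:
        raw[~np.isfinite(raw)] = finite.max()
    else:
        raw[:] = 0.0
    return raw


def heart_rate_timeline(
    seq: EmbeddingSequence, beat_times: Sequence[float]
) -> list[tuple[float, float]]:
    """Per-slice heart-rate estimates: (midpoint time s, 60*f bpm).

    Requires a variant that models the pace explicitly (the shape variant
    stores no frequency and is rejected).
    """
    if seq.variant is Variant.SHAPE:
        raise ValueError("shape variant stores no frequency; no heart-rate timeline")
    times = np.asarray(beat_times, dtype=np.float64)
    if times.size != len(seq.embeddings):
        raise ValueError("beat_times length must match the number of embeddings")
    return [(float(t), 60.0 * float(e.f)) for t, e in zip(times, seq.embeddings)]
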