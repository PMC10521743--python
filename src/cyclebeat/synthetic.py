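"""Synthetic single-lead ECG generation with known ground truth.

The generator emulates the kind of data mobile single-lead recorders
produce (300 Hz, a few-mV dynamic range): a P-QRS-T morphology built from
five Gaussian bumps per beat, a log-normal RR tachogram with controllable
mean heart rate and variability, optional P-wave suppression (the classic
atrial-fibrillation signature together with RR irregularity), additive
white noise, mild sinusoidal baseline wander, and noise-only records for
the "too noisy to classify" class.

Every record is fully reproducible from its seed and is returned together
with a :class:`SynthTruth` carrying the exact R-peak times and RR
intervals, so downstream detectors and encoders can be scored against
construction-time truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import yaml

from .io import ECGRecord

__all__ = ["SynthConfig", "SynthTruth", "generate_record", "generate_dataset"]

# (amplitude mV, phase offset as fraction of the RR interval, width fraction)
# Beats span R-to-R, so the cycle runs R, S, T, ..., P, Q(of the next beat).
_WAVES = (
    ("P", 0.15, 0.88, 0.040),
    ("Q", -0.10, 0.965, 0.014),
    ("R", 1.00, 0.0, 0.016),
    ("S", -0.20, 0.035, 0.014),
    ("T", 0.30, 0.30, 0.060),
)

_BASELINE_AMP_MV = 0.05
_BASELINE_FREQ_HZ = 0.3
RR_CLIP_S = (0.3, 2.0)


@dataclass
class SynthConfig:
    """Parameters of one synthetic record.

    ``rr_cv`` is the coefficient of variation (sd/mean) of the RR
    intervals; ``p_wave_amplitude = 0`` suppresses atrial activity;
    ``noise_only`` produces a beat-free record of noise plus baseline
    wander labelled NOISY.
    """

    fs: float = 300.0
    duration_s: float = 30.0
    mean_hr_bpm: float = 70.0
    rr_cv: float = 0.03
    p_wave_amplitude: float = 0.15
    noise_sd: float = 0.02
    noise_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 30.0 <= self.mean_hr_bpm <= 220.0:
            raise ValueError(f"mean_hr_bpm must be in [30, 220], got {self.mean_hr_bpm}")
        if not 0.0 <= self.rr_cv <= 0.5:
            raise ValueError(f"rr_cv must be in [0, 0.5], got {self.rr_cv}")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if self.noise_sd < 0 or self.p_wave_amplitude < 0:
            raise ValueError("noise_sd and p_wave_amplitude must be non-negative")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SynthConfig":
        return cls(**yaml.safe_load(text))


@dataclass
class SynthTruth:
    """Construction-time ground truth of a synthetic record."""

    r_peak_times_s: np.ndarray
    rr_intervals_s: np.ndarray
    rhythm_label: str

    def __post_init__(self) -> None:
        self.r_peak_times_s = np.asarray(self.r_peak_times_s, dtype=np.float64)
        self.rr_intervals_s = np.asarray(self.rr_intervals_s, dtype=np.float64)


def _lognormal_rr(rng: np.random.Generator, mean_s: float, cv: float, n: int) -> np.ndarray:
    if cv == 0.0:
        return np.full(n, mean_s)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean_s) - sigma2 / 2.0
    return np.clip(rng.lognormal(mu, np.sqrt(sigma2), size=n), *RR_CLIP_S)


def _beat_waveform(t: np.ndarray, beat_starts: np.ndarray, rrs: np.ndarray,
                   p_amp: float) -> np.ndarray:
    """Sum of per-beat Gaussian bumps evaluated on the time grid ``t``."""
    sig = np.zeros_like(t)
    for name, amp, phase, width in _WAVES:
        if name == "P":
            amp = p_amp
        if amp == 0.0:
            continue
        centers = beat_starts + phase * rrs
        widths = width * rrs
        for c, w in zip(centers, widths):
            lo = np.searchsorted(t, c - 5 * w)
            hi = np.searchsorted(t, c + 5 * w)
            sig[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / w) ** 2)
    return sig


def generate_record(
    config: SynthConfig,
    record_id: Optional[str] = None,
    rhythm_label: Optional[str] = None,
    rr_pattern: Optional[np.ndarray] = None,
) -> tuple[ECGRecord, SynthTruth]:
    """Generate one synthetic record and its ground truth.

    RR intervals are i.i.d. log-normal with the configured mean and CV,
    clipped to [0.3, 2.0] s, unless an explicit ``rr_pattern`` (seconds) is
    supplied — used e.g. for bigeminy-like alternating rhythms.  The noisy
    class is produced with ``noise_only=True``.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.fs * config.duration_s))
    t = np.arange(n) / config.fs

    baseline = _BASELINE_AMP_MV * np.sin(2 * np.pi * _BASELINE_FREQ_HZ * t)

    if config.noise_only:
        samples = baseline + rng.normal(0.0, max(config.noise_sd, 1e-12), size=n)
        record = ECGRecord(
            record_id=record_id or f"synth-{config.seed}",
            samples=samples,
            fs=config.fs,
            rhythm_label=rhythm_label or "NOISY",
        )
        truth = SynthTruth(np.empty(0), np.empty(0), record.rhythm_label)
        return record, truth

    mean_rr = 60.0 / config.mean_hr_bpm
    if config.duration_s < mean_rr:
        raise ValueError("duration_s too short for a single beat at this heart rate")

    if rr_pattern is not None:
        rrs = np.asarray(rr_pattern, dtype=np.float64)
    else:
        # generous draw, then truncate to the record length
        n_draw = int(np.ceil(config.duration_s / RR_CLIP_S[0])) + 2
        rrs = _lognormal_rr(rng, mean_rr, config.rr_cv, n_draw)
    starts = np.concatenate([[0.0], np.cumsum(rrs)])
    keep = starts[:-1] + rrs <= config.duration_s
    rrs = rrs[keep]
    starts = starts[: rrs.size]
    if rrs.size == 0:
        raise ValueError("duration_s too short for a single beat at this heart rate")

    # the final beat's closing R-peak belongs to a truncated extra cycle, so
    # every RR interval in the truth is bracketed by two rendered R-peaks
    gen_starts = np.append(starts, starts[-1] + rrs[-1])
    gen_rrs = np.append(rrs, rrs[-1])
    clean = _beat_waveform(t, gen_starts, gen_rrs, config.p_wave_amplitude)
    samples = clean + baseline
    if config.noise_sd > 0:
        samples = samples + rng.normal(0.0, config.noise_sd, size=n)

    label = rhythm_label or ("AF" if config.p_wave_amplitude == 0 else "NSR")
    record = ECGRecord(
        record_id=record_id or f"synth-{config.seed}",
        samples=samples,
        fs=config.fs,
        rhythm_label=label,
    )
    truth = SynthTruth(r_peak_times_s=gen_starts, rr_intervals_s=rrs, rhythm_label=label)
    return record, truth


def _class_config(label: str, rng: np.random.Generator, fs: float, duration_s: float,
                  noise_sd: float, seed: int) -> tuple[SynthConfig, Optional[np.ndarray]]:
    """Draw class-conditional generator settings.

    NSR: regular rhythm (CV <= 0.05) with P waves.  AF: irregular rhythm
    (CV >= 0.15) with suppressed P waves.  OTHER: bigeminy-like alternating
    short/long RR with P waves.  NOISY: noise only.
    """
    if label == "NSR":
        cfg = SynthConfig(fs=fs, duration_s=duration_s,
                          mean_hr_bpm=float(rng.uniform(55, 95)),
                          rr_cv=float(rng.uniform(0.01, 0.05)),
                          p_wave_amplitude=0.15, noise_sd=noise_sd, seed=seed)
        return cfg, None
    if label == "AF":
        cfg = SynthConfig(fs=fs, duration_s=duration_s,
                          mean_hr_bpm=float(rng.uniform(70, 130)),
                          rr_cv=float(rng.uniform(0.15, 0.30)),
                          p_wave_amplitude=0.0, noise_sd=noise_sd, seed=seed)
        return cfg, None
    if label == "OTHER":
        hr = float(rng.uniform(55, 95))
        mean_rr = 60.0 / hr
        n_draw = int(np.ceil(duration_s / (0.6 * mean_rr))) + 2
        jitter = rng.normal(0.0, 0.01 * mean_rr, size=n_draw)
        pattern = np.where(np.arange(n_draw) % 2 == 0, 0.72 * mean_rr, 1.28 * mean_rr)
        cfg = SynthConfig(fs=fs, duration_s=duration_s, mean_hr_bpm=hr,
                          rr_cv=0.0, p_wave_amplitude=0.15, noise_sd=noise_sd, seed=seed)
        return cfg, np.clip(pattern + jitter, *RR_CLIP_S)
    if label == "NOISY":
        cfg = SynthConfig(fs=fs, duration_s=duration_s, noise_only=True,
                          noise_sd=max(noise_sd, 0.25), seed=seed)
        return cfg, None
    raise ValueError(f"unknown class label {label!r}")


def generate_dataset(
    n_records: int,
    class_mix: dict[str, float] | tuple[float, float, float, float],
    seed: int = 0,
    fs: float = 300.0,
    duration_s: float = 30.0,
    noise_sd: float = 0.02,
) -> list[tuple[ECGRecord, SynthTruth]]:
    """Generate a labelled dataset with exact class proportions.

    ``class_mix`` gives proportions over (NSR, AF, OTHER, NOISY) summing to
    1; class counts follow the largest-remainder rule so divisible mixes
    are honoured exactly.  Per-record seeds are derived deterministically
    from the master seed.
    """
    if n_records < 0:
        raise ValueError("n_records must be non-negative")
    if isinstance(class_mix, dict):
        mix = np.array([class_mix.get(c, 0.0) for c in ("NSR", "AF", "OTHER", "NOISY")])
    else:
        mix = np.asarray(class_mix, dtype=np.float64)
    if mix.size != 4 or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
        raise ValueError("class_mix must be 4 non-negative proportions summing to 1")
    if n_records == 0:
        return []

    exact = mix * n_records
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for i in np.argsort(-remainder)[: n_records - counts.sum()]:
        counts[i] += 1

    labels = [lab for lab, c in zip(("NSR", "AF", "OTHER", "NOISY"), counts) for _ in range(c)]
    master = np.random.default_rng(seed)
    order = master.permutation(n_records)
    out: list[tuple[ECGRecord, SynthTruth]] = []
    for k, pos in enumerate(order):
        label = labels[pos]
        sub_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(sub_seed)
        cfg, pattern = _class_config(label, rng, fs, duration_s, noise_sd, sub_seed + 1)
        rec, truth = generate_record(
            cfg, record_id=f"synth-{seed}-{k:04d}", rhythm_label=label, rr_pattern=pattern
        )
        out.append((rec, truth))
    return out
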