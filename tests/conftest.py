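"""Shared fixtures: small synthetic datasets and quickly trained models."""

import warnings

import numpy as np
import pytest

from cyclebeat import (
    CyclicAutoencoder,
    SynthConfig,
    extract_heartbeats,
    generate_record,
    pan_tompkins,
)


def collect_beats(n_records: int, seed0: int = 0, mean_hr_bpm: float = 75.0,
                  rr_cv: float = 0.10, noise_sd: float = 0.02,
                  duration_s: float = 60.0) -> list:
    beats = []
    for i in range(n_records):
        rec, _ = generate_record(
            SynthConfig(duration_s=duration_s, mean_hr_bpm=mean_hr_bpm, rr_cv=rr_cv,
                        noise_sd=noise_sd, seed=seed0 + i)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beats.extend(extract_heartbeats(rec, pan_tompkins(rec)))
    return beats


@pytest.fixture(scope="session")
def nsr_beats():
    """A few hundred clean heartbeats from regular-rhythm records."""
    return collect_beats(5, seed0=10)


@pytest.fixture(scope="session")
def pace_model(nsr_beats):
    """A small trained pace-variant autoencoder for contract tests."""
    return CyclicAutoencoder(variant="pace", d=8, epochs=8, random_state=0).fit(nsr_beats)


@pytest.fixture(scope="session")
def shape_model(nsr_beats):
    """A small trained shape-variant autoencoder."""
    return CyclicAutoencoder(variant="shape", d=8, epochs=8, random_state=0).fit(nsr_beats)
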