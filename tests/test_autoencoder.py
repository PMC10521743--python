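"""Autoencoder contracts: bookkeeping, determinism, invariances, recovery."""

import numpy as np
import pytest

from cyclebeat.autoencoder import CyclicAutoencoder, EncoderConfig, train
from cyclebeat.slicing import Slice, SliceKind
from cyclebeat.trajectory import Variant


def sinusoid_beats(n=300, period=0.8, fs=300.0, seed=0):
    """Single-cycle sinusoid slices of a fixed period, HEARTBEAT kind."""
    rng = np.random.default_rng(seed)
    out = []
    k = int(round(period * fs))
    for i in range(n):
        t = np.arange(k) / fs
        v = np.sin(2 * np.pi * t / period) + rng.normal(0, 0.01, size=k)
        out.append(Slice(values=v, times=t, record_id=f"s{i}", start_index=0,
                         kind=SliceKind.HEARTBEAT))
    return out


class TestContracts:
    def test_parameter_count_bookkeeping(self, nsr_beats):
        few = nsr_beats[:80]
        for variant, expect in (("full", lambda d: d), ("pace", lambda d: d - 1),
                                ("shape", lambda d: d - 2)):
            m = CyclicAutoencoder(variant=variant, d=8, epochs=1, batch_size=32,
                                  random_state=0).fit(few)
            params = m.encode(few[0])
            assert params.n_stored == expect(8)
            assert m.transform(few[:3]).shape == (3, expect(8))
            if variant != "shape":
                assert params.f > 0

    def test_encode_deterministic(self, pace_model, nsr_beats):
        a = pace_model.encode(nsr_beats[0]).to_vector()
        b = pace_model.encode(nsr_beats[0]).to_vector()
        assert np.array_equal(a, b)

    def test_fit_reproducible_from_seed(self, nsr_beats):
        few = nsr_beats[:100]
        m1 = CyclicAutoencoder(variant="pace", d=8, epochs=2, batch_size=32,
                               random_state=7).fit(few)
        m2 = CyclicAutoencoder(variant="pace", d=8, epochs=2, batch_size=32,
                               random_state=7).fit(few)
        assert m1.training_log_ == m2.training_log_
        assert np.array_equal(m1.transform(few[:5]), m2.transform(few[:5]))

    def test_training_loss_decreases(self, pace_model):
        assert pace_model.training_log_[-1] < pace_model.training_log_[0]

    def test_reconstruct_shape_contract(self, pace_model, nsr_beats):
        params = pace_model.encode(nsr_beats[0])
        times = np.linspace(0, 0.7, 123)
        assert pace_model.reconstruct(params, times).shape == (123,)

    def test_reconstruction_periodicity(self, pace_model, nsr_beats):
        params = pace_model.encode(nsr_beats[0])
        t = np.linspace(0, 0.5, 50)
        a = pace_model.reconstruct(params, t)
        b = pace_model.reconstruct(params, t + 1.0 / params.f)
        assert np.allclose(a, b, atol=1e-9)

    def test_save_load_round_trip(self, pace_model, nsr_beats, tmp_path):
        path = str(tmp_path / "model.npz")
        pace_model.save(path)
        back = CyclicAutoencoder.load(path)
        assert np.array_equal(back.transform(nsr_beats[:4]),
                              pace_model.transform(nsr_beats[:4]))


class TestValidation:
    def test_shape_variant_rejects_non_beat_slices(self, nsr_beats):
        s = nsr_beats[0]
        rnd = Slice(values=s.values, times=s.times, record_id=s.record_id,
                    start_index=s.start_index, kind=SliceKind.RANDOM)
        with pytest.raises(ValueError, match="HEARTBEAT"):
            CyclicAutoencoder(variant="shape", d=8, epochs=1,
                              batch_size=8).fit([rnd] * 16)

    def test_shape_variant_rejects_non_beat_encode(self, shape_model, nsr_beats):
        s = nsr_beats[0]
        rnd = Slice(values=s.values, times=s.times, record_id=s.record_id,
                    start_index=s.start_index, kind=SliceKind.RANDOM)
        with pytest.raises(ValueError):
            shape_model.encode(rnd)

    def test_overlong_slice_rejected(self, pace_model):
        t = np.arange(0, 3.0, 1 / 300.0)
        s = Slice(values=np.zeros(t.size), times=t, record_id="x", start_index=0,
                  kind=SliceKind.RPEAK_ALIGNED)
        with pytest.raises(ValueError, match="max_len_s"):
            pace_model.encode(s)

    def test_too_few_slices_rejected(self, nsr_beats):
        with pytest.raises(ValueError, match="batch_size"):
            CyclicAutoencoder(variant="pace", batch_size=64).fit(nsr_beats[:10])

    def test_d_floor(self, nsr_beats):
        with pytest.raises(ValueError, match="d"):
            CyclicAutoencoder(variant="pace", d=2, batch_size=8).fit(nsr_beats[:16])

    def test_unfitted_raises(self):
        with pytest.raises(ValueError, match="not fitted"):
            CyclicAutoencoder().transform([])


class TestShapeInvariance:
    def test_time_stretch_invariance(self, shape_model, nsr_beats):
        """Shape codes depend on cycle phase only, not on beat duration."""
        s = nsr_beats[3]
        stretched = Slice(values=s.values, times=s.times * 1.3,
                          record_id=s.record_id, start_index=s.start_index,
                          kind=SliceKind.HEARTBEAT)
        a = shape_model.encode(s).to_vector()
        b = shape_model.encode(stretched).to_vector()
        assert np.allclose(a, b, atol=1e-9)


class TestFrequencyRecovery:
    def test_sinusoid_frequency_recovery(self):
        """One-cycle sinusoids of period 0.8 s: recovered pace ~ 1.25 Hz."""
        beats = sinusoid_beats(n=256, period=0.8)
        m = CyclicAutoencoder(variant="pace", d=8, epochs=15, batch_size=64,
                              random_state=0).fit(beats)
        f = np.array([m.encode(b).f for b in beats[:64]])
        assert abs(np.median(f) - 1.25) / 1.25 < 0.05


def test_functional_wrappers(nsr_beats):
    cfg = EncoderConfig(variant="pace", d=8, epochs=1, batch_size=32, seed=0)
    model = train(nsr_beats[:64], cfg)
    from cyclebeat.autoencoder import encode, reconstruct

    p = encode(model, nsr_beats[0])
    assert p.variant is Variant.PACE
    assert reconstruct(model, p, np.linspace(0, 0.5, 10)).shape == (10,)
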