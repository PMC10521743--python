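"""Synthetic generator: ground-truth consistency, class construction, determinism."""

import numpy as np
import pytest

from cyclebeat.synthetic import SynthConfig, generate_dataset, generate_record


class TestGenerateRecord:
    def test_zero_variance_rr_at_60_bpm(self):
        rec, truth = generate_record(
            SynthConfig(duration_s=30, mean_hr_bpm=60, rr_cv=0.0, noise_sd=0.0, seed=1)
        )
        assert np.allclose(truth.rr_intervals_s, 1.0, atol=1.0 / rec.fs)
        assert np.allclose(np.diff(truth.r_peak_times_s), truth.rr_intervals_s,
                           atol=1.0 / rec.fs)

    def test_same_seed_bit_identical(self):
        cfg = SynthConfig(duration_s=20, seed=42)
        a, _ = generate_record(cfg)
        b, _ = generate_record(cfg)
        assert np.array_equal(a.samples, b.samples)

    def test_p_wave_suppression(self):
        base = dict(duration_s=20, mean_hr_bpm=60, rr_cv=0.0, noise_sd=0.0, seed=3)
        with_p, truth = generate_record(SynthConfig(p_wave_amplitude=0.15, **base))
        no_p, _ = generate_record(SynthConfig(p_wave_amplitude=0.0, **base))
        # P wave sits at 88% of the cycle; the two signals differ there by ~0.15 mV
        fs = with_p.fs
        idx = int(round((truth.r_peak_times_s[3] + 0.88 * truth.rr_intervals_s[3]) * fs))
        assert with_p.samples[idx] - no_p.samples[idx] == pytest.approx(0.15, abs=0.02)
        assert no_p.rhythm_label == "AF" or no_p.rhythm_label is not None

    def test_r_peak_truth_matches_signal_maximum(self):
        rec, truth = generate_record(
            SynthConfig(duration_s=30, mean_hr_bpm=70, rr_cv=0.1, noise_sd=0.0, seed=7)
        )
        fs = rec.fs
        for k in range(truth.rr_intervals_s.size):
            r = truth.r_peak_times_s[k]
            half = 0.25 * truth.rr_intervals_s[k]
            lo, hi = int(round((r - half) * fs)), int(round((r + half) * fs))
            lo = max(lo, 0)
            m = lo + int(np.argmax(rec.samples[lo:hi]))
            assert abs(m - int(round(r * fs))) <= 1

    def test_rr_cv_converges(self):
        # ~300 beats: empirical CV within 20% relative of the target
        target = 0.2
        rec, truth = generate_record(
            SynthConfig(duration_s=260, mean_hr_bpm=72, rr_cv=target, noise_sd=0.0, seed=9)
        )
        assert truth.rr_intervals_s.size >= 280
        cv = truth.rr_intervals_s.std() / truth.rr_intervals_s.mean()
        assert abs(cv - target) / target < 0.2

    def test_noise_only_record(self):
        rec, truth = generate_record(SynthConfig(duration_s=10, noise_only=True,
                                                 noise_sd=0.25, seed=4))
        assert rec.rhythm_label == "NOISY"
        assert truth.r_peak_times_s.size == 0 and truth.rr_intervals_s.size == 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mean_hr_bpm=20.0),
            dict(mean_hr_bpm=300.0),
            dict(rr_cv=0.9),
            dict(noise_sd=-0.1),
            dict(duration_s=-1.0),
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            SynthConfig(**kwargs)

    def test_duration_too_short_for_one_beat(self):
        with pytest.raises(ValueError):
            generate_record(SynthConfig(duration_s=0.4, mean_hr_bpm=30.0, seed=0))

    def test_config_yaml_round_trip(self):
        cfg = SynthConfig(duration_s=12.5, mean_hr_bpm=80, rr_cv=0.2, seed=11)
        assert SynthConfig.from_yaml(cfg.to_yaml()) == cfg


class TestGenerateDataset:
    def test_exact_proportions_at_divisible_n(self):
        ds = generate_dataset(10, (0.5, 0.5, 0.0, 0.0), seed=0, duration_s=10)
        labels = [rec.rhythm_label for rec, _ in ds]
        assert labels.count("NSR") == 5 and labels.count("AF") == 5

    def test_all_four_classes(self):
        ds = generate_dataset(8, (0.25, 0.25, 0.25, 0.25), seed=1, duration_s=10)
        labels = {rec.rhythm_label for rec, _ in ds}
        assert labels == {"NSR", "AF", "OTHER", "NOISY"}

    def test_empty_and_negative(self):
        assert generate_dataset(0, (1.0, 0.0, 0.0, 0.0)) == []
        with pytest.raises(ValueError):
            generate_dataset(-1, (1.0, 0.0, 0.0, 0.0))

    def test_master_seed_determinism(self):
        a = generate_dataset(6, (0.5, 0.5, 0, 0), seed=3, duration_s=10)
        b = generate_dataset(6, (0.5, 0.5, 0, 0), seed=3, duration_s=10)
        for (ra, _), (rb, _) in zip(a, b):
            assert ra.record_id == rb.record_id
            assert np.array_equal(ra.samples, rb.samples)

    def test_af_records_are_irregular_without_p(self):
        ds = generate_dataset(6, (0.0, 1.0, 0.0, 0.0), seed=5, duration_s=30)
        for _, truth in ds:
            cv = truth.rr_intervals_s.std() / truth.rr_intervals_s.mean()
            assert cv > 0.08  # drawn with rr_cv >= 0.15 before clipping

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(4, (0.5, 0.2, 0.0, 0.0))
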