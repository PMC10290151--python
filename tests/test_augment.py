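import numpy as np
import pytest
from scipy.fft import dct

from conftest import fixed_rate_record
from ecgssl.augment import (AugmentationPolicy, RPeakList, apply_policy,
                            channel_mask, crop_resize, cycle_mask,
                            detect_r_peaks, frequency_dropout)
from ecgssl.io import CANONICAL_LEADS, EcgRecord


def _rand_record(seed=0, n=600, leads=12):
    rng = np.random.default_rng(seed)
    names = CANONICAL_LEADS if leads == 12 else tuple(
        f"CH{i}" for i in range(leads))
    return EcgRecord(rng.standard_normal((leads, n)), 100.0, names, "r")


class TestFrequencyDropout:
    def test_zero_drops_is_identity(self):
        rec = _rand_record()
        out = frequency_dropout(rec, 0, seed=1)
        np.testing.assert_allclose(out.signal, rec.signal, atol=1e-9)

    def test_dropping_a_basis_vector_bin_annihilates_it(self):
        """A signal equal to DCT basis vector j is untouched unless bin j is
        among the dropped bins, in which case the output is exactly zero
        (orthonormality oracle); both cases must occur across seeds."""
        n, j = 16, 5
        basis = dct(np.eye(n), type=3, norm="ortho", axis=1)[j]
        rec = EcgRecord(basis[None, :], 100.0, ("CH0",), "b")
        hits = misses = 0
        for seed in range(60):
            out = frequency_dropout(rec, 1, seed=seed)
            if np.allclose(out.signal, 0.0, atol=1e-9):
                hits += 1
            elif np.allclose(out.signal, rec.signal, atol=1e-9):
                misses += 1
            else:
                raise AssertionError("output neither zero nor identity")
        assert hits > 0 and misses > 0

    def test_parseval_energy_accounting(self):
        """Energy removed equals the dropped coefficients' energy."""
        rec = _rand_record(seed=2, leads=1)
        out = frequency_dropout(rec, 40, seed=3)
        c_in = dct(rec.signal[0], type=2, norm="ortho")
        c_out = dct(out.signal[0], type=2, norm="ortho")
        dropped = np.where(np.abs(c_out) < 1e-10)[0]
        assert len(dropped) >= 40
        e_in = np.sum(rec.signal[0] ** 2)
        e_out = np.sum(out.signal[0] ** 2)
        assert e_out == pytest.approx(e_in - np.sum(c_in[dropped] ** 2),
                                      rel=1e-9)

    def test_idempotent_for_fixed_seed(self):
        rec = _rand_record(seed=4)
        once = frequency_dropout(rec, 25, seed=9)
        twice = frequency_dropout(once, 25, seed=9)
        np.testing.assert_allclose(twice.signal, once.signal, atol=1e-9)

    def test_out_of_range_rejected(self):
        rec = _rand_record()
        with pytest.raises(ValueError):
            frequency_dropout(rec, rec.n_samples + 1, seed=0)


class TestCropResize:
    def test_full_fraction_identity(self):
        rec = _rand_record()
        np.testing.assert_array_equal(crop_resize(rec, 1.0, 0).signal,
                                      rec.signal)

    @pytest.mark.parametrize("frac", [0.5, 0.63, 0.9])
    def test_shape_preserved(self, frac):
        rec = _rand_record(n=7500)
        out = crop_resize(rec, frac, seed=1)
        assert out.signal.shape == (12, 7500)

    def test_sinusoid_frequency_scales_by_fraction(self):
        """FFT-peak oracle: cropping rho of an f-Hz tone and stretching it
        back moves the dominant bin to about f*rho."""
        fs, n, f, rho = 250.0, 5000, 10.0, 0.6
        t = np.arange(n) / fs
        rec = EcgRecord(np.sin(2 * np.pi * f * t)[None, :], fs, ("CH0",), "s")
        out = crop_resize(rec, rho, seed=5)
        spec = np.abs(np.fft.rfft(out.signal[0]))
        peak = np.fft.rfftfreq(n, 1 / fs)[np.argmax(spec[1:]) + 1]
        assert peak == pytest.approx(f * rho, rel=0.05)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            crop_resize(_rand_record(), 0.0, 0)


class TestRPeakDetection:
    @pytest.mark.parametrize("hr,expected", [(60, 15), (120, 30)])
    def test_count_and_position_against_generator_truth(self, hr, expected):
        rec, truth = fixed_rate_record(hr, fs=500.0, duration_s=15.0)
        peaks = detect_r_peaks(rec)
        assert abs(len(peaks) - expected) <= 1
        tol = int(round(0.020 * rec.fs))
        for p in peaks.indices:
            assert np.abs(truth.r_peaks - p).min() <= tol

    def test_all_zero_signal_gives_empty_list(self):
        rec = EcgRecord(np.zeros((12, 1000)), 500.0, CANONICAL_LEADS, "z")
        assert len(detect_r_peaks(rec)) == 0

    def test_refractory_period_enforced(self, clean_record):
        rec, _ = clean_record
        peaks = detect_r_peaks(rec)
        if len(peaks) > 1:
            assert np.diff(peaks.indices).min() >= 0.2 * rec.fs


class TestCycleMask:
    def test_zero_width_identity(self, clean_record):
        rec, truth = clean_record
        out = cycle_mask(rec, RPeakList(truth.r_peaks), -40.0, 0.0)
        np.testing.assert_array_equal(out.signal, rec.signal)

    def test_masked_sample_count_by_index_arithmetic(self):
        """15 interior peaks, 50-sample windows -> exactly 750 zeros/lead."""
        rec = EcgRecord(np.ones((3, 7500)), 500.0, ("A", "B", "C"), "o")
        peaks = RPeakList(np.arange(300, 7400, 470)[:15])
        out = cycle_mask(rec, peaks, offset_ms=0.0, width_ms=100.0)
        assert (out.signal == 0).sum(axis=1).tolist() == [750, 750, 750]

    def test_complement_bit_identical(self, clean_record):
        rec, truth = clean_record
        peaks = RPeakList(truth.r_peaks)
        out = cycle_mask(rec, peaks, -40.0, 80.0)
        mask = np.zeros(rec.n_samples, dtype=bool)
        off = int(round(-40.0 * rec.fs / 1000))
        width = int(round(80.0 * rec.fs / 1000))
        for r in truth.r_peaks:
            mask[max(0, r + off):min(rec.n_samples, r + off + width)] = True
        np.testing.assert_array_equal(out.signal[:, ~mask],
                                      rec.signal[:, ~mask])
        assert (out.signal[:, mask] == 0).all()

    def test_idempotent(self, clean_record):
        rec, truth = clean_record
        peaks = RPeakList(truth.r_peaks)
        once = cycle_mask(rec, peaks, -40.0, 60.0)
        twice = cycle_mask(once, peaks, -40.0, 60.0)
        np.testing.assert_array_equal(twice.signal, once.signal)


class TestChannelMask:
    def test_endpoints(self):
        rec = _rand_record()
        np.testing.assert_array_equal(channel_mask(rec, 0, 0).signal,
                                      rec.signal)
        assert (channel_mask(rec, 12, 0).signal == 0).all()

    def test_unmasked_leads_bit_identical_and_deterministic(self):
        rec = _rand_record(seed=6)
        a = channel_mask(rec, 3, seed=11)
        b = channel_mask(rec, 3, seed=11)
        np.testing.assert_array_equal(a.signal, b.signal)
        zeroed = np.where((a.signal == 0).all(axis=1))[0]
        assert len(zeroed) == 3
        kept = [i for i in range(12) if i not in zeroed]
        np.testing.assert_array_equal(a.signal[kept], rec.signal[kept])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            channel_mask(_rand_record(), 13, 0)


class TestPolicy:
    def test_all_probabilities_zero_is_identity(self, clean_record):
        rec, _ = clean_record
        out = apply_policy(rec, AugmentationPolicy.off(), seed=0)
        np.testing.assert_array_equal(out.signal, rec.signal)

    def test_same_seed_replays_same_view(self, clean_record):
        rec, _ = clean_record
        pol = AugmentationPolicy()
        a = apply_policy(rec, pol, seed=42)
        b = apply_policy(rec, pol, seed=42)
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_distinct_seeds_give_distinct_views(self, clean_record):
        rec, _ = clean_record
        pol = AugmentationPolicy(p_frequency_dropout=1.0, p_crop_resize=1.0,
                                 p_cycle_mask=1.0, p_channel_mask=1.0)
        views = [apply_policy(rec, pol, seed=s).signal for s in range(4)]
        for i in range(4):
            for j in range(i + 1, 4):
                assert not np.array_equal(views[i], views[j])

    def test_multi_view_replay_equality(self, clean_record):
        """The N+1 views used by contrastive pretraining replay exactly
        from their seed sequence."""
        rec, _ = clean_record
        pol = AugmentationPolicy()
        first = [apply_policy(rec, pol, seed=100 + k).signal
                 for k in range(4)]
        second = [apply_policy(rec, pol, seed=100 + k).signal
                  for k in range(4)]
        for a, b in zip(first, second):
            np.testing.assert_array_equal(a, b)

    def test_shape_and_fs_preserved_by_every_operator(self, clean_record):
        rec, truth = clean_record
        outs = [
            frequency_dropout(rec, 10, 0), crop_resize(rec, 0.7, 0),
            cycle_mask(rec, RPeakList(truth.r_peaks), -40, 60),
            channel_mask(rec, 2, 0),
            apply_policy(rec, AugmentationPolicy(), 0),
        ]
        for out in outs:
            assert out.signal.shape == rec.signal.shape
            assert out.fs == rec.fs
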