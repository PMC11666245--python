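"""Segment pairing, DFT scaling, bin bookkeeping, vector averaging,
Hotelling's T-squared, amplitude summaries and FDR."""

import numpy as np
import pytest

from ssveptag.containers import EpochSet
from ssveptag.design import ExperimentDesign
from ssveptag.spectral import (ComplexSpectrum, category_rms_amplitude,
                               classify_bins, default_roi_set, dft_spectrum,
                               fdr_bh, load_roi_set, noise_amplitude,
                               pair_segments, roi_participant_spectrum,
                               tcirc_test, vector_average)


def _epochset(n_epochs, n_channels=2, n_samples=490, condition="faces",
              data=None, valid=None):
    data = data if data is not None else np.zeros((n_epochs, n_channels, n_samples))
    valid = valid if valid is not None else np.ones((n_epochs, n_channels), bool)
    return EpochSet(data, np.array([condition] * n_epochs), valid, 420.0,
                    n_samples / 420.0, [f"c{i}" for i in range(n_channels)])


class TestPairSegments:
    def test_ten_epochs_give_five_segments(self):
        rng = np.random.default_rng(0)
        eps = _epochset(10, data=rng.normal(size=(10, 2, 490)))
        seg, n_pairs = pair_segments(eps, "faces")
        assert seg.shape == (2, 980)
        assert np.all(n_pairs == 5)

    def test_trailing_unpaired_epoch_dropped(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(11, 2, 490))
        eps = _epochset(11, data=data)
        seg, n_pairs = pair_segments(eps, "faces")
        assert np.all(n_pairs == 5)
        manual = data[:10, 0, :].reshape(5, 980).mean(axis=0)
        assert np.allclose(seg[0], manual)

    def test_identical_epochs_give_their_concatenation(self):
        e = np.sin(np.linspace(0, 5, 490))
        data = np.tile(e, (4, 2, 1))
        seg, _ = pair_segments(_epochset(4, data=data), "faces")
        assert np.allclose(seg[0], np.concatenate([e, e]))

    def test_invalid_epochs_skipped_per_channel(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(5, 2, 490))
        valid = np.ones((5, 2), bool)
        valid[0, 1] = False  # channel 1 pairs epochs (1,2) and drops (3,4)... 4 valid -> 2 pairs
        seg, n_pairs = pair_segments(_epochset(5, data=data, valid=valid), "faces")
        assert n_pairs[0] == 2 and n_pairs[1] == 2
        manual = data[[1, 2, 3, 4], 1, :].reshape(2, 980).mean(axis=0)
        assert np.allclose(seg[1], manual)

    def test_channel_without_a_pair_is_missing(self):
        valid = np.ones((3, 2), bool)
        valid[[0, 1], 1] = False
        seg, n_pairs = pair_segments(_epochset(3, valid=valid), "faces")
        assert n_pairs[1] == 0
        assert np.isnan(seg[1]).all()

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            pair_segments(_epochset(4), "houses")


class TestDftSpectrum:
    def test_exact_bin_sinusoid_reads_its_amplitude(self):
        t = np.arange(980) / 420.0
        x = 3.0 * np.sin(2 * np.pi * (6.0 / 7.0) * t)
        s = dft_spectrum(x, 420.0)
        k = s.bin_index(6.0 / 7.0)
        assert np.abs(s.coefficients[k]) == pytest.approx(3.0, abs=1e-9)
        others = np.delete(np.abs(s.coefficients), k)
        assert np.max(others) < 1e-9

    def test_bin_spacing_is_0_4286_hz(self):
        s = dft_spectrum(np.zeros(980), 420.0)
        assert s.resolution == pytest.approx(3.0 / 7.0)
        assert s.frequencies[0] == pytest.approx(0.42857142857)

    def test_constant_signal_has_no_ac_energy(self):
        s = dft_spectrum(np.full(980, 5.0), 420.0)
        assert np.max(np.abs(s.coefficients)) < 1e-9

    def test_parseval_bookkeeping(self):
        # build a signal from exact in-band bins and check the 2/N convention
        rng = np.random.default_rng(3)
        t = np.arange(980) / 420.0
        amps = rng.uniform(0.5, 2.0, 5)
        freqs = np.array([2, 5, 10, 31, 100]) * 3.0 / 7.0
        phases = rng.uniform(0, 2 * np.pi, 5)
        x = 1.5 + sum(a * np.cos(2 * np.pi * f * t + p)
                      for a, f, p in zip(amps, freqs, phases))
        s = dft_spectrum(x, 420.0)
        mean_sq = np.mean(x ** 2)
        assert mean_sq == pytest.approx(1.5 ** 2 + np.sum(s.amplitude() ** 2) / 2)


class TestClassifyBins:
    def test_first_five_noise_bins(self, design):
        h = classify_bins(design, 30.0)
        np.testing.assert_allclose(
            h.frequencies("noise")[:5],
            [0.4286, 1.2857, 2.1429, 3.0, 3.8571], atol=1e-3)

    def test_image_category_overlap_goes_to_image(self, design):
        h = classify_bins(design, 30.0)
        img = h.frequencies("image")
        cat = h.frequencies("category")
        assert np.any(np.isclose(img, 30.0 / 7.0))
        assert not np.any(np.isclose(cat, 30.0 / 7.0))
        assert not np.any(np.isclose(cat, 60.0 / 7.0))

    def test_cap_8571_noise_bins_are_all_odd_indices(self, design):
        h = classify_bins(design, 60.0 / 7.0)
        k = np.round(h.frequencies("noise") / design.bin_spacing).astype(int)
        assert np.all(k % 2 == 1)
        k_cat = np.round(h.frequencies("category") / design.bin_spacing).astype(int)
        assert np.all(k_cat % 2 == 0)

    def test_partition_is_disjoint_and_complete(self, design):
        h = classify_bins(design, 30.0)
        all_idx = np.concatenate([h.image_idx, h.category_idx, h.noise_idx])
        assert len(all_idx) == len(set(all_idx))
        assert sorted(all_idx) == list(range(len(h.bin_frequencies)))

    def test_cap_above_nyquist_rejected(self, design):
        with pytest.raises(ValueError):
            classify_bins(design, 300.0)


class TestVectorAverage:
    def test_opposite_phases_cancel(self):
        a = ComplexSpectrum(np.array([1 + 0j]), 3 / 7)
        b = ComplexSpectrum(np.array([-1 + 0j]), 3 / 7)
        assert np.abs(vector_average([a, b]).coefficients[0]) == 0

    def test_identical_participants_equal_individual(self):
        c = np.array([1 + 2j, 0.5 - 1j])
        spectra = [ComplexSpectrum(c.copy(), 3 / 7) for _ in range(5)]
        assert np.allclose(vector_average(spectra).coefficients, c)

    def test_group_amplitude_bounded_by_mean_amplitude(self):
        rng = np.random.default_rng(4)
        draws = rng.normal(size=(1000, 8, 6)) + 1j * rng.normal(size=(1000, 8, 6))
        for d in draws[:50]:  # triangle inequality on 50 random groups
            spectra = [ComplexSpectrum(row, 3 / 7) for row in d]
            group = np.abs(vector_average(spectra).coefficients)
            mean_amp = np.mean(np.abs(d), axis=0)
            assert np.all(group <= mean_amp + 1e-12)

    def test_grid_mismatch_rejected(self):
        a = ComplexSpectrum(np.zeros(3), 3 / 7)
        b = ComplexSpectrum(np.zeros(4), 3 / 7)
        with pytest.raises(ValueError):
            vector_average([a, b])


class TestTcirc:
    def test_all_zero_coefficients(self):
        res = tcirc_test(np.zeros(10, dtype=complex))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=20) + 1j * rng.normal(size=20) + (2 + 1j)
        r1 = tcirc_test(z)
        r2 = tcirc_test(z * np.exp(1j * 1.234))
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            tcirc_test(np.array([1 + 1j, 2 + 2j]))

    def test_collinear_samples_use_ridge(self):
        z = np.array([1 + 1j, 2 + 2j, 3 + 3j, 4 + 4j])
        res = tcirc_test(z)
        assert res.ridge_used
        assert 0 <= res.p <= 1

    def test_strong_signal_is_significant(self):
        rng = np.random.default_rng(6)
        z = 5 + 0j + 0.1 * (rng.normal(size=14) + 1j * rng.normal(size=14))
        assert tcirc_test(z).p < 1e-6


class TestRoiSpectrum:
    def _spec(self, coefs):
        return ComplexSpectrum(np.asarray(coefs), 3 / 7)

    def test_single_channel_roi_is_identity(self):
        s = self._spec([[1 + 2j, 3 - 1j]])
        out = roi_participant_spectrum(s, ["c0"], ["c0"])
        assert np.allclose(out.coefficients, s.coefficients[0])

    def test_opposite_phase_channels_cancel(self):
        s = self._spec([[1 + 0j], [-1 + 0j]])
        out = roi_participant_spectrum(s, ["c0", "c1"], ["c0", "c1"])
        assert np.abs(out.coefficients[0]) == 0

    def test_missing_channels_skipped(self):
        s = self._spec([[1 + 1j], [np.nan + 1j * np.nan]])
        out = roi_participant_spectrum(s, ["c0", "c1"], ["c0", "c1"])
        assert np.allclose(out.coefficients, [1 + 1j])

    def test_fully_missing_roi_rejected(self):
        s = self._spec([[np.nan + 1j * np.nan]])
        with pytest.raises(ValueError):
            roi_participant_spectrum(s, ["c0"], ["c0"])


class TestAmplitudeSummaries:
    def _roi_spectrum(self, a1, a2, design):
        n_bins = 30
        c = np.zeros(n_bins, complex)
        c[1] = a1  # 0.857 Hz is bin index 1 (k=2)
        c[3] = a2  # 1.714 Hz is bin index 3 (k=4)
        return ComplexSpectrum(c, design.bin_spacing)

    def test_rms_of_3_and_4_is_3_5355(self, design):
        s = self._roi_spectrum(3.0, 4.0, design)
        assert category_rms_amplitude(s, design) == pytest.approx(3.5355, abs=1e-4)

    def test_rms_zero_and_equal_cases(self, design):
        assert category_rms_amplitude(self._roi_spectrum(0, 0, design), design) == 0
        assert category_rms_amplitude(
            self._roi_spectrum(2.0, 2.0, design), design) == pytest.approx(2.0)

    def test_noise_amplitude_uses_first_five_noise_bins(self, design):
        h = classify_bins(design, 60.0 / 7.0)
        c = np.zeros(30, complex)
        c[h.noise_idx[:5]] = 2.0
        s = ComplexSpectrum(c, design.bin_spacing)
        assert noise_amplitude(s, h, 5) == pytest.approx(2.0)
        np.testing.assert_allclose(
            h.bin_frequencies[h.noise_idx[:5]],
            [0.4286, 1.2857, 2.1429, 3.0, 3.8571], atol=1e-3)

    def test_noise_amplitude_matches_rayleigh_mean(self, design):
        # complex-Gaussian coefficients with per-component sd s have mean
        # modulus s * sqrt(pi/2)
        rng = np.random.default_rng(7)
        h = classify_bins(design, 60.0 / 7.0)
        s_true = 1.3
        vals = []
        for _ in range(1000):
            c = s_true * (rng.normal(size=25) + 1j * rng.normal(size=25))
            vals.append(noise_amplitude(ComplexSpectrum(c, design.bin_spacing), h, 5))
        assert np.mean(vals) == pytest.approx(s_true * np.sqrt(np.pi / 2), rel=0.1)

    def test_noiseless_spectrum_gives_zero(self, design):
        h = classify_bins(design, 60.0 / 7.0)
        s = ComplexSpectrum(np.zeros(30, complex), design.bin_spacing)
        assert noise_amplitude(s, h, 5) == 0.0


class TestFdr:
    def test_single_small_p_rejected(self):
        assert fdr_bh([0.04], 0.05).tolist() == [True]

    def test_step_up_rejects_all_four(self):
        assert fdr_bh([0.01, 0.02, 0.03, 0.04], 0.05).all()

    def test_all_ones_not_rejected(self):
        assert not fdr_bh([1.0, 1.0, 1.0], 0.05).any()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestRoiSet:
    def test_default_has_23_channels(self):
        rs = default_roi_set()
        assert len(rs["LOT"]) == 7 and len(rs["ROT"]) == 7 and len(rs["OCC"]) == 9
        assert len(rs.all_channels) == 23

    def test_loader_accepts_default_name(self):
        assert load_roi_set("paper_default").names == ["LOT", "OCC", "ROT"]

    def test_overlapping_rois_rejected(self, tmp_path):
        import json
        p = tmp_path / "rois.json"
        p.write_text(json.dumps({"A": ["E1", "E2"], "B": ["E2"]}))
        with pytest.raises(ValueError, match="overlap"):
            load_roi_set(str(p))

    def test_custom_single_roi_accepted(self, tmp_path):
        import json
        p = tmp_path / "rois.json"
        p.write_text(json.dumps({"ALL": ["E1", "E2", "E3"]}))
        rs = load_roi_set(str(p))
        assert rs.names == ["ALL"]
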