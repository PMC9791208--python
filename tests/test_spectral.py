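import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rfqus import (
    AcquisitionMeta,
    PowerSpectrum,
    SpectralConfig,
    SubBand,
    band_features,
    partition_band,
    patch_psd,
    regression_features,
    spectral_feature_vector,
)
from rfqus.errors import DegenerateSpectrumError, ROITooSmallError, UndefinedFeatureError
from rfqus.spectral import SPECTRAL_FEATURE_NAMES, _regression_features_batch


class TestPartition:
    def test_seven_bands_with_stated_edges(self):
        bands = partition_band()
        assert len(bands) == 7
        edges = [b.f_l / 1e6 for b in bands] + [bands[-1].f_u / 1e6]
        assert edges == [0.0, 1.5, 6.5, 10.5, 14.5, 18.5, 22.5, 25.0]

    def test_contiguous_union_covers_0_to_25_mhz(self):
        bands = partition_band()
        for a, b in zip(bands[:-1], bands[1:]):
            assert a.f_u == b.f_l
        assert bands[0].f_l == 0.0 and bands[-1].f_u == 25e6

    def test_harmonics_sit_at_band_centers(self):
        bands = partition_band()
        # the 8 MHz harmonic falls at the center of the [6.5, 10.5] MHz band
        assert bands[2].center == pytest.approx(8.5e6)
        assert bands[2].f_l < 8e6 < bands[2].f_u


class TestPatchPSD:
    meta = AcquisitionMeta(sample_rate=3.2e7, sound_speed=154_000.0, beam_pitch=0.3,
                           n_axial=420, n_beams=30, n_frames=1)

    def test_white_noise_psd_is_flat_after_averaging(self, rng):
        roi = rng.normal(size=(420, 30))  # 10 x 10 = 100 one-mm patches
        spectra = patch_psd(roi, self.meta, 1.0)
        assert len(spectra) >= 100
        avg = np.mean([s.psd for s in spectra], axis=0)
        avg = avg[1:]  # DC bin is suppressed by mean removal by construction
        assert avg.max() / avg.min() < 3.0

    def test_tone_peaks_at_its_frequency(self):
        n = np.arange(420)
        roi = np.cos(2 * np.pi * 4e6 * n / self.meta.sample_rate)[:, None] * np.ones((1, 4))
        spectra = patch_psd(roi, self.meta, 1.0)
        ps = spectra[0]
        assert abs(ps.frequencies[np.argmax(ps.psd)] - 4e6) <= ps.df

    def test_zero_roi_gives_zero_psd(self):
        spectra = patch_psd(np.zeros((84, 6)), self.meta, 1.0)
        for s in spectra:
            np.testing.assert_array_equal(s.psd, 0.0)

    def test_roi_smaller_than_patch_rejected(self):
        with pytest.raises(ROITooSmallError):
            patch_psd(np.zeros((10, 2)), self.meta, 1.0)


class TestBandFeatures:
    def test_flat_spectrum_flatness_is_one_and_crest_is_one(self):
        ps = PowerSpectrum(frequencies=np.linspace(0, 10e6, 101), psd=np.full(101, 3.7))
        feats = band_features(ps, SubBand(1e6, 9e6))
        assert feats["spectral_flatness"] == pytest.approx(1.0, abs=1e-12)
        assert feats["crest_factor"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_spectrum_hand_values(self):
        # grid in MHz units: P=2 on 3 bins spaced 0.5 apart -> power 2*3*0.5
        ps = PowerSpectrum(frequencies=np.array([1.0, 1.5, 2.0]), psd=np.array([2.0, 2.0, 2.0]))
        feats = band_features(ps, SubBand(0.75, 2.25))
        assert feats["signal_power"] == pytest.approx(3.0)
        assert feats["crest_factor"] == pytest.approx(1.0)

    def test_three_bin_hand_computation(self):
        ps = PowerSpectrum(frequencies=np.array([1e6, 2e6, 3e6]), psd=np.array([1.0, 2.0, 4.0]))
        feats = band_features(ps, SubBand(0.5e6, 3.5e6))
        assert feats["spectral_flatness"] == pytest.approx(6.0 / 7.0)
        assert feats["spectral_centroid"] == pytest.approx(17.0 / 7.0 * 1e6)

    def test_zero_power_band_undefined(self):
        ps = PowerSpectrum(frequencies=np.linspace(0, 10e6, 11), psd=np.zeros(11))
        with pytest.raises(UndefinedFeatureError):
            band_features(ps, SubBand(1e6, 9e6))

    def test_power_additive_over_partition(self, rng):
        freqs = np.linspace(0, 25e6, 512)
        ps = PowerSpectrum(frequencies=freqs, psd=rng.uniform(0.1, 2.0, 512))
        total = band_features(ps, SubBand(1e-3, 25e6))["signal_power"]
        parts = sum(
            band_features(ps, b)["signal_power"]
            for b in partition_band()
        )
        # the [0,25] partition includes the f=0 bin that SubBand(1e-3,...) excludes
        total_with_dc = total + ps.psd[0] * ps.df
        assert parts == pytest.approx(total_with_dc, rel=1e-9)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None)
    def test_bounds_hold_on_random_spectra(self, seed):
        r = np.random.default_rng(seed)
        psd = r.uniform(0.0, 1.0, 64) ** 2
        psd[r.integers(0, 64)] += 1.0  # ensure nonzero power
        ps = PowerSpectrum(frequencies=np.linspace(1e6, 9e6, 64), psd=psd)
        band = SubBand(1e6, 9.1e6)
        feats = band_features(ps, band)
        assert 0.0 <= feats["spectral_flatness"] <= 1.0 + 1e-12
        assert feats["crest_factor"] >= 1.0 - 1e-12
        assert band.f_l <= feats["spectral_centroid"] <= band.f_u

    def test_scaling_signal_scales_power_quadratically(self, rng):
        n = np.arange(420)
        meta = TestPatchPSD.meta
        roi = rng.normal(size=(420, 30))
        f1 = spectral_feature_vector(roi[:, :, None], meta)
        f2 = spectral_feature_vector(3.0 * roi[:, :, None], meta)
        for b in range(1, 4):  # bands below the 16 MHz Nyquist
            assert f2[f"band{b}_signal_power"] == pytest.approx(9.0 * f1[f"band{b}_signal_power"], rel=1e-9)
            for name in ("spectral_centroid", "spectral_bandwidth", "spectral_flatness", "crest_factor"):
                assert f2[f"band{b}_{name}"] == pytest.approx(f1[f"band{b}_{name}"], rel=1e-9)
        assert f2["s2_slope"] == pytest.approx(f1["s2_slope"], rel=1e-9)


class TestRegression:
    def test_closed_form_ols_matches_polyfit(self, rng):
        # dual route: the vectorized OLS vs numpy's least squares on the
        # same normalized spectra
        X = rng.normal(size=(5, 16))
        s1, s2 = _regression_features_batch(X)
        for i in range(5):
            intercept, slope = regression_features(X[i])
            assert intercept == pytest.approx(s1[i], rel=1e-9)
            assert slope == pytest.approx(s2[i], rel=1e-9)
            x = X[i] - X[i].mean()
            mag = np.abs(np.fft.rfft(x, n=32))
            mag /= mag.max()
            nu = np.linspace(0, 1, mag.size)
            b, a = np.polyfit(nu[1:], mag[1:], 1)  # DC bin excluded
            assert slope == pytest.approx(b, rel=1e-9)
            assert intercept == pytest.approx(a, rel=1e-9)

    def test_white_noise_slope_is_zero_on_average(self):
        r = np.random.default_rng(7)
        X = r.normal(size=(1000, 64))
        _, s2 = _regression_features_batch(X)
        se = s2.std(ddof=1) / np.sqrt(len(s2))
        assert abs(s2.mean()) < 3 * se

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            regression_features(np.ones(16))


class TestFeatureVector:
    def test_length_and_canonical_names(self, small_stack, small_roi):
        from rfqus import extract_roi
        vec = spectral_feature_vector(extract_roi(small_stack, small_roi))
        assert len(vec) == 37
        assert list(vec.index) == list(SPECTRAL_FEATURE_NAMES)

    def test_deterministic_on_identical_rois(self, small_stack, small_roi):
        from rfqus import extract_roi
        sub = extract_roi(small_stack, small_roi)
        a = spectral_feature_vector(sub)
        b = spectral_feature_vector(sub)
        assert (a == b).all()

    def test_bands_above_nyquist_zeroed_with_warning(self, rng):
        meta = AcquisitionMeta(sample_rate=3.2e7, sound_speed=154_000.0, beam_pitch=0.3,
                               n_axial=84, n_beams=6, n_frames=1)
        roi = rng.normal(size=(84, 6, 1))
        with pytest.warns(UserWarning):
            vec = spectral_feature_vector(roi, meta)
        assert len(vec) == 37
        # Nyquist is 16 MHz: bands [14.5,18.5], [18.5,22.5], [22.5,25] are out
        for b in (5, 6, 7):
            assert vec[f"band{b}_signal_power"] == 0.0
        assert vec["band2_signal_power"] > 0.0
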