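import numpy as np
import pytest

from rfqus import (
    AcquisitionMeta,
    MapConfig,
    PhantomSpec,
    dea_map,
    dec_at_point,
    hilbert_envelope,
    nakagami_m,
    nakagami_map,
    simulate_rf,
    skewness,
    skewness_map,
)
from rfqus.errors import ConfigError, DegenerateWindowError, ROITooSmallError

from oracles import nakagami_samples

PAPER_META = AcquisitionMeta(sample_rate=3.2e7, sound_speed=154_000.0, beam_pitch=0.3,
                             n_axial=1024, n_beams=8, n_frames=1)


class TestNakagamiEstimator:
    @pytest.mark.parametrize("m_true, tol", [(0.6, 0.05), (1.0, 0.05), (2.0, 0.05)])
    def test_moment_estimator_recovers_m(self, m_true, tol):
        for seed in (1, 2, 3):
            r = nakagami_samples(m_true, 1.0, 10**5, np.random.default_rng(seed))
            m_hat, omega = nakagami_m(r)
            assert abs(m_hat - m_true) <= tol
            assert omega == pytest.approx(1.0, abs=0.05)

    def test_rayleigh_is_m_one(self):
        r = np.random.default_rng(0).rayleigh(2.0, 10**6)
        m_hat, _ = nakagami_m(r)
        assert m_hat == pytest.approx(1.0, abs=0.01)

    def test_scale_invariance(self, rng):
        r = rng.rayleigh(1.0, 10**4)
        m1, _ = nakagami_m(r)
        m2, _ = nakagami_m(7.3 * r)
        assert m1 == pytest.approx(m2, rel=1e-9)

    def test_constant_window_rejected(self):
        with pytest.raises(DegenerateWindowError):
            nakagami_m(np.ones(64))


class TestNakagamiMap:
    def test_output_dims_at_step_one(self, rng):
        env = rng.rayleigh(size=(40, 10))
        fm = nakagami_map(env, MapConfig(nak_window_axial=11, nak_window_beams=3))
        assert fm.values.shape == (30, 8)
        assert (fm.valid_region.height, fm.valid_region.width) == (30, 8)

    def test_homogeneous_rayleigh_speckle_maps_near_one(self):
        stack = simulate_rf(PhantomSpec(seed=7, scatterer_density=16.0,
                                        attenuation=0.0, noise_db=40,
                                        n_axial=2048, n_beams=48))
        env = hilbert_envelope(stack.frame(0), stack.meta)
        fm = nakagami_map(env, MapConfig(nak_window_axial=301, nak_window_beams=9))
        assert np.nanmean(fm.values) == pytest.approx(1.0, abs=0.1)

    def test_dense_region_has_higher_m_than_sparse(self):
        dense = simulate_rf(PhantomSpec(seed=3, scatterer_density=10.0, attenuation=0.0))
        sparse = simulate_rf(PhantomSpec(seed=3, scatterer_density=0.4, attenuation=0.0))
        cfg = MapConfig(nak_window_axial=145, nak_window_beams=3)
        m_dense = np.nanmean(nakagami_map(hilbert_envelope(dense.frame(0)), cfg).values)
        m_sparse = np.nanmean(nakagami_map(hilbert_envelope(sparse.frame(0)), cfg).values)
        assert m_dense > m_sparse

    def test_map_std_shrinks_with_window_area(self):
        stack = simulate_rf(PhantomSpec(seed=9, scatterer_density=16.0,
                                        attenuation=0.0, noise_db=40,
                                        n_axial=2048, n_beams=48))
        env = hilbert_envelope(stack.frame(0), stack.meta)
        stds = []
        for wa, wb in ((145, 3), (241, 5), (301, 9)):
            fm = nakagami_map(env, MapConfig(nak_window_axial=wa, nak_window_beams=wb))
            stds.append(np.nanstd(fm.values))
        assert stds[0] > stds[1] > stds[2]

    def test_window_larger_than_image_rejected(self, rng):
        with pytest.raises(ConfigError):
            nakagami_map(rng.rayleigh(size=(20, 4)), MapConfig(nak_window_axial=31))


class TestDEC:
    cfg = MapConfig()

    def test_identical_segments_give_zero(self):
        n = np.arange(256)
        beam = np.sin(2 * np.pi * n / 8)  # period 8 divides the 16-sample interval
        assert dec_at_point(beam, 10, self.cfg, PAPER_META) == pytest.approx(0.0, abs=1e-9)

    def test_energy_ratio_ten_gives_hand_value(self):
        # energy concentrated outside the segment overlap: a^2/b^2 = 10
        beam = np.zeros(128)
        beam[0:16] = np.sqrt(10.0)
        beam[64:80] = 1.0
        dec = dec_at_point(beam, 0, self.cfg, PAPER_META)
        # distance = 16 * 154000 / (2 * 3.2e7) = 0.0385 cm -> 10/0.0385 dB/cm
        assert dec == pytest.approx(259.7402597, rel=1e-6)

    def test_amplitude_scale_invariance(self, rng):
        beam = rng.normal(size=256)
        a = dec_at_point(beam, 5, self.cfg, PAPER_META)
        b = dec_at_point(4.2 * beam, 5, self.cfg, PAPER_META)
        assert a == pytest.approx(b, rel=1e-9)

    def test_exponential_decay_recovered(self):
        gamma = 2e-4  # per-sample amplitude decay
        n = np.arange(2048)
        beam = np.exp(-gamma * n) * np.sin(2 * np.pi * n / 8)
        dist_cm = 16 * PAPER_META.sound_speed / (2 * PAPER_META.sample_rate)
        expected = 10 * np.log10(np.exp(2 * gamma * 16)) / dist_cm
        decs = [dec_at_point(beam, i, self.cfg, PAPER_META) for i in range(100, 1900, 50)]
        decs = np.array(decs)
        assert np.all(np.abs(decs - expected) <= 0.15 * expected)
        assert np.mean(decs) == pytest.approx(expected, rel=0.15)


class TestDEAMap:
    def test_height_is_roi_minus_80_at_defaults(self, rng):
        roi = rng.normal(size=(200, 6))
        fm = dea_map(roi, MapConfig(), PAPER_META)
        assert fm.values.shape == (120, 6)

    def test_homogeneous_phantom_mean_near_zero(self):
        stack = simulate_rf(PhantomSpec(seed=5, attenuation=0.0, n_axial=1024))
        fm = dea_map(stack.frame(0)[100:900], MapConfig(), stack.meta)
        assert abs(np.nanmean(fm.values)) < 0.1 * np.nanstd(fm.values)

    def test_attenuating_phantom_mean_positive(self):
        stack = simulate_rf(PhantomSpec(seed=5, attenuation=0.8, n_axial=1024))
        fm = dea_map(stack.frame(0)[100:900], MapConfig(), stack.meta)
        assert np.nanmean(fm.values) > 0

    def test_too_short_roi_rejected(self, rng):
        with pytest.raises(ROITooSmallError):
            dea_map(rng.normal(size=(80, 4)), MapConfig(), PAPER_META)


class TestSkewness:
    def test_symmetric_sample_is_zero(self):
        assert skewness(np.array([-2.0, -1.0, 0.0, 1.0, 2.0])) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_four_point_sample(self):
        assert skewness(np.array([0.0, 0.0, 0.0, 1.0])) == pytest.approx(2 / np.sqrt(3), rel=1e-12)

    def test_gaussian_draws_near_zero(self):
        x = np.random.default_rng(1).normal(size=10**6)
        assert skewness(x) == pytest.approx(0.0, abs=0.01)

    def test_affine_equivariance(self, rng):
        x = rng.exponential(size=5000)
        s = skewness(x)
        assert skewness(3.0 + 2.0 * x) == pytest.approx(s, rel=1e-9)
        assert skewness(3.0 - 2.0 * x) == pytest.approx(-s, rel=1e-9)

    def test_constant_window_rejected(self):
        with pytest.raises(DegenerateWindowError):
            skewness(np.full(16, 3.0))


class TestSkewnessMap:
    cfg = MapConfig(nak_window_axial=31, nak_window_beams=3)

    def test_output_dims(self, rng):
        fm = skewness_map(rng.normal(size=(100, 10)), self.cfg)
        assert fm.values.shape == (70, 8)

    def test_symmetric_noise_mean_near_zero(self, rng):
        fm = skewness_map(rng.normal(size=(400, 24)), self.cfg)
        vals = fm.values[~np.isnan(fm.values)]
        assert abs(vals.mean()) < 0.05

    def test_injected_asymmetry_raises_map_mean(self):
        sym = simulate_rf(PhantomSpec(seed=2, asymmetry=0.0))
        asym = simulate_rf(PhantomSpec(seed=2, asymmetry=0.3))
        m_sym = np.nanmean(skewness_map(sym.frame(0)[100:500], self.cfg).values)
        m_asym = np.nanmean(skewness_map(asym.frame(0)[100:500], self.cfg).values)
        assert m_asym > m_sym


class TestExport:
    def test_tiff_round_trip_and_summary(self, tmp_path, rng):
        import pandas as pd
        import tifffile

        from rfqus.feature_maps import export_feature_map
        from rfqus import FeatureMap, ROIRect

        values = rng.normal(size=(12, 6))
        fmap = FeatureMap(kind="DEA", values=values,
                          valid_region=ROIRect(0, 0, 12, 6))
        export_feature_map(fmap, tmp_path / "m.tif", tmp_path / "m.csv")
        back = tifffile.imread(tmp_path / "m.tif")
        assert back.dtype == np.float32
        np.testing.assert_allclose(back, values, rtol=1e-6)
        summary = pd.read_csv(tmp_path / "m.csv")
        assert summary.loc[0, "kind"] == "DEA"
        assert summary.loc[0, "mean"] == pytest.approx(values.mean(), rel=1e-6)
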