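"""Task/seed correlation maps and spatial ICA."""

import numpy as np
import pytest

from rgbrsfc.errors import AnalysisError, ConfigError
from rgbrsfc.funcmaps import (HRFModel, SeedSpec, build_theoretical_response,
                              ica_maps, normalize_for_ica, pearson_map,
                              seed_map, task_map)
from rgbrsfc.hemodynamics import ConcentrationVideo
from rgbrsfc.video_io import StimulusProtocol


def _conc_from(series_hbo2, frame_rate=10.0):
    """ConcentrationVideo with hb = -0.4 * hbo2."""
    return ConcentrationVideo(dc_hbo2=series_hbo2, dc_hb=-0.4 * series_hbo2,
                              frame_rate=frame_rate,
                              valid_mask=np.ones(series_hbo2.shape[1:], bool))


class TestTheoreticalResponse:
    def test_hb_theory_is_exact_negation(self):
        protocol = StimulusProtocol.block_design(20, 20, 100, 10)
        hbo2, hb = build_theoretical_response(protocol, HRFModel(), 10.0)
        np.testing.assert_array_equal(hb, -hbo2)

    def test_impulse_returns_sampled_hrf(self):
        samples = np.zeros(400)
        samples[0] = 1.0
        hbo2, _ = build_theoretical_response(StimulusProtocol(samples),
                                             HRFModel(), 10.0)
        kernel = HRFModel().sample(10.0)
        np.testing.assert_allclose(hbo2[:kernel.size], kernel)
        assert np.all(hbo2[kernel.size:] == 0.0)

    def test_all_rest_protocol_gives_zero_response(self):
        hbo2, hb = build_theoretical_response(StimulusProtocol(np.zeros(100)),
                                              HRFModel(), 10.0)
        assert np.all(hbo2 == 0.0) and np.all(hb == 0.0)

    def test_identical_blocks_give_shifted_identical_responses(self):
        # two 10 s blocks separated by 60 s of rest: steady state by block 2
        protocol = StimulusProtocol.from_intervals([(10, 20), (80, 90)],
                                                   140, 10.0)
        hbo2, _ = build_theoretical_response(protocol, HRFModel(), 10.0)
        block1 = hbo2[100:500]
        block2 = hbo2[800:1200]
        np.testing.assert_allclose(block1, block2, atol=1e-6)

    def test_hrf_kernel_integrates_positive_and_peaks_near_6s(self):
        kernel = HRFModel().sample(frame_rate=10.0)
        assert kernel.sum() > 0
        assert np.argmax(kernel) / 10.0 == pytest.approx(6.0, abs=0.5)


class TestTaskMap:
    def test_pixel_equal_to_theory_scores_plus_one(self):
        protocol = StimulusProtocol.block_design(20, 20, 100, 10)
        theory = build_theoretical_response(protocol, HRFModel(), 10.0)
        h = theory[0]
        series = np.tile(h[:, None, None], (1, 2, 2))
        maps = task_map(_conc_from(series), theory)
        np.testing.assert_allclose(maps["hbo2"].values, 1.0, atol=1e-12)

    def test_pixel_equal_to_negated_theory_scores_minus_one(self):
        protocol = StimulusProtocol.block_design(20, 20, 100, 10)
        theory = build_theoretical_response(protocol, HRFModel(), 10.0)
        series = np.tile(-theory[0][:, None, None], (1, 2, 2))
        maps = task_map(_conc_from(series), theory)
        np.testing.assert_allclose(maps["hbo2"].values, -1.0, atol=1e-12)

    def test_constant_theory_rejected(self):
        series = np.random.default_rng(0).normal(size=(50, 2, 2))
        with pytest.raises(AnalysisError):
            task_map(_conc_from(series), (np.ones(50), -np.ones(50)))

    def test_constant_pixel_scores_zero(self):
        protocol = StimulusProtocol.block_design(20, 20, 100, 10)
        theory = build_theoretical_response(protocol, HRFModel(), 10.0)
        series = np.tile(theory[0][:, None, None], (1, 2, 2))
        series[:, 0, 0] = 5.0
        maps = task_map(_conc_from(series), theory)
        assert maps["hbo2"].values[0, 0] == 0.0


class TestSeedMap:
    def test_shared_signal_gives_unit_map(self):
        rng = np.random.default_rng(1)
        signal = rng.normal(size=100)
        series = np.tile(signal[:, None, None], (1, 40, 40))
        maps = seed_map(_conc_from(series), SeedSpec(center=(20, 20)))
        np.testing.assert_allclose(maps["hbo2"].values, 1.0, atol=1e-9)

    def test_one_pixel_seed_equals_pixelwise_correlation(self):
        rng = np.random.default_rng(2)
        series = rng.normal(size=(80, 10, 10))
        conc = _conc_from(series)
        maps = seed_map(conc, SeedSpec(center=(4, 4), diameter=1))
        expected = pearson_map(series, series[:, 4, 4])
        np.testing.assert_allclose(maps["hbo2"].values, expected, atol=1e-12)

    def test_default_diameter_is_twenty_pixels(self):
        assert SeedSpec(center=(50, 50)).diameter == 20

    def test_seed_disk_must_fit_inside_image(self):
        series = np.random.default_rng(3).normal(size=(20, 30, 30))
        with pytest.raises(ConfigError):
            seed_map(_conc_from(series), SeedSpec(center=(2, 2)))

    def test_map_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(4)
        series = rng.normal(size=(60, 12, 12))
        conc_a = _conc_from(series)
        conc_b = _conc_from(3.0 * series + 7.0)
        spec = SeedSpec(center=(6, 6), diameter=5)
        ma = seed_map(conc_a, spec)["hbo2"].values
        mb = seed_map(conc_b, spec)["hbo2"].values
        np.testing.assert_allclose(ma, mb, atol=1e-9)


class TestICA:
    def test_normalization_gives_zero_mean_unit_variance_rows(self):
        rng = np.random.default_rng(5)
        series = rng.normal(loc=4.0, scale=2.0, size=(100, 6, 6))
        z, idx, report = normalize_for_ica(series)
        assert np.abs(z.mean(axis=1)).max() < 1e-12
        np.testing.assert_allclose(z.var(axis=1), 1.0, atol=1e-9)
        assert report["n_excluded"] == 0

    def test_affine_transform_leaves_normalized_rows_unchanged(self):
        rng = np.random.default_rng(6)
        series = rng.normal(size=(50, 4, 4))
        z1, _, _ = normalize_for_ica(series)
        z2, _, _ = normalize_for_ica(2.5 * series + 1.0)
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_constant_pixels_are_excluded_and_reported(self):
        series = np.random.default_rng(7).normal(size=(50, 3, 3))
        series[:, 0, 0] = 2.0
        z, idx, report = normalize_for_ica(series)
        assert report["n_excluded"] == 1
        assert 0 not in idx

    def test_all_constant_pixels_rejected(self):
        with pytest.raises(AnalysisError):
            normalize_for_ica(np.ones((50, 2, 2)))

    @pytest.fixture()
    def planted_two_source_series(self):
        """16 x 16 image, two disjoint regions carrying independent sources."""
        rng = np.random.default_rng(8)
        t = 300
        s1 = np.sin(2 * np.pi * 0.03 * np.arange(t) / 10.0)
        s2 = np.sign(np.sin(2 * np.pi * 0.011 * np.arange(t) / 10.0))
        series = 0.05 * rng.normal(size=(t, 16, 16))
        series[:, 2:7, 2:7] += s1[:, None, None]
        series[:, 9:14, 9:14] += s2[:, None, None]
        mask1 = np.zeros((16, 16), bool)
        mask1[2:7, 2:7] = True
        mask2 = np.zeros((16, 16), bool)
        mask2[9:14, 9:14] = True
        return series, mask1, mask2

    def test_components_localize_planted_regions(self, planted_two_source_series):
        series, mask1, mask2 = planted_two_source_series
        decomp = ica_maps(series, k=3, rng_seed=0)
        for mask in (mask1, mask2):
            best = max(
                abs(np.corrcoef(m.ravel(), mask.ravel().astype(float))[0, 1])
                for m in decomp.mixing_maps)
            assert best >= 0.9

    def test_reconstruction_matches_rank_k_subspace(self, planted_two_source_series):
        series, _, _ = planted_two_source_series
        k = 3
        decomp = ica_maps(series, k=k, rng_seed=0)
        z, idx, _ = normalize_for_ica(series)  # P x T
        # oracle: rank-k PCA reconstruction of the same matrix
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        rank_k = u[:, :k] * s[:k] @ vt[:k]
        flat = decomp.mixing_maps.reshape(k, -1)[:, idx]  # K x P
        recon = flat.T @ decomp.sources  # P x T
        rel = np.linalg.norm(recon - rank_k) / np.linalg.norm(z)
        assert rel <= 0.05

    def test_decomposition_deterministic_under_fixed_seed(self,
                                                          planted_two_source_series):
        series, _, _ = planted_two_source_series
        d1 = ica_maps(series, k=3, rng_seed=42)
        d2 = ica_maps(series, k=3, rng_seed=42)
        np.testing.assert_array_equal(d1.mixing_maps, d2.mixing_maps)
        np.testing.assert_array_equal(d1.sources, d2.sources)

    def test_maps_sorted_by_ascending_spatial_variance(self,
                                                       planted_two_source_series):
        series, _, _ = planted_two_source_series
        decomp = ica_maps(series, k=3, rng_seed=0)
        variances = decomp.mixing_maps.reshape(3, -1).var(axis=1)
        assert np.all(np.diff(variances) >= -1e-12)

    def test_sign_convention_largest_weight_positive(self,
                                                     planted_two_source_series):
        series, _, _ = planted_two_source_series
        decomp = ica_maps(series, k=3, rng_seed=0)
        for m in decomp.mixing_maps:
            flat = m.ravel()
            assert flat[np.argmax(np.abs(flat))] > 0

    def test_k_must_be_smaller_than_problem(self):
        series = np.random.default_rng(9).normal(size=(10, 4, 4))
        with pytest.raises(ConfigError):
            ica_maps(series, k=12, rng_seed=0)
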