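"""The digital-cortex phantom generator and its ground-truth contracts."""

import numpy as np
import pytest
from scipy.signal import periodogram

import rgbrsfc as rf
from rgbrsfc.errors import ConfigError, GenerationError
from rgbrsfc.phantom import (PhantomConfig, bandlimited_noise, default_config,
                             disk_mask, generate_network_sources,
                             render_phantom, write_phantom)
from rgbrsfc.video_io import StimulusProtocol


class TestSources:
    def test_distinct_networks_are_uncorrelated(self):
        cfg = default_config(rng_seed=5)
        sources = generate_network_sources(cfg)
        r = np.corrcoef(sources[0]["hbo2"], sources[1]["hbo2"])[0, 1]
        assert abs(r) < 0.3

    def test_gamma_one_gives_exact_negation(self):
        cfg = default_config(rng_seed=1)
        cfg.hb_gamma = 1.0
        sources = generate_network_sources(cfg)
        np.testing.assert_array_equal(sources[0]["hb"], -sources[0]["hbo2"])

    def test_spectral_containment_below_point_one_hertz(self):
        cfg = default_config(rng_seed=2)
        for src in generate_network_sources(cfg):
            f, p = periodogram(src["hbo2"], fs=cfg.frame_rate)
            assert p[f > 0.1].sum() <= 0.01 * p.sum()

    def test_band_outside_nyquist_rejected(self):
        cfg = default_config(rng_seed=0)
        cfg.frame_rate = 0.15
        with pytest.raises(ConfigError):
            generate_network_sources(cfg)

    def test_sources_start_at_zero_with_unit_peak_amplitude(self):
        cfg = default_config(rng_seed=3)
        for src in generate_network_sources(cfg):
            assert src["hbo2"][0] == 0.0
            assert np.abs(src["hbo2"]).max() == pytest.approx(
                cfg.network_amplitude)

    def test_bandlimited_noise_has_no_out_of_band_power(self):
        rng = np.random.default_rng(0)
        x = bandlimited_noise(1000, 10.0, (0.01, 0.08), rng)
        f, p = periodogram(x, fs=10.0)
        in_band = p[(f > 0.01) & (f < 0.08)].sum()
        assert in_band / p.sum() > 0.999


class TestTaskResponse:
    def test_block_protocol_response_has_40s_period(self):
        protocol = StimulusProtocol.block_design(20, 20, 200, 10)
        hbo2, _ = rf.generate_task_response(protocol, rf.HRFModel(), 10.0)
        # steady-state cycles (skip the first) repeat every 40 s = 400 frames
        np.testing.assert_allclose(hbo2[800:1200], hbo2[1200:1600], atol=1e-6)

    def test_delegates_to_map_module(self):
        protocol = StimulusProtocol.block_design(20, 20, 100, 10)
        a = rf.generate_task_response(protocol, rf.HRFModel(), 10.0)
        b = rf.build_theoretical_response(protocol, rf.HRFModel(), 10.0)
        np.testing.assert_array_equal(a[0], b[0])


class TestRendering:
    def test_quiet_empty_phantom_is_static(self):
        cfg = PhantomConfig(image_height=16, image_width=16, duration=10.0,
                            noise_sd=0.0, motion_amplitude=0.0,
                            drift_slope=(0.0, 0.0, 0.0), rng_seed=0)
        video, _ = render_phantom(cfg)
        for t in range(1, video.n_frames):
            np.testing.assert_array_equal(video.frames[t], video.frames[0])

    def test_same_config_and_seed_bit_identical(self):
        cfg1 = default_config(rng_seed=9)
        cfg1.image_height = cfg1.image_width = 48
        cfg1.duration = 30.0
        cfg1.network_masks = [disk_mask((48, 48), (16, 16), 8),
                              disk_mask((48, 48), (32, 32), 8)]
        cfg1.class_layout = None
        cfg2 = default_config(rng_seed=9)
        cfg2.image_height = cfg2.image_width = 48
        cfg2.duration = 30.0
        cfg2.network_masks = [m.copy() for m in cfg1.network_masks]
        cfg2.class_layout = None
        v1, _ = render_phantom(cfg1)
        v2, _ = render_phantom(cfg2)
        np.testing.assert_array_equal(v1.frames, v2.frames)

    def test_truth_reproduces_sources_inside_masks(self, tiny_quiet_config):
        _, truth = render_phantom(tiny_quiet_config)
        for mask, src in zip(truth.network_masks, truth.source_signals):
            pixel = tuple(np.argwhere(mask)[0])
            np.testing.assert_array_equal(
                truth.true_concentrations.dc_hbo2[:, pixel[0], pixel[1]],
                src["hbo2"])

    def test_applied_motion_zero_on_first_frame(self):
        cfg = default_config(rng_seed=0)
        cfg.image_height = cfg.image_width = 32
        cfg.duration = 10.0
        cfg.network_masks = []
        cfg.class_layout = None
        _, truth = render_phantom(cfg)
        np.testing.assert_array_equal(truth.applied_motion[0], (0.0, 0.0))
        assert np.abs(truth.applied_motion).max() > 0

    def test_overlapping_network_masks_rejected(self):
        cfg = default_config(rng_seed=0)
        cfg.network_masks = [disk_mask((128, 128), (40, 40), 18)] * 2
        with pytest.raises(ConfigError, match="disjoint"):
            cfg.validate()

    def test_absurd_amplitude_raises_generation_error(self):
        cfg = PhantomConfig(image_height=8, image_width=8, duration=100.0,
                            noise_sd=0.0, motion_amplitude=0.0,
                            drift_slope=(0.0, 0.0, 0.0), rng_seed=0,
                            network_amplitude=0.1)  # 0.1 mol/L: unphysical
        cfg.network_masks = [disk_mask((8, 8), (4, 4), 3)]
        with pytest.raises(GenerationError, match="frame"):
            render_phantom(cfg)

    def test_task_mask_without_protocol_rejected(self):
        cfg = default_config(rng_seed=0)
        cfg.task_mask = disk_mask((128, 128), (64, 64), 10)
        with pytest.raises(ConfigError, match="protocol"):
            render_phantom(cfg)


class TestPersistence:
    def test_write_phantom_emits_complete_bundle(self, tmp_path):
        cfg = default_config(rng_seed=4, task_on_network=0)
        cfg.image_height = cfg.image_width = 48
        cfg.duration = 50.0
        cfg.network_masks = [disk_mask((48, 48), (16, 16), 8),
                             disk_mask((48, 48), (32, 32), 8)]
        cfg.task_mask = cfg.network_masks[0].copy()
        cfg.protocol = StimulusProtocol.block_design(20, 20, 50, 10)
        cfg.class_layout = None
        out = write_phantom(cfg, tmp_path / "ph")
        for name in ("video.tif", "labels.png", "network_1_mask.png",
                     "network_2_mask.png", "network_1_source.csv",
                     "task_mask.png", "task_source.csv",
                     "applied_motion.csv", "phantom_config.yaml",
                     "protocol.csv"):
            assert (out / name).exists(), name

    def test_written_source_csv_round_trips(self, tmp_path):
        import pandas as pd
        cfg = default_config(rng_seed=4)
        cfg.image_height = cfg.image_width = 48
        cfg.duration = 30.0
        cfg.network_masks = [disk_mask((48, 48), (16, 16), 8),
                             disk_mask((48, 48), (32, 32), 8)]
        cfg.class_layout = None
        out = write_phantom(cfg, tmp_path / "ph")
        _, truth = render_phantom(cfg)
        df = pd.read_csv(out / "network_1_source.csv")
        np.testing.assert_allclose(df["hbo2_molL"].to_numpy(),
                                   truth.source_signals[0]["hbo2"])
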