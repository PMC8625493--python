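"""Synthetic "digital cortex" phantom: RGB videos with known ground truth.

The phantom emulates the statistical structure the analysis pipeline assumes
about an exposed cortex filmed with an RGB camera:

* spatially coherent low-frequency (< 0.1 Hz) hemoglobin fluctuations shared
  by the pixels of each planted resting-state network, independent across
  networks, with deoxyhemoglobin anticorrelated to oxyhemoglobin;
* optionally, a task response (stimulus boxcar convolved with an HRF) planted
  in a task region;
* the modified Beer-Lambert forward model with per-tissue-class baselines and
  photon path lengths;
* slow multiplicative intensity drift (tissue desiccation), periodic rigid
  translation (cardiac/respiratory brain motion) and per-pixel Gaussian
  sensor noise.

Everything is driven by a single RNG seed: identical configs give
byte-identical videos.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import yaml

from .errors import ConfigError, FormatError, GenerationError
from .funcmaps import HRFModel, build_theoretical_response
from .hemodynamics import ConcentrationVideo, forward_beer_lambert
from .video_io import (OpticsTables, RGBVideo, StimulusProtocol,
                       TissueClassMap, default_optics, write_label_map,
                       write_mask, write_video)

#: default peak amplitude of planted oxyhemoglobin excursions, mol/L
DEFAULT_AMPLITUDE = 1e-6
#: default Hb = -gamma * HbO2 coupling
DEFAULT_GAMMA = 0.4


def disk_mask(shape: tuple[int, int], center: tuple[int, int],
              radius: float) -> np.ndarray:
    rr, cc = np.ogrid[:shape[0], :shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def default_class_layout(shape: tuple[int, int]) -> TissueClassMap:
    """Gray matter with one surface-vessel and one buried-vessel stripe."""
    labels = np.zeros(shape, dtype=np.uint8)
    h, w = shape
    # vertical surface vessel near the left edge, diagonal buried vessel
    labels[:, w // 8: w // 8 + max(2, w // 32)] = 1
    for r in range(h):
        c = int(0.75 * w - 0.25 * r)
        labels[r, max(c, 0): max(c, 0) + max(2, w // 32)] = 2
    return TissueClassMap(labels=labels)


#: default per-class (R, G, B) baseline intensities, arbitrary camera units.
#: Vessels are redder and darker than gray matter; the buried vessel is
#: brighter (washed out by overlying tissue) than the surface one.
DEFAULT_BASELINE = np.array([
    [180.0, 120.0, 80.0],   # gray matter
    [150.0, 60.0, 40.0],    # surface vessel
    [160.0, 90.0, 60.0],    # buried vessel
])


@dataclass
class PhantomConfig:
    """Study conditions of the digital cortex.

    Defaults mirror an intraoperative resting-state acquisition: 100 s of
    128 x 128 video at 10 Hz, two planted networks fluctuating in the
    0.01-0.08 Hz band at 1 umol/L peak, ~1 Hz periodic motion of 2 px,
    a fraction-of-a-percent sensor noise and a slow percent-level drift.
    """

    image_height: int = 128
    image_width: int = 128
    frame_rate: float = 10.0
    duration: float = 100.0
    network_masks: list[np.ndarray] = field(default_factory=list)
    network_band: tuple[float, float] = (0.01, 0.08)
    network_amplitude: float = DEFAULT_AMPLITUDE
    hb_gamma: float = DEFAULT_GAMMA
    task_mask: np.ndarray | None = None
    task_amplitude: float = DEFAULT_AMPLITUDE
    protocol: StimulusProtocol | None = None
    hrf: HRFModel = field(default_factory=HRFModel)
    class_layout: TissueClassMap | None = None
    baseline_intensity: np.ndarray = field(
        default_factory=lambda: DEFAULT_BASELINE.copy())
    drift_slope: tuple[float, float, float] = (-2e-4, -3e-4, -2.5e-4)  # /s
    motion_amplitude: float = 2.0  # px
    motion_period: float = 1.1  # s
    noise_sd: float = 0.005  # fraction of baseline
    rng_seed: int = 0
    optics: OpticsTables | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return (self.image_height, self.image_width)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def validate(self) -> None:
        low, high = self.network_band
        if not 0 < low < high:
            raise ConfigError(f"invalid network band {self.network_band}")
        if high > 0.1:
            raise ConfigError("network band must lie within (0, 0.1] Hz")
        if self.frame_rate <= 2 * high:
            raise ConfigError("frame_rate must exceed twice the band's high edge")
        if np.any(np.asarray(self.baseline_intensity) <= 0):
            raise ConfigError("baseline intensities must be positive")
        for i, m in enumerate(self.network_masks):
            if m.shape != self.shape:
                raise ConfigError(f"network mask {i} shape {m.shape} != {self.shape}")
        for i, a in enumerate(self.network_masks):
            for b in self.network_masks[i + 1:]:
                if (a & b).any():
                    raise ConfigError("network masks must be pairwise disjoint")
        if self.task_mask is not None and self.task_mask.shape != self.shape:
            raise ConfigError("task mask shape mismatch")
        if self.class_layout is not None and self.class_layout.shape != self.shape:
            raise ConfigError("class layout shape mismatch")
        if not 0 < self.hb_gamma <= 1:
            raise ConfigError("hb_gamma must be in (0, 1]")


@dataclass
class PhantomTruth:
    """Ground truth of a rendered phantom, for recovery tests."""

    network_masks: list[np.ndarray]
    source_signals: list[dict[str, np.ndarray]]  # per network: hbo2, hb traces
    task_mask: np.ndarray | None
    task_signal: dict[str, np.ndarray] | None
    true_concentrations: ConcentrationVideo
    applied_motion: np.ndarray  # T x 2, (dx, dy) px, zero on frame 0
    class_layout: TissueClassMap


def default_config(rng_seed: int = 0, with_task: bool = False,
                   task_on_network: int | None = None) -> PhantomConfig:
    """The default two-network phantom; optionally with a task response.

    ``with_task`` plants the standard 20 s rest / 20 s stimulation block
    design in its own region; ``task_on_network`` instead plants it on the
    given planted network, so the task region and a resting-state network
    coincide (the configuration the cross-method comparisons assume).
    """
    cfg = PhantomConfig(rng_seed=rng_seed)
    shape = cfg.shape
    cfg.network_masks = [disk_mask(shape, (40, 40), 18),
                         disk_mask(shape, (88, 88), 18)]
    cfg.class_layout = default_class_layout(shape)
    if with_task or task_on_network is not None:
        cfg.protocol = StimulusProtocol.block_design(
            rest_s=20.0, stim_s=20.0, duration=cfg.duration,
            frame_rate=cfg.frame_rate)
        if task_on_network is not None:
            cfg.task_mask = cfg.network_masks[task_on_network].copy()
        else:
            cfg.task_mask = disk_mask(shape, (40, 40), 18)
            cfg.network_masks = []
    return cfg


def bandlimited_noise(n: int, frame_rate: float, band: tuple[float, float],
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-peak Gaussian noise whose spectrum is confined to ``band``.

    Synthesized directly in the frequency domain (random Gaussian Fourier
    coefficients inside the band, zero outside), i.e., white noise filtered
    by an ideal brick-wall band-pass — the standard band-limited surrogate
    for resting-state fluctuations, with exact spectral containment.
    """
    low, high = band
    freqs = np.fft.rfftfreq(n, 1.0 / frame_rate)
    # open interval: modes strictly inside the band, so planted sources stay
    # clear of the analysis filter's cut-off and of the record-length mode
    sel = (freqs > low) & (freqs < high)
    if not sel.any():
        raise ConfigError(f"band {band} holds no Fourier mode at length {n}")
    spec = np.zeros(freqs.size, dtype=complex)
    spec[sel] = rng.standard_normal(sel.sum()) + 1j * rng.standard_normal(sel.sum())
    x = np.fft.irfft(spec, n=n)
    # concentration changes are referenced to frame 0, so the planted source
    # must start at zero (a DC offset, irrelevant to band content)
    x -= x[0]
    return x / np.max(np.abs(x))


def generate_network_sources(config: PhantomConfig,
                             rng: np.random.Generator | None = None
                             ) -> list[dict[str, np.ndarray]]:
    """One independent band-limited chromophore source pair per network.

    Each network gets an HbO2 trace of peak amplitude ``network_amplitude``
    and an anticorrelated Hb trace ``hb = -gamma * hbo2``. Sources of
    distinct networks are drawn independently and then decorrelated
    in-sample (Gram-Schmidt on the centered traces), so the planted ground
    truth realizes the zero-correlation assumption at finite duration
    instead of carrying the sampling noise of a short record.
    """
    config.validate()
    low, high = config.network_band
    if not 0 < low < high < config.frame_rate / 2:
        raise ConfigError(f"band {config.network_band} outside "
                          f"(0, {config.frame_rate / 2}) Hz")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    raw = [bandlimited_noise(config.n_frames, config.frame_rate,
                             config.network_band, rng)
           for _ in config.network_masks]
    sources = []
    basis: list[np.ndarray] = []
    for x in raw:
        xc = x - x.mean()
        for b in basis:
            xc = xc - (xc @ b) * b
        norm = np.linalg.norm(xc)
        if norm < 1e-12 * config.n_frames:
            raise ConfigError(
                "cannot plant this many mutually uncorrelated sources in "
                "the requested band and duration")
        basis.append(xc / norm)
        xc -= xc[0]  # reference to frame 0 (constant shift keeps orthogonality)
        hbo2 = config.network_amplitude * xc / np.max(np.abs(xc))
        sources.append({"hbo2": hbo2, "hb": -config.hb_gamma * hbo2})
    return sources


def generate_task_response(protocol: StimulusProtocol, hrf: HRFModel,
                           frame_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Theoretical (HbO2, Hb) task responses; thin wrapper over the map module."""
    return build_theoretical_response(protocol, hrf, frame_rate)


def render_phantom(config: PhantomConfig) -> tuple[RGBVideo, PhantomTruth]:
    """Render the phantom video and its ground truth.

    Order of effects: paint sources into the true concentration video, apply
    the Beer-Lambert forward model, multiply per-channel drift, apply the
    periodic rigid translation, add sensor noise, clip to positive.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    t, (h, w) = config.n_frames, config.shape
    classes = config.class_layout or TissueClassMap(np.zeros((h, w), np.uint8))
    optics = config.optics or default_optics()

    dc_hbo2 = np.zeros((t, h, w))
    dc_hb = np.zeros((t, h, w))
    sources = generate_network_sources(config, rng)
    for mask, src in zip(config.network_masks, sources):
        dc_hbo2[:, mask] += src["hbo2"][:, None]
        dc_hb[:, mask] += src["hb"][:, None]
    task_signal = None
    if config.task_mask is not None:
        if config.protocol is None:
            raise ConfigError("task_mask set but no protocol given")
        if config.protocol.samples.size != t:
            raise ConfigError("protocol length does not match frame count")
        hbo2_th, hb_th = generate_task_response(config.protocol, config.hrf,
                                                config.frame_rate)
        peak = np.max(np.abs(hbo2_th))
        if peak == 0:
            raise ConfigError("all-rest protocol yields a zero task response")
        scale = config.task_amplitude / peak
        # task responses are +H / -H at equal magnitude; the gamma coupling
        # only shapes the spontaneous network sources
        task_signal = {"hbo2": scale * hbo2_th, "hb": scale * hb_th}
        dc_hbo2[:, config.task_mask] += task_signal["hbo2"][:, None]
        dc_hb[:, config.task_mask] += task_signal["hb"][:, None]

    truth_conc = ConcentrationVideo(dc_hbo2=dc_hbo2, dc_hb=dc_hb,
                                    frame_rate=config.frame_rate,
                                    valid_mask=np.ones((h, w), bool))
    try:
        with np.errstate(over="ignore", under="ignore"):
            video = forward_beer_lambert(truth_conc, classes, optics,
                                         np.asarray(config.baseline_intensity))
        frames = video.frames
        bad_frames = ~np.isfinite(frames).all(axis=(1, 2, 3)) | \
            (frames <= 0).any(axis=(1, 2, 3))
    except FormatError:
        bad_frames = None
    if bad_frames is None or bad_frames.any():
        if bad_frames is None:
            excursion = np.abs(dc_hbo2).max(axis=(1, 2)) + np.abs(dc_hb).max(axis=(1, 2))
            bad = int(np.argmax(excursion))
        else:
            bad = int(np.argwhere(bad_frames)[0, 0])
        raise GenerationError(
            f"concentration excursions drive modeled intensity out of "
            f"range at frame {bad}")

    times = np.arange(t) / config.frame_rate
    drift = 1.0 + np.asarray(config.drift_slope)[None, :] * times[:, None]
    if np.any(drift <= 0):
        raise GenerationError("drift drives intensities nonpositive")
    frames = frames * drift[:, None, None, :]

    applied_motion = np.zeros((t, 2))
    if config.motion_amplitude > 0:
        phase = 2 * np.pi * times / config.motion_period
        applied_motion[:, 0] = config.motion_amplitude * np.sin(phase)       # dx
        applied_motion[:, 1] = 0.5 * config.motion_amplitude * np.sin(phase)  # dy
        for i in range(1, t):
            dx, dy = applied_motion[i]
            frames[i] = ndi.shift(frames[i], (dy, dx, 0.0), order=1,
                                  mode="nearest")

    if config.noise_sd > 0:
        base_img = np.asarray(config.baseline_intensity)[classes.labels]
        noise = rng.standard_normal(frames.shape)
        frames = frames + config.noise_sd * base_img[None] * noise
    np.clip(frames, 1e-9, None, out=frames)

    truth = PhantomTruth(network_masks=[m.copy() for m in config.network_masks],
                         source_signals=sources,
                         task_mask=None if config.task_mask is None
                         else config.task_mask.copy(),
                         task_signal=task_signal,
                         true_concentrations=truth_conc,
                         applied_motion=applied_motion,
                         class_layout=classes)
    return RGBVideo(frames=frames, frame_rate=config.frame_rate), truth


def write_phantom(config: PhantomConfig, outdir: str | Path) -> Path:
    """Render and persist a phantom: video, labels, truth bundle and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    video, truth = render_phantom(config)
    write_video(video, outdir / "video.tif")
    write_label_map(truth.class_layout, outdir / "labels.png")
    times = np.arange(config.n_frames) / config.frame_rate
    for i, (mask, src) in enumerate(zip(truth.network_masks,
                                        truth.source_signals), start=1):
        write_mask(mask, outdir / f"network_{i}_mask.png")
        pd.DataFrame({"time_s": times, "hbo2_molL": src["hbo2"],
                      "hb_molL": src["hb"]}).to_csv(
            outdir / f"network_{i}_source.csv", index=False)
    if truth.task_mask is not None:
        write_mask(truth.task_mask, outdir / "task_mask.png")
        pd.DataFrame({"time_s": times,
                      "hbo2_molL": truth.task_signal["hbo2"],
                      "hb_molL": truth.task_signal["hb"]}).to_csv(
            outdir / "task_source.csv", index=False)
    pd.DataFrame(truth.applied_motion, columns=["dx_px", "dy_px"]).to_csv(
        outdir / "applied_motion.csv", index_label="frame")
    meta = {
        "image_height": config.image_height, "image_width": config.image_width,
        "frame_rate": config.frame_rate, "duration": config.duration,
        "network_band": list(config.network_band),
        "network_amplitude": config.network_amplitude,
        "hb_gamma": config.hb_gamma,
        "task_amplitude": config.task_amplitude,
        "drift_slope": list(config.drift_slope),
        "motion_amplitude": config.motion_amplitude,
        "motion_period": config.motion_period,
        "noise_sd": config.noise_sd, "rng_seed": config.rng_seed,
        "n_networks": len(config.network_masks),
        "has_task": config.task_mask is not None,
    }
    with open(outdir / "phantom_config.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    if config.protocol is not None:
        from .video_io import write_protocol
        write_protocol(config.protocol, outdir / "protocol.csv")
    return outdir
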