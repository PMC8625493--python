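"""Functional map computation: task correlation, seed correlation and spatial ICA.

All three families operate on the concentration-change videos produced by the
Beer-Lambert inversion and output per-pixel real-valued maps:

* task maps — Pearson correlation of each pixel's time course with a
  theoretical response (stimulus boxcar convolved with a hemodynamic response
  function, positive for HbO2 and negated for Hb);
* seed maps — Pearson correlation of each pixel with the spatial mean time
  course of a small seed disk;
* ICA maps — spatial weights of a FastICA decomposition of the pixels x time
  matrix, the standard model-free route to resting-state networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from sklearn.decomposition import FastICA

from .errors import AnalysisError, ConfigError, FormatError
from .hemodynamics import ConcentrationVideo
from .video_io import StimulusProtocol

DEFAULT_K = 5
DEFAULT_SEED_DIAMETER = 20


@dataclass
class HRFModel:
    """Canonical double-gamma hemodynamic response function.

    Defaults are the community-standard values: response peaking at 6 s with a
    16 s undershoot of 1/6 relative amplitude, both with unit dispersion. The
    kernel is sampled at the video frame rate and scaled to unit peak (scale
    is irrelevant to correlation maps).
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0

    def sample(self, frame_rate: float) -> np.ndarray:
        t = np.arange(0.0, self.duration, 1.0 / frame_rate)
        # gamma(shape a, scale b) has its mode at (a - 1) b: shape delay/b + 1
        # puts the response peak exactly at the stated delay
        peak = scipy.stats.gamma.pdf(
            t, self.peak_delay / self.peak_dispersion + 1,
            scale=self.peak_dispersion)
        under = scipy.stats.gamma.pdf(
            t, self.undershoot_delay / self.undershoot_dispersion + 1,
            scale=self.undershoot_dispersion)
        kernel = peak - self.undershoot_ratio * under
        if kernel.sum() <= 0:
            raise ConfigError("HRF kernel must integrate to a positive value")
        return kernel / kernel.max()


@dataclass
class SeedSpec:
    """A circular seed region: ``center`` (row, col) and ``diameter`` in pixels."""

    center: tuple[int, int]
    diameter: int = DEFAULT_SEED_DIAMETER

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.diameter < 1:
            raise ConfigError("seed diameter must be >= 1")
        r0, c0 = self.center
        radius = self.diameter / 2.0
        if (r0 - radius < -0.5 or c0 - radius < -0.5
                or r0 + radius > shape[0] - 0.5 or c0 + radius > shape[1] - 0.5):
            raise ConfigError(f"seed disk {self} does not fit inside {shape}")
        rr, cc = np.ogrid[:shape[0], :shape[1]]
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2


@dataclass
class FunctionalMap:
    """An H x W real-valued functional map plus its provenance."""

    values: np.ndarray
    kind: str  # task | seed | ica
    chromophore: str  # hbo2 | hb
    component_index: int | None = None


@dataclass
class ICADecomposition:
    """Spatial ICA of one chromophore's pixels x time matrix.

    ``mixing_maps`` holds the K spatial weight images (columns of the
    estimated mixing matrix, the pseudo-inverse of the unmixing matrix,
    reshaped; excluded pixels filled with 0), sorted ascending by spatial
    variance. ``sources`` are the matching K temporal sources. Components
    are sign-fixed so each map's largest-magnitude weight is positive.
    """

    mixing_maps: np.ndarray  # K,H,W
    sources: np.ndarray  # K,T
    unmixing: np.ndarray  # K,P_valid
    order: np.ndarray  # original component indices after variance sort
    k: int
    rng_seed: int
    chromophore: str = ""
    n_iter: int = 0

    def maps(self, chromophore: str | None = None) -> list[FunctionalMap]:
        chrom = chromophore or self.chromophore
        return [FunctionalMap(values=self.mixing_maps[i], kind="ica",
                              chromophore=chrom, component_index=i)
                for i in range(self.k)]


def build_theoretical_response(protocol: StimulusProtocol, hrf: HRFModel,
                               frame_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Theoretical chromophore responses to a stimulus protocol.

    H = protocol (*) hrf, causal and truncated to the protocol length; the
    HbO2 theory is +H and the Hb theory is -H (deoxyhemoglobin washes out
    while oxyhemoglobin rises).
    """
    samples = protocol.samples
    if samples.size == 0:
        raise FormatError("empty protocol")
    kernel = hrf.sample(frame_rate)
    h = np.convolve(samples, kernel)[:samples.size]
    return h, -h


def pearson_map(series: np.ndarray, reference: np.ndarray,
                valid_mask: np.ndarray | None = None) -> np.ndarray:
    """Pearson r of every pixel's time course against a reference time course.

    ``series`` is T x H x W. Pixels with a constant series (or outside
    ``valid_mask``) get r = 0.
    """
    x = np.asarray(series, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if x.shape[0] != ref.shape[0]:
        raise FormatError("series and reference lengths differ")
    ref_sd = ref.std()
    if ref_sd == 0:
        raise AnalysisError("reference time course is constant")
    refz = (ref - ref.mean()) / ref_sd
    xm = x - x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0)
    good = sd > 0
    if valid_mask is not None:
        good &= valid_mask
    r = np.zeros(x.shape[1:])
    num = np.tensordot(refz, xm, axes=(0, 0)) / x.shape[0]
    np.divide(num, sd, out=r, where=good)
    return np.clip(r, -1.0, 1.0)


def task_map(conc: ConcentrationVideo,
             theory: tuple[np.ndarray, np.ndarray]
             ) -> dict[str, FunctionalMap]:
    """Per-pixel Pearson correlation with the theoretical task responses.

    The HbO2 series are correlated with the +H theory and the Hb series with
    the -H theory.
    """
    hbo2_theory, hb_theory = theory
    return {
        "hbo2": FunctionalMap(pearson_map(conc.dc_hbo2, hbo2_theory,
                                          conc.valid_mask), "task", "hbo2"),
        "hb": FunctionalMap(pearson_map(conc.dc_hb, hb_theory,
                                        conc.valid_mask), "task", "hb"),
    }


def seed_map(conc: ConcentrationVideo, seed: SeedSpec) -> dict[str, FunctionalMap]:
    """Seed correlation maps: each pixel vs the seed disk's mean time course."""
    disk = seed.mask(conc.shape)
    usable = disk & conc.valid_mask
    if not usable.any():
        raise AnalysisError("seed disk covers no valid pixels")
    out = {}
    for chrom in ("hbo2", "hb"):
        series = conc.chromophore(chrom)
        reference = series[:, usable].mean(axis=1)
        out[chrom] = FunctionalMap(pearson_map(series, reference,
                                               conc.valid_mask), "seed", chrom)
    return out


def normalize_for_ica(series: np.ndarray,
                      valid_mask: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Standardize each pixel's time course to zero mean, unit variance.

    Returns the P_valid x T matrix, the flat indices of the included pixels,
    and a report of exclusions (zero-variance or invalid pixels).
    """
    x = np.asarray(series, dtype=float)
    t = x.shape[0]
    if t < 2:
        raise FormatError("need at least 2 frames to standardize")
    flat = x.reshape(t, -1)
    sd = flat.std(axis=0)
    keep = sd > 0
    if valid_mask is not None:
        keep &= valid_mask.ravel()
    if not keep.any():
        raise AnalysisError("all pixels have zero variance")
    idx = np.flatnonzero(keep)
    sub = flat[:, idx]
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0)
    report = {"n_pixels": flat.shape[1], "n_included": idx.size,
              "n_excluded": flat.shape[1] - idx.size}
    return z.T, idx, report


def ica_maps(series: np.ndarray, valid_mask: np.ndarray | None = None,
             k: int = DEFAULT_K, rng_seed: int = 0, max_iter: int = 1000,
             tol: float = 1e-3, n_restarts: int = 5,
             chromophore: str = "") -> ICADecomposition:
    """Spatial ICA of one chromophore's concentration video.

    The standardized pixels x time matrix dC' is modeled as a linear mixture
    dC' = A S of K independent temporal sources S (K x T). FastICA estimates
    the unmixing matrix W with S~ = W dC'; the spatial distribution A~ is the
    pseudo-inverse of W, reshaped into K images. Images are sorted ascending
    by their spatial variance and sign-fixed so the largest-|weight| pixel of
    each map is positive. Fully deterministic given ``rng_seed``.
    """
    z, idx, _report = normalize_for_ica(series, valid_mask)  # P_valid x T
    p_valid, t = z.shape
    if not 1 <= k < min(p_valid, t):
        raise ConfigError(f"K={k} must be in [1, min(P, T)) = [1, {min(p_valid, t)})")
    # tol=1e-3 on the unmixing update is ample for spatial map topology;
    # tighter tolerances make the noise-chasing minor components oscillate.
    # The fixed-point iteration can still stall from an unlucky start, so a
    # deterministic sequence of restarts is tried before giving up.
    sources_t = None
    for attempt in range(max(1, n_restarts)):
        state = (int(rng_seed) + attempt * 1_000_003) % (2 ** 31)
        ica = FastICA(n_components=k, random_state=state,
                      whiten="unit-variance", max_iter=max_iter, tol=tol)
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=UserWarning)
            try:
                # samples = frames, features = pixels: sources come out
                # temporal (T x K) and the mixing matrix spatial (P x K),
                # matching the dC' = A S convention.
                sources_t = ica.fit_transform(z.T)
                break
            except UserWarning:  # sklearn signals non-convergence this way
                continue
    if sources_t is None:
        raise AnalysisError(
            f"FastICA did not converge within {max_iter} iterations "
            f"in any of {n_restarts} restarts")
    mixing = ica.mixing_  # P_valid x K
    unmixing = ica.components_  # K x P_valid
    shape = series.shape[1:]
    maps = np.zeros((k,) + shape)
    flat = maps.reshape(k, -1)
    flat[:, idx] = mixing.T
    # ascending spatial variance over included pixels
    order = np.argsort(mixing.var(axis=0), kind="stable")
    maps = maps[order]
    sources = sources_t.T[order]
    unmixing = unmixing[order]
    for i in range(k):
        flat_i = maps[i].ravel()
        if flat_i[np.argmax(np.abs(flat_i))] < 0:
            maps[i] = -maps[i]
            sources[i] = -sources[i]
            unmixing[i] = -unmixing[i]
    return ICADecomposition(mixing_maps=maps, sources=sources,
                            unmixing=unmixing, order=order, k=k,
                            rng_seed=int(rng_seed), chromophore=chromophore,
                            n_iter=int(ica.n_iter_))
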