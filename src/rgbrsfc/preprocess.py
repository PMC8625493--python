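"""Motion compensation, drift correction and low-pass isolation of slow hemodynamics.

The pipeline order is fixed: motion -> drift -> low-pass, applied to RGB
intensities before the chromophore inversion. The low-pass default cut-off of
0.08 Hz isolates the <0.1 Hz band where resting-state fluctuations live while
rejecting cardiac and respiratory components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.signal
from skimage.registration import phase_cross_correlation

from .errors import ConfigError, RegistrationError, TooShortError
from .video_io import RGBVideo


@dataclass
class PreprocessConfig:
    """Knobs for the three preprocessing stages.

    cutoff               low-pass cut-off frequency, Hz
    filter_order         Butterworth order (applied forward-backward, so the
                         effective magnitude response is squared)
    detrend_degree       polynomial degree removed per pixel/channel; 0 is a no-op
                         because the mean is restored after detrending
    registration_upsample  subpixel refinement factor of the phase correlation
    reference_frame      frame every other frame is aligned to
    """

    cutoff: float = 0.08
    filter_order: int = 4
    detrend_degree: int = 1
    registration_upsample: int = 10
    reference_frame: int = 0

    def validate(self, frame_rate: float) -> None:
        if not 0 < self.cutoff < frame_rate / 2:
            raise ConfigError(
                f"cutoff {self.cutoff} Hz outside (0, {frame_rate / 2}) Hz")
        if self.detrend_degree < 0:
            raise ConfigError("detrend_degree must be >= 0")


def compensate_motion(video: RGBVideo,
                      cfg: PreprocessConfig | None = None
                      ) -> tuple[RGBVideo, np.ndarray]:
    """Rigidly align every frame to the reference frame by translation.

    The shift of each frame is estimated at subpixel precision by phase
    correlation on the grayscale channel mean, then applied by bilinear
    interpolation with edge replication at the borders.

    Returns the registered video and the applied corrective shifts as a
    (T, 2) array of ``(dx, dy)`` pixels (column shift, row shift). A frame
    whose content moved by ``(+dx, +dy)`` gets correction ``(-dx, -dy)``.
    """
    cfg = cfg or PreprocessConfig()
    frames = video.frames.astype(float, copy=False)
    gray = frames.mean(axis=-1)
    ref = gray[cfg.reference_frame]
    h, w = ref.shape
    out = np.empty_like(frames)
    shifts = np.zeros((video.n_frames, 2))
    for t in range(video.n_frames):
        if t == cfg.reference_frame:
            out[t] = frames[t]
            continue
        (dy, dx), _, _ = phase_cross_correlation(
            ref, gray[t], upsample_factor=cfg.registration_upsample,
            normalization=None)
        if abs(dy) > 0.25 * h or abs(dx) > 0.25 * w:
            raise RegistrationError(
                f"frame {t}: estimated shift ({dx:.1f}, {dy:.1f}) px exceeds "
                f"25% of the frame size")
        shifts[t] = (dx, dy)
        if dx == 0.0 and dy == 0.0:
            out[t] = frames[t]
        else:
            out[t] = ndi.shift(frames[t], (dy, dx, 0.0), order=1, mode="nearest")
    return RGBVideo(frames=out, frame_rate=video.frame_rate), shifts


def correct_drift(series: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Remove a least-squares polynomial trend along time, per pixel and channel.

    The temporal mean is restored afterwards so the baseline intensity — the
    reference the Beer-Lambert absorbance ratios are taken against — survives
    detrending. Constant series come back unchanged; degree 0 is the identity.

    ``series`` has time on axis 0 and any trailing shape.
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(series, dtype=float)
    t = x.shape[0]
    if t <= cfg.detrend_degree + 1:
        raise TooShortError(
            f"need more than {cfg.detrend_degree + 1} frames to detrend, got {t}")
    if cfg.detrend_degree == 0:
        return x.copy()
    tt = np.arange(t, dtype=float)
    # Vandermonde in ascending powers; column 0 is the constant term.
    v = np.vander(tt, cfg.detrend_degree + 1, increasing=True)
    flat = x.reshape(t, -1)
    coef, *_ = np.linalg.lstsq(v, flat, rcond=None)
    trend = v @ coef
    detrended = flat - trend + flat.mean(axis=0, keepdims=True)
    return detrended.reshape(x.shape)


def lowpass(series: np.ndarray, frame_rate: float,
            cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0.

    Forward-backward filtering doubles the attenuation and cancels the phase
    response, so in-band hemodynamic timing (which the correlation maps rely
    on) is preserved. DC gain is exactly 1: baselines pass through.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(frame_rate)
    x = np.asarray(series, dtype=float)
    sos = scipy.signal.butter(cfg.filter_order, cfg.cutoff, btype="low",
                              fs=frame_rate, output="sos")
    # sosfiltfilt pads 3 * (2 * n_sections + 1) samples on each side
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[0] <= padlen:
        raise TooShortError(
            f"series of length {x.shape[0]} shorter than filter warm-up {padlen + 1}")
    return scipy.signal.sosfiltfilt(sos, x, axis=0)


def preprocess_video(video: RGBVideo,
                     cfg: PreprocessConfig | None = None
                     ) -> tuple[RGBVideo, np.ndarray]:
    """Full preprocessing branch: motion -> drift -> low-pass.

    Returns the preprocessed video and the motion corrections.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(video.frame_rate)
    registered, shifts = compensate_motion(video, cfg)
    detrended = correct_drift(registered.frames, cfg)
    filtered = lowpass(detrended, video.frame_rate, cfg)
    # the filter can produce tiny negative excursions near zero; intensities
    # must stay nonnegative for the log-ratio step
    np.clip(filtered, 0.0, None, out=filtered)
    return RGBVideo(frames=filtered, frame_rate=video.frame_rate), shifts
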