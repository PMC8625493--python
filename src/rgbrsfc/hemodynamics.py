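"""Tissue segmentation and the modified Beer-Lambert model.

The modified Beer-Lambert law links the per-channel log-ratio of intensities
to chromophore concentration changes:

    dA_c(p, t) = log10( I_c(p, 0) / I_c(p, t) )
               = sum_n  eps_n(c) * L_c(class(p)) * dC_n(p, t)

with channels c in {R, G, B}, chromophores n in {HbO2, Hb}, eps the molar
extinction coefficient and L the mean photon path length of the pixel's
tissue class. Three channels and two chromophores give an overdetermined
3 x 2 linear system per pixel and frame, solved in least squares.

Absorbance uses base-10 logarithms; extinction coefficients are in
cm^-1 (mol/L)^-1, path lengths in cm and concentration changes in mol/L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError
from .video_io import (BURIED_VESSEL, GRAY_MATTER, SURFACE_VESSEL,
                       TISSUE_CLASSES, OpticsTables, RGBVideo, TissueClassMap)


@dataclass
class ConcentrationVideo:
    """Per-pixel oxy/deoxyhemoglobin concentration changes from baseline.

    ``dc_hbo2`` and ``dc_hb`` are T x H x W in mol/L, relative to frame 0
    (frame 0 is identically zero). ``valid_mask`` marks pixels where the
    inversion succeeded (all intensities positive).
    """

    dc_hbo2: np.ndarray
    dc_hb: np.ndarray
    frame_rate: float
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.dc_hbo2.shape != self.dc_hb.shape:
            raise FormatError("dc_hbo2 and dc_hb shapes differ")
        if self.valid_mask.shape != self.dc_hbo2.shape[1:]:
            raise FormatError("valid_mask shape does not match frames")

    @property
    def n_frames(self) -> int:
        return self.dc_hbo2.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.dc_hbo2.shape[1:]

    def chromophore(self, name: str) -> np.ndarray:
        if name == "hbo2":
            return self.dc_hbo2
        if name == "hb":
            return self.dc_hb
        raise KeyError(name)


def segment_tissue(first_frame: np.ndarray, vessel_ratio: float = 1.05,
                   ) -> TissueClassMap:
    """Heuristic three-class segmentation of the first video frame.

    Blood vessels absorb green and blue strongly, so they stand out in the
    redness ratio R / (G + B). Pixels above ``vessel_ratio`` are vessels;
    among those, the darker half (below the median vessel brightness) is
    labeled surface vessel and the brighter half buried vessel, following the
    idea that a vessel under a layer of tissue appears washed out. The split
    degrades to all-surface when vessel brightness has no spread.

    Deterministic. A user-supplied label map should be preferred whenever one
    exists; this heuristic is a stand-in for a dedicated segmentation model.
    """
    frame = np.asarray(first_frame, dtype=float)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise FormatError("segmentation needs an H x W x 3 frame")
    r, g, b = frame[..., 0], frame[..., 1], frame[..., 2]
    denom = g + b
    ratio = np.divide(r, denom, out=np.zeros_like(r), where=denom > 0)
    labels = np.full(frame.shape[:2], GRAY_MATTER, dtype=np.uint8)
    vessel = ratio >= vessel_ratio
    if vessel.any():
        brightness = frame.sum(axis=-1)
        vb = brightness[vessel]
        if vb.std() > 1e-6 * max(vb.mean(), 1.0):
            split = np.median(vb)
            labels[vessel & (brightness <= split)] = SURFACE_VESSEL
            labels[vessel & (brightness > split)] = BURIED_VESSEL
        else:
            labels[vessel] = SURFACE_VESSEL
    return TissueClassMap(labels=labels)


def forward_beer_lambert(conc: ConcentrationVideo, classes: TissueClassMap,
                         optics: OpticsTables,
                         baseline: np.ndarray) -> RGBVideo:
    """Render intensities from concentration changes (the phantom's forward model).

    I_c(p, t) = I_c(p, 0) * 10 ** (-dA_c(p, t)), with the baseline frame taken
    from ``baseline``: either a (3 classes x 3 channels) table of per-class
    intensities or a full H x W x 3 baseline image.
    """
    if classes.shape != conc.shape:
        raise FormatError("class map shape does not match concentrations")
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape == (3, 3):
        base_img = baseline[classes.labels]
    elif baseline.shape == conc.shape + (3,):
        base_img = baseline
    else:
        raise FormatError(f"baseline shape {baseline.shape} not understood")
    t, h, w = conc.dc_hbo2.shape
    frames = np.empty((t, h, w, 3))
    dc = np.stack([conc.dc_hbo2, conc.dc_hb], axis=-1)  # T,H,W,2
    for k in TISSUE_CLASSES:
        sel = classes.labels == k
        if not sel.any():
            continue
        m = optics.design_matrix(k)  # 3x2
        da = dc[:, sel, :] @ m.T  # T,N,3
        frames[:, sel, :] = base_img[sel][None, :, :] * 10.0 ** (-da)
    return RGBVideo(frames=frames, frame_rate=conc.frame_rate)


def invert_beer_lambert(video: RGBVideo, classes: TissueClassMap,
                        optics: OpticsTables) -> ConcentrationVideo:
    """Recover dC_HbO2 / dC_Hb time courses from an RGB video.

    Per pixel and frame the three channel absorbance changes
    ``dA_c = log10(I_c(0) / I_c(t))`` are solved against the pixel class's
    3 x 2 design matrix in ordinary least squares. Pixels with a nonpositive
    intensity anywhere in their series are marked invalid and carry zeros.
    Frame 0 is exactly zero by construction.
    """
    if classes.shape != video.shape:
        raise FormatError("class map shape does not match video frames")
    frames = video.frames.astype(float, copy=False)
    valid = (frames > 0).all(axis=(0, 3))
    t, h, w = frames.shape[:3]
    dc_hbo2 = np.zeros((t, h, w))
    dc_hb = np.zeros((t, h, w))
    log_frames = np.log10(frames, where=frames > 0,
                          out=np.zeros_like(frames))
    da = log_frames[0][None] - log_frames  # T,H,W,3
    for k in TISSUE_CLASSES:
        sel = (classes.labels == k) & valid
        if not sel.any():
            continue
        pinv = np.linalg.pinv(optics.design_matrix(k))  # 2x3
        sol = da[:, sel, :] @ pinv.T  # T,N,2
        dc_hbo2[:, sel] = sol[..., 0]
        dc_hb[:, sel] = sol[..., 1]
    return ConcentrationVideo(dc_hbo2=dc_hbo2, dc_hb=dc_hb,
                              frame_rate=video.frame_rate, valid_mask=valid)
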