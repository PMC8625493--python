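"""Binarization of functional maps and agreement metrics between binary maps.

A map I is binarized against the threshold

    T = mu_I + alpha * sigma_I   if mu_I >= 0   (keep values >= T)
    T = mu_I - alpha * sigma_I   otherwise      (keep values <= T)

so that both branches select the extreme tail on the side of the mean's sign;
alpha (the severity criterion, in [0, 1]) defaults to 0.75. Binary maps are
cleaned with a morphological opening followed by a closing using a circular
structuring element (default 20 px wide) and compared with the DICE and
overlap coefficients:

    DICE(X, Y)    = 2 |X n Y| / (|X| + |Y|)        (symmetric)
    Overlap(X, Y) = |X n Y| / |X|                  (fraction of X inside Y)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.morphology import closing, disk, opening

from .errors import FormatError
from .funcmaps import FunctionalMap

DEFAULT_ALPHA = 0.75
DEFAULT_STRUCT_DIAMETER = 20


@dataclass
class BinaryMap:
    """A thresholded functional map."""

    mask: np.ndarray
    source_kind: str
    threshold_used: float
    alpha: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class ComparisonResult:
    dice: float
    overlap: float
    pair: tuple[str, str]
    ebs_points_inside: list[bool] | None = None


def _as_mask(x) -> np.ndarray:
    if isinstance(x, BinaryMap):
        return x.mask
    return np.asarray(x, dtype=bool)


def threshold_map(fmap: FunctionalMap | np.ndarray,
                  alpha: float = DEFAULT_ALPHA,
                  valid_mask: np.ndarray | None = None) -> BinaryMap:
    """Binarize a functional map with the mean +/- alpha * sd rule.

    Statistics are computed over valid pixels only. A flat map (sigma = 0)
    yields an empty mask with a warning.
    """
    if isinstance(fmap, FunctionalMap):
        values, kind = fmap.values, fmap.kind
    else:
        values, kind = np.asarray(fmap, dtype=float), "unknown"
    sel = np.isfinite(values)
    if valid_mask is not None:
        sel &= valid_mask
    if not sel.any():
        raise FormatError("no valid pixels to threshold")
    mu = float(values[sel].mean())
    sigma = float(values[sel].std())
    if sigma <= 1e-12 * max(abs(mu), 1.0):
        warnings.warn("flat map: sigma = 0, returning empty mask")
        return BinaryMap(np.zeros(values.shape, bool), kind, mu, alpha)
    if mu >= 0:
        thr = mu + alpha * sigma
        mask = (values >= thr) & sel
    else:
        thr = mu - alpha * sigma
        mask = (values <= thr) & sel
    return BinaryMap(mask, kind, thr, alpha)


def morph_cleanup(binary: BinaryMap | np.ndarray,
                  diameter: int = DEFAULT_STRUCT_DIAMETER) -> BinaryMap:
    """Opening then closing with a circular structuring element.

    Removes specks smaller than the element and fills comparably small holes.
    ``diameter`` is the element width in pixels (a radius-diameter//2 disk).
    """
    mask = _as_mask(binary)
    footprint = disk(diameter // 2)
    cleaned = closing(opening(mask, footprint), footprint).astype(bool)
    if isinstance(binary, BinaryMap):
        return BinaryMap(cleaned, binary.source_kind, binary.threshold_used,
                         binary.alpha)
    return BinaryMap(cleaned, "unknown", float("nan"), float("nan"))


def dice(x, y) -> float:
    """DICE coefficient 2|X n Y| / (|X| + |Y|); 0 (with a warning) if both empty."""
    xm, ym = _as_mask(x), _as_mask(y)
    if xm.shape != ym.shape:
        raise FormatError(f"mask shapes differ: {xm.shape} vs {ym.shape}")
    total = int(xm.sum()) + int(ym.sum())
    if total == 0:
        warnings.warn("DICE of two empty masks defined as 0")
        return 0.0
    return 2.0 * int((xm & ym).sum()) / total


def overlap(x, y) -> float:
    """Overlap coefficient |X n Y| / |X| — asymmetric, X is the reference map."""
    xm, ym = _as_mask(x), _as_mask(y)
    if xm.shape != ym.shape:
        raise FormatError(f"mask shapes differ: {xm.shape} vs {ym.shape}")
    nx = int(xm.sum())
    if nx == 0:
        warnings.warn("overlap with empty reference mask defined as 0")
        return 0.0
    return int((xm & ym).sum()) / nx


def ebs_inside(point: tuple[int, int], binary: BinaryMap | np.ndarray) -> bool:
    """Whether a stimulation-marked point falls inside a binary map.

    Pixel membership, no interpolation: a point on a boundary pixel counts.
    """
    mask = _as_mask(binary)
    r, c = point
    if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
        raise FormatError(f"point {point} outside image bounds {mask.shape}")
    return bool(mask[int(r), int(c)])


def compare_maps(x, y, pair: tuple[str, str] = ("x", "y"),
                 ebs_points: list[tuple[int, int]] | None = None
                 ) -> ComparisonResult:
    """DICE + overlap for a pair of binary maps, with optional point inclusion in Y."""
    result = ComparisonResult(dice=dice(x, y), overlap=overlap(x, y), pair=pair)
    if ebs_points is not None:
        result.ebs_points_inside = [ebs_inside(p, y) for p in ebs_points]
    return result
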