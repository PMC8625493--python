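"""I/O and domain containers for RGB cortex videos and their side tables.

Conventions used by every module in the package:

* pixel coordinates are row-major, 0-based ``(row, col)``, origin top-left;
* channel order is fixed ``(R, G, B)``;
* sampling is uniform at ``frame_rate`` Hz, time of frame ``t`` is ``t / frame_rate`` s;
* tissue-class labels are ``0`` gray matter, ``1`` surface vessel, ``2`` buried vessel.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigError, FormatError, TooShortError

GRAY_MATTER, SURFACE_VESSEL, BURIED_VESSEL = 0, 1, 2
TISSUE_CLASSES = (GRAY_MATTER, SURFACE_VESSEL, BURIED_VESSEL)
CLASS_NAMES = {GRAY_MATTER: "gray_matter", SURFACE_VESSEL: "surface_vessel",
               BURIED_VESSEL: "buried_vessel"}
CHANNELS = ("R", "G", "B")
CHROMOPHORES = ("hbo2", "hb")


@dataclass
class RGBVideo:
    """T-frame H x W x 3 intensity stack in arbitrary camera units."""

    frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise FormatError(f"frames must be T x H x W x 3, got {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise TooShortError("a video needs at least 2 frames")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise FormatError("video intensities must be finite")
        if np.any(self.frames < 0):
            raise FormatError("video intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of a single frame."""
        return self.frames.shape[1:3]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class TissueClassMap:
    """Per-pixel tissue label selecting the photon path lengths."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("labels must be a 2-D image")
        if not np.isin(self.labels, TISSUE_CLASSES).all():
            bad = sorted(set(np.unique(self.labels)) - set(TISSUE_CLASSES))
            raise FormatError(f"labels outside the 3-class set: {bad}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class StimulusProtocol:
    """Per-frame binary stimulation series: 0 = rest, 1 = stimulation."""

    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise FormatError("protocol must be a nonempty 1-D series")
        if not np.isin(self.samples, (0.0, 1.0)).all():
            raise FormatError("protocol values must be 0 or 1")

    @classmethod
    def from_intervals(cls, intervals: list[tuple[float, float]],
                       duration: float, frame_rate: float) -> "StimulusProtocol":
        """Build the per-frame series from stimulation ``(start_s, end_s)`` intervals."""
        n = int(round(duration * frame_rate))
        t = np.arange(n) / frame_rate
        samples = np.zeros(n)
        last_end = None
        for start, end in sorted(intervals):
            if end <= start:
                raise FormatError(f"empty interval ({start}, {end})")
            if end > duration + 1e-9:
                raise FormatError(f"interval ({start}, {end}) exceeds duration {duration}")
            if last_end is not None and start < last_end:
                raise FormatError("stimulation intervals overlap")
            last_end = end
            samples[(t >= start) & (t < end)] = 1.0
        return cls(samples)

    @classmethod
    def block_design(cls, rest_s: float, stim_s: float, duration: float,
                     frame_rate: float) -> "StimulusProtocol":
        """Alternating rest/stimulation blocks, starting with rest."""
        intervals = []
        t = rest_s
        while t < duration:
            intervals.append((t, min(t + stim_s, duration)))
            t += rest_s + stim_s
        return cls.from_intervals(intervals, duration, frame_rate)


@dataclass
class OpticsTables:
    """Extinction spectra and per-class mean photon path lengths.

    ``extinction``: (3 channels x 2 chromophores) molar extinction coefficients,
    cm^-1 (mol/L)^-1, rows ordered R, G, B and columns ordered (HbO2, Hb).
    ``pathlength``: (3 channels x 3 tissue classes) mean photon path lengths, cm,
    columns ordered (gray matter, surface vessel, buried vessel).
    """

    extinction: np.ndarray
    pathlength: np.ndarray

    def __post_init__(self) -> None:
        self.extinction = np.asarray(self.extinction, dtype=float)
        self.pathlength = np.asarray(self.pathlength, dtype=float)
        if self.extinction.shape != (3, 2):
            raise ConfigError("extinction must be 3 channels x 2 chromophores")
        if self.pathlength.shape != (3, 3):
            raise ConfigError("pathlength must be 3 channels x 3 tissue classes")
        if np.any(self.extinction <= 0):
            raise ConfigError("extinction coefficients must be positive")
        if np.any(self.pathlength <= 0):
            raise ConfigError("path lengths must be positive")
        for k in TISSUE_CLASSES:
            m = self.design_matrix(k)
            if np.linalg.matrix_rank(m) < 2:
                raise ConfigError(
                    f"design matrix for class {CLASS_NAMES[k]} is rank deficient: "
                    "channels cannot separate HbO2 from Hb")

    def design_matrix(self, tissue_class: int) -> np.ndarray:
        """3 x 2 matrix M with M[c, n] = epsilon_n(c) * L_c(class)."""
        return self.extinction * self.pathlength[:, tissue_class][:, None]


def read_video(path: str | Path, frame_rate: float) -> RGBVideo:
    """Read a multi-page TIFF or a directory of equally sized frames.

    Directory frames are ordered by filename sort; page order is preserved for
    TIFF stacks. Intensities are read losslessly.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if len(files) < 2:
            raise TooShortError(f"directory {path} holds {len(files)} frames, need >= 2")
        frames = []
        shape = None
        for f in files:
            img = iio.imread(f)
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise FormatError(f"frame {f.name} has shape {img.shape}, "
                                  f"expected {shape}")
            frames.append(img)
        stack = np.stack(frames)
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 3 and stack.shape[-1] == 3:
            raise TooShortError(f"{path} holds a single frame, need >= 2")
    if stack.ndim != 4 or stack.shape[-1] != 3:
        raise FormatError(f"expected T x H x W x 3 frames, got {stack.shape}")
    return RGBVideo(frames=stack, frame_rate=frame_rate)


def write_video(video: RGBVideo, path: str | Path) -> None:
    """Write the stack as a multi-page TIFF, one page per frame, dtype preserved."""
    tifffile.imwrite(Path(path), video.frames, photometric="rgb")


def read_label_map(path: str | Path) -> TissueClassMap:
    return TissueClassMap(labels=iio.imread(Path(path)))


def write_label_map(classes: TissueClassMap, path: str | Path) -> None:
    iio.imwrite(Path(path), classes.labels.astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return iio.imread(Path(path)) > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_protocol(path: str | Path, duration: float | None = None,
                  frame_rate: float | None = None) -> StimulusProtocol:
    """Read a stimulus protocol.

    YAML files hold a list of stimulation ``[start_s, end_s]`` intervals (and
    require ``duration``/``frame_rate``); CSV files hold a per-frame 0/1 column
    named ``stim``.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            intervals = yaml.safe_load(fh)
        if duration is None or frame_rate is None:
            raise ConfigError("interval protocols need duration and frame_rate")
        return StimulusProtocol.from_intervals(
            [tuple(map(float, iv)) for iv in intervals], duration, frame_rate)
    df = pd.read_csv(path)
    col = "stim" if "stim" in df.columns else df.columns[-1]
    return StimulusProtocol(df[col].to_numpy())


def write_protocol(protocol: StimulusProtocol, path: str | Path) -> None:
    pd.DataFrame({"stim": protocol.samples.astype(int)}).to_csv(path, index=False)


def read_optics_tables(path: str | Path) -> OpticsTables:
    """Read extinction/pathlength tables from a long-format CSV.

    Columns: ``quantity`` (extinction | pathlength), ``channel`` (R | G | B),
    ``key`` (chromophore or tissue-class name) and ``value``. All 6 extinction
    and 9 pathlength entries must be present.
    """
    df = pd.read_csv(path, comment="#")
    required = {"quantity", "channel", "key", "value"}
    if not required.issubset(df.columns):
        raise FormatError(f"optics table needs columns {sorted(required)}")
    extinction = np.full((3, 2), np.nan)
    pathlength = np.full((3, 3), np.nan)
    chan_idx = {c: i for i, c in enumerate(CHANNELS)}
    chrom_idx = {c: i for i, c in enumerate(CHROMOPHORES)}
    class_idx = {CLASS_NAMES[k]: k for k in TISSUE_CLASSES}
    for _, row in df.iterrows():
        c = chan_idx.get(str(row["channel"]).strip().upper())
        if c is None:
            raise FormatError(f"unknown channel {row['channel']!r}")
        key = str(row["key"]).strip().lower()
        if row["quantity"] == "extinction":
            if key not in chrom_idx:
                raise FormatError(f"unknown chromophore {key!r}")
            extinction[c, chrom_idx[key]] = row["value"]
        elif row["quantity"] == "pathlength":
            if key not in class_idx:
                raise FormatError(f"unknown tissue class {key!r}")
            pathlength[c, class_idx[key]] = row["value"]
        else:
            raise FormatError(f"unknown quantity {row['quantity']!r}")
    if np.isnan(extinction).any():
        raise FormatError("missing extinction entries")
    if np.isnan(pathlength).any():
        raise FormatError("missing pathlength entries")
    return OpticsTables(extinction=extinction, pathlength=pathlength)


def default_optics() -> OpticsTables:
    """The packaged default optics tables (placeholder path lengths)."""
    ref = importlib.resources.files("rgbrsfc") / "data" / "optics_default.csv"
    with importlib.resources.as_file(ref) as p:
        return read_optics_tables(p)


def write_map_tiff(values: np.ndarray, path: str | Path) -> None:
    """Save a real-valued functional map as a float32 TIFF."""
    tifffile.imwrite(Path(path), np.asarray(values, dtype=np.float32))


def write_map_preview(values: np.ndarray, path: str | Path) -> None:
    """Save a PNG preview with a diverging color scale normalized to max |value|."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = float(np.nanmax(np.abs(values))) or 1.0
    plt.imsave(Path(path), np.nan_to_num(values), cmap="RdBu_r",
               vmin=-vmax, vmax=vmax)
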