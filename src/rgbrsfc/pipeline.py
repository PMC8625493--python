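"""End-to-end orchestration: one config in, all maps and comparisons out.

Stage order is fixed: motion compensation -> drift correction -> low-pass ->
tissue segmentation (or user labels) -> Beer-Lambert inversion -> enabled map
analyses -> thresholding + morphology -> pairwise comparisons. No stage
mutates an upstream artifact and all randomness flows from a single seed, so
identical configs give identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare as cmp
from . import funcmaps, hemodynamics, preprocess, video_io
from .errors import ConfigError
from .funcmaps import FunctionalMap, HRFModel, SeedSpec
from .hemodynamics import ConcentrationVideo
from .preprocess import PreprocessConfig
from .video_io import OpticsTables, RGBVideo, StimulusProtocol, TissueClassMap

CHROMOPHORES = ("hbo2", "hb")


@dataclass
class PipelineConfig:
    """Everything a run needs; usually loaded from a YAML file."""

    video: str
    frame_rate: float
    output: str
    labels: str | None = None
    optics: str | None = None
    protocol: str | None = None
    seeds: list[tuple[int, int]] = field(default_factory=list)
    seed_diameter: int = funcmaps.DEFAULT_SEED_DIAMETER
    ebs_points: list[tuple[int, int]] = field(default_factory=list)
    analyses: tuple[str, ...] = ("task", "seed", "ica")
    alpha: float = cmp.DEFAULT_ALPHA
    k: int = funcmaps.DEFAULT_K
    morph_diameter: int = cmp.DEFAULT_STRUCT_DIAMETER
    rng_seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        pp = PreprocessConfig(**raw.pop("preprocess", {}))
        raw["seeds"] = [tuple(s) for s in raw.get("seeds", [])]
        raw["ebs_points"] = [tuple(p) for p in raw.get("ebs_points", [])]
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        if "K" in raw:
            raw["k"] = raw.pop("K")
        return cls(preprocess=pp, **raw)

    def validate(self) -> None:
        if not self.analyses:
            raise ConfigError("at least one analysis must be enabled")
        unknown = set(self.analyses) - {"task", "seed", "ica"}
        if unknown:
            raise ConfigError(f"unknown analyses: {sorted(unknown)}")
        if "task" in self.analyses and self.protocol is None:
            raise ConfigError("task analysis enabled but no protocol given")
        if "seed" in self.analyses and not self.seeds:
            raise ConfigError("seed analysis enabled but no seed given")
        for name in ("video", "labels", "optics", "protocol"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} file {p} does not exist")


@dataclass
class RunResult:
    """In-memory products of a pipeline run."""

    conc: ConcentrationVideo
    shifts: np.ndarray
    classes: TissueClassMap
    maps: dict[str, FunctionalMap]
    binary: dict[str, cmp.BinaryMap]
    comparisons: pd.DataFrame
    ebs_report: dict
    timings: dict[str, float]


def _map_key(kind: str, chrom: str, component: int | None = None) -> str:
    return f"{kind}_{chrom}" if component is None else f"{kind}_{chrom}_c{component}"


def analyze_video(video: RGBVideo,
                  labels: TissueClassMap | None = None,
                  optics: OpticsTables | None = None,
                  pp_cfg: PreprocessConfig | None = None,
                  protocol: StimulusProtocol | None = None,
                  hrf: HRFModel | None = None,
                  seed: SeedSpec | None = None,
                  ebs_points: list[tuple[int, int]] | None = None,
                  analyses: tuple[str, ...] = ("task", "seed", "ica"),
                  alpha: float = cmp.DEFAULT_ALPHA,
                  k: int = funcmaps.DEFAULT_K,
                  morph_diameter: int = cmp.DEFAULT_STRUCT_DIAMETER,
                  rng_seed: int = 0) -> RunResult:
    """Run the full analysis on an in-memory video.

    This is the library core behind the CLI ``run`` command; every artifact
    the file-based entry point writes comes out of the returned RunResult.
    """
    pp_cfg = pp_cfg or PreprocessConfig()
    hrf = hrf or HRFModel()
    ebs_points = ebs_points or []
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    clean, shifts = preprocess.preprocess_video(video, pp_cfg)
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if labels is None:
        labels = hemodynamics.segment_tissue(clean.frames[0])
    timings["segmentation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    conc = hemodynamics.invert_beer_lambert(
        clean, labels, optics or video_io.default_optics())
    timings["inversion"] = time.perf_counter() - t0

    maps: dict[str, FunctionalMap] = {}
    if "task" in analyses:
        if protocol is None:
            raise ConfigError("task analysis requires a protocol")
        t0 = time.perf_counter()
        theory = funcmaps.build_theoretical_response(protocol, hrf,
                                                     video.frame_rate)
        for chrom, fmap in funcmaps.task_map(conc, theory).items():
            maps[_map_key("task", chrom)] = fmap
        timings["task"] = time.perf_counter() - t0
    if "seed" in analyses:
        if seed is None:
            raise ConfigError("seed analysis requires a seed")
        t0 = time.perf_counter()
        for chrom, fmap in funcmaps.seed_map(conc, seed).items():
            maps[_map_key("seed", chrom)] = fmap
        timings["seed"] = time.perf_counter() - t0
    if "ica" in analyses:
        t0 = time.perf_counter()
        for chrom in CHROMOPHORES:
            decomp = funcmaps.ica_maps(conc.chromophore(chrom), conc.valid_mask,
                                       k=k, rng_seed=rng_seed,
                                       chromophore=chrom)
            for fmap in decomp.maps():
                maps[_map_key("ica", chrom, fmap.component_index)] = fmap
        timings["ica"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    binary = {key: cmp.morph_cleanup(
        cmp.threshold_map(fmap, alpha, conc.valid_mask), morph_diameter)
        for key, fmap in maps.items()}
    timings["threshold"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    comparisons = _pairwise_comparisons(binary, k)
    ebs_report = {key: [bool(cmp.ebs_inside(p, bmap)) for p in ebs_points]
                  for key, bmap in binary.items()}
    timings["compare"] = time.perf_counter() - t0

    return RunResult(conc=conc, shifts=shifts, classes=labels, maps=maps,
                     binary=binary, comparisons=comparisons,
                     ebs_report={"points": [list(p) for p in ebs_points],
                                 "inside": ebs_report},
                     timings=timings)


def _pairwise_comparisons(binary: dict[str, cmp.BinaryMap],
                          k: int) -> pd.DataFrame:
    """Task-vs-resting-state and seed-vs-ICA agreement, per chromophore.

    The overlap coefficient keeps the first named map as its reference set X.
    """
    rows = []

    def add(x_key: str, y_key: str, chrom: str, component) -> None:
        if x_key not in binary or y_key not in binary:
            return
        x, y = binary[x_key], binary[y_key]
        rows.append({"pair": f"{x_key}|{y_key}", "chromophore": chrom,
                     "component": component,
                     "dice": cmp.dice(x, y), "overlap": cmp.overlap(x, y),
                     "threshold_x": x.threshold_used,
                     "threshold_y": y.threshold_used,
                     "area_x": x.area, "area_y": y.area})

    for chrom in CHROMOPHORES:
        add(f"task_{chrom}", f"seed_{chrom}", chrom, None)
        for c in range(k):
            add(f"task_{chrom}", f"ica_{chrom}_c{c}", chrom, c)
            add(f"seed_{chrom}", f"ica_{chrom}_c{c}", chrom, c)
    return pd.DataFrame(rows, columns=["pair", "chromophore", "component",
                                       "dice", "overlap", "threshold_x",
                                       "threshold_y", "area_x", "area_y"])


def run(config: PipelineConfig) -> dict:
    """File-based pipeline run: read inputs, analyze, write all artifacts.

    Returns the report dictionary (also written to ``report.json``).
    """
    config.validate()
    outdir = Path(config.output)
    outdir.mkdir(parents=True, exist_ok=True)

    video = video_io.read_video(config.video, config.frame_rate)
    labels = (video_io.read_label_map(config.labels)
              if config.labels else None)
    optics = (video_io.read_optics_tables(config.optics)
              if config.optics else None)
    protocol = (video_io.read_protocol(config.protocol, video.duration,
                                       video.frame_rate)
                if config.protocol else None)
    seed = (SeedSpec(center=tuple(config.seeds[0]),
                     diameter=config.seed_diameter)
            if config.seeds else None)

    result = analyze_video(video, labels=labels, optics=optics,
                           pp_cfg=config.preprocess, protocol=protocol,
                           seed=seed, ebs_points=config.ebs_points,
                           analyses=config.analyses, alpha=config.alpha,
                           k=config.k, morph_diameter=config.morph_diameter,
                           rng_seed=config.rng_seed)

    shifts_df = pd.DataFrame(result.shifts, columns=["dx_px", "dy_px"])
    shifts_df.to_csv(outdir / "motion_shifts.csv", index_label="frame")
    video_io.write_label_map(result.classes, outdir / "labels_used.png")
    video_io.write_mask(result.conc.valid_mask, outdir / "valid_mask.png")

    artifacts = {}
    for key, fmap in result.maps.items():
        video_io.write_map_tiff(fmap.values, outdir / f"map_{key}.tif")
        video_io.write_map_preview(fmap.values, outdir / f"map_{key}.png")
        video_io.write_mask(result.binary[key].mask, outdir / f"mask_{key}.png")
        artifacts[key] = {"map": f"map_{key}.tif", "mask": f"mask_{key}.png",
                          "threshold": result.binary[key].threshold_used,
                          "area": result.binary[key].area}
    result.comparisons.to_csv(outdir / "comparisons.csv", index=False)
    with open(outdir / "ebs_report.json", "w") as fh:
        json.dump(result.ebs_report, fh, indent=2)

    cfg_repr = repr(config).encode()
    report = {
        "package": "rgbrsfc",
        "config_hash": hashlib.sha256(cfg_repr).hexdigest(),
        "versions": _versions(),
        "frame_rate": config.frame_rate,
        "n_frames": video.n_frames,
        "image_shape": list(video.shape),
        "analyses": list(config.analyses),
        "alpha": config.alpha, "k": config.k,
        "rng_seed": config.rng_seed,
        "timings_s": {k: round(v, 3) for k, v in result.timings.items()},
        "artifacts": artifacts,
        "output_dir": str(outdir),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def compare_runs(report_a: str | Path, report_b: str | Path,
                 kinds: tuple[str, ...] | None = None) -> pd.DataFrame:
    """All pairwise DICE/overlap between the binary maps of two runs.

    Typical use: a task acquisition against a resting-state acquisition of
    the same cortex. Geometries must match.
    """
    rows = []
    masks_a = _load_masks(report_a, kinds)
    masks_b = _load_masks(report_b, kinds)
    for key_a, mask_a in masks_a.items():
        for key_b, mask_b in masks_b.items():
            if mask_a.shape != mask_b.shape:
                raise ConfigError(
                    f"geometry mismatch: {mask_a.shape} vs {mask_b.shape}")
            rows.append({"map_a": key_a, "map_b": key_b,
                         "dice": cmp.dice(mask_a, mask_b),
                         "overlap": cmp.overlap(mask_a, mask_b)})
    return pd.DataFrame(rows, columns=["map_a", "map_b", "dice", "overlap"])


def _load_masks(report_path: str | Path,
                kinds: tuple[str, ...] | None) -> dict[str, np.ndarray]:
    report_path = Path(report_path)
    with open(report_path) as fh:
        report = json.load(fh)
    outdir = report_path.parent
    masks = {}
    for key, art in report["artifacts"].items():
        if kinds is not None and not any(key.startswith(k) for k in kinds):
            continue
        masks[key] = video_io.read_mask(outdir / art["mask"])
    return masks


def _versions() -> dict[str, str]:
    import scipy
    import skimage
    import sklearn
    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
            "scikit-learn": sklearn.__version__,
            "pandas": pd.__version__}
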