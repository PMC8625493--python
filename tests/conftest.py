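"""Shared fixtures: phantom renders and pipeline runs reused across test modules.

The three full-size phantom runs are expensive (tens of seconds each), so they
are session-scoped; tests must not mutate what they return.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

import rgbrsfc as rf
from rgbrsfc.compare import dice, morph_cleanup, threshold_map

SEED = 0
NETWORK1_CENTER = (40, 40)


@pytest.fixture(scope="session")
def rest_case():
    """Default two-network resting-state phantom + seed/ICA analysis."""
    cfg = rf.default_config(rng_seed=SEED)
    video, truth = rf.render_phantom(cfg)
    res = rf.analyze_video(video, labels=truth.class_layout,
                           seed=rf.SeedSpec(center=NETWORK1_CENTER),
                           analyses=("seed", "ica"), rng_seed=SEED)
    return SimpleNamespace(cfg=cfg, truth=truth, res=res,
                           frame0=video.frames[0].copy())


@pytest.fixture(scope="session")
def task_case():
    """Task-only phantom (20 s rest / 20 s stimulation) + task analysis."""
    cfg = rf.default_config(rng_seed=SEED, with_task=True)
    video, truth = rf.render_phantom(cfg)
    res = rf.analyze_video(video, labels=truth.class_layout,
                           protocol=cfg.protocol, analyses=("task",),
                           rng_seed=SEED)
    return SimpleNamespace(cfg=cfg, truth=truth, res=res)


@pytest.fixture(scope="session")
def joint_case():
    """Phantom whose task region coincides with network 1; all analyses."""
    cfg = rf.default_config(rng_seed=SEED, task_on_network=0)
    video, truth = rf.render_phantom(cfg)
    res = rf.analyze_video(video, labels=truth.class_layout,
                           protocol=cfg.protocol,
                           seed=rf.SeedSpec(center=NETWORK1_CENTER),
                           analyses=("task", "seed", "ica"), rng_seed=SEED)
    return SimpleNamespace(cfg=cfg, truth=truth, res=res)


@pytest.fixture()
def tiny_quiet_config():
    """Small noise/motion/drift-free phantom config for exact-model tests."""
    from rgbrsfc.phantom import default_class_layout, disk_mask
    cfg = rf.PhantomConfig(image_height=32, image_width=32, duration=20.0,
                           noise_sd=0.0, motion_amplitude=0.0,
                           drift_slope=(0.0, 0.0, 0.0), rng_seed=3)
    cfg.network_masks = [disk_mask((32, 32), (10, 10), 6),
                         disk_mask((32, 32), (22, 22), 6)]
    cfg.class_layout = default_class_layout((32, 32))
    return cfg


def best_ica_dice(res, mask: np.ndarray, chromophore: str) -> float:
    """Best DICE of any ICA component's binary map against a truth mask,
    assessed up to component permutation and sign (the standard ICA
    ambiguities)."""
    scores = []
    for key, bmap in res.binary.items():
        if not key.startswith(f"ica_{chromophore}"):
            continue
        scores.append(dice(bmap, mask))
        flipped = morph_cleanup(threshold_map(-res.maps[key].values))
        scores.append(dice(flipped, mask))
    return max(scores)
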