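"""Desk-scale end-to-end study: synthetic slides through the full protocol.

This module bundles the package's standard small-scale study conditions:
~40 synthetic 192x192 scenes (one MNG plus ~15 mononucleated cells each),
128x128 panels with a handful of random translations per MNG expanded by the
8 dihedral transforms, a depth-3 / 8-filter U-Net trained for 3 epochs, and
a coarse (epoch, brightness, area) grid. These sizes let the whole
five-configuration cross-validation run in minutes on one CPU core while
exercising every pipeline stage at full fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crossval import FoldAssignment, FoldConfigResult, run_protocol
from .network import NetworkConfig
from .panels import AugmentationConfig
from .synthetic import SceneConfig, generate_scene

__all__ = ["StudyConfig", "generate_study_scenes", "run_synthetic_study"]


@dataclass
class StudyConfig:
    """Conditions of the desk-scale synthetic study."""

    n_scenes: int = 40
    scene_shape: tuple[int, int] = (192, 192)
    n_mng_per_scene: int = 1
    n_mononucleated: int = 15
    panel_size: int = 128
    panels_per_mng: int = 2
    epochs: int = 3
    depth: int = 3
    base_filters: int = 8
    batch_size: int = 4
    learning_rate: float = 2e-3
    n_folds: int = 5
    brightness_grid: tuple[int, ...] = (100, 160, 200, 240)
    area_grid: tuple[float, ...] = (20.0, 50.0, 150.0, 300.0)
    seed: int = 0


def generate_study_scenes(config: StudyConfig):
    """One synthetic slide per scene, each with known MNG ground truth."""
    scenes = []
    for i in range(config.n_scenes):
        scfg = SceneConfig(
            image_shape=config.scene_shape,
            n_mng=config.n_mng_per_scene,
            n_mononucleated=config.n_mononucleated,
            seed=config.seed * 100_003 + i,
            slide_id=f"slide_{i:03d}",
            slice_id="0",
        )
        scenes.append(generate_scene(scfg))
    return scenes


def run_synthetic_study(
    config: StudyConfig | None = None,
) -> tuple[FoldAssignment, list[FoldConfigResult]]:
    """Generate scenes and run the full batch-stratified protocol on them."""
    if config is None:
        config = StudyConfig()
    scenes = generate_study_scenes(config)
    aug = AugmentationConfig(
        panels_per_mng=config.panels_per_mng,
        panel_size=config.panel_size,
        seed=config.seed + 1,
    )
    net = NetworkConfig(
        input_size=config.panel_size,
        depth=config.depth,
        base_filters=config.base_filters,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        seed=config.seed + 2,
    )
    return run_protocol(
        scenes,
        aug,
        net,
        config.brightness_grid,
        config.area_grid,
        n_folds=config.n_folds,
    )
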