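"""Batch-stratified cross-validation and hyperparameter grid search.

Slides (not individual testis slices) are the unit of fold assignment, so a
fold never mixes slices of one slide into different splits. Slides are sorted
by MNG count, chunked into groups of ``n_folds``, and each group's slides are
spread across distinct folds so per-fold MNG totals are as even as possible.

Five fold configurations are run: each fold serves once as holdout, the next
fold (cyclically) as test, the rest as training. The training folds fit the
network; the test fold selects (epoch, brightness cutoff, area cutoff) by
grid search on pooled-object F1; the holdout fold, untouched by selection,
measures final accuracy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .evaluation import (
    ConfusionCounts,
    EvaluationResult,
    UndefinedMetricError,
    match_detections,
    precision_recall_f1,
)
from .network import EpochCheckpoint, NetworkConfig, build_network, predict_heatmap, train
from .panels import AugmentationConfig, dihedral_expand, sample_mng_panels
from .postprocess import DetectionRegion, DetectionSet, filter_regions, region_area
from .postprocess import apply_brightness_cutoff, connected_components
from .slides import MNGAnnotation, SlideImage, TruthMask

__all__ = [
    "FoldAssignment",
    "GridPoint",
    "GridSearchResult",
    "FoldConfigResult",
    "stratify_slides",
    "fold_configurations",
    "grid_search",
    "select_optimal",
    "evaluate_holdout",
    "run_protocol",
]

# exhaustive-search budget: number of per-group permutation combinations
_EXACT_LIMIT = 200_000


@dataclass
class FoldAssignment:
    n_folds: int
    assignment: dict[str, int]  # slide_id -> fold
    fold_totals: list[int]

    def slides_in_fold(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)


def _fold_variance(totals: Sequence[float]) -> float:
    return float(np.var(totals))


def stratify_slides(
    slide_mng_counts: Mapping[str, int], n_folds: int = 5
) -> FoldAssignment:
    """Assign slides to folds, one slide per count-sorted group per fold,
    minimizing the variance of per-fold MNG totals.

    Small instances are solved exactly (exhaustive search over per-group
    permutations, with the first group pinned since fold labels are
    symmetric); larger ones use a sequential greedy search, choosing for each
    group in order the permutation that minimizes the running variance.
    """
    if len(slide_mng_counts) < n_folds:
        raise ValueError(
            f"need at least {n_folds} slides, got {len(slide_mng_counts)}"
        )
    # sort by count descending; slide id breaks ties deterministically
    slides = sorted(slide_mng_counts, key=lambda s: (-slide_mng_counts[s], s))
    groups = [slides[i : i + n_folds] for i in range(0, len(slides), n_folds)]

    def perms(group: Sequence[str]):
        return itertools.permutations(range(n_folds), len(group))

    n_states = 1
    for g in groups[1:]:
        n_states *= math.perm(n_folds, len(g))

    assignment: dict[str, int] = {}
    totals = [0.0] * n_folds

    if n_states <= _EXACT_LIMIT:
        # pin the first group to the identity assignment (fold labels are
        # symmetric) and search all remaining per-group permutations
        base = list(range(len(groups[0])))
        best: tuple | None = None
        for combo in itertools.product(*(perms(g) for g in groups[1:])):
            t = [0.0] * n_folds
            for slide, f in zip(groups[0], base):
                t[f] += slide_mng_counts[slide]
            for g, perm in zip(groups[1:], combo):
                for slide, f in zip(g, perm):
                    t[f] += slide_mng_counts[slide]
            key = (_fold_variance(t), combo)
            if best is None or key < best[0]:
                best = (key, combo, t)
        _, combo, totals = best
        for slide, f in zip(groups[0], base):
            assignment[slide] = f
        for g, perm in zip(groups[1:], combo):
            for slide, f in zip(g, perm):
                assignment[slide] = f
    else:
        for gi, g in enumerate(groups):
            best = None
            for perm in perms(g):
                t = list(totals)
                for slide, f in zip(g, perm):
                    t[f] += slide_mng_counts[slide]
                key = (_fold_variance(t), perm)
                if best is None or key < best[0]:
                    best = (key, perm, t)
            for slide, f in zip(g, best[1]):
                assignment[slide] = f
            totals = best[2]

    return FoldAssignment(
        n_folds=n_folds,
        assignment=assignment,
        fold_totals=[int(t) for t in totals],
    )


def fold_configurations(
    n_folds: int = 5,
) -> list[tuple[list[int], int, int]]:
    """(train folds, test fold, holdout fold) for each choice of holdout;
    test = (holdout + 1) mod n_folds, train = the rest."""
    if n_folds < 3:
        raise ValueError("need at least 3 folds for train/test/holdout")
    configs = []
    for holdout in range(n_folds):
        test = (holdout + 1) % n_folds
        trainf = [f for f in range(n_folds) if f not in (holdout, test)]
        configs.append((trainf, test, holdout))
    return configs


@dataclass(frozen=True)
class GridPoint:
    epoch: int
    cutoff_brightness: int
    cutoff_area: float
    counts: ConfusionCounts
    f1: float


@dataclass
class GridSearchResult:
    optimal: GridPoint
    grid: list[GridPoint]
    holdout_counts: ConfusionCounts | None = None
    holdout_f1: float | None = None


# Scene = (image, annotations, truth mask)
Scene = tuple[SlideImage, list[MNGAnnotation], TruthMask]


def _pooled_f1(counts: ConfusionCounts) -> float:
    try:
        return precision_recall_f1(counts).f1
    except UndefinedMetricError:
        return 0.0


def _regions_from_binary(binary: np.ndarray, connectivity: int) -> list[DetectionRegion]:
    regions = []
    for pix in connected_components(binary, connectivity):
        boundary, area = region_area(pix)
        regions.append(
            DetectionRegion(
                pixel_set=pix,
                boundary_polygon=boundary,
                greens_area=area,
                centroid=(float(pix[:, 0].mean()), float(pix[:, 1].mean())),
            )
        )
    return regions


def _scene_ann_masks(scene: Scene) -> list[np.ndarray]:
    from .slides import rasterize_annotations

    image, annotations, _ = scene
    return [
        rasterize_annotations([a], image.shape).pixels.astype(bool)
        for a in annotations
    ]


def _evaluate_point(
    per_image_regions: Sequence[tuple[list[DetectionRegion], Scene, list]],
    cutoff_brightness: int,
    cutoff_area: float,
) -> ConfusionCounts:
    total = ConfusionCounts(0, 0, 0)
    for regions, (image, annotations, _mask), masks in per_image_regions:
        kept = filter_regions(regions, cutoff_area)
        dset = DetectionSet(
            regions=kept,
            cutoff_brightness=cutoff_brightness,
            cutoff_area=cutoff_area,
        )
        total = total + match_detections(
            dset, annotations, image.shape, ann_masks=masks
        )
    return total


def grid_search(
    checkpoints: Sequence[EpochCheckpoint],
    test_scenes: Sequence[Scene],
    brightness_grid: Sequence[int],
    area_grid: Sequence[float],
    panel_size: int | None = None,
    stride: int | None = None,
    connectivity: int = 8,
) -> GridSearchResult:
    """Exhaustive search over (epoch, brightness cutoff, area cutoff).

    For each grid point the full predict -> detect -> match chain runs over
    all test images and the confusion counts are pooled across images before
    computing F1. The maximizing point is selected with deterministic
    tie-breaking: lowest epoch, then highest brightness, then highest area.
    """
    if not test_scenes:
        raise ValueError("grid search needs a nonempty test set")
    if not checkpoints or not brightness_grid or not len(area_grid):
        raise ValueError("grids and checkpoints must be nonempty")

    grid: list[GridPoint] = []
    scene_masks = [_scene_ann_masks(s) for s in test_scenes]
    for ckpt in checkpoints:
        heatmaps = [
            predict_heatmap(ckpt, img, panel_size, stride)
            for img, _a, _m in test_scenes
        ]
        for b in brightness_grid:
            per_image = []
            for heat, scene, masks in zip(heatmaps, test_scenes, scene_masks):
                binary = apply_brightness_cutoff(heat, b)
                per_image.append(
                    (_regions_from_binary(binary, connectivity), scene, masks)
                )
            for a in area_grid:
                counts = _evaluate_point(per_image, b, a)
                grid.append(
                    GridPoint(
                        epoch=ckpt.epoch_index,
                        cutoff_brightness=int(b),
                        cutoff_area=float(a),
                        counts=counts,
                        f1=_pooled_f1(counts),
                    )
                )

    return GridSearchResult(optimal=select_optimal(grid), grid=grid)


def select_optimal(grid: Sequence[GridPoint]) -> GridPoint:
    """Maximize F1; break ties by lowest epoch (cheapest model), then highest
    brightness, then highest area (most conservative detector)."""
    if not grid:
        raise ValueError("empty grid")
    return max(
        grid,
        key=lambda g: (g.f1, -g.epoch, g.cutoff_brightness, g.cutoff_area),
    )


def evaluate_holdout(
    result: GridSearchResult,
    checkpoints: Sequence[EpochCheckpoint],
    holdout_scenes: Sequence[Scene],
    panel_size: int | None = None,
    stride: int | None = None,
    connectivity: int = 8,
) -> GridSearchResult:
    """Apply the selected (epoch, cutoffs) unchanged to the holdout images;
    pooled counts and F1 are stored on the result. The holdout set plays no
    part in selection."""
    opt = result.optimal
    ckpt = next(c for c in checkpoints if c.epoch_index == opt.epoch)
    total = ConfusionCounts(0, 0, 0)
    for image, annotations, _mask in holdout_scenes:
        heat = predict_heatmap(ckpt, image, panel_size, stride)
        binary = apply_brightness_cutoff(heat, opt.cutoff_brightness)
        regions = _regions_from_binary(binary, connectivity)
        kept = filter_regions(regions, opt.cutoff_area)
        dset = DetectionSet(
            regions=kept,
            cutoff_brightness=opt.cutoff_brightness,
            cutoff_area=opt.cutoff_area,
        )
        total = total + match_detections(dset, annotations, image.shape)
    result.holdout_counts = total
    result.holdout_f1 = _pooled_f1(total)
    return result


@dataclass
class FoldConfigResult:
    """One row of the protocol summary (mirrors the grid-search report:
    holdout fold, test fold, optimal parameters, test and holdout scores)."""

    holdout_fold: int
    test_fold: int
    optimal_epoch: int
    optimal_brightness: int
    optimal_area: float
    test_counts: ConfusionCounts
    test_f1: float
    holdout_counts: ConfusionCounts
    holdout_f1: float
    grid: list[GridPoint] | None = None  # full (epoch, b, a) -> F1 table


def run_protocol(
    scenes: Sequence[Scene],
    aug_config: AugmentationConfig,
    net_config: NetworkConfig,
    brightness_grid: Sequence[int],
    area_grid: Sequence[float],
    n_folds: int = 5,
    stride: int | None = None,
) -> tuple[FoldAssignment, list[FoldConfigResult]]:
    """Run the full stratified protocol over labeled scenes.

    Slides are stratified into folds by MNG count; for each of the
    ``n_folds`` fold configurations a network is trained from scratch on the
    training folds' augmented panels, the grid search selects parameters on
    the test fold, and the holdout fold is scored with them.
    """
    slide_counts: dict[str, int] = {}
    for img, anns, _m in scenes:
        slide_counts[img.slide_id] = slide_counts.get(img.slide_id, 0) + len(anns)
    folds = stratify_slides(slide_counts, n_folds)

    by_fold: dict[int, list[Scene]] = {f: [] for f in range(n_folds)}
    for scene in scenes:
        by_fold[folds.assignment[scene[0].slide_id]].append(scene)

    results = []
    for trainf, testf, holdf in fold_configurations(n_folds):
        panels = []
        for img, anns, mask in [s for f in trainf for s in by_fold[f]]:
            if not anns:
                continue
            cfg = AugmentationConfig(
                panels_per_mng=aug_config.panels_per_mng,
                panel_size=aug_config.panel_size,
                seed=aug_config.seed + 7919 * holdf,
                edge_policy=aug_config.edge_policy,
            )
            for panel in sample_mng_panels(img, mask, anns, cfg):
                panels.extend(dihedral_expand(panel))
        cfg_net = NetworkConfig(
            input_size=net_config.input_size,
            depth=net_config.depth,
            base_filters=net_config.base_filters,
            epochs=net_config.epochs,
            batch_size=net_config.batch_size,
            learning_rate=net_config.learning_rate,
            seed=net_config.seed + holdf,
        )
        model = build_network(cfg_net)
        checkpoints = train(model, panels, cfg_net)
        gs = grid_search(
            checkpoints, by_fold[testf], brightness_grid, area_grid, stride=stride
        )
        gs = evaluate_holdout(gs, checkpoints, by_fold[holdf], stride=stride)
        opt = gs.optimal
        results.append(
            FoldConfigResult(
                holdout_fold=holdf,
                test_fold=testf,
                optimal_epoch=opt.epoch,
                optimal_brightness=opt.cutoff_brightness,
                optimal_area=opt.cutoff_area,
                test_counts=opt.counts,
                test_f1=opt.f1,
                holdout_counts=gs.holdout_counts,
                holdout_f1=gs.holdout_f1,
                grid=gs.grid,
            )
        )
    return folds, results
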