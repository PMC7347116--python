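"""Training-panel sampling, dihedral augmentation, and inference tiling.

Training panels are sampled around each annotated MNG with the MNG center
placed uniformly at random within the panel, which both randomizes location
and enlarges the negative (background) area the network sees. Each sampled
panel is then expanded by the 8 symmetries of the square (identity, three
rotations, four reflections) applied identically to image and mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .heatmap import HeatMap
from .slides import MNGAnnotation, SlideImage, TruthMask

__all__ = [
    "Panel",
    "AugmentationConfig",
    "sample_mng_panels",
    "dihedral_expand",
    "dihedral_transform",
    "tile_for_inference",
    "stitch",
]


@dataclass
class Panel:
    """A square image patch with its aligned binary mask and provenance."""

    image_patch: np.ndarray
    mask_patch: np.ndarray
    slide_id: str = ""
    slice_id: str = ""
    x_offset: int = 0
    y_offset: int = 0
    transform_index: int = 0

    def __post_init__(self) -> None:
        if self.image_patch.shape != self.mask_patch.shape:
            raise ValueError("image and mask patches must share shape")
        if not 0 <= self.transform_index <= 7:
            raise ValueError("transform_index must be in [0, 7]")


@dataclass
class AugmentationConfig:
    """Panel-sampling parameters. ``panels_per_mng`` defaults to 500, the
    full-scale augmentation count; desk-scale runs reduce it."""

    panels_per_mng: int = 500
    panel_size: int = 512
    seed: int = 0
    edge_policy: str = "clip_shift"  # or "reflect_pad"

    def __post_init__(self) -> None:
        if self.panels_per_mng < 1:
            raise ValueError("panels_per_mng must be >= 1")
        if self.panel_size < 32 or self.panel_size % 2:
            raise ValueError("panel_size must be even and >= 32")
        if self.edge_policy not in ("clip_shift", "reflect_pad"):
            raise ValueError(f"unknown edge_policy {self.edge_policy!r}")


def sample_mng_panels(
    image: SlideImage,
    mask: TruthMask,
    annotations: Sequence[MNGAnnotation],
    config: AugmentationConfig,
) -> list[Panel]:
    """Sample ``panels_per_mng`` panels per MNG, each containing that MNG's
    center at a uniformly random within-panel position.

    With ``clip_shift`` the window is shifted back inside the image when the
    random placement would overhang an edge (the center stays contained);
    with ``reflect_pad`` the overhanging region is mirror-padded instead.
    """
    p = config.panel_size
    h, w = image.shape
    if mask.shape != (h, w):
        raise ValueError("mask must be aligned with the image")
    if config.edge_policy == "clip_shift" and (h < p or w < p):
        raise ValueError(f"image {w}x{h} smaller than panel size {p}")

    rng = np.random.default_rng(config.seed)
    img = image.pixels
    msk = mask.pixels
    panels: list[Panel] = []
    for ann in annotations:
        cx, cy = int(round(ann.center[0])), int(round(ann.center[1]))
        for _ in range(config.panels_per_mng):
            # uniform position of the center within the panel
            ux = int(rng.integers(0, p))
            uy = int(rng.integers(0, p))
            x0, y0 = cx - ux, cy - uy
            if config.edge_policy == "clip_shift":
                x0 = min(max(x0, 0), w - p)
                y0 = min(max(y0, 0), h - p)
                ip = img[y0 : y0 + p, x0 : x0 + p]
                mp = msk[y0 : y0 + p, x0 : x0 + p]
            else:
                ip = _reflect_crop(img, x0, y0, p)
                mp = _reflect_crop(msk, x0, y0, p)
            panels.append(
                Panel(
                    image_patch=ip.copy(),
                    mask_patch=mp.copy(),
                    slide_id=image.slide_id,
                    slice_id=image.slice_id,
                    x_offset=x0,
                    y_offset=y0,
                )
            )
    return panels


def _reflect_crop(arr: np.ndarray, x0: int, y0: int, p: int) -> np.ndarray:
    h, w = arr.shape
    pad = max(0, -x0, -y0, x0 + p - w, y0 + p - h)
    if pad:
        arr = np.pad(arr, pad, mode="reflect")
        x0, y0 = x0 + pad, y0 + pad
    return arr[y0 : y0 + p, x0 : x0 + p]


def dihedral_transform(patch: np.ndarray, index: int) -> np.ndarray:
    """Apply element ``index`` (0-7) of the square's symmetry group.

    0-3 are counterclockwise rotations by 0/90/180/270 degrees; 4-7 are a
    horizontal flip followed by the same rotations. Index 0 is the identity.
    """
    if not 0 <= index <= 7:
        raise ValueError("transform index must be in [0, 7]")
    out = np.fliplr(patch) if index >= 4 else patch
    return np.rot90(out, k=index % 4)


def dihedral_expand(panel: Panel) -> list[Panel]:
    """Expand one panel into the 8 flip/rotation variants (identity first),
    transforming image and mask identically."""
    s = panel.image_patch.shape
    if len(s) != 2 or s[0] != s[1]:
        raise ValueError("dihedral expansion requires a square panel")
    return [
        Panel(
            image_patch=np.ascontiguousarray(
                dihedral_transform(panel.image_patch, k)
            ),
            mask_patch=np.ascontiguousarray(
                dihedral_transform(panel.mask_patch, k)
            ),
            slide_id=panel.slide_id,
            slice_id=panel.slice_id,
            x_offset=panel.x_offset,
            y_offset=panel.y_offset,
            transform_index=k,
        )
        for k in range(8)
    ]


def tile_for_inference(
    image: SlideImage, panel_size: int, stride: int | None = None
) -> list[tuple[np.ndarray, int, int]]:
    """Cover the image with ``panel_size`` tiles at the given stride.

    When the stride does not divide the image evenly, the final tile in each
    direction is shifted inward so the right/bottom edges are still covered
    without padding. Default stride is ``panel_size // 2`` (half overlap).
    """
    if stride is None:
        stride = panel_size // 2
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = image.shape
    if h < panel_size or w < panel_size:
        raise ValueError(
            f"image {w}x{h} smaller than panel size {panel_size}"
        )

    def offsets(dim: int) -> list[int]:
        offs = list(range(0, dim - panel_size + 1, stride))
        if offs[-1] + panel_size < dim:
            offs.append(dim - panel_size)
        return offs

    img = image.pixels
    return [
        (img[y : y + panel_size, x : x + panel_size], x, y)
        for y in offsets(h)
        for x in offsets(w)
    ]


def stitch(
    heat_tiles: Sequence[tuple[np.ndarray, int, int]],
    shape: tuple[int, int],
    source_image_id: str = "",
    checkpoint_id: str = "",
) -> HeatMap:
    """Blend overlapping heat tiles into one heatmap by per-pixel arithmetic
    mean, rounded to integers in [0, 255]. Every pixel must be covered."""
    h, w = shape
    acc = np.zeros((h, w), dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.int64)
    for tile, x, y in heat_tiles:
        th, tw = tile.shape
        acc[y : y + th, x : x + tw] += tile
        cnt[y : y + th, x : x + tw] += 1
    if (cnt == 0).any():
        n = int((cnt == 0).sum())
        raise ValueError(f"{n} pixels not covered by any tile")
    pixels = np.clip(np.rint(acc / cnt), 0, 255).astype(np.uint8)
    return HeatMap(pixels, source_image_id=source_image_id, checkpoint_id=checkpoint_id)
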