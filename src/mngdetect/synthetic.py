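"""Synthetic hematoxylin-like testis sections with known MNG ground truth.

The generator emulates the features the detector relies on: a light
background (tissue/cytoplasm), dense dark nuclei, mononucleated germ cells
rendered as a single nucleus inside a cytoplasm rim, and rarer MNGs rendered
as 2+ nuclei packed inside one cell boundary. Each MNG is annotated with a
center point and a filled polygon (convex hull of its nuclei, dilated by the
cytoplasm margin), so every downstream stage can be tested without real
slides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint, Point

from .heatmap import HeatMap
from .slides import MNGAnnotation, SlideImage, TruthMask, rasterize_annotations

__all__ = ["SceneConfig", "GenerationError", "generate_scene", "oracle_heatmap"]


class GenerationError(RuntimeError):
    """Raised when objects cannot be placed without overlap."""


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene.

    Intensities follow hematoxylin contrast: nuclei dark (~60), cytoplasm
    mid-gray (~160), background light (~205). At the pipeline's working
    resolution 1 px = 1 micron, so radii are in both microns and pixels.
    Germ-cell nuclei are large (~5-7 um radius in cross-section); the
    somatic/mononucleated nuclei here are drawn slightly smaller so that an
    MNG's multi-nucleus cluster is the distinguishing feature, not raw size
    alone.
    """

    image_shape: tuple[int, int] = (128, 128)
    n_mononucleated: int = 25
    n_mng: int = 1
    nuclei_per_mng: tuple[int, int] = (2, 3)
    mng_nucleus_radius: tuple[float, float] = (5.0, 7.0)
    mono_nucleus_radius: tuple[float, float] = (2.5, 4.0)
    cell_margin: float = 3.0
    background_mean: float = 205.0
    background_sd: float = 4.0
    nucleus_mean: float = 60.0
    nucleus_sd: float = 6.0
    cytoplasm_mean: float = 160.0
    cytoplasm_sd: float = 5.0
    noise_sd: float = 3.0
    seed: int = 0
    max_placement_tries: int = 200
    slide_id: str = "synthetic"
    slice_id: str = "0"

    def __post_init__(self) -> None:
        if self.nuclei_per_mng[0] < 2:
            raise ValueError("MNGs need >= 2 nuclei")
        for lo, hi in (self.mng_nucleus_radius, self.mono_nucleus_radius):
            if lo <= 0 or hi < lo:
                raise ValueError("nucleus radius ranges must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_mng < 0 or self.n_mononucleated < 0:
            raise ValueError("object counts must be >= 0")


def _disk(canvas: np.ndarray, cx: float, cy: float, r: float, value: np.ndarray):
    """Paint `value` (same shape as canvas) where (x-cx)^2+(y-cy)^2 <= r^2."""
    h, w = canvas.shape
    x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
    y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    hit = (xs - cx) ** 2 + (ys - cy) ** 2 <= r**2
    canvas[y0:y1, x0:x1][hit] = value[y0:y1, x0:x1][hit]


def generate_scene(
    config: SceneConfig,
) -> tuple[SlideImage, list[MNGAnnotation], TruthMask]:
    """Render one scene; identical config (incl. seed) -> identical outputs.

    Returns the grayscale image, exactly ``n_mng`` annotations (mononucleated
    cells are rendered but never annotated), and the truth mask obtained by
    rasterizing the returned polygons.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape

    # Reserve a bounding radius per object and rejection-sample placements so
    # cells never overlap; MNGs are placed first (they are the rarer, larger
    # objects and the hardest to fit).
    placed: list[tuple[float, float, float]] = []  # (cx, cy, clearance radius)

    def place(clearance: float) -> tuple[float, float]:
        for _ in range(config.max_placement_tries):
            cx = rng.uniform(clearance, w - 1 - clearance)
            cy = rng.uniform(clearance, h - 1 - clearance)
            if all(
                (cx - px) ** 2 + (cy - py) ** 2 >= (clearance + pr) ** 2
                for px, py, pr in placed
            ):
                placed.append((cx, cy, clearance))
                return cx, cy
        raise GenerationError(
            f"could not place object of clearance {clearance:.1f} "
            f"in a {w}x{h} scene after {config.max_placement_tries} tries"
        )

    image = rng.normal(config.background_mean, config.background_sd, (h, w))

    annotations: list[MNGAnnotation] = []
    nucleus_layers: list[tuple[float, float, float]] = []

    for _ in range(config.n_mng):
        k = int(rng.integers(config.nuclei_per_mng[0], config.nuclei_per_mng[1] + 1))
        radii = rng.uniform(*config.mng_nucleus_radius, size=k)
        # nuclei packed around the cell center, touching but not concentric
        cluster_r = radii.max() * (1 + 0.8 * (k - 1))
        clearance = cluster_r + config.cell_margin + 2
        cx, cy = place(clearance)
        angles = rng.uniform(0, 2 * np.pi) + np.arange(k) * (2 * np.pi / k)
        offsets = radii * 0.9 if k > 1 else np.zeros(1)
        centers = [
            (cx + off * np.cos(a), cy + off * np.sin(a))
            for a, off in zip(angles, offsets)
        ]
        circles = [
            Point(px, py).buffer(r, quad_segs=8)
            for (px, py), r in zip(centers, radii)
        ]
        hull = MultiPoint(
            [pt for c in circles for pt in c.exterior.coords]
        ).convex_hull.buffer(config.cell_margin, quad_segs=8)
        polygon = [(float(x), float(y)) for x, y in hull.exterior.coords[:-1]]
        # cytoplasm body
        cyto = rng.normal(config.cytoplasm_mean, config.cytoplasm_sd, (h, w))
        _disk(image, cx, cy, cluster_r + config.cell_margin, cyto)
        for (px, py), r in zip(centers, radii):
            nucleus_layers.append((px, py, r))
        annotations.append(
            MNGAnnotation(
                center=(cx, cy),
                polygon=polygon,
                slide_id=config.slide_id,
                slice_id=config.slice_id,
            )
        )

    for _ in range(config.n_mononucleated):
        r = rng.uniform(*config.mono_nucleus_radius)
        clearance = r + config.cell_margin
        try:
            cx, cy = place(clearance)
        except GenerationError:
            if config.n_mng == 0:
                raise
            break  # crowded scene: fewer mono cells is acceptable
        cyto = rng.normal(config.cytoplasm_mean, config.cytoplasm_sd, (h, w))
        _disk(image, cx, cy, clearance, cyto)
        nucleus_layers.append((cx, cy, r))

    nuc = rng.normal(config.nucleus_mean, config.nucleus_sd, (h, w))
    for px, py, r in nucleus_layers:
        _disk(image, px, py, r, nuc)

    if config.noise_sd > 0:
        image = image + rng.normal(0, config.noise_sd, (h, w))
    pixels = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    slide = SlideImage(
        pixels=pixels,
        microns_per_pixel=1.0,
        slide_id=config.slide_id,
        slice_id=config.slice_id,
    )
    mask = rasterize_annotations(annotations, (h, w))
    return slide, annotations, mask


def oracle_heatmap(
    mask: TruthMask,
    blur_radius: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> HeatMap:
    """Turn a truth mask into an idealized 0-255 likelihood map.

    Stands in for a trained network's output so the post-processing stages can
    be tested in isolation. With ``blur_radius = noise_sd = 0`` the result is
    exactly ``255 * mask``.
    """
    if blur_radius < 0 or noise_sd < 0:
        raise ValueError("blur_radius and noise_sd must be >= 0")
    heat = mask.pixels.astype(np.float64) * 255.0
    if blur_radius > 0:
        heat = ndimage.gaussian_filter(heat, sigma=blur_radius)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heat = heat + rng.normal(0, noise_sd, heat.shape)
    pixels = np.clip(np.rint(heat), 0, 255).astype(np.uint8)
    return HeatMap(pixels, checkpoint_id="oracle")
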