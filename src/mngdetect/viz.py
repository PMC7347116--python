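"""Overlay rendering: detection outcomes drawn over the section image.

Correctly found MNGs are outlined in green, missed reference MNGs in red,
spurious detections in yellow — the standard at-a-glance QC image for a
scored slide.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image, ImageDraw

from .slides import SlideImage

__all__ = ["render_overlay"]

_COLORS = {"matched": (0, 200, 0), "missed": (220, 0, 0), "spurious": (230, 200, 0)}


def render_overlay(
    image: SlideImage,
    matched: Sequence[Sequence[tuple[float, float]]] = (),
    missed: Sequence[Sequence[tuple[float, float]]] = (),
    spurious: Sequence[Sequence[tuple[float, float]]] = (),
    path: str | Path | None = None,
) -> np.ndarray:
    """Draw polygon outlines over the grayscale image; returns the RGB array
    and optionally writes a PNG."""
    rgb = Image.fromarray(image.pixels, mode="L").convert("RGB")
    draw = ImageDraw.Draw(rgb)
    for polys, kind in ((matched, "matched"), (missed, "missed"), (spurious, "spurious")):
        for poly in polys:
            pts = [(float(x), float(y)) for x, y in poly]
            if len(pts) >= 2:
                draw.polygon(pts, outline=_COLORS[kind], width=2)
    arr = np.asarray(rgb)
    if path is not None:
        rgb.save(path, format="PNG")
    return arr
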