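"""Slide images, MNG annotations, and truth masks.

Coordinate convention (used throughout the package): 0-based, ``(x, y)`` =
(column, row), pixel centers at integer coordinates. Polygons are vertex lists
in that same frame. Images are single-channel 8-bit grayscale at a known
physical resolution (target 1 micron/pixel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from PIL import Image
from shapely.geometry import Polygon as ShapelyPolygon

__all__ = [
    "SlideImage",
    "MNGAnnotation",
    "TruthMask",
    "load_slide_image",
    "save_slide_image",
    "rasterize_annotations",
    "read_annotations",
    "write_annotations",
    "AnnotationError",
]

#: ITU-R BT.601 luma weights for RGB -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


class AnnotationError(ValueError):
    """Raised for malformed annotation records or files."""


@dataclass
class SlideImage:
    """A 2-D 8-bit grayscale section image with slide/slice identity.

    Parameters
    ----------
    pixels
        2-D uint8 array of intensities in [0, 255].
    microns_per_pixel
        Physical resolution; the pipeline targets 1.0 micron/pixel.
    slide_id, slice_id
        Identity of the physical slide and the testis slice cropped from it.
    """

    pixels: np.ndarray
    microns_per_pixel: float = 1.0
    slide_id: str = ""
    slice_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a 2-D grid with both dims >= 1")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class MNGAnnotation:
    """One human-identified MNG: a center point plus a filled polygon."""

    center: tuple[float, float]
    polygon: list[tuple[float, float]]
    slide_id: str = ""
    slice_id: str = ""

    def __post_init__(self) -> None:
        self.center = (float(self.center[0]), float(self.center[1]))
        self.polygon = [(float(x), float(y)) for x, y in self.polygon]
        if len(self.polygon) < 3:
            raise AnnotationError(
                f"polygon needs >= 3 vertices, got {len(self.polygon)}"
            )

    def shapely_polygon(self) -> ShapelyPolygon:
        return ShapelyPolygon(self.polygon)


@dataclass
class TruthMask:
    """Binary grid aligned with a SlideImage; 1 where an MNG polygon covers
    the pixel center."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.isin(self.pixels, (0, 1)).all():
            raise ValueError("mask values must be 0/1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse a color image to luma (BT.601), rounding to nearest int."""
    if arr.ndim == 2:
        return arr.astype(np.float64)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.shape[2] == 1:
        return arr[:, :, 0].astype(np.float64)
    return arr[:, :, :3].astype(np.float64) @ _LUMA


def load_slide_image(
    path: str | Path,
    source_microns_per_pixel: float = 1.0,
    target_microns_per_pixel: float = 1.0,
    slide_id: str = "",
    slice_id: str = "",
) -> SlideImage:
    """Load a raster image, convert to 8-bit grayscale, and resample to the
    target physical resolution.

    Resampling uses area averaging (box filter) before rounding back to
    integer intensities, so uniform regions keep their mean gray level.
    """
    if source_microns_per_pixel <= 0 or target_microns_per_pixel <= 0:
        raise ValueError("micron-per-pixel scales must be positive")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (OSError, SyntaxError) as exc:
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc

    gray = np.clip(np.rint(_to_grayscale(arr)), 0, 255).astype(np.uint8)

    scale = source_microns_per_pixel / target_microns_per_pixel
    if not np.isclose(scale, 1.0):
        h, w = gray.shape
        new_w = max(1, int(round(w * scale)))
        new_h = max(1, int(round(h * scale)))
        resized = Image.fromarray(gray).resize((new_w, new_h), Image.BOX)
        gray = np.asarray(resized, dtype=np.uint8)

    return SlideImage(
        pixels=gray,
        microns_per_pixel=target_microns_per_pixel,
        slide_id=slide_id,
        slice_id=slice_id,
    )


def save_slide_image(image: SlideImage, path: str | Path) -> None:
    """Write an 8-bit single-channel PNG."""
    Image.fromarray(image.pixels, mode="L").save(path, format="PNG")


def rasterize_annotations(
    annotations: Sequence[MNGAnnotation], shape: tuple[int, int]
) -> TruthMask:
    """Rasterize filled annotation polygons into a binary truth mask.

    A mask pixel is 1 iff its center (integer ``(x, y)``) lies inside or on
    the boundary of at least one polygon (even-odd rule, boundary counts as
    inside). Overlapping polygons union.
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=np.uint8)
    for ann in annotations:
        poly = ann.shapely_polygon()
        minx, miny, maxx, maxy = poly.bounds
        x0 = max(0, int(np.floor(minx)))
        y0 = max(0, int(np.floor(miny)))
        x1 = min(w - 1, int(np.ceil(maxx)))
        y1 = min(h - 1, int(np.ceil(maxy)))
        if x1 < x0 or y1 < y0:
            continue
        xs, ys = np.meshgrid(
            np.arange(x0, x1 + 1), np.arange(y0, y1 + 1)
        )
        # intersects == covers-or-touches: boundary-inclusive containment
        inside = shapely.intersects_xy(poly, xs.ravel(), ys.ravel())
        mask[ys.ravel()[inside], xs.ravel()[inside]] = 1
    return TruthMask(mask)


def _annotation_to_record(ann: MNGAnnotation) -> dict:
    return {
        "slide_id": ann.slide_id,
        "slice_id": ann.slice_id,
        "center": [ann.center[0], ann.center[1]],
        "polygon": [[x, y] for x, y in ann.polygon],
    }


def write_annotations(
    annotations: Sequence[MNGAnnotation], path: str | Path
) -> None:
    """Write annotations as a JSON list of records."""
    records = [_annotation_to_record(a) for a in annotations]
    Path(path).write_text(json.dumps(records, indent=1))


def read_annotations(path: str | Path) -> list[MNGAnnotation]:
    """Read annotations from JSON; write -> read round-trips exactly."""
    text = Path(path).read_text()
    try:
        records = json.loads(text)
    except json.JSONDecodeError as exc:
        raise AnnotationError(
            f"malformed annotation file {path!r} at line {exc.lineno}: {exc.msg}"
        ) from exc
    if not isinstance(records, list):
        raise AnnotationError(f"{path!r}: top-level JSON value must be a list")
    out = []
    for i, rec in enumerate(records):
        try:
            out.append(
                MNGAnnotation(
                    center=tuple(rec["center"]),
                    polygon=[tuple(v) for v in rec["polygon"]],
                    slide_id=rec.get("slide_id", ""),
                    slice_id=rec.get("slice_id", ""),
                )
            )
        except (KeyError, TypeError, AnnotationError) as exc:
            raise AnnotationError(
                f"{path!r}: bad annotation record {i}: {exc}"
            ) from exc
    return out
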