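"""Heatmap -> discrete MNG detections.

A heatmap is converted to detections in four stages: (1) a brightness cutoff
removes pixels below threshold, (2) the survivors are grouped into connected
components, (3) each component's outer boundary is traced through pixel
centers (Moore-neighbor tracing) and its Green's-theorem (shoelace) area is
computed, and (4) components below the area cutoff are dropped. Green's-
theorem areas are slightly smaller than literal pixel counts — a solid
w x h rectangle has area (w-1)(h-1) — and degenerate one-pixel-wide regions
have area 0, which makes the area cutoff an effective speck filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .heatmap import HeatMap, as_heat_array

__all__ = [
    "DetectionRegion",
    "DetectionSet",
    "apply_brightness_cutoff",
    "connected_components",
    "trace_boundary",
    "shoelace_area",
    "region_area",
    "filter_regions",
    "detect",
    "write_detections",
    "read_detections",
]


@dataclass
class DetectionRegion:
    """One connected surviving region of the thresholded heatmap."""

    pixel_set: np.ndarray  # (n, 2) int array of (x, y) member pixels
    boundary_polygon: list[tuple[int, int]]
    greens_area: float
    centroid: tuple[float, float]


@dataclass
class DetectionSet:
    """All regions surviving the brightness and area cutoffs."""

    regions: list[DetectionRegion]
    cutoff_brightness: int
    cutoff_area: float
    source_heatmap_id: str = ""

    def __len__(self) -> int:
        return len(self.regions)


def apply_brightness_cutoff(
    heatmap: HeatMap | np.ndarray, cutoff: int
) -> np.ndarray:
    """Binary map: 1 where heatmap value >= cutoff (pixels below the cutoff
    are removed)."""
    if not 0 <= cutoff <= 255:
        raise ValueError(f"brightness cutoff must be in [0, 255], got {cutoff}")
    return (as_heat_array(heatmap) >= cutoff).astype(np.uint8)


_STRUCT = {
    8: np.ones((3, 3), dtype=int),
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
}


def connected_components(
    binary: np.ndarray, connectivity: int = 8
) -> list[np.ndarray]:
    """Partition foreground pixels into maximal connected sets.

    Returns one (n, 2) array of (x, y) coordinates per component, in
    row-major discovery order.
    """
    if connectivity not in _STRUCT:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(np.asarray(binary) != 0, structure=_STRUCT[connectivity])
    out = []
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        ys, xs = np.nonzero(labels[sl] == lab)
        out.append(
            np.column_stack([xs + sl[1].start, ys + sl[0].start]).astype(np.int64)
        )
    return out


# clockwise Moore neighborhood in image coordinates (x right, y down),
# starting from west
_MOORE = [(-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1)]


def trace_boundary(pixel_set: np.ndarray) -> list[tuple[int, int]]:
    """Trace the outer boundary of a connected pixel set through pixel
    centers, clockwise, with Jacob's stopping criterion.

    Starts at the uppermost-leftmost member pixel. Single pixels yield a
    one-vertex "polygon"; 1-pixel-wide regions trace out and back.
    """
    if len(pixel_set) == 0:
        raise ValueError("cannot trace an empty pixel set")
    pix = {(int(x), int(y)) for x, y in pixel_set}
    start = min(pix, key=lambda p: (p[1], p[0]))  # top row, then leftmost

    if len(pix) == 1:
        return [start]

    boundary = [start]
    cur = start
    back = (start[0] - 1, start[1])  # west neighbor: background by start choice
    first_move = None
    max_steps = 8 * len(pix) + 8
    for _ in range(max_steps):
        sd = _MOORE.index((back[0] - cur[0], back[1] - cur[1]))
        found = None
        for k in range(8):
            d = (sd + k) % 8
            nb = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if nb in pix:
                found = (nb, d)
                break
        if found is None:  # unreachable for a connected set of size > 1
            break
        nxt, d = found
        if first_move is None:
            first_move = (nxt, d)
        elif (nxt, d) == first_move:
            break  # Jacob's criterion: same pixel re-entered the same way
        boundary.append(nxt)
        # backtrack = neighbor examined just before the found one
        pd = (d - 1) % 8
        back = (cur[0] + _MOORE[pd][0], cur[1] + _MOORE[pd][1])
        cur = nxt
    # drop a trailing revisit of the start vertex
    while len(boundary) > 1 and boundary[-1] == start:
        boundary.pop()
    return boundary


def shoelace_area(polygon: Sequence[tuple[float, float]]) -> float:
    """Absolute polygon area by the shoelace (Green's theorem) formula."""
    if len(polygon) < 3:
        return 0.0
    pts = np.asarray(polygon, dtype=np.float64)
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)) / 2.0)


def region_area(
    pixel_set: np.ndarray,
) -> tuple[list[tuple[int, int]], float]:
    """Outer boundary polygon (through pixel centers) and its Green's-theorem
    area. Interior holes are ignored; 1-pixel-wide regions have area 0."""
    boundary = trace_boundary(pixel_set)
    return boundary, shoelace_area(boundary)


def filter_regions(
    regions: Sequence[DetectionRegion], cutoff_area: float
) -> list[DetectionRegion]:
    """Keep exactly the regions with greens_area >= cutoff_area."""
    if cutoff_area < 0:
        raise ValueError("area cutoff must be >= 0")
    return [r for r in regions if r.greens_area >= cutoff_area]


def detect(
    heatmap: HeatMap | np.ndarray,
    cutoff_brightness: int,
    cutoff_area: float,
    connectivity: int = 8,
) -> DetectionSet:
    """Full post-processing chain: threshold, label, measure, filter."""
    binary = apply_brightness_cutoff(heatmap, cutoff_brightness)
    components = connected_components(binary, connectivity)
    regions = []
    for pix in components:
        boundary, area = region_area(pix)
        regions.append(
            DetectionRegion(
                pixel_set=pix,
                boundary_polygon=boundary,
                greens_area=area,
                centroid=(float(pix[:, 0].mean()), float(pix[:, 1].mean())),
            )
        )
    kept = filter_regions(regions, cutoff_area)
    source = heatmap.source_image_id if isinstance(heatmap, HeatMap) else ""
    return DetectionSet(
        regions=kept,
        cutoff_brightness=cutoff_brightness,
        cutoff_area=cutoff_area,
        source_heatmap_id=source,
    )


def write_detections(detections: DetectionSet, path: str | Path) -> None:
    payload = {
        "cutoff_brightness": detections.cutoff_brightness,
        "cutoff_area": detections.cutoff_area,
        "source_heatmap_id": detections.source_heatmap_id,
        "regions": [
            {
                "centroid": list(r.centroid),
                "area": r.greens_area,
                "polygon": [list(v) for v in r.boundary_polygon],
                "pixels": [[int(x), int(y)] for x, y in r.pixel_set],
            }
            for r in detections.regions
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_detections(path: str | Path) -> DetectionSet:
    payload = json.loads(Path(path).read_text())
    regions = [
        DetectionRegion(
            pixel_set=np.asarray(r["pixels"], dtype=np.int64).reshape(-1, 2),
            boundary_polygon=[tuple(v) for v in r["polygon"]],
            greens_area=float(r["area"]),
            centroid=tuple(r["centroid"]),
        )
        for r in payload["regions"]
    ]
    return DetectionSet(
        regions=regions,
        cutoff_brightness=int(payload["cutoff_brightness"]),
        cutoff_area=float(payload["cutoff_area"]),
        source_heatmap_id=payload.get("source_heatmap_id", ""),
    )
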