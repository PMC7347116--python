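"""Per-pixel MNG-likelihood maps on an integer 0-255 scale."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HeatMap", "as_heat_array"]


@dataclass
class HeatMap:
    """A likelihood map: pixel brightness 0-255 encodes relative MNG
    likelihood. Provenance records which model/image produced it."""

    pixels: np.ndarray
    source_image_id: str = ""
    checkpoint_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("heatmap must be 2-D")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("heatmap values must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def as_heat_array(heatmap: "HeatMap | np.ndarray") -> np.ndarray:
    """Accept a HeatMap or a bare uint8 array; return the pixel array."""
    if isinstance(heatmap, HeatMap):
        return heatmap.pixels
    return HeatMap(np.asarray(heatmap)).pixels
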