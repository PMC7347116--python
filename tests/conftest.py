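import numpy as np
import pytest

from mngdetect import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A 160x160 scene with 2 MNGs and a dozen mononucleated cells."""
    cfg = SceneConfig(
        image_shape=(160, 160), n_mng=2, n_mononucleated=12, seed=42
    )
    return generate_scene(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def point_in_polygon_oracle(px: float, py: float, polygon) -> bool:
    """Independent even-odd ray-casting test; boundary points count inside.

    Used as the brute-force oracle against the shapely-backed rasterizer.
    """
    n = len(polygon)
    # boundary check: point on any segment
    for i in range(n):
        x1, y1 = polygon[i]
        x2, y2 = polygon[(i + 1) % n]
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if abs(cross) < 1e-9:
            if min(x1, x2) - 1e-9 <= px <= max(x1, x2) + 1e-9 and (
                min(y1, y2) - 1e-9 <= py <= max(y1, y2) + 1e-9
            ):
                return True
    inside = False
    for i in range(n):
        x1, y1 = polygon[i]
        x2, y2 = polygon[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside
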