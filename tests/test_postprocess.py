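import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon as ShapelyPolygon

from mngdetect import (
    DetectionSet,
    apply_brightness_cutoff,
    connected_components,
    detect,
    filter_regions,
    region_area,
)
from mngdetect.heatmap import HeatMap
from mngdetect.postprocess import (
    read_detections,
    shoelace_area,
    trace_boundary,
    write_detections,
)


def random_blob(seed: int, size: int = 24) -> np.ndarray:
    """A random connected blob: threshold of smoothed noise, largest
    component kept."""
    from scipy import ndimage

    r = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(r.random((size, size)), 2.5)
    binary = field > np.quantile(field, 0.7)
    labels, n = ndimage.label(binary, structure=np.ones((3, 3)))
    assert n >= 1
    sizes = ndimage.sum_labels(binary, labels, range(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    ys, xs = np.nonzero(labels == keep)
    return np.column_stack([xs, ys])


class TestBrightnessCutoff:
    def test_example_values(self):
        heat = np.array([[239, 240, 241], [255, 0, 100]], dtype=np.uint8)
        out = apply_brightness_cutoff(heat, 240)
        assert out.sum() == 3
        np.testing.assert_array_equal(out, [[0, 1, 1], [1, 0, 0]])

    def test_cutoff_zero_keeps_all(self, rng):
        heat = rng.integers(0, 256, (10, 10)).astype(np.uint8)
        assert apply_brightness_cutoff(heat, 0).all()

    def test_cutoff_255_keeps_only_saturated(self, rng):
        heat = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        out = apply_brightness_cutoff(heat, 255)
        np.testing.assert_array_equal(out, heat == 255)

    @pytest.mark.parametrize("bad", [-1, 256])
    def test_out_of_range_cutoff_rejected(self, bad):
        with pytest.raises(ValueError):
            apply_brightness_cutoff(np.zeros((2, 2), np.uint8), bad)


class TestConnectedComponents:
    def test_diagonal_pixels_8_vs_4(self):
        binary = np.zeros((4, 4), np.uint8)
        binary[1, 1] = binary[2, 2] = 1
        assert len(connected_components(binary, 8)) == 1
        assert len(connected_components(binary, 4)) == 2

    def test_all_zero_gives_empty_list(self):
        assert connected_components(np.zeros((5, 5), np.uint8)) == []

    def test_partition_covers_all_foreground(self, rng):
        binary = (rng.random((30, 30)) > 0.6).astype(np.uint8)
        comps = connected_components(binary, 8)
        total = sum(len(c) for c in comps)
        assert total == binary.sum()


class TestRegionArea:
    @pytest.mark.parametrize("w,h", [(2, 2), (3, 3), (5, 2), (7, 4), (20, 20)])
    def test_solid_rectangle_closed_form(self, w, h):
        binary = np.zeros((h + 4, w + 4), np.uint8)
        binary[2 : 2 + h, 2 : 2 + w] = 1
        pix = connected_components(binary)[0]
        boundary, area = region_area(pix)
        assert area == (w - 1) * (h - 1)

    def test_3x3_boundary_is_outer_ring(self):
        binary = np.zeros((7, 7), np.uint8)
        binary[2:5, 2:5] = 1
        boundary, area = region_area(connected_components(binary)[0])
        assert len(boundary) == 8  # the 8 outer pixel centers
        assert (2, 2) in boundary and (3, 3) not in boundary
        assert area == 4.0

    def test_single_pixel_and_line_are_degenerate(self):
        assert region_area(np.array([[5, 5]]))[1] == 0.0
        line = np.array([[x, 3] for x in range(1, 6)])
        assert region_area(line)[1] == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            region_area(np.empty((0, 2), dtype=np.int64))

    @pytest.mark.parametrize("seed", range(20))
    def test_random_blob_matches_polygon_oracle(self, seed):
        """Green's-theorem area equals an independent polygon-area
        computation on the traced boundary, and never exceeds pixel count."""
        pix = random_blob(seed)
        boundary, area = region_area(pix)
        if len(boundary) >= 3:
            oracle = ShapelyPolygon(boundary).buffer(0).area
            assert area == pytest.approx(oracle, abs=1e-9)
        assert area <= len(pix)


class TestFilterRegions:
    def test_area_threshold_inclusive(self):
        sets = []
        # areas 0, 4, 361 from solid squares 1x1, 3x3, 20x20
        for side in (1, 3, 20):
            binary = np.zeros((24, 24), np.uint8)
            binary[1 : 1 + side, 1 : 1 + side] = 1
            pix = connected_components(binary)[0]
            b, a = region_area(pix)
            from mngdetect.postprocess import DetectionRegion

            sets.append(DetectionRegion(pix, b, a, (0.0, 0.0)))
        assert len(filter_regions(sets, 150)) == 1
        assert len(filter_regions(sets, 0)) == 3
        assert len(filter_regions(sets, 1000)) == 0
        assert len(filter_regions(sets, 4.0)) == 2  # >= is inclusive

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            filter_regions([], -1)


class TestDetect:
    def test_oracle_square_closed_form(self):
        heat = np.zeros((64, 64), np.uint8)
        heat[10:30, 10:30] = 255
        ds = detect(heat, 128, 150)
        assert len(ds) == 1
        assert ds.regions[0].greens_area == 361.0  # (20-1)^2
        assert ds.regions[0].centroid == (19.5, 19.5)

    def test_all_zero_heatmap_empty(self):
        assert len(detect(np.zeros((32, 32), np.uint8), 128, 10)) == 0

    def test_two_blobs_separate_at_high_cutoff(self):
        """Two bright blobs joined by a dimmer bridge split at cutoff 240
        but merge at a lower cutoff."""
        heat = np.zeros((40, 40), np.uint8)
        heat[10:20, 5:15] = 250
        heat[10:20, 18:28] = 250
        heat[14:16, 15:18] = 200  # bridge below 240, above 150
        assert len(detect(heat, 240, 10)) == 2
        assert len(detect(heat, 150, 10)) == 1

    def test_deterministic(self, rng):
        heat = rng.integers(0, 256, (50, 50)).astype(np.uint8)
        d1 = detect(heat, 100, 5)
        d2 = detect(heat, 100, 5)
        assert len(d1) == len(d2)
        for r1, r2 in zip(d1.regions, d2.regions):
            np.testing.assert_array_equal(r1.pixel_set, r2.pixel_set)
            assert r1.greens_area == r2.greens_area

    @given(
        cut1=st.integers(0, 255),
        cut2=st.integers(0, 255),
        seed=st.integers(0, 50),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_brightness_cutoff(self, cut1, cut2, seed):
        heat = np.random.default_rng(seed).integers(0, 256, (24, 24)).astype(np.uint8)
        lo, hi = sorted((cut1, cut2))
        assert (
            apply_brightness_cutoff(heat, hi).sum()
            <= apply_brightness_cutoff(heat, lo).sum()
        )

    @given(
        a1=st.floats(0, 50),
        a2=st.floats(0, 50),
        seed=st.integers(0, 20),
    )
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_monotone_in_area_cutoff(self, a1, a2, seed):
        heat = np.random.default_rng(seed).integers(0, 256, (24, 24)).astype(np.uint8)
        lo, hi = sorted((a1, a2))
        assert len(detect(heat, 128, hi)) <= len(detect(heat, 128, lo))


class TestDetectionIO:
    def test_json_roundtrip(self, tmp_path, rng):
        heat = np.zeros((32, 32), np.uint8)
        heat[4:12, 4:12] = 255
        heat[20:30, 18:31] = 250
        ds = detect(HeatMap(heat, source_image_id="s/x"), 200, 5)
        p = tmp_path / "det.json"
        write_detections(ds, p)
        back = read_detections(p)
        assert back.cutoff_brightness == 200
        assert back.cutoff_area == 5
        assert len(back) == len(ds)
        for r1, r2 in zip(ds.regions, back.regions):
            assert r1.greens_area == r2.greens_area
            np.testing.assert_array_equal(r1.pixel_set, r2.pixel_set)
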