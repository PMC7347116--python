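import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mngdetect import (
    ConfusionCounts,
    MNGAnnotation,
    aggregate,
    detect,
    fp_fn_ratio,
    match_detections,
    oracle_heatmap,
    precision_recall_f1,
    rasterize_annotations,
)
from mngdetect.evaluation import UndefinedMetricError
from mngdetect.postprocess import DetectionRegion, DetectionSet


def _region_from_square(x0, y0, side):
    pix = np.array(
        [[x, y] for y in range(y0, y0 + side) for x in range(x0, x0 + side)]
    )
    return DetectionRegion(
        pixel_set=pix,
        boundary_polygon=[],
        greens_area=float((side - 1) ** 2),
        centroid=(float(pix[:, 0].mean()), float(pix[:, 1].mean())),
    )


def _square_ann(x0, y0, side):
    return MNGAnnotation(
        center=(x0 + side / 2, y0 + side / 2),
        polygon=[(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)],
    )


def _dset(regions):
    return DetectionSet(regions=regions, cutoff_brightness=128, cutoff_area=0.0)


def brute_force_max_matching(overlaps) -> int:
    """Maximum bipartite matching size by exhaustive enumeration
    (oracle for <= 6 objects)."""
    dets = sorted({d for d, a in overlaps})
    best = 0
    for k in range(len(dets), -1, -1):
        for det_subset in itertools.combinations(dets, k):
            for perm in itertools.permutations(
                sorted({a for d, a in overlaps}), k
            ):
                if all((d, a) in overlaps for d, a in zip(det_subset, perm)):
                    return k
    return best


class TestMatchDetections:
    def test_no_detections_all_fn(self):
        anns = [_square_ann(5, 5, 6), _square_ann(20, 20, 6), _square_ann(30, 5, 6)]
        c = match_detections(_dset([]), anns, (40, 40))
        assert (c.tp, c.fp, c.fn) == (0, 0, 3)

    def test_exact_detections_all_tp(self, small_scene):
        img, anns, mask = small_scene
        ds = detect(oracle_heatmap(mask, 0, 0), 128, 0.0)
        c = match_detections(ds, anns, img.shape)
        assert (c.tp, c.fp, c.fn) == (len(anns), 0, 0)

    def test_partial_overlap_example(self):
        """2 annotations, 3 detections, exactly 1 overlapping pair."""
        anns = [_square_ann(2, 2, 6), _square_ann(30, 30, 6)]
        dets = _dset(
            [
                _region_from_square(4, 4, 4),   # overlaps annotation 0
                _region_from_square(18, 2, 4),  # overlaps nothing
                _region_from_square(2, 18, 4),  # overlaps nothing
            ]
        )
        c = match_detections(dets, anns, (40, 40))
        assert (c.tp, c.fp, c.fn) == (1, 2, 1)

    def test_one_detection_covering_two_annotations_is_one_tp(self):
        anns = [_square_ann(2, 2, 5), _square_ann(9, 2, 5)]
        dets = _dset([_region_from_square(2, 2, 12)])
        c = match_detections(dets, anns, (20, 20))
        assert (c.tp, c.fp, c.fn) == (1, 0, 1)

    def test_count_identities(self):
        """tp + fn = #annotations and tp + fp = #detections, always."""
        r = np.random.default_rng(0)
        for _ in range(10):
            anns = [
                _square_ann(int(r.integers(0, 30)), int(r.integers(0, 30)), 5)
                for _ in range(int(r.integers(0, 4)))
            ]
            dets = _dset(
                [
                    _region_from_square(
                        int(r.integers(0, 30)), int(r.integers(0, 30)), 4
                    )
                    for _ in range(int(r.integers(0, 4)))
                ]
            )
            c = match_detections(dets, anns, (40, 40))
            assert c.tp + c.fn == len(anns)
            assert c.tp + c.fp == len(dets.regions)

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_equals_optimal_on_small_instances(self, seed):
        """Greedy one-to-one matching achieves the brute-force maximum
        matching size on random <= 6-object instances."""
        r = np.random.default_rng(seed)
        n_ann, n_det = int(r.integers(1, 4)), int(r.integers(1, 4))
        anns = [
            _square_ann(int(r.integers(0, 40)), int(r.integers(0, 40)), 8)
            for _ in range(n_ann)
        ]
        dets = _dset(
            [
                _region_from_square(int(r.integers(0, 40)), int(r.integers(0, 40)), 8)
                for _ in range(n_det)
            ]
        )
        shape = (56, 56)
        c = match_detections(dets, anns, shape)
        # overlap graph for the oracle
        overlaps = set()
        for di, reg in enumerate(dets.regions):
            for ai, ann in enumerate(anns):
                amask = rasterize_annotations([ann], shape).pixels.astype(bool)
                xs, ys = reg.pixel_set[:, 0], reg.pixel_set[:, 1]
                if amask[ys, xs].sum() >= 1:
                    overlaps.add((di, ai))
        assert c.tp == brute_force_max_matching(overlaps)


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [
            (34, 10, 11, 0.764),   # human test scorer 1
            (95, 10, 41, 0.788),   # human test scorer 2
            (91, 27, 17, 0.805),   # best fold configuration, holdout set
        ],
    )
    def test_reference_scorer_f1(self, tp, fp, fn, expected):
        result = precision_recall_f1(ConfusionCounts(tp, fp, fn))
        assert round(result.f1, 3) == expected

    def test_perfect_detection(self):
        r = precision_recall_f1(ConfusionCounts(17, 0, 0))
        assert r.precision == r.recall == r.f1 == 1.0

    def test_zero_tp_gives_zero_f1(self):
        assert precision_recall_f1(ConfusionCounts(0, 3, 2)).f1 == 0.0

    def test_all_zero_counts_is_explicit_error(self):
        with pytest.raises(UndefinedMetricError):
            precision_recall_f1(ConfusionCounts(0, 0, 0))

    def test_f1_is_harmonic_mean(self):
        r = precision_recall_f1(ConfusionCounts(10, 5, 3))
        assert r.f1 == pytest.approx(
            2 / (1 / r.precision + 1 / r.recall)
        )

    @given(
        tp=st.integers(1, 200),
        fp=st.integers(0, 200),
        fn=st.integers(0, 200),
        k=st.integers(1, 5),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, tp, fp, fn, k):
        """F1 is invariant to scaling all three counts by a positive int."""
        a = precision_recall_f1(ConfusionCounts(tp, fp, fn))
        b = precision_recall_f1(ConfusionCounts(k * tp, k * fp, k * fn))
        assert a.f1 == pytest.approx(b.f1)

    @given(tp=st.integers(1, 100), fp=st.integers(0, 100), fn=st.integers(0, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_f1_bounded_by_min_component(self, tp, fp, fn):
        r = precision_recall_f1(ConfusionCounts(tp, fp, fn))
        lo = min(r.precision, r.recall)
        assert lo - 1e-12 <= r.f1 <= 2 * lo + 1e-12


class TestFpFnRatio:
    def test_best_fold_ratio(self):
        assert fp_fn_ratio(ConfusionCounts(91, 27, 17)) == pytest.approx(
            1.588, abs=0.001
        )

    def test_zero_fp(self):
        assert fp_fn_ratio(ConfusionCounts(5, 0, 3)) == 0.0

    def test_zero_fn_is_error(self):
        with pytest.raises(UndefinedMetricError):
            fp_fn_ratio(ConfusionCounts(5, 2, 0))


class TestAggregate:
    def test_mean_and_sample_sd(self):
        m, sd = aggregate([1.0, 2.0, 3.0, 4.0])
        assert m == 2.5
        assert sd == pytest.approx(np.std([1, 2, 3, 4], ddof=1))

    def test_single_value(self):
        m, sd = aggregate([0.7])
        assert m == 0.7
        assert sd is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])
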