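"""Reference confusion counts from the original five-fold rat-testis MNG
benchmark this pipeline was developed against.

These raw object counts (true positives / "matches", false positives, false
negatives) are inputs: the derived statistics — precision, recall, F1, FP:FN
ratios, and cross-fold aggregates — are always recomputed from them with the
functions in :mod:`mngdetect.evaluation`, never stored.

``GRID_SEARCH_ROWS`` holds one row per fold configuration: the holdout fold,
test fold, the selected (epoch, brightness cutoff, area cutoff), and the
test-set counts. ``HOLDOUT_COUNTS`` holds the holdout-set counts per fold
configuration, keyed by holdout fold. ``HUMAN_SCORERS`` holds the two human
test scorers' counts against the reference scorer.
"""

from __future__ import annotations

from .evaluation import ConfusionCounts

__all__ = ["HUMAN_SCORERS", "GRID_SEARCH_ROWS", "HOLDOUT_COUNTS", "BEST_FOLD"]

HUMAN_SCORERS: dict[str, ConfusionCounts] = {
    "human_1": ConfusionCounts(tp=34, fp=10, fn=11),
    "human_2": ConfusionCounts(tp=95, fp=10, fn=41),
}

#: holdout fold -> (test fold, optimal epoch, optimal brightness,
#: optimal area, test-set counts)
GRID_SEARCH_ROWS: dict[int, dict] = {
    0: {"test_fold": 1, "epoch": 13, "brightness": 240, "area": 150,
        "test_counts": ConfusionCounts(78, 22, 29)},
    1: {"test_fold": 2, "epoch": 2, "brightness": 120, "area": 700,
        "test_counts": ConfusionCounts(78, 4, 25)},
    2: {"test_fold": 3, "epoch": 1, "brightness": 246, "area": 400,
        "test_counts": ConfusionCounts(94, 17, 14)},
    3: {"test_fold": 4, "epoch": 5, "brightness": 220, "area": 300,
        "test_counts": ConfusionCounts(73, 17, 30)},
    4: {"test_fold": 0, "epoch": 5, "brightness": 210, "area": 20,
        "test_counts": ConfusionCounts(126, 29, 49)},
}

#: holdout fold -> holdout-set counts
HOLDOUT_COUNTS: dict[int, ConfusionCounts] = {
    0: ConfusionCounts(119, 41, 56),
    1: ConfusionCounts(71, 21, 36),
    2: ConfusionCounts(72, 12, 31),
    3: ConfusionCounts(91, 27, 17),
    4: ConfusionCounts(61, 32, 42),
}

#: the fold configuration with the best holdout F1
BEST_FOLD = 3
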