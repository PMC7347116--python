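"""Recompute the benchmark's derived statistics from raw confusion counts.

The reference rat-testis benchmark reports raw object counts (matches,
false positives, false negatives) for two human test scorers and for the
five cross-validation fold configurations. Everything else — precision,
recall, F1, FP:FN ratios, and the cross-fold mean and standard deviation —
is derived, and this script derives it with the package's evaluation
functions.
"""

from mngdetect import aggregate, fp_fn_ratio, precision_recall_f1
from mngdetect.benchmarks import (
    BEST_FOLD,
    GRID_SEARCH_ROWS,
    HOLDOUT_COUNTS,
    HUMAN_SCORERS,
)

print("human test scorers (vs the reference scorer):")
for name, c in HUMAN_SCORERS.items():
    r = precision_recall_f1(c)
    print(f"  {name}: tp={c.tp} fp={c.fp} fn={c.fn} -> F1 {r.f1:.3f}")

print("test-set F1 per fold configuration (grid-search selection):")
for holdout, row in sorted(GRID_SEARCH_ROWS.items()):
    f1 = precision_recall_f1(row["test_counts"]).f1
    print(f"  holdout {holdout} (test fold {row['test_fold']}): F1 {f1:.3f}")

print("holdout-set F1 per fold configuration (final accuracy):")
f1s = []
for holdout, c in sorted(HOLDOUT_COUNTS.items()):
    f1 = precision_recall_f1(c).f1
    f1s.append(f1)
    tag = " <- best" if holdout == BEST_FOLD else ""
    print(f"  holdout {holdout}: F1 {f1:.3f}{tag}")
mean, sd = aggregate(f1s)
print(f"  mean {mean:.3f}, sample sd {sd:.3f}")

best = HOLDOUT_COUNTS[BEST_FOLD]
others = [fp_fn_ratio(c) for f, c in sorted(HOLDOUT_COUNTS.items())
          if f != BEST_FOLD]
all_five = [fp_fn_ratio(c) for _, c in sorted(HOLDOUT_COUNTS.items())]
print(f"FP:FN ratio, best configuration: {fp_fn_ratio(best):.2f}")
print(f"FP:FN ratio, mean of the other four: {aggregate(others)[0]:.2f}")
print(f"FP:FN ratio, mean of all five: {aggregate(all_five)[0]:.2f}")
# In all but the best configuration the model misses more MNGs than it
# invents (ratio < 1); the best configuration errs the other way.
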