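"""Inspect the packaged reference tables.

The package ships the per-trial sample-count grids of the motivating
study's dataset (25 trials x 10 road conditions; 25 level-walking trials
x 6 gait phases) and the reference column-normalized confusion matrices
of its two trained recognizers.  This script verifies their arithmetic:
column totals, the grand total, and column sums of 1.
"""

from imugait import load_confusion_fixture, load_count_fixture, metrics

t1 = load_count_fixture("table1")
print("road-condition dataset (25 trials x 10 states)")
print(t1.counts.head(3).to_string())
print(f"  column totals: {t1.column_totals.to_dict()}")
print(f"  grand total:   {t1.grand_total:,} samples\n")

t2 = load_count_fixture("table2")
print("gait-phase dataset (25 level-walking trials x 6 phases)")
print(f"  column totals: {t2.column_totals.to_dict()}\n")

for tid, name in (("table4", "motion-state SVM"), ("table6", "gait-phase LSTM")):
    m = load_confusion_fixture(tid)
    sums = m.sum(axis=0)
    print(f"{name} reference confusion matrix: "
          f"column sums in [{sums.min():.3f}, {sums.max():.3f}] (printed rounding)")

print("\nmetric identities on a perfect 6-class confusion matrix:")
import numpy as np

print(" ", metrics(np.eye(6) * 100))
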