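"""Recognize the 10 motion states with the binary-tree RBF-SVM.

Simulates all ten road conditions for five synthetic subjects, trains the
tree of binary SVMs (C = 2, gamma = "scale") on four subjects and scores
the held-out fifth — a subject-wise split, so the test subject's gait
timing and amplitudes were never seen in training.
"""

import numpy as np

from imugait import (
    MOTION_STATES,
    evaluate,
    fit_stats,
    generate_dataset,
    standardize,
    subject_split,
)
from imugait.svm import build_tree, fit_tree

dataset = generate_dataset(MOTION_STATES, n_subjects=5, cycles_per_state=6, seed=0)
X, y, subjects = dataset.sample_arrays()
train_mask, test_mask = subject_split(subjects, 4)

stats = fit_stats([X[train_mask]])  # fitted on training subjects only
Xs = standardize(X, stats)

tree = fit_tree(build_tree(), Xs[train_mask][::5], y[train_mask][::5])
print(f"tree: {len(tree.root.internal_nodes())} binary SVMs, depth {tree.root.depth}")

report = evaluate(y[test_mask], tree.predict(Xs[test_mask]), MOTION_STATES)
print(f"held-out subject: ACC {report.accuracy:.4f}  "
      f"macro-F1 {report.macro_f1:.4f}  MCC {report.mcc:.4f}")
print("\ncolumn-normalized confusion diagonal (per true state):")
for state, d in zip(MOTION_STATES, np.diag(report.normalized)):
    print(f"  {state:3s}: {d:.3f}")
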