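"""Shared fixtures: synthetic datasets and trained models.

The heavier artifacts (the 10-state SVM run and the LSTM phase run) are
session-scoped so the unit tests and the acceptance checks share one
training pass each.
"""

import numpy as np
import pytest

from imugait import (
    EVENT_ORDER,
    MOTION_STATES,
    evaluate,
    fit_stats,
    generate_dataset,
    label_phases,
    make_sequences,
    standardize,
    subject_split,
)
from imugait.lstm import TrainConfig, predict_phase, train
from imugait.svm import build_tree, fit_tree


@pytest.fixture(scope="session")
def state_dataset():
    """Full 10-state dataset: 5 subjects x 6 cycles per state."""
    return generate_dataset(MOTION_STATES, n_subjects=5, cycles_per_state=6, seed=0)


@pytest.fixture(scope="session")
def state_holdout_report(state_dataset):
    """Train the SVM tree on 4 subjects, evaluate on the held-out 5th."""
    X, y, g = state_dataset.sample_arrays()
    train_mask, test_mask = subject_split(g, 4)
    stats = fit_stats([X[train_mask]])
    Xs = standardize(X, stats)
    tree = fit_tree(build_tree(), Xs[train_mask][::5], y[train_mask][::5])
    report = evaluate(y[test_mask], tree.predict(Xs[test_mask]), MOTION_STATES)
    return report


@pytest.fixture(scope="session")
def phase_sequences():
    """Standardized length-5 sequences + targets + subjects for LW bouts."""
    ds = generate_dataset(["LW"], n_subjects=5, cycles_per_state=20, seed=5)
    train_streams = [s.data for i, s in enumerate(ds.streams) if ds.subject_ids[i] < 4]
    stats = fit_stats(train_streams)
    seqs, targs, groups = [], [], []
    for i, stream in enumerate(ds.streams):
        labels = label_phases(ds.event_truth[i], stream.n_samples)
        Xi = standardize(stream, stats)
        s_i, t_i = make_sequences(Xi, labels, n=5)
        seqs.append(s_i)
        targs.append(t_i)
        groups.append(np.full(len(s_i), ds.subject_ids[i]))
    return np.concatenate(seqs), np.concatenate(targs), np.concatenate(groups)


@pytest.fixture(scope="session")
def phase_holdout_report(phase_sequences):
    """Desk-scale LSTM (hidden 32, 30 epochs) on 4 train + 1 test subject."""
    S, T, G = phase_sequences
    tr, te = subject_split(G, 4)
    cfg = TrainConfig(epochs=30, batch_size=64, hidden_size=32, seed=5)
    params, head, losses = train(cfg, S[tr], T[tr])
    pred = predict_phase(params, head, S[te])
    report = evaluate(T[te], pred, EVENT_ORDER)
    return report, losses
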