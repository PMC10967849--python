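"""Classifier evaluation: ACC, macro-F1, multiclass MCC, column-normalized
confusion matrices, subject-wise splits and grouped k-fold cross-validation.

Conventions
-----------
* Confusion matrices index (predicted row, true column); normalization
  divides each column by its true-class support, so every supported
  column sums to 1 (zero-support columns stay all-zero and are flagged).
* F1 is macro-averaged (unweighted mean over classes); classes with no
  true and no predicted samples are excluded from the mean and flagged.
* MCC uses the multiclass covariance form over the confusion counts,

      MCC = (c s - sum_k p_k t_k) /
            sqrt((s^2 - sum_k p_k^2)(s^2 - sum_k t_k^2))

  with c the trace, s the total, p_k / t_k the predicted / true marginal
  counts; it reduces to the binary MCC for two classes.
* Splits and cross-validation folds are grouped by subject: no subject's
  samples ever span the train/test boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EvalReport:
    """Metrics plus confusion matrices, optionally with per-fold copies."""

    classes: tuple[str, ...]
    counts: np.ndarray
    accuracy: float
    macro_f1: float
    mcc: float
    zero_support_classes: tuple[str, ...] = ()
    folds: list["EvalReport"] = field(default_factory=list)

    @property
    def normalized(self) -> np.ndarray:
        return _normalize_columns(self.counts)

    def fold_summary(self) -> dict[str, tuple[float, float]]:
        """(mean, std) of each metric across folds."""
        if not self.folds:
            raise ValueError("report has no per-fold results")
        out = {}
        for m in ("accuracy", "macro_f1", "mcc"):
            vals = np.array([getattr(f, m) for f in self.folds])
            out[m] = (float(vals.mean()), float(vals.std()))
        return out

    def to_dict(self) -> dict:
        d = {
            "classes": list(self.classes),
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "mcc": self.mcc,
            "f1_averaging": "macro",
            "confusion_counts": self.counts.tolist(),
            "confusion_column_normalized": self.normalized.tolist(),
            "zero_support_classes": list(self.zero_support_classes),
        }
        if self.folds:
            d["folds"] = [f.to_dict() for f in self.folds]
            d["fold_summary"] = {
                k: {"mean": v[0], "std": v[1]} for k, v in self.fold_summary().items()
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def confusion_frame(self, normalized: bool = True) -> pd.DataFrame:
        m = self.normalized if normalized else self.counts
        return pd.DataFrame(m, index=list(self.classes), columns=list(self.classes))


def confusion(y_true, y_pred, classes) -> tuple[np.ndarray, np.ndarray]:
    """Confusion counts and column-normalized matrix.

    Entry ``[i, j]`` counts samples of true class ``classes[j]`` predicted
    as ``classes[i]``.  Unknown labels raise.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    index = {c: k for k, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}; classes: {list(classes)}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}; classes: {list(classes)}")
        counts[index[p], index[t]] += 1
    return counts, _normalize_columns(counts)


def _normalize_columns(counts: np.ndarray) -> np.ndarray:
    support = counts.sum(axis=0)
    out = np.zeros(counts.shape, dtype=float)
    nz = support > 0
    out[:, nz] = counts[:, nz] / support[nz]
    return out


def metrics(counts: np.ndarray) -> dict[str, float]:
    """ACC, macro-F1 and multiclass MCC from confusion counts."""
    counts = np.asarray(counts, dtype=float)
    s = counts.sum()
    if s == 0:
        raise ValueError("confusion counts are empty")
    c = np.trace(counts)
    acc = c / s

    t_k = counts.sum(axis=0)  # true support per class (columns)
    p_k = counts.sum(axis=1)  # predicted per class (rows)
    f1s = []
    for k in range(len(t_k)):
        if t_k[k] + p_k[k] == 0:
            continue  # excluded from the macro mean, flagged by caller
        f1s.append(2.0 * counts[k, k] / (t_k[k] + p_k[k]))
    macro_f1 = float(np.mean(f1s))

    denom = np.sqrt(float(s**2 - (p_k**2).sum())) * np.sqrt(float(s**2 - (t_k**2).sum()))
    mcc = 0.0 if denom == 0 else float((c * s - (p_k * t_k).sum()) / denom)
    return {"accuracy": float(acc), "macro_f1": macro_f1, "mcc": mcc}


def evaluate(y_true, y_pred, classes) -> EvalReport:
    """Full report for one prediction run."""
    counts, _ = confusion(y_true, y_pred, classes)
    m = metrics(counts)
    support = counts.sum(axis=0) + counts.sum(axis=1)
    zero = tuple(c for c, sup in zip(classes, support) if sup == 0)
    return EvalReport(
        classes=tuple(classes),
        counts=counts,
        accuracy=m["accuracy"],
        macro_f1=m["macro_f1"],
        mcc=m["mcc"],
        zero_support_classes=zero,
    )


def subject_split(subject_ids, n_train_subjects: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic whole-subject split by sorted subject-id order.

    Returns boolean (train_mask, test_mask) over samples; the first
    ``n_train_subjects`` subjects (ascending id) train, the rest test.
    """
    subject_ids = np.asarray(subject_ids)
    uniq = np.unique(subject_ids)
    if n_train_subjects < 1 or n_train_subjects >= len(uniq):
        raise ValueError(
            f"n_train_subjects must be in [1, {len(uniq) - 1}] "
            f"for {len(uniq)} subjects, got {n_train_subjects}"
        )
    train_subjects = set(uniq[:n_train_subjects].tolist())
    train = np.array([s in train_subjects for s in subject_ids])
    return train, ~train


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    subject_ids: np.ndarray,
    trainer,
    k: int = 5,
    seed: int = 0,
    classes=None,
) -> EvalReport:
    """Subject-grouped k-fold cross-validation.

    Subjects are shuffled with ``seed`` and dealt into ``k`` folds; every
    sample appears in exactly one test fold and no subject spans folds.
    ``trainer(X_train, y_train)`` must return an object with a
    ``predict(X)`` method.  The returned report pools the confusion
    counts over folds and carries per-fold reports.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    subject_ids = np.asarray(subject_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    uniq = np.unique(subject_ids)
    if len(uniq) < k:
        raise ValueError(f"need at least k={k} subjects, got {len(uniq)}")
    if classes is None:
        classes = tuple(np.unique(y).tolist())
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq)
    fold_of = {s: i % k for i, s in enumerate(order.tolist())}
    fold_reports: list[EvalReport] = []
    pooled = np.zeros((len(classes), len(classes)), dtype=int)
    for fold in range(k):
        test_mask = np.array([fold_of[s] == fold for s in subject_ids])
        model = trainer(X[~test_mask], y[~test_mask])
        pred = model.predict(X[test_mask])
        rep = evaluate(y[test_mask], pred, classes)
        fold_reports.append(rep)
        pooled += rep.counts
    m = metrics(pooled)
    support = pooled.sum(axis=0) + pooled.sum(axis=1)
    zero = tuple(c for c, sup in zip(classes, support) if sup == 0)
    return EvalReport(
        classes=tuple(classes),
        counts=pooled,
        accuracy=m["accuracy"],
        macro_f1=m["macro_f1"],
        mcc=m["mcc"],
        zero_support_classes=zero,
        folds=fold_reports,
    )
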