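"""Standardized 30-channel feature vectors and fixed-length sequences.

Both classifiers consume the raw 30 inertial channels after per-channel
z-scoring with statistics fitted on training data only (test data is
transformed with the training statistics — no leakage).  The motion-state
classifier takes the instantaneous standardized 30-vector; the phase
classifier takes a sliding window of ``n`` consecutive vectors (default
n = 5) whose target is the label of the window's **last** sample, so a
prediction at time t only ever uses samples t-n+1 ... t (causal, suitable
for online use).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .streams import CHANNELS, ImuStream

DEFAULT_SEQUENCE_LENGTH = 5


@dataclass
class ChannelStats:
    """Per-channel mean and standard deviation fitted on training data."""

    mean: np.ndarray
    std: np.ndarray
    channels: tuple[str, ...] = field(default=CHANNELS)
    constant_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.mean.shape != (len(self.channels),) or self.std.shape != self.mean.shape:
            raise ValueError("mean/std must be 1-D with one entry per channel")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "channels": list(self.channels),
                    "mean": self.mean.tolist(),
                    "std": self.std.tolist(),
                    "constant_channels": list(self.constant_channels),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "ChannelStats":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            np.array(d["mean"]),
            np.array(d["std"]),
            tuple(d["channels"]),
            tuple(d["constant_channels"]),
        )


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, ImuStream):
        return x.data
    return np.asarray(x, dtype=float)


def fit_stats(training_streams) -> ChannelStats:
    """Fit per-channel mean/std over all samples of the training streams.

    Accepts a list of :class:`ImuStream`/arrays or a single one.  Channels
    with zero variance are flagged in ``constant_channels`` and assigned
    unit std so standardization is well defined.
    """
    if isinstance(training_streams, (ImuStream, np.ndarray)):
        training_streams = [training_streams]
    mats = [_as_matrix(s) for s in training_streams]
    if not mats or sum(m.shape[0] for m in mats) == 0:
        raise ValueError("cannot fit channel statistics on an empty training set")
    X = np.vstack(mats)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    constant = tuple(CHANNELS[i] for i in np.flatnonzero(std == 0))
    std = np.where(std == 0, 1.0, std)
    return ChannelStats(mean, std, CHANNELS, constant)


def standardize(stream, stats: ChannelStats) -> np.ndarray:
    """(x - mean) / std per channel; returns an (n_samples, 30) array."""
    X = _as_matrix(stream)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(stats.channels):
        raise ValueError(
            f"stream has {X.shape[1]} channels, stats were fitted on "
            f"{len(stats.channels)}: {list(stats.channels)}"
        )
    return (X - stats.mean) / stats.std


def destandardize(X: np.ndarray, stats: ChannelStats) -> np.ndarray:
    """Inverse of :func:`standardize`."""
    return np.asarray(X, dtype=float) * stats.std + stats.mean


def state_feature_vector(sample, stats: ChannelStats | None = None) -> np.ndarray:
    """The instantaneous 30-channel feature vector in canonical order.

    ``sample`` may be a dict mapping channel name to value (any order —
    names are canonicalized) or an already ordered length-30 array.  When
    ``stats`` is given the vector is standardized.
    """
    if isinstance(sample, dict):
        missing = [c for c in CHANNELS if c not in sample]
        if missing:
            raise KeyError(f"sample is missing channels: {missing}")
        vec = np.array([float(sample[c]) for c in CHANNELS])
    else:
        vec = np.asarray(sample, dtype=float)
        if vec.shape != (len(CHANNELS),):
            raise ValueError(f"expected a length-{len(CHANNELS)} vector, got {vec.shape}")
    if stats is not None:
        vec = standardize(vec, stats)[0]
    return vec


def make_sequences(
    X: np.ndarray,
    labels: np.ndarray | None = None,
    n: int = DEFAULT_SEQUENCE_LENGTH,
    stride: int = 1,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Sliding windows of ``n`` consecutive standardized samples.

    Returns ``(sequences, targets)`` where sequences has shape
    ``(m, n, 30)`` with ``m = (len(X) - n) // stride + 1`` and each
    target is the label of its window's last sample.  A stream shorter
    than ``n`` yields zero sequences.
    """
    X = np.asarray(X, dtype=float)
    if n < 1 or stride < 1:
        raise ValueError("n and stride must be >= 1")
    if len(X) < n:
        return np.empty((0, n, X.shape[1] if X.ndim == 2 else 0)), (
            np.empty(0, dtype=object) if labels is not None else None
        )
    starts = np.arange(0, len(X) - n + 1, stride)
    seqs = np.stack([X[s : s + n] for s in starts])
    targets = None
    if labels is not None:
        labels = np.asarray(labels)
        if len(labels) != len(X):
            raise ValueError("labels must align with samples")
        targets = labels[starts + n - 1]
    return seqs, targets
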