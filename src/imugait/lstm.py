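"""Gait-phase recognition with an LSTM sequence classifier, in NumPy.

The recurrent cell is the classic LSTM with forget gate f, input gate i,
output gate o and cell state C, all acting on the concatenation of the
previous hidden state and the current input [h_{t-1}, x_t]:

    f_t = sigma(W_f . [h_{t-1}, x_t] + b_f)
    i_t = sigma(W_i . [h_{t-1}, x_t] + b_i)
    o_t = sigma(W_o . [h_{t-1}, x_t] + b_o)
    C_t = f_t * C_{t-1} + i_t * tanh(W_c . [h_{t-1}, x_t] + b_c)
    h_t = o_t * tanh(C_t)

A window of n standardized 30-channel samples (n = 5 by default) is
unrolled through the cell from zero initial state; the final hidden state
passes through a fully connected ReLU layer and a softmax over the six
gait-phase classes.  Reference capacity is 128 LSTM units and a 32-unit FC
layer trained for 200 epochs in batches of 64; a desk-scale configuration
(hidden 32, 30 epochs) trains in seconds and is used throughout the test
suite.  Training minimizes categorical cross-entropy with Adam;
everything — initialization, shuffling — is driven by one seed, so
training is exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .events import EVENT_ORDER

_GATES = ("f", "i", "o", "c")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class LstmParams:
    """Gate weight matrices (hidden x (hidden + input)) and bias vectors."""

    W: dict[str, np.ndarray]
    b: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {g: self.W[g].shape for g in _GATES}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"all four gate weights must share one shape, got {shapes}")
        h = self.hidden_size
        for g in _GATES:
            if self.b[g].shape != (h,):
                raise ValueError(f"bias b_{g} must have shape ({h},), got {self.b[g].shape}")

    @property
    def hidden_size(self) -> int:
        return self.W["f"].shape[0]

    @property
    def input_size(self) -> int:
        return self.W["f"].shape[1] - self.W["f"].shape[0]


@dataclass
class HeadParams:
    """Fully connected ReLU layer and softmax output layer."""

    W1: np.ndarray  # (fc, hidden)
    b1: np.ndarray
    W2: np.ndarray  # (classes, fc)
    b2: np.ndarray
    classes: tuple[str, ...] = field(default=EVENT_ORDER)


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, shape)


def init_params(
    input_size: int = 30,
    hidden_size: int = 128,
    fc_size: int = 32,
    n_classes: int = 6,
    seed: int = 0,
    classes: tuple[str, ...] = EVENT_ORDER,
) -> tuple[LstmParams, HeadParams]:
    """Glorot-uniform weights, zero biases, from one seed."""
    rng = np.random.default_rng(seed)
    W = {g: _glorot(rng, (hidden_size, hidden_size + input_size)) for g in _GATES}
    b = {g: np.zeros(hidden_size) for g in _GATES}
    head = HeadParams(
        W1=_glorot(rng, (fc_size, hidden_size)),
        b1=np.zeros(fc_size),
        W2=_glorot(rng, (n_classes, fc_size)),
        b2=np.zeros(n_classes),
        classes=tuple(classes),
    )
    return LstmParams(W, b), head


def cell_step(
    params: LstmParams,
    h_prev: np.ndarray,
    C_prev: np.ndarray,
    x: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update; works on vectors or (batch, dim) arrays."""
    h_prev = np.asarray(h_prev, dtype=float)
    C_prev = np.asarray(C_prev, dtype=float)
    x = np.asarray(x, dtype=float)
    H, I = params.hidden_size, params.input_size
    if h_prev.shape[-1] != H or C_prev.shape[-1] != H:
        raise ValueError(f"h_prev/C_prev must have last dimension {H}")
    if x.shape[-1] != I:
        raise ValueError(
            f"input has {x.shape[-1]} features but gate matrices W_* expect {I}"
        )
    a = np.concatenate([h_prev, x], axis=-1)
    f = _sigmoid(a @ params.W["f"].T + params.b["f"])
    i = _sigmoid(a @ params.W["i"].T + params.b["i"])
    o = _sigmoid(a @ params.W["o"].T + params.b["o"])
    g = np.tanh(a @ params.W["c"].T + params.b["c"])
    C = f * C_prev + i * g
    h = o * np.tanh(C)
    return h, C


def forward(
    params: LstmParams,
    head: HeadParams,
    sequence: np.ndarray,
) -> np.ndarray:
    """Class probabilities for one (n, input) window or a (batch, n, input)
    stack: unroll the cell from zero state, then FC + ReLU + softmax."""
    seq = np.asarray(sequence, dtype=float)
    single = seq.ndim == 2
    if single:
        seq = seq[None]
    B, n, _ = seq.shape
    h = np.zeros((B, params.hidden_size))
    C = np.zeros_like(h)
    for t in range(n):
        h, C = cell_step(params, h, C, seq[:, t, :])
    r = np.maximum(h @ head.W1.T + head.b1, 0.0)
    p = softmax(r @ head.W2.T + head.b2)
    return p[0] if single else p


def predict_phase(params: LstmParams, head: HeadParams, sequence: np.ndarray):
    """Argmax class of :func:`forward`; ties break to the lowest class
    index.  Accepts one window (returns a label) or a stack (array)."""
    p = forward(params, head, sequence)
    if p.ndim == 1:
        return head.classes[int(np.argmax(p))]
    return np.array([head.classes[k] for k in np.argmax(p, axis=1)], dtype=object)


@dataclass
class TrainConfig:
    """Training hyperparameters.  Reference scale: 200 epochs, batch 64,
    hidden 128; the loss is categorical cross-entropy under Adam."""

    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    hidden_size: int = 128
    fc_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _forward_cached(params, head, X):
    """Forward pass keeping every intermediate needed for BPTT."""
    B, n, _ = X.shape
    H = params.hidden_size
    h = np.zeros((B, H))
    C = np.zeros((B, H))
    cache = []
    for t in range(n):
        a = np.concatenate([h, X[:, t, :]], axis=-1)
        f = _sigmoid(a @ params.W["f"].T + params.b["f"])
        i = _sigmoid(a @ params.W["i"].T + params.b["i"])
        o = _sigmoid(a @ params.W["o"].T + params.b["o"])
        g = np.tanh(a @ params.W["c"].T + params.b["c"])
        C_new = f * C + i * g
        h_new = o * np.tanh(C_new)
        cache.append((a, f, i, o, g, C, C_new))
        h, C = h_new, C_new
    pre1 = h @ head.W1.T + head.b1
    r = np.maximum(pre1, 0.0)
    logits = r @ head.W2.T + head.b2
    p = softmax(logits)
    return p, (cache, h, pre1, r)


def _backward(params, head, X, p, targets_onehot, fwd_cache):
    """Gradients of mean cross-entropy w.r.t. all parameters."""
    cache, h_final, pre1, r = fwd_cache
    B, n, _ = X.shape
    H = params.hidden_size

    dlogits = (p - targets_onehot) / B
    gW2 = dlogits.T @ r
    gb2 = dlogits.sum(axis=0)
    dr = dlogits @ head.W2
    dr[pre1 <= 0] = 0.0
    gW1 = dr.T @ h_final
    gb1 = dr.sum(axis=0)
    dh = dr @ head.W1

    gW = {g: np.zeros_like(params.W[g]) for g in _GATES}
    gb = {g: np.zeros_like(params.b[g]) for g in _GATES}
    dC_next = np.zeros((B, H))
    for t in range(n - 1, -1, -1):
        a, f, i, o, g, C_prev, C = cache[t]
        tC = np.tanh(C)
        dC = dh * o * (1.0 - tC**2) + dC_next
        dzo = dh * tC * o * (1.0 - o)
        dzf = dC * C_prev * f * (1.0 - f)
        dzi = dC * g * i * (1.0 - i)
        dzg = dC * i * (1.0 - g**2)
        for name, dz in (("f", dzf), ("i", dzi), ("o", dzo), ("c", dzg)):
            gW[name] += dz.T @ a
            gb[name] += dz.sum(axis=0)
        da = dzf @ params.W["f"] + dzi @ params.W["i"] + dzo @ params.W["o"] + dzg @ params.W["c"]
        dh = da[:, :H]
        dC_next = dC * f
    return gW, gb, gW1, gb1, gW2, gb2


class _Adam:
    def __init__(self, lr: float):
        self.lr = lr
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self, tensors_and_grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, (x, g) in enumerate(tensors_and_grads):
            m = self.m.setdefault(k, np.zeros_like(x))
            v = self.v.setdefault(k, np.zeros_like(x))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            x -= self.lr * mhat / (np.sqrt(vhat) + eps)


def train(
    config: TrainConfig,
    sequences: np.ndarray,
    targets: np.ndarray,
    classes: tuple[str, ...] = EVENT_ORDER,
) -> tuple[LstmParams, HeadParams, list[float]]:
    """Train the phase classifier; returns (params, head, per-epoch losses).

    ``sequences`` is (m, n, input); ``targets`` the per-window class
    labels.  Classes absent from the training data trigger a warning but
    not an error.  The per-epoch mean loss history is returned for
    monitoring (non-increasing on average over training).
    """
    import warnings

    X = np.asarray(sequences, dtype=float)
    y = np.asarray(targets)
    if X.ndim != 3:
        raise ValueError("sequences must be (m, n, input)")
    if len(X) != len(y):
        raise ValueError("sequences and targets must align")
    present = set(np.unique(y).tolist())
    if len(present) < 2:
        raise ValueError("need at least 2 classes in the training data")
    missing = [c for c in classes if c not in present]
    if missing:
        warnings.warn(f"classes absent from training data: {missing}", stacklevel=2)

    class_index = {c: k for k, c in enumerate(classes)}
    try:
        y_idx = np.array([class_index[t] for t in y])
    except KeyError as exc:
        raise ValueError(f"target {exc.args[0]!r} not in classes {classes}") from None
    onehot = np.eye(len(classes))[y_idx]

    params, head = init_params(
        input_size=X.shape[2],
        hidden_size=config.hidden_size,
        fc_size=config.fc_size,
        n_classes=len(classes),
        seed=config.seed,
        classes=classes,
    )
    opt = _Adam(config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    losses: list[float] = []
    m = len(X)
    for _epoch in range(config.epochs):
        order = rng.permutation(m)
        epoch_loss = 0.0
        for start in range(0, m, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb, tb = X[idx], onehot[idx]
            p, fwd_cache = _forward_cached(params, head, Xb)
            eps = 1e-12
            epoch_loss += -float(np.sum(tb * np.log(p + eps)))
            gW, gb, gW1, gb1, gW2, gb2 = _backward(params, head, Xb, p, tb, fwd_cache)
            opt.step(
                [(params.W[g], gW[g]) for g in _GATES]
                + [(params.b[g], gb[g]) for g in _GATES]
                + [(head.W1, gW1), (head.b1, gb1), (head.W2, gW2), (head.b2, gb2)]
            )
        losses.append(epoch_loss / m)
    return params, head, losses


def save_model(directory, params: LstmParams, head: HeadParams, config: TrainConfig | None = None) -> None:
    """JSON manifest (shapes, classes, config) + NPZ weight arrays."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "kind": "imugait-lstm",
        "hidden_size": params.hidden_size,
        "input_size": params.input_size,
        "fc_size": head.W1.shape[0],
        "classes": list(head.classes),
        "config": None
        if config is None
        else {
            "epochs": config.epochs,
            "batch_size": config.batch_size,
            "learning_rate": config.learning_rate,
            "seed": config.seed,
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    arrays = {f"W_{g}": params.W[g] for g in _GATES}
    arrays.update({f"b_{g}": params.b[g] for g in _GATES})
    arrays.update({"W1": head.W1, "b1": head.b1, "W2": head.W2, "b2": head.b2})
    np.savez(directory / "weights.npz", **arrays)


def load_model(directory) -> tuple[LstmParams, HeadParams]:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    arrs = np.load(directory / "weights.npz")
    params = LstmParams(
        W={g: arrs[f"W_{g}"] for g in _GATES},
        b={g: arrs[f"b_{g}"] for g in _GATES},
    )
    head = HeadParams(
        W1=arrs["W1"], b1=arrs["b1"], W2=arrs["W2"], b2=arrs["b2"],
        classes=tuple(manifest["classes"]),
    )
    return params, head
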