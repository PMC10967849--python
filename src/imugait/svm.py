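"""Motion-state recognition: RBF-SVMs composed in a binary tree.

The 10 motion states are separated by a tree of soft-margin binary SVMs:
each internal node splits its class subset into two halves with one RBF
classifier, and prediction descends from the root by decision sign until a
single-class leaf is reached.  The binary subproblems are solved with
scikit-learn's ``SVC`` (an SMO-type quadratic-programming solver); the
decision function of every node is the usual kernel expansion

    f(x) = sum_i lambda_i y_i K(x_i, x) + b,    K(a, b) = exp(-gamma ||a-b||^2)

with dual coefficients bounded in [0, C] by the soft-margin box constraint.
Defaults: C = 2, gamma = "scale", i.e. 1 / (n_features * Var(X)) resolved
on each node's own training subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .synthio import MOTION_STATES

DEFAULT_C = 2.0


@dataclass
class SvmBinaryModel:
    """One trained soft-margin RBF-SVM with its kernel expansion exposed.

    ``dual_coef`` holds the signed products lambda_i * y_i (so
    ``|dual_coef| <= C``); ``intercept`` is the bias b; ``gamma`` is the
    resolved numeric kernel width.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    C: float

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """f(x) = sum_i lambda_i y_i K(x_i, x) + b for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = (
            (X**2).sum(axis=1)[:, None]
            + (self.support_vectors**2).sum(axis=1)[None, :]
            - 2.0 * X @ self.support_vectors.T
        )
        K = np.exp(-self.gamma * d2)
        return K @ self.dual_coef + self.intercept


def resolve_gamma(X: np.ndarray, gamma: float | str = "scale") -> float:
    """Resolve the RBF width: "scale" -> 1 / (n_features * Var(X))."""
    if isinstance(gamma, str):
        if gamma != "scale":
            raise ValueError(f"unknown gamma setting {gamma!r}; use 'scale' or a float")
        v = float(np.asarray(X, dtype=float).var())
        if v == 0:
            raise ValueError("cannot resolve gamma='scale' on constant features")
        return 1.0 / (X.shape[1] * v)
    return float(gamma)


def train_binary(
    X: np.ndarray,
    y: np.ndarray,
    C: float = DEFAULT_C,
    gamma: float | str = "scale",
) -> SvmBinaryModel:
    """Train one binary soft-margin RBF-SVM on labels in {-1, +1}."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if set(classes.tolist()) != {-1, 1}:
        raise ValueError(f"binary training requires both labels -1 and +1, got {classes}")
    g = resolve_gamma(X, gamma)
    svc = SVC(C=C, kernel="rbf", gamma=g)
    svc.fit(X, y)
    # sklearn orders classes ascending (-1, +1), so dual_coef_ already holds
    # lambda_i * y_i with the conventional sign.
    return SvmBinaryModel(
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        gamma=g,
        C=C,
    )


@dataclass
class TreeNode:
    """A node of the class-partition tree: a leaf holds one class, an
    internal node a (left, right) class split and, once fitted, a model."""

    classes: tuple[str, ...]
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    model: SvmBinaryModel | None = None

    @property
    def is_leaf(self) -> bool:
        return len(self.classes) == 1

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.classes[0]]
        return self.left.leaves() + self.right.leaves()

    def internal_nodes(self) -> list["TreeNode"]:
        if self.is_leaf:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()

    @property
    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth, self.right.depth)


def build_tree(classes=MOTION_STATES, strategy: str = "balanced") -> TreeNode:
    """Build the multiclass decomposition skeleton.

    ``balanced`` splits the class list in order into two halves of sizes
    ceil(n/2) / floor(n/2) recursively, giving n-1 internal nodes of depth
    ceil(log2 n).  The class order is the caller's; the package default is
    the fixed order SD, LW, US, DS, USL, DSL, TL, TR, LS, RS.
    """
    classes = tuple(classes)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to build a tree")
    if len(set(classes)) != len(classes):
        raise ValueError("classes must be distinct")
    if strategy != "balanced":
        raise ValueError(f"unknown strategy {strategy!r}; only 'balanced' is provided")

    def _split(cs: tuple[str, ...]) -> TreeNode:
        if len(cs) == 1:
            return TreeNode(cs)
        mid = (len(cs) + 1) // 2
        return TreeNode(cs, _split(cs[:mid]), _split(cs[mid:]))

    return _split(classes)


@dataclass
class TreeClassifier:
    """A fitted binary-tree multiclass SVM."""

    root: TreeNode
    C: float = DEFAULT_C
    gamma: float | str = "scale"
    fitted: bool = field(default=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Root-to-leaf descent by decision sign for each row of X.

        A decision value >= 0 goes to the first (left) branch — the >= is
        the deterministic tie rule.
        """
        if not self.fitted:
            raise RuntimeError("tree is not fitted; call fit_tree first")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(len(X), dtype=object)
        for i, x in enumerate(X):
            out[i] = self._descend(x)[0]
        return out

    def _descend(self, x: np.ndarray) -> tuple[str, list[tuple[tuple[str, ...], float]]]:
        node = self.root
        trace: list[tuple[tuple[str, ...], float]] = []
        while not node.is_leaf:
            val = float(node.model.decision_function(x[None, :])[0])
            trace.append((node.classes, val))
            node = node.left if val >= 0 else node.right
        return node.classes[0], trace

    def decision_path(self, x: np.ndarray) -> list[tuple[tuple[str, ...], float]]:
        """Per-node decision values along the descent, for audit."""
        if not self.fitted:
            raise RuntimeError("tree is not fitted; call fit_tree first")
        return self._descend(np.asarray(x, dtype=float))[1]

    def save(self, directory) -> None:
        """JSON manifest (topology, hyperparameters) + one NPZ per node."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        nodes = self.root.internal_nodes()
        manifest = {
            "kind": "imugait-svm-tree",
            "C": self.C,
            "gamma": self.gamma if isinstance(self.gamma, str) else float(self.gamma),
            "classes": list(self.root.classes),
            "nodes": [
                {
                    "classes": list(n.classes),
                    "left": list(n.left.classes),
                    "right": list(n.right.classes),
                    "gamma": n.model.gamma,
                    "intercept": n.model.intercept,
                    "file": f"node{i}.npz",
                }
                for i, n in enumerate(nodes)
            ],
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        for i, n in enumerate(nodes):
            np.savez(
                directory / f"node{i}.npz",
                support_vectors=n.model.support_vectors,
                dual_coef=n.model.dual_coef,
            )

    @classmethod
    def load(cls, directory) -> "TreeClassifier":
        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        root = build_tree(manifest["classes"])
        by_classes = {tuple(n.classes): n for n in root.internal_nodes()}
        for spec in manifest["nodes"]:
            node = by_classes[tuple(spec["classes"])]
            arrs = np.load(directory / spec["file"])
            node.model = SvmBinaryModel(
                support_vectors=arrs["support_vectors"],
                dual_coef=arrs["dual_coef"],
                intercept=spec["intercept"],
                gamma=spec["gamma"],
                C=manifest["C"],
            )
        return cls(root, C=manifest["C"], gamma=manifest["gamma"], fitted=True)


def fit_tree(
    skeleton: TreeNode,
    X: np.ndarray,
    y: np.ndarray,
    C: float = DEFAULT_C,
    gamma: float | str = "scale",
) -> TreeClassifier:
    """Train every internal node on its class subset.

    At each node, the samples of the left subset are labeled +1 and those
    of the right subset -1; gamma="scale" is resolved per node on that
    node's training subset.  A node whose branch has no samples raises an
    error naming the missing class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    present = set(np.unique(y).tolist())
    leaves = set(skeleton.leaves())
    if not present <= leaves:
        raise ValueError(f"labels {sorted(present - leaves)} are not tree leaves")
    for node in skeleton.internal_nodes():
        left, right = set(node.left.classes), set(node.right.classes)
        for branch in (left, right):
            empty = [c for c in branch if not np.any(y == c)]
            if len(empty) == len(branch):
                raise ValueError(
                    f"no training samples for branch classes {sorted(branch)} "
                    f"at node {node.classes}"
                )
        mask = np.isin(y, list(node.classes))
        yb = np.where(np.isin(y[mask], list(left)), 1, -1)
        node.model = train_binary(X[mask], yb, C=C, gamma=gamma)
    return TreeClassifier(skeleton, C=C, gamma=gamma, fitted=True)
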