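"""Gradient-boosted regression trees, written from first principles.

The ensemble is built stage-wise: start from the constant minimizing the
loss, then at each stage fit a regression tree to the negative gradient of
the loss at the current scores (the pseudo-residuals), pick a single step
size by one-dimensional line search, and add the shrunken stage to the
model:

    F_0 = argmin_c sum_i L(y_i, c)
    r_i = -dL(y_i, F)/dF |_{F = F_{m-1}(x_i)}
    h_m = regression tree fit to (X, r)
    g_m = argmin_g sum_i L(y_i, F_{m-1}(x_i) + g * h_m(x_i))
    F_m = F_{m-1} + nu * g_m * h_m

Binary classification uses the binomial deviance (logistic loss) with
probabilities sigmoid(F); squared loss is also provided. Trees use greedy
exact variance-reduction splits with ties broken by lowest feature index,
then lowest threshold. One step size per tree (not per leaf), matching the
single-coefficient line-search formulation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

Loss = Literal["squared", "logistic"]

_MIN_GAIN = 1e-12
_LOGODDS_CLAMP = 30.0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def loss_value(y: np.ndarray, F: np.ndarray, loss: Loss) -> float:
    """Total loss sum_i L(y_i, F_i)."""
    if loss == "squared":
        return float(0.5 * np.sum((y - F) ** 2))
    # binomial deviance: log(1+exp(F)) - y*F, computed stably
    return float(np.sum(np.logaddexp(0.0, F) - y * F))


def init_constant(y: np.ndarray, loss: Loss) -> float:
    """The loss-minimizing constant score F0 (Eq: argmin_c sum L(y_i, c)).

    Squared loss: mean(y). Logistic: log-odds of the positive rate; an
    all-one or all-zero label vector would give infinite log-odds, so the
    value is clamped with a warning.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty label vector")
    if loss == "squared":
        return float(np.mean(y))
    p = float(np.mean(y))
    if p <= 0.0 or p >= 1.0:
        warnings.warn("all labels identical: clamping initial log-odds")
        return _LOGODDS_CLAMP if p >= 1.0 else -_LOGODDS_CLAMP
    return float(np.log(p / (1.0 - p)))


def pseudo_residuals(y: np.ndarray, F_prev: np.ndarray, loss: Loss) -> np.ndarray:
    """Negative loss gradient at the current scores.

    Squared: y - F. Logistic: y - sigmoid(F).
    """
    y = np.asarray(y, dtype=np.float64)
    F_prev = np.asarray(F_prev, dtype=np.float64)
    if y.shape != F_prev.shape:
        raise ValueError("shape mismatch between y and F_prev")
    if not np.all(np.isfinite(F_prev)):
        raise FloatingPointError("non-finite entries in current scores")
    if loss == "squared":
        return y - F_prev
    return y - _sigmoid(F_prev)


# ---------------------------------------------------------------------------
# regression tree


@dataclass
class _Node:
    feature: int = -1  # -1 marks a leaf
    threshold: float = 0.0
    value: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None

    def to_dict(self) -> dict:
        if self.feature < 0:
            return {"value": self.value}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Node":
        if "value" in d:
            return cls(value=float(d["value"]))
        return cls(
            feature=int(d["feature"]),
            threshold=float(d["threshold"]),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


@dataclass
class RegressionTree:
    """Binary regression tree with axis-aligned threshold splits.

    Samples with x[feature] <= threshold go left. Leaf value is the mean
    residual of the training samples reaching the leaf.
    """

    root: _Node
    max_depth: int
    min_samples_leaf: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        out = np.empty(X.shape[0])

        def recurse(node: _Node, idx: np.ndarray) -> None:
            if node.feature < 0:
                out[idx] = node.value
                return
            go_left = X[idx, node.feature] <= node.threshold
            recurse(node.left, idx[go_left])
            recurse(node.right, idx[~go_left])

        recurse(self.root, np.arange(X.shape[0]))
        return out


def _best_split(V: np.ndarray, R: np.ndarray, min_leaf: int):
    """Exact best variance-reduction split of one node, or None.

    ``V`` and ``R`` are the node's feature values and residuals, both
    already sorted per feature column. Candidate thresholds are midpoints
    between consecutive distinct sorted feature values; gain is the
    decrease in sum of squared deviations. Ties are broken by lowest
    feature index, then lowest threshold.
    """
    n, f = V.shape
    if n < 2 * min_leaf:
        return None
    C = np.cumsum(R, axis=0)
    total = C[-1, 0]
    nl = np.arange(1, n, dtype=np.float64)[:, None]
    nr = n - nl
    Cl = C[:-1]
    gains = Cl**2 / nl + (total - Cl) ** 2 / nr - total**2 / n
    valid = V[1:] > V[:-1]
    if min_leaf > 1:
        ok = (nl >= min_leaf) & (nr >= min_leaf)
        valid = valid & ok
    gains = np.where(valid, gains, -np.inf)
    flat = gains.T.ravel()  # feature-major => first index tie-break is (feature, threshold)
    gmax = flat.max()
    if not np.isfinite(gmax) or gmax <= _MIN_GAIN:
        return None
    # treat gains within fp noise of the max as exact ties so the
    # (lowest feature, lowest threshold) rule is robust to rounding
    tol = 1e-9 * max(1.0, abs(gmax))
    j = int(np.argmax(flat >= gmax - tol))
    gain = flat[j]
    feat, pos = divmod(j, n - 1)
    thr = 0.5 * (V[pos, feat] + V[pos + 1, feat])
    return feat, thr, gain


def fit_tree(
    X: np.ndarray,
    r: np.ndarray,
    max_depth: int = 3,
    min_samples_leaf: int = 1,
    presorted: np.ndarray | None = None,
) -> RegressionTree:
    """Greedy depth-limited regression tree on pseudo-residuals.

    ``presorted`` may carry argsort(X, axis=0) computed once by the caller
    (boosting re-fits trees on the same X every stage); per-node sorted
    orders are then obtained by filtering instead of re-sorting.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    r = np.asarray(r, dtype=np.float64)
    if X.shape[0] != r.shape[0]:
        raise ValueError("X and r row counts differ")
    if X.shape[0] < 1:
        raise ValueError("empty training set")
    n_total, f = X.shape
    if presorted is None:
        presorted = np.argsort(X, axis=0, kind="stable")
    member = np.zeros(n_total, dtype=bool)
    col_idx = np.arange(f)

    def build(idx: np.ndarray, order: np.ndarray, depth: int) -> _Node:
        if depth >= max_depth or idx.size < 2 * min_samples_leaf:
            return _Node(value=float(r[idx].mean()))
        V = X[order, col_idx]
        found = _best_split(V, r[order], min_samples_leaf)
        if found is None:
            return _Node(value=float(r[idx].mean()))
        feat, thr, _ = found
        go_left = X[idx, feat] <= thr
        left_idx, right_idx = idx[go_left], idx[~go_left]
        # filter each sorted column down to the child's members
        member[left_idx] = True
        keep = member[order]
        left_order = order.T[keep.T].reshape(f, left_idx.size).T
        right_order = order.T[~keep.T].reshape(f, right_idx.size).T
        member[left_idx] = False
        return _Node(
            feature=feat,
            threshold=thr,
            left=build(left_idx, left_order, depth + 1),
            right=build(right_idx, right_order, depth + 1),
        )

    root = build(np.arange(n_total), presorted, 0)
    return RegressionTree(root=root, max_depth=max_depth, min_samples_leaf=min_samples_leaf)


# ---------------------------------------------------------------------------
# line search


def line_search(y: np.ndarray, F_prev: np.ndarray, h_values: np.ndarray, loss: Loss) -> float:
    """Step size g minimizing sum_i L(y_i, F_i + g h_i).

    Squared loss has the closed form <r, h>/<h, h>; the logistic case is
    solved by safeguarded Newton iteration (the objective is convex in g)
    to gradient tolerance 1e-10.
    """
    y = np.asarray(y, dtype=np.float64)
    F_prev = np.asarray(F_prev, dtype=np.float64)
    h = np.asarray(h_values, dtype=np.float64)
    hh = float(h @ h)
    if hh == 0.0:
        warnings.warn("all-zero weak learner: step size 0")
        return 0.0
    if loss == "squared":
        return float((y - F_prev) @ h / hh)
    g = 0.0
    for _ in range(100):
        s = _sigmoid(F_prev + g * h)
        grad = float(h @ (s - y))
        hess = float((h * h) @ (s * (1.0 - s)))
        if abs(grad) < 1e-10:
            break
        step = grad / hess if hess > 1e-12 else np.sign(grad) * 1.0
        g -= step
        g = float(np.clip(g, -1e3, 1e3))
    return g


# ---------------------------------------------------------------------------
# boosting


@dataclass
class BoostedEnsemble:
    """Additive model F(x) = F0 + sum_m nu * g_m * h_m(x)."""

    F0: float
    stages: list[tuple[RegressionTree, float]]
    loss: Loss
    learning_rate: float
    train_loss_: list[float] = field(default_factory=list)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        F = np.full(X.shape[0], self.F0)
        for tree, gamma in self.stages:
            F += self.learning_rate * gamma * tree.predict(X)
        return F

    def save(self, path: str | Path) -> None:
        payload = {
            "F0": self.F0,
            "loss": self.loss,
            "learning_rate": self.learning_rate,
            "train_loss": self.train_loss_,
            "stages": [
                {"gamma": g, "max_depth": t.max_depth,
                 "min_samples_leaf": t.min_samples_leaf, "tree": t.root.to_dict()}
                for t, g in self.stages
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "BoostedEnsemble":
        with open(path) as fh:
            d = json.load(fh)
        stages = [
            (
                RegressionTree(
                    root=_Node.from_dict(s["tree"]),
                    max_depth=s["max_depth"],
                    min_samples_leaf=s["min_samples_leaf"],
                ),
                float(s["gamma"]),
            )
            for s in d["stages"]
        ]
        return cls(F0=float(d["F0"]), stages=stages, loss=d["loss"],
                   learning_rate=float(d["learning_rate"]),
                   train_loss_=list(d.get("train_loss", [])))


def fit(
    X: np.ndarray,
    y: np.ndarray,
    n_stages: int = 300,
    learning_rate: float = 0.1,
    max_depth: int = 3,
    min_samples_leaf: int = 5,
    loss: Loss = "logistic",
    seed: int | None = None,  # reserved: no stochastic subsampling is used
) -> BoostedEnsemble:
    """Stage-wise boosting; training loss is checked to be non-increasing.

    With the step size chosen by exact line search and the loss convex in
    the score, every shrunken update (0 < nu <= 1) cannot increase the
    training loss; a tiny floating-point slack is allowed in the check.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    if loss == "logistic" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("logistic loss requires binary 0/1 labels")
    F0 = init_constant(y, loss)
    F = np.full(y.shape[0], F0)
    model = BoostedEnsemble(F0=F0, stages=[], loss=loss, learning_rate=learning_rate)
    prev_loss = loss_value(y, F, loss)
    model.train_loss_.append(prev_loss)
    presorted = np.argsort(X, axis=0, kind="stable")
    for _ in range(n_stages):
        r = pseudo_residuals(y, F, loss)
        tree = fit_tree(X, r, max_depth=max_depth,
                        min_samples_leaf=min_samples_leaf, presorted=presorted)
        h = tree.predict(X)
        gamma = line_search(y, F, h, loss)
        F = F + learning_rate * gamma * h
        cur = loss_value(y, F, loss)
        if cur > prev_loss + 1e-9 * max(1.0, abs(prev_loss)):
            raise AssertionError(
                f"training loss increased at stage {len(model.stages)}: "
                f"{prev_loss} -> {cur}"
            )
        model.stages.append((tree, gamma))
        model.train_loss_.append(cur)
        prev_loss = cur
    return model


def predict_proba(model: BoostedEnsemble, X: np.ndarray) -> np.ndarray:
    """P(label=1 | x); sigmoid of the additive score under logistic loss."""
    F = model.decision_function(X)
    if model.loss == "logistic":
        return _sigmoid(F)
    return np.clip(F, 0.0, 1.0)
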