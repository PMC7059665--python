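"""Soft-margin RBF support vector classification, solved from scratch.

The binary machine solves the usual dual quadratic program

    min  (1/2) a' Q a - e' a       Q_ij = y_i y_j K(x_i, x_j)
    s.t. y' a = 0,  0 <= a_i <= C

with K(u, v) = exp(-gamma ||u - v||^2), via two-variable working-set
ascent (SMO with maximal-violating-pair selection).  Multiclass problems
use a one-vs-one ensemble with majority voting, and the penalty C and
kernel width gamma are tuned by a log-decade grid search scored on a held
out validation set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "rbf_kernel", "BinarySVCModel", "solve_binary_svc", "decision_value",
    "dual_objective",
    "RBFSupportVectorClassifier", "train_multiclass_svc", "predict",
    "GridSearchResult", "grid_search", "default_grid",
    "ConvergenceError", "save_svc", "load_svc",
]

_TAU = 1e-12  # floor for non-positive-definite working-set curvature


class ConvergenceError(RuntimeError):
    pass


def rbf_kernel(u: np.ndarray, v: np.ndarray, gamma: float) -> np.ndarray:
    """K(u, v) = exp(-gamma * ||u - v||^2); scalar for two vectors."""
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    u = np.atleast_2d(np.asarray(u, dtype=float))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if u.shape[1] != v.shape[1]:
        raise ValueError(f"dimension mismatch: {u.shape[1]} vs {v.shape[1]}")
    K = np.exp(-gamma * cdist(u, v, "sqeuclidean"))
    return K[0, 0] if K.shape == (1, 1) else K


@dataclass
class BinarySVCModel:
    """One trained soft-margin RBF machine for a label pair.

    ``class_pair`` maps (positive, negative) labels to (+1, -1);
    ``dual_coef`` holds alpha_i * y_i for the support vectors.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    bias: float
    gamma: float
    cost: float
    class_pair: tuple
    alpha: np.ndarray = field(default=None, repr=False)  # full alpha (diagnostics)
    kkt_violation: float = np.nan
    n_iter: int = 0

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.support_vectors.shape[1]:
            raise ValueError(
                f"dimension mismatch: {X.shape[1]} vs "
                f"{self.support_vectors.shape[1]}")
        K = np.exp(-self.gamma * cdist(X, self.support_vectors, "sqeuclidean"))
        return K @ self.dual_coef + self.bias


def _smo(Q: np.ndarray, y: np.ndarray, C: float, tol: float,
         max_iter: int) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Maximal-violating-pair SMO on the dual; returns (alpha, G, gap, iters)."""
    n = len(y)
    alpha = np.zeros(n)
    G = -np.ones(n)  # gradient of (1/2)a'Qa - e'a at a = 0
    eps = 1e-12
    for it in range(1, max_iter + 1):
        up = ((y > 0) & (alpha < C - eps)) | ((y < 0) & (alpha > eps))
        low = ((y < 0) & (alpha < C - eps)) | ((y > 0) & (alpha > eps))
        vals = -y * G
        m_val = np.max(np.where(up, vals, -np.inf))
        M_val = np.min(np.where(low, vals, np.inf))
        gap = m_val - M_val
        if gap <= tol:
            return alpha, G, max(gap, 0.0), it - 1
        i = int(np.argmax(np.where(up, vals, -np.inf)))
        j = int(np.argmin(np.where(low, vals, np.inf)))

        ai_old, aj_old = alpha[i], alpha[j]
        if y[i] != y[j]:
            quad = Q[i, i] + Q[j, j] + 2 * Q[i, j]
            quad = quad if quad > _TAU else _TAU
            delta = (-G[i] - G[j]) / quad
            diff = ai_old - aj_old
            ai, aj = ai_old + delta, aj_old + delta
            if diff > 0:
                if aj < 0:
                    aj, ai = 0.0, diff
            else:
                if ai < 0:
                    ai, aj = 0.0, -diff
            if diff > 0:
                if ai > C:
                    ai, aj = C, C - diff
            else:
                if aj > C:
                    aj, ai = C, C + diff
        else:
            quad = Q[i, i] + Q[j, j] - 2 * Q[i, j]
            quad = quad if quad > _TAU else _TAU
            delta = (G[i] - G[j]) / quad
            total = ai_old + aj_old
            ai, aj = ai_old - delta, aj_old + delta
            if total > C:
                if ai > C:
                    ai, aj = C, total - C
                if aj > C:
                    aj, ai = C, total - C
            else:
                if aj < 0:
                    aj, ai = 0.0, total
                if ai < 0:
                    ai, aj = 0.0, total
        alpha[i], alpha[j] = ai, aj
        G += Q[:, i] * (ai - ai_old) + Q[:, j] * (aj - aj_old)
    # re-evaluate the gap for the error message
    up = ((y > 0) & (alpha < C - eps)) | ((y < 0) & (alpha > eps))
    low = ((y < 0) & (alpha < C - eps)) | ((y > 0) & (alpha > eps))
    vals = -y * G
    gap = np.max(np.where(up, vals, -np.inf)) - np.min(np.where(low, vals, np.inf))
    raise ConvergenceError(
        f"SMO did not reach tolerance {tol} within {max_iter} iterations "
        f"(KKT violation {gap:.3g})")


def solve_binary_svc(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
                     tol: float = 1e-3, max_iter: int | None = None,
                     class_pair: tuple = (1, -1),
                     kernel_matrix: np.ndarray | None = None) -> BinarySVCModel:
    """Train one binary machine; ``y`` must be in {-1, +1}.

    The bias is the mean of ``y_i - sum_j a_j y_j K(x_j, x_i)`` over free
    support vectors (0 < alpha < C); with no free vector it is the midpoint
    of the interval the bound vectors allow.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("y must contain only -1/+1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if C <= 0 or gamma <= 0:
        raise ValueError("C and gamma must be > 0")
    n = len(y)
    if max_iter is None:
        max_iter = 10_000 * n
    K = kernel_matrix if kernel_matrix is not None else rbf_kernel(X, X, gamma)
    Q = (y[:, None] * y[None, :]) * K
    alpha, G, gap, n_iter = _smo(Q, y, C, tol, max_iter)

    vals = -y * G  # equals y_i - f0(x_i) at each training point
    free = (alpha > 1e-8 * C) & (alpha < C * (1 - 1e-8))
    if free.any():
        bias = float(vals[free].mean())
    else:
        eps = 1e-12
        up = ((y > 0) & (alpha < C - eps)) | ((y < 0) & (alpha > eps))
        low = ((y < 0) & (alpha < C - eps)) | ((y > 0) & (alpha > eps))
        hi = np.max(np.where(up, vals, -np.inf))
        lo = np.min(np.where(low, vals, np.inf))
        bias = float((hi + lo) / 2)

    sv = alpha > 1e-12 * max(C, 1.0)
    return BinarySVCModel(
        support_vectors=X[sv].copy(),
        dual_coef=(alpha * y)[sv],
        bias=bias,
        gamma=gamma,
        cost=C,
        class_pair=class_pair,
        alpha=alpha,
        kkt_violation=gap,
        n_iter=n_iter,
    )


def decision_value(model: BinarySVCModel, x: np.ndarray) -> float | np.ndarray:
    """Pre-sign decision value sum_i a_i y_i K(sv_i, x) + b."""
    x = np.asarray(x, dtype=float)
    out = model.decision_function(x)
    return float(out[0]) if x.ndim == 1 else out


def dual_objective(model: BinarySVCModel, X: np.ndarray, y: np.ndarray) -> float:
    """(1/2) a'Qa - e'a of the stored solution on its training data."""
    y = np.asarray(y, dtype=float)
    K = rbf_kernel(X, X, model.gamma)
    Q = (y[:, None] * y[None, :]) * K
    a = model.alpha
    return float(0.5 * a @ Q @ a - a.sum())


class RBFSupportVectorClassifier(ClassifierMixin, BaseEstimator):
    """One-vs-one multiclass soft-margin SVC with an RBF kernel.

    Parameters
    ----------
    C : float
        Penalty assigned to margin violations.
    gamma : float
        RBF kernel width parameter.
    tol : float
        KKT tolerance of the SMO solver.
    max_iter : int or None
        Iteration cap per binary machine (default ``10_000 * n``).

    Attributes
    ----------
    classes_ : sorted unique training labels.
    machines_ : dict mapping each unordered label pair ``(a, b)`` with
        ``a < b`` to its :class:`BinarySVCModel` (``a`` is the +1 class).
    """

    def __init__(self, C: float = 1.0, gamma: float = 1.0, tol: float = 1e-3,
                 max_iter: int | None = None):
        self.C = C
        self.gamma = gamma
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        counts = {c: int((y == c).sum()) for c in self.classes_}
        empty = [c for c, n in counts.items() if n < 1]
        if empty:
            raise ValueError(f"empty classes: {empty}")
        self.machines_ = {}
        for a, b in itertools.combinations(self.classes_, 2):
            sel = (y == a) | (y == b)
            yy = np.where(y[sel] == a, 1.0, -1.0)
            self.machines_[(a, b)] = solve_binary_svc(
                X[sel], yy, self.C, self.gamma, tol=self.tol,
                max_iter=self.max_iter, class_pair=(a, b))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        """Majority vote over pairwise machines.

        Ties break toward the tied label with the largest summed
        |decision value| over the machines it won, then toward the
        smallest label value.
        """
        check_is_fitted(self, "machines_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = len(X)
        classes = list(self.classes_)
        votes = np.zeros((n, len(classes)), dtype=int)
        conf = np.zeros((n, len(classes)))
        for (a, b), machine in self.machines_.items():
            dv = machine.decision_function(X)
            ia, ib = classes.index(a), classes.index(b)
            win_a = dv >= 0
            votes[win_a, ia] += 1
            votes[~win_a, ib] += 1
            conf[win_a, ia] += np.abs(dv[win_a])
            conf[~win_a, ib] += np.abs(dv[~win_a])
        out = np.empty(n, dtype=self.classes_.dtype)
        for r in range(n):
            best = votes[r].max()
            tied = np.where(votes[r] == best)[0]
            if len(tied) > 1:
                best_conf = conf[r, tied].max()
                tied = tied[conf[r, tied] >= best_conf - 1e-12]
            out[r] = classes[int(tied.min())]  # classes_ sorted ascending
        return out


def train_multiclass_svc(X: np.ndarray, labels: np.ndarray, C: float,
                         gamma: float, tol: float = 1e-3) -> RBFSupportVectorClassifier:
    return RBFSupportVectorClassifier(C=C, gamma=gamma, tol=tol).fit(X, labels)


def predict(model: RBFSupportVectorClassifier, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def default_grid(n_min: int = -8, n_max: int = 8) -> list[tuple[float, float]]:
    """Log-decade (C, gamma) grid: {10^N} x {10^N}, N = n_min..n_max."""
    decades = [10.0 ** n for n in range(n_min, n_max + 1)]
    return [(c, g) for c in decades for g in decades]


@dataclass
class GridSearchResult:
    """Grid of (C, gamma) cells with accuracies and the selected model."""

    table: pd.DataFrame  # columns: C, gamma, train_accuracy, val_accuracy
    best_C: float
    best_gamma: float
    best_model: RBFSupportVectorClassifier
    best_train_accuracy: float
    best_val_accuracy: float


def grid_search(train: tuple[np.ndarray, np.ndarray],
                validation: tuple[np.ndarray, np.ndarray],
                grid: list[tuple[float, float]] | None = None,
                tol: float = 1e-3) -> GridSearchResult:
    """Train one one-vs-one model per (C, gamma) cell and pick the best.

    Selection: highest validation accuracy, ties broken by higher training
    accuracy, then smaller C, then smaller gamma.
    """
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValueError("grid must be non-empty")
    X_tr, y_tr = train
    X_val, y_val = validation
    rows = []
    best = None
    best_key = None
    for C, gamma in grid:
        try:
            model = RBFSupportVectorClassifier(C=C, gamma=gamma, tol=tol
                                               ).fit(X_tr, y_tr)
        except ConvergenceError as exc:
            raise ConvergenceError(f"grid cell (C={C}, gamma={gamma}): {exc}") from exc
        train_acc = float((model.predict(X_tr) == y_tr).mean())
        val_acc = float((model.predict(X_val) == y_val).mean())
        rows.append({"C": C, "gamma": gamma,
                     "train_accuracy": train_acc, "val_accuracy": val_acc})
        key = (val_acc, train_acc, -C, -gamma)
        if best_key is None or key > best_key:
            best_key = key
            best = (C, gamma, model, train_acc, val_acc)
    table = pd.DataFrame(rows)
    C, gamma, model, train_acc, val_acc = best
    return GridSearchResult(table=table, best_C=C, best_gamma=gamma,
                            best_model=model, best_train_accuracy=train_acc,
                            best_val_accuracy=val_acc)


def save_svc(model: RBFSupportVectorClassifier, path) -> None:
    """Serialize a fitted one-vs-one ensemble to a flat text file."""
    check_is_fitted(model, "machines_")
    with open(path, "w") as fh:
        fh.write(f"C: {model.C:.17g}\n")
        fh.write(f"gamma: {model.gamma:.17g}\n")
        fh.write(f"n_features: {model.n_features_in_}\n")
        fh.write("classes: " + " ".join(str(c) for c in model.classes_) + "\n")
        for (a, b), m in model.machines_.items():
            fh.write(f"machine: {a} {b}\n")
            fh.write(f"bias: {m.bias:.17g}\n")
            fh.write("dual_coef: " + " ".join(f"{v:.17g}" for v in m.dual_coef)
                     + "\n")
            for row in m.support_vectors:
                fh.write("sv: " + " ".join(f"{v:.17g}" for v in row) + "\n")


def load_svc(path) -> RBFSupportVectorClassifier:
    from pathlib import Path

    lines = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    machines: list[dict] = []
    for line in lines:
        key, _, value = line.partition(":")
        value = value.strip()
        if key == "machine":
            a, b = value.split()
            machines.append({"pair": (int(a), int(b)), "svs": []})
        elif key == "bias":
            machines[-1]["bias"] = float(value)
        elif key == "dual_coef":
            machines[-1]["dual_coef"] = np.array([float(v) for v in value.split()])
        elif key == "sv":
            machines[-1]["svs"].append([float(v) for v in value.split()])
        else:
            header[key] = value
    model = RBFSupportVectorClassifier(C=float(header["C"]),
                                       gamma=float(header["gamma"]))
    model.classes_ = np.array([int(c) for c in header["classes"].split()])
    model.n_features_in_ = int(header["n_features"])
    model.machines_ = {}
    for m in machines:
        model.machines_[m["pair"]] = BinarySVCModel(
            support_vectors=np.array(m["svs"]),
            dual_coef=m["dual_coef"],
            bias=m["bias"],
            gamma=model.gamma,
            cost=model.C,
            class_pair=m["pair"],
        )
    return model
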