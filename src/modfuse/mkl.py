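"""Multiple kernel learning with simplex-constrained kernel weights.

Solves the SimpleMKL-style problem for binary classification,

    min_{beta, w, b}  sum_m ||w_m||^2 / (2 beta_m) + C sum_i hinge_i
    s.t.              beta_m >= 0,  ||beta||_1 <= 1,

where each basis kernel ``m`` is a linear kernel on a group of feature
coordinates (default: one singleton group per feature, so the learned
``beta`` is a per-feature relevance profile).  The convention 0/0 -> 0
applies: a kernel with ``beta_m = 0`` contributes ``w_m = 0``.

The solver alternates (i) an exact soft-margin SVM on the composite kernel
``sum_m beta_m K_m`` at fixed ``beta`` with (ii) the closed-form update
``beta_m = ||w_m||_2 / sum_k ||w_k||_2``, which is the minimizer of the
first term over the l1 simplex at fixed ``w``.  Both half-steps decrease
the objective, so the recorded objective trace is non-increasing; a step
that fails to decrease it (numerically exhausted) terminates the loop with
the previous iterate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC


def _singleton_groups(d: int) -> list[np.ndarray]:
    return [np.array([j]) for j in range(d)]


@dataclass
class MKLProblem:
    """Binary MKL problem: data, labels in {-1,+1}, cost C, feature groups."""

    X: np.ndarray
    y: np.ndarray
    C: float = 1.0
    groups: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y, float)
        if self.X.ndim != 2 or self.y.shape != (self.X.shape[0],):
            raise ValueError("X must be (N, d) with matching y")
        if set(np.unique(self.y)) != {-1.0, 1.0}:
            raise ValueError("y must contain both labels -1 and +1")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        d = self.X.shape[1]
        if self.groups is None:
            self.groups = _singleton_groups(d)
        else:
            self.groups = [np.asarray(g, int) for g in self.groups]
            cat = np.concatenate(self.groups) if self.groups else np.array([], int)
            if sorted(cat.tolist()) != list(range(d)):
                raise ValueError("groups must partition the feature indices")


@dataclass
class MKLModel:
    """Fitted MKL model: kernel weights, per-group primal weights, bias."""

    beta: np.ndarray
    w_groups: list[np.ndarray]
    b: float
    groups: list[np.ndarray]
    objective_trace: list[float] = field(default_factory=list)

    @property
    def feature_weights(self) -> np.ndarray:
        """Per-feature |w| expanded to the original feature layout."""
        d = 1 + max(int(g.max()) for g in self.groups)
        v = np.zeros(d)
        for g, w in zip(self.groups, self.w_groups):
            v[g] = np.abs(w)
        return v

    @property
    def coef(self) -> np.ndarray:
        """Concatenated primal weight vector in original feature order."""
        d = 1 + max(int(g.max()) for g in self.groups)
        v = np.zeros(d)
        for g, w in zip(self.groups, self.w_groups):
            v[g] = w
        return v

    def to_json(self, path: str | Path) -> None:
        obj = {
            "beta": self.beta.tolist(),
            "w_groups": [w.tolist() for w in self.w_groups],
            "b": self.b,
            "groups": [g.tolist() for g in self.groups],
            "objective_trace": self.objective_trace,
        }
        Path(path).write_text(json.dumps(obj))


def mkl_objective(problem: MKLProblem, beta, w_groups, b) -> float:
    """Evaluate the MKL objective; groups with beta_m = 0 contribute 0/0 -> 0."""
    reg = 0.0
    for bm, wm in zip(beta, w_groups):
        n2 = float(wm @ wm)
        if bm > 0:
            reg += n2 / (2.0 * bm)
        elif n2 > 0:
            return np.inf
    scores = _decision(problem.X, w_groups, b, problem.groups)
    hinge = np.maximum(0.0, 1.0 - problem.y * scores).sum()
    return reg + problem.C * hinge


def _decision(X, w_groups, b, groups) -> np.ndarray:
    s = np.full(X.shape[0], float(b))
    for g, w in zip(groups, w_groups):
        s += X[:, g] @ w
    return s


def _svm_step(problem: MKLProblem, beta: np.ndarray, svm_tol: float):
    """Exact SVM on the composite kernel; returns (w_groups, b)."""
    scale = np.zeros(problem.X.shape[1])
    for bm, g in zip(beta, problem.groups):
        scale[g] = np.sqrt(max(bm, 0.0))
    Xs = problem.X * scale  # composite kernel = Xs Xs^T
    K = Xs @ Xs.T
    svc = SVC(kernel="precomputed", C=problem.C, tol=svm_tol, shrinking=False)
    svc.fit(K, problem.y)
    alpha_y = np.zeros(problem.X.shape[0])
    alpha_y[svc.support_] = svc.dual_coef_.ravel()  # already y_i * alpha_i
    w_groups = [
        bm * (problem.X[:, g].T @ alpha_y) for bm, g in zip(beta, problem.groups)
    ]
    return w_groups, float(svc.intercept_[0])


def mkl_fit(
    problem: MKLProblem,
    tol: float = 1e-6,
    max_iter: int = 100,
    svm_tol: float = 1e-8,
) -> MKLModel:
    """Alternating SVM / kernel-weight optimization of the MKL objective."""
    M = len(problem.groups)
    beta = np.full(M, 1.0 / M)
    w_groups, b = _svm_step(problem, beta, svm_tol)
    obj = mkl_objective(problem, beta, w_groups, b)
    trace = [obj]
    best = (beta.copy(), [w.copy() for w in w_groups], b)
    for _ in range(max_iter):
        norms = np.array([np.linalg.norm(w) for w in w_groups])
        total = norms.sum()
        if total <= 0:
            break  # all-zero solution; beta is immaterial
        beta_new = norms / total
        w_new, b_new = _svm_step(problem, beta_new, svm_tol)
        obj_new = mkl_objective(problem, beta_new, w_new, b_new)
        if obj_new >= obj:
            break  # numerically exhausted: keep previous iterate
        beta, w_groups, b = beta_new, w_new, b_new
        best = (beta.copy(), [w.copy() for w in w_groups], b)
        trace.append(obj_new)
        if obj - obj_new < tol:
            obj = obj_new
            break
        obj = obj_new
    beta, w_groups, b = best
    return MKLModel(beta=beta, w_groups=w_groups, b=b, groups=problem.groups,
                    objective_trace=trace)


def mkl_predict(model: MKLModel, X_new: np.ndarray) -> np.ndarray:
    """Real-valued decision scores ``sum_m w_m^T x[G_m] + b``; sign = label."""
    X_new = np.asarray(X_new, float)
    d = 1 + max(int(g.max()) for g in model.groups)
    if X_new.ndim != 2 or X_new.shape[1] != d:
        raise ValueError(f"expected {d} feature columns, got {X_new.shape}")
    return _decision(X_new, model.w_groups, model.b, model.groups)
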