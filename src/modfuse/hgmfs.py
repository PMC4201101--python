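"""High-order graph-matching regularized feature selection (HGM-FS).

Extends the LASSO regression of multi-output targets by two geometric
consistency penalties that ask the predicted vectors ``W^T x_i`` not only
to approximate the targets ``y_i`` but to be *distributed* like them:

* a pairwise term ``B = sum_{i,j} ||(y_i - y_j) - W^T(x_i - x_j)||_F^2``
  matching all difference vectors, and
* a triplet term
  ``T = sum_{i,j,k} ||(y_i - y_j)^T (y_j - y_k)
                     - (x_i - x_j)^T W W^T (x_j - x_k)||_F^2``
  matching the inner products of consecutive difference vectors over all
  ordered triples (repeated indices included; their contributions are well
  defined and often zero).

Full objective, minimized over the coefficient matrix ``W`` (d x L):

    F(W) = ||W^T X - Y||_F^2 + lam1 ||W||_1 + lam2 B + lam3 T

with ``||W||_1`` the entrywise sum of absolute values.  Features whose row
of ``W`` carries any coefficient above a small threshold are selected.

Both penalties admit closed forms: ``B = 2N ||R H||_F^2`` for the residual
``R = Y - W^T X`` and the centering projector ``H = I - (1/N) 11^T``; and
``T`` is a quartic polynomial in ``W`` that collapses to O(N^2) statistics
of the matrix ``M = Y^T Y - X^T W W^T X`` (derivation mirrored by the
explicit triple-loop path used at small N).  The solver is a monotone
FISTA: accelerated proximal gradient with backtracking line search and a
fallback to the plain proximal step whenever the extrapolated step fails
to decrease the objective, so the objective trace is non-increasing even
though the triplet term makes the problem nonconvex.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Above this many samples the triplet term switches from the explicit
#: all-triples evaluation to the O(N^2) closed form (they agree to
#: round-off; the closed form avoids the N^3 intermediate).
TRIPLET_LOOP_MAX_N = 60


@dataclass
class HGMFSProblem:
    """Regression-based selection problem: X (d x N), Y (L x N), penalties."""

    X: np.ndarray
    Y: np.ndarray
    lambdas: tuple[float, float, float] = (0.1, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.Y = np.asarray(self.Y, float)
        if self.Y.ndim == 1:
            self.Y = self.Y[None, :]
        if self.X.ndim != 2 or self.Y.ndim != 2 or self.X.shape[1] != self.Y.shape[1]:
            raise ValueError("X (d x N) and Y (L x N) must share column count")
        if any(l < 0 for l in self.lambdas):
            raise ValueError("lambdas must be >= 0")


@dataclass
class HGMFSModel:
    """Fitted HGM-FS model with selection threshold already applied."""

    W: np.ndarray
    objective_trace: list[float]
    select_tol: float = 1e-6

    @property
    def selected(self) -> np.ndarray:
        """Indices of features with any coefficient above ``select_tol``."""
        return np.flatnonzero(np.abs(self.W).max(axis=1) > self.select_tol)

    @property
    def feature_weights(self) -> np.ndarray:
        """Row-wise l2 norms of W — the per-feature weight profile."""
        return np.linalg.norm(self.W, axis=1)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "W": self.W.tolist(),
                    "objective_trace": self.objective_trace,
                    "select_tol": self.select_tol,
                }
            )
        )


# ---------------------------------------------------------------------------
# Penalty terms
# ---------------------------------------------------------------------------

def pairwise_term(W: np.ndarray, X: np.ndarray, Y: np.ndarray) -> float:
    """``B = sum_{i,j} ||(y_i - y_j) - W^T (x_i - x_j)||^2``, closed form.

    Equals ``2 N ||R H||_F^2`` with ``R = Y - W^T X`` column-centered by
    ``H = I - 11^T/N`` (expand the double sum and cancel cross terms).
    """
    W, X, Y = (np.asarray(a, float) for a in (W, X, Y))
    if Y.ndim == 1:
        Y = Y[None, :]
    _check_shapes(W, X, Y)
    N = X.shape[1]
    R = Y - W.T @ X
    Rc = R - R.mean(axis=1, keepdims=True)
    return 2.0 * N * float((Rc**2).sum())


def pairwise_term_loop(W: np.ndarray, X: np.ndarray, Y: np.ndarray) -> float:
    """Literal double-loop evaluation of B (reference path, O(N^2 d L))."""
    W, X, Y = (np.asarray(a, float) for a in (W, X, Y))
    if Y.ndim == 1:
        Y = Y[None, :]
    _check_shapes(W, X, Y)
    N = X.shape[1]
    R = Y - W.T @ X  # (y_i - y_j) - W^T(x_i - x_j) = r_i - r_j
    total = 0.0
    for i in range(N):
        for j in range(N):
            diff = R[:, i] - R[:, j]
            total += float(diff @ diff)
    return total


def _check_shapes(W, X, Y) -> None:
    d, N = X.shape
    L = Y.shape[0]
    if W.shape != (d, L) or Y.shape[1] != N:
        raise ValueError(
            f"inconsistent shapes: W{W.shape}, X{X.shape}, Y{Y.shape}"
        )


def _triplet_from_M(M: np.ndarray) -> float:
    """Closed form of ``sum_{ijk} (M_ij - M_ik - M_jj + M_jk)^2`` in O(N^2)."""
    N = M.shape[0]
    r = M.sum(axis=1)
    c = M.sum(axis=0)
    dg = np.diag(M).copy()
    S1 = float(M.sum())
    S2 = float((M**2).sum())
    MM_total = float(r @ c)  # 1^T M M 1 = (row sums) . (col sums)
    return (
        3.0 * N * S2
        + N * N * float(dg @ dg)
        - 2.0 * float(r @ r)
        - 2.0 * N * float(c @ dg)
        + 2.0 * MM_total
        + 2.0 * S1 * float(dg.sum())
        - 2.0 * float(c @ c)
        - 2.0 * N * float(dg @ r)
    )


def _triplet_tensor(M: np.ndarray) -> float:
    """All ordered triples, evaluated explicitly (reference path, O(N^3))."""
    A = (
        M[:, :, None]
        - M[:, None, :]
        - np.diag(M)[None, :, None]
        + M[None, :, :]
    )
    return float((A**2).sum())


def triplet_term(W: np.ndarray, X: np.ndarray, Y: np.ndarray) -> float:
    """``T = sum_{i,j,k} ((y_i-y_j)^T(y_j-y_k) - (x_i-x_j)^T W W^T (x_j-x_k))^2``.

    All ordered triples (i, j, k), repeated indices included.  Writing
    ``M = Y^T Y - (W^T X)^T (W^T X)`` the summand is
    ``(M_ij - M_ik - M_jj + M_jk)^2``; small problems evaluate the triple
    sum explicitly, larger ones the algebraically identical O(N^2) form.
    """
    W, X, Y = (np.asarray(a, float) for a in (W, X, Y))
    if Y.ndim == 1:
        Y = Y[None, :]
    _check_shapes(W, X, Y)
    S = W.T @ X
    M = Y.T @ Y - S.T @ S
    N = M.shape[0]
    if N <= TRIPLET_LOOP_MAX_N:
        return _triplet_tensor(M)
    return _triplet_from_M(M)


def _triplet_grad_M(M: np.ndarray) -> np.ndarray:
    """Gradient of the triplet polynomial with respect to the entries of M."""
    N = M.shape[0]
    r = M.sum(axis=1)
    c = M.sum(axis=0)
    dg = np.diag(M).copy()
    S1 = float(M.sum())
    tr = float(dg.sum())
    ones = np.ones(N)
    G = 6.0 * N * M
    G += 2.0 * N * N * np.diag(dg)
    G -= 4.0 * np.outer(r, ones)
    G -= 2.0 * N * (np.outer(ones, dg) + np.diag(c))
    G += 2.0 * (np.outer(ones, r) + np.outer(c, ones))
    G += 2.0 * (tr * np.ones((N, N)) + S1 * np.eye(N))
    G -= 4.0 * np.outer(ones, c)
    G -= 2.0 * N * (np.diag(r) + np.outer(dg, ones))
    return G


def smooth_value_grad(
    W: np.ndarray, problem: HGMFSProblem
) -> tuple[float, np.ndarray]:
    """Value and gradient of the smooth part ``fit + lam2 B + lam3 T``."""
    X, Y = problem.X, problem.Y
    _, lam2, lam3 = problem.lambdas
    N = X.shape[1]
    E = W.T @ X - Y  # L x N residual
    val = float((E**2).sum())
    grad = 2.0 * X @ E.T
    if lam2 > 0:
        Ec = E - E.mean(axis=1, keepdims=True)
        val += lam2 * 2.0 * N * float((Ec**2).sum())
        grad += lam2 * 4.0 * N * (X @ Ec.T)
    if lam3 > 0:
        S = W.T @ X
        M = Y.T @ Y - S.T @ S
        val += lam3 * (
            _triplet_tensor(M) if N <= TRIPLET_LOOP_MAX_N else _triplet_from_M(M)
        )
        G = _triplet_grad_M(M)
        grad += lam3 * (-(X @ (G + G.T) @ X.T @ W))
    return val, grad


def hgmfs_objective(W: np.ndarray, problem: HGMFSProblem) -> float:
    val, _ = smooth_value_grad(W, problem)
    return val + problem.lambdas[0] * float(np.abs(W).sum())


def _soft(A: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(A) * np.maximum(np.abs(A) - thr, 0.0)


def hgmfs_fit(
    problem: HGMFSProblem,
    select_tol: float = 1e-6,
    max_iter: int = 500,
    tol: float = 1e-8,
    rtol: float = 0.0,
    init_step: float | None = None,
) -> HGMFSModel:
    """Monotone FISTA on the HGM-FS objective, started from ``W = 0``.

    Backtracking halves the step until the local quadratic model upper-
    bounds the smooth part at the candidate, which guarantees a decrease
    of the full objective at every accepted step.  When the accelerated
    (extrapolated) candidate fails to decrease the objective the momentum
    is dropped for that iteration and the step restarts from the current
    iterate, keeping the trace monotone on nonconvex instances.
    """
    lam1 = problem.lambdas[0]
    d, N = problem.X.shape
    L = problem.Y.shape[0]
    W = np.zeros((d, L))
    V = W.copy()  # extrapolated point
    t_mom = 1.0
    obj = hgmfs_objective(W, problem)
    trace = [obj]
    if init_step is None:
        # Lipschitz guess from the fit + pairwise quadratic part
        lead = np.linalg.norm(problem.X, 2) ** 2
        step = 1.0 / (2.0 * lead * (1.0 + 4.0 * N * problem.lambdas[1]) + 1e-12)
        step = max(step, 1e-12)
    else:
        step = init_step

    def prox_step(base: np.ndarray, step: float):
        g, grad = smooth_value_grad(base, problem)
        for _ in range(80):
            cand = _soft(base - step * grad, step * lam1)
            delta = cand - base
            g_cand, _ = smooth_value_grad(cand, problem)
            ub = g + float((grad * delta).sum()) + float((delta**2).sum()) / (2 * step)
            if g_cand <= ub + 1e-12:
                return cand, step
            step *= 0.5
        raise RuntimeError("line search failed to find a decreasing step")

    for _ in range(max_iter):
        cand, step = prox_step(V, step)
        obj_cand = hgmfs_objective(cand, problem)
        if obj_cand > obj:
            # momentum overshoot: plain proximal step from the iterate
            cand, step = prox_step(W, step)
            obj_cand = hgmfs_objective(cand, problem)
            t_mom = 1.0
            if obj_cand > obj:
                break  # no further decrease possible at machine precision
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        V = cand + ((t_mom - 1.0) / t_new) * (cand - W)
        W = cand
        t_mom = t_new
        trace.append(obj_cand)
        decrease = obj - obj_cand
        obj = obj_cand
        step *= 1.25  # allow the step to grow back after backtracking
        if decrease < max(tol, rtol * abs(trace[0])):
            break
    return HGMFSModel(W=W, objective_trace=trace, select_tol=select_tol)
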