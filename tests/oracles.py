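"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (explicit loops, generic
optimizers) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from sklearn.svm import SVC


# ---------------------------------------------------------------------------
# Unsupervised scores
# ---------------------------------------------------------------------------

def laplacian_score_bruteforce(X: np.ndarray, sigma: float) -> np.ndarray:
    """Dense-matrix evaluation of the Laplacian score, feature by feature."""
    X = np.asarray(X, float)
    d, N = X.shape
    W = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            diff = X[:, i] - X[:, j]
            W[i, j] = np.exp(-(diff @ diff) / sigma)
    D = np.diag(W.sum(axis=1))
    L = D - W
    out = np.zeros(d)
    for k in range(d):
        num = X[k] @ L @ X[k]
        den = X[k] @ D @ X[k]
        out[k] = num / den if den > 0 else 0.0
    return np.maximum(out, 0.0)


def lgd_score_bruteforce(X: np.ndarray, m: int, eps: float = 1e-8) -> np.ndarray:
    """Double-loop evaluation of the local-global variance-ratio score."""
    X = np.asarray(X, float)
    d, N = X.shape
    out = np.zeros(d)
    for k in range(d):
        v = X[k]
        num = sum((v[i] - v.mean()) ** 2 for i in range(N))
        den = 0.0
        for j in range(N):
            order = sorted(range(N), key=lambda i: (abs(v[i] - v[j]), i))
            nbr = order[:m]
            mu = sum(v[i] for i in nbr) / m
            den += sum((v[i] - mu) ** 2 for i in nbr)
        out[k] = num / (den + eps)
    return out


# ---------------------------------------------------------------------------
# HGM-FS terms
# ---------------------------------------------------------------------------

def pairwise_bruteforce(W, X, Y) -> float:
    W, X, Y = (np.asarray(a, float) for a in (W, X, Y))
    if Y.ndim == 1:
        Y = Y[None, :]
    N = X.shape[1]
    total = 0.0
    for i in range(N):
        for j in range(N):
            diff = (Y[:, i] - Y[:, j]) - W.T @ (X[:, i] - X[:, j])
            total += float(diff @ diff)
    return total


def triplet_bruteforce(W, X, Y) -> float:
    W, X, Y = (np.asarray(a, float) for a in (W, X, Y))
    if Y.ndim == 1:
        Y = Y[None, :]
    N = X.shape[1]
    G = W @ W.T
    total = 0.0
    for i in range(N):
        for j in range(N):
            for k in range(N):
                a = (Y[:, i] - Y[:, j]) @ (Y[:, j] - Y[:, k])
                b = (X[:, i] - X[:, j]) @ G @ (X[:, j] - X[:, k])
                total += (a - b) ** 2
    return total


def hgmfs_objective_bruteforce(W, X, Y, lambdas) -> float:
    W, X, Y = (np.asarray(a, float) for a in (W, X, Y))
    if Y.ndim == 1:
        Y = Y[None, :]
    l1, l2, l3 = lambdas
    fit = float(((W.T @ X - Y) ** 2).sum())
    return (
        fit
        + l1 * float(np.abs(W).sum())
        + l2 * pairwise_bruteforce(W, X, Y)
        + l3 * triplet_bruteforce(W, X, Y)
    )


def hgmfs_multistart_oracle(X, Y, lambdas, n_starts=50, seed=0) -> float:
    """Best objective over derivative-free minimizations from random inits."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[None, :]
    d, L = X.shape[0], Y.shape[0]
    rng = np.random.default_rng(seed)

    def f(w):
        return hgmfs_objective_bruteforce(w.reshape(d, L), X, Y, lambdas)

    best = f(np.zeros(d * L))
    for _ in range(n_starts):
        w0 = rng.normal(scale=0.5, size=d * L)
        res = minimize(f, w0, method="Powell", options={"maxiter": 4000, "xtol": 1e-8})
        best = min(best, float(res.fun))
    return best


# ---------------------------------------------------------------------------
# SVM / MKL
# ---------------------------------------------------------------------------

def svm_primal_objective(w, b, X, y, C) -> float:
    margins = 1.0 - y * (X @ w + b)
    return 0.5 * float(w @ w) + C * float(np.maximum(margins, 0.0).sum())


def svm_qp_oracle(X, y, C) -> float:
    """Soft-margin linear SVM primal objective via a generic NLP solver."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    N, d = X.shape

    def unpack(z):
        return z[:d], z[d], z[d + 1 :]

    def obj(z):
        w, b, xi = unpack(z)
        return 0.5 * w @ w + C * xi.sum()

    cons = [
        {"type": "ineq", "fun": lambda z: unpack(z)[2]},
        {
            "type": "ineq",
            "fun": lambda z: y * (X @ unpack(z)[0] + unpack(z)[1])
            - 1.0
            + unpack(z)[2],
        },
    ]
    z0 = np.zeros(d + 1 + N)
    z0[d + 1 :] = 1.0
    res = minimize(obj, z0, constraints=cons, method="SLSQP",
                   options={"maxiter": 1000, "ftol": 1e-14})
    return float(res.fun)


def mkl_grid_oracle(X, y, C, groups, n_grid=101, svm_tol=1e-10) -> float:
    """Min over a simplex grid of beta (2 kernels), each solved by an SVM."""
    assert len(groups) == 2
    best = np.inf
    for t in np.linspace(0.0, 1.0, n_grid):
        beta = np.array([t, 1.0 - t])
        scale = np.zeros(X.shape[1])
        for bm, g in zip(beta, groups):
            scale[np.asarray(g)] = np.sqrt(bm)
        Xs = X * scale
        K = Xs @ Xs.T
        svc = SVC(kernel="precomputed", C=C, tol=svm_tol, shrinking=False)
        svc.fit(K, y)
        alpha_y = np.zeros(X.shape[0])
        alpha_y[svc.support_] = svc.dual_coef_.ravel()
        b = float(svc.intercept_[0])
        reg, scores = 0.0, np.full(X.shape[0], b)
        ok = True
        for bm, g in zip(beta, groups):
            g = np.asarray(g)
            wm = bm * (X[:, g].T @ alpha_y)
            scores += X[:, g] @ wm
            n2 = float(wm @ wm)
            if bm > 0:
                reg += n2 / (2 * bm)
            elif n2 > 1e-18:
                ok = False
        if not ok:
            continue
        hinge = float(np.maximum(0.0, 1.0 - y * scores).sum())
        best = min(best, reg + C * hinge)
    return best


# ---------------------------------------------------------------------------
# SMML convex oracle: SLSQP on the exact cone reformulation
# ---------------------------------------------------------------------------

def smml_convex_oracle(blocks, Y, gammas, W_warm=None) -> float:
    """Globally solve the SMML program via slack + second-order-cone
    variables and a generic NLP solver.  Small instances only.

    Runs from a neutral start and, when ``W_warm`` is given, also from
    that point (letting the solver polish or refute it); the best value
    found is returned."""
    X = np.hstack([np.asarray(b, float) for b in blocks])
    Y = np.asarray(Y, float)
    N, d = X.shape
    L = Y.shape[0]
    g1, g2 = gammas
    slices, start = [], 0
    for b in blocks:
        dq = np.asarray(b).shape[1]
        slices.append(slice(start, start + dq))
        start += dq
    K = len(slices)
    nW, nXi, nT, nR = d * L, N * L, K * L, d

    def unpack(z):
        W = z[:nW].reshape(d, L)
        xi = z[nW : nW + nXi].reshape(N, L)
        t = z[nW + nXi : nW + nXi + nT].reshape(K, L)
        r = z[nW + nXi + nT :]
        return W, xi, t, r

    def obj(z):
        W, xi, t, r = unpack(z)
        return xi.sum() + g1 * t.sum() + g2 * r.sum()

    cons = [
        {"type": "ineq", "fun": lambda z: unpack(z)[1].ravel()},
        {
            "type": "ineq",
            "fun": lambda z: (
                unpack(z)[1] - (1.0 - Y.T * (X @ unpack(z)[0]))
            ).ravel(),
        },
        {"type": "ineq", "fun": lambda z: unpack(z)[2].ravel()},
        {
            "type": "ineq",
            "fun": lambda z: np.concatenate(
                [
                    unpack(z)[2][q] ** 2 - (unpack(z)[0][sl] ** 2).sum(axis=0)
                    for q, sl in enumerate(slices)
                ]
            ),
        },
        {"type": "ineq", "fun": lambda z: unpack(z)[3]},
        {
            "type": "ineq",
            "fun": lambda z: unpack(z)[3] ** 2
            - (unpack(z)[0] ** 2).sum(axis=1),
        },
    ]
    starts = []
    z0 = np.zeros(nW + nXi + nT + nR)
    z0[nW : nW + nXi] = 1.5
    z0[nW + nXi :] = 1.0
    starts.append(z0)
    if W_warm is not None:
        W_warm = np.asarray(W_warm, float)
        zw = np.empty_like(z0)
        zw[:nW] = W_warm.ravel()
        zw[nW : nW + nXi] = (
            np.maximum(1.0 - Y.T * (X @ W_warm), 0.0).ravel() + 1e-3
        )
        zw[nW + nXi : nW + nXi + nT] = (
            np.array(
                [np.linalg.norm(W_warm[sl], axis=0) for sl in slices]
            ).ravel()
            + 1e-3
        )
        zw[nW + nXi + nT :] = np.linalg.norm(W_warm, axis=1) + 1e-3
        starts.append(zw)
    best = np.inf
    for z in starts:
        res = minimize(obj, z, constraints=cons, method="SLSQP",
                       options={"maxiter": 1000, "ftol": 1e-14})
        best = min(best, float(res.fun))
    return best
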