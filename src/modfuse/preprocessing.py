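"""Unsupervised feature screening and train-fitted normalization.

Two unsupervised per-feature scores for pre-screening very wide blocks
(in practice the SNP genotype block before the expensive selectors run):

* the Laplacian score, a graph-based criterion that favours features
  varying smoothly over a heat-kernel similarity graph of the samples; and
* a local-global discriminative (LGD) score, the ratio of a feature's
  global variance to the variance within per-sample value neighborhoods —
  large when a feature is locally flat but globally spread out.

Both return a :class:`FeatureScores` whose ranking is descending by score
with ties broken by ascending feature index, so top-k selection is fully
deterministic.

Normalization follows the three train-fitted schemes used in the
classification protocol: per-feature z-scoring (population standard
deviation, i.e. 1/N inside the root), min-max scaling, and scaling each
feature to the l2-norm unit ball over the training rows.  All statistics
are fitted on training rows only and re-applied verbatim to test rows, so
test values may fall outside [0, 1] under min-max — that is intended.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

DEFAULT_EPS = 1e-8

SCHEMES = ("zscore", "minmax", "unitball")


@dataclass(frozen=True)
class LaplacianParams:
    """Heat-kernel bandwidth for the Laplacian score; ``sigma > 0``."""

    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class LGDParams:
    """Neighborhood size (values nearest by magnitude, self included) and
    denominator guard for the LGD score."""

    neighborhood_size: int = 5
    epsilon: float = DEFAULT_EPS

    def __post_init__(self) -> None:
        if self.neighborhood_size < 1:
            raise ValueError("neighborhood_size must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class FeatureScores:
    """Per-feature scores with a deterministic descending ranking."""

    scores: np.ndarray
    ranking: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, float)
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        self.scores = scores
        # stable sort on -scores => ties resolve to ascending feature index
        self.ranking = np.argsort(-scores, kind="stable")

    def to_frame(self, feature_names=None):
        import pandas as pd

        names = (
            list(feature_names)
            if feature_names is not None
            else [str(i) for i in range(self.scores.size)]
        )
        return pd.DataFrame({"feature": names, "score": self.scores})


def heat_kernel_similarity(X: np.ndarray, sigma: float) -> np.ndarray:
    """All-pairs similarity ``W_ij = exp(-||x_i - x_j||^2 / sigma)``.

    ``X`` is features x samples; columns are the sample vectors.
    """
    X = np.asarray(X, float)
    sq = squareform(pdist(X.T, "sqeuclidean")) if X.shape[1] > 1 else np.zeros((1, 1))
    return np.exp(-sq / sigma)


def laplacian_score(
    X: np.ndarray,
    params: LaplacianParams,
    similarity: np.ndarray | None = None,
    centered: bool = False,
) -> FeatureScores:
    """Laplacian score of every feature (row) of ``X`` (features x samples).

    With ``W`` the heat-kernel similarity over samples, ``D`` its diagonal
    row-sum matrix and ``L = D - W`` the graph Laplacian, the score of
    feature ``k`` is ``s(k) = X_k L X_k^T / (X_k D X_k^T)``.  Features with
    a zero denominator score 0.  ``similarity`` overrides the heat-kernel
    graph (useful to hold the graph fixed).  ``centered=True`` applies the
    classical D-weighted centering of each feature before scoring; the
    default evaluates the ratio exactly as written above.
    """
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (features x samples)")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    W = heat_kernel_similarity(X, params.sigma) if similarity is None else np.asarray(similarity, float)
    d = W.sum(axis=1)
    if centered:
        X = X - (X @ d / d.sum())[:, None]
    num = np.einsum("ki,ij,kj->k", X, np.diag(d) - W, X)
    den = np.einsum("ki,i,ki->k", X, d, X)
    scores = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    # clip tiny negatives from round-off: L is PSD so the ratio is >= 0
    return FeatureScores(np.maximum(scores, 0.0))


def lgd_score(X: np.ndarray, params: LGDParams) -> FeatureScores:
    """Local-global discriminative score of every feature (row) of ``X``.

    For feature ``k`` with values ``x_i(k)``, the score is the global sum
    of squares around the feature mean divided by the summed within-
    neighborhood sum of squares (plus ``epsilon``), where the neighborhood
    ``o(x_j(k))`` holds the ``m`` values nearest to ``x_j(k)`` (self
    included, ties broken by ascending sample index) and deviations are
    taken from the neighborhood mean.
    """
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (features x samples)")
    d, N = X.shape
    m = params.neighborhood_size
    if m > N:
        raise ValueError(f"neighborhood_size={m} exceeds sample count {N}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    scores = np.empty(d)
    for k in range(d):
        v = X[k]
        num = float(((v - v.mean()) ** 2).sum())
        dist = np.abs(v[:, None] - v[None, :])
        nbr = np.argsort(dist, axis=1, kind="stable")[:, :m]  # ties -> low index
        vals = v[nbr]
        den = float(((vals - vals.mean(axis=1, keepdims=True)) ** 2).sum())
        scores[k] = num / (den + params.epsilon)
    return FeatureScores(scores)


def select_top_k(scores: FeatureScores, k: int) -> np.ndarray:
    """Indices of the ``k`` top-ranked features (deterministic under ties)."""
    d = scores.scores.size
    if not 1 <= k <= d:
        raise ValueError(f"k={k} outside [1, {d}]")
    return scores.ranking[:k].copy()


@dataclass
class NormalizationParams:
    """Train-fitted per-feature statistics for one normalization scheme.

    ``stats`` holds (mean, std) for z-scoring, (min, max) for min-max, or
    (l2norm,) for unit-ball scaling; ``epsilon`` guards every denominator.
    """

    scheme: str
    stats: tuple[np.ndarray, ...]
    epsilon: float = DEFAULT_EPS

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "stats": [s.tolist() for s in self.stats],
            "epsilon": self.epsilon,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(d["scheme"], tuple(np.asarray(s, float) for s in d["stats"]), d["epsilon"])


def fit_normalizer(
    X_train: np.ndarray, scheme: str, epsilon: float = DEFAULT_EPS
) -> NormalizationParams:
    """Fit per-feature statistics on training rows (samples x features)."""
    X = np.asarray(X_train, float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X_train must be 2-D with at least one row")
    if scheme == "zscore":
        stats = (X.mean(axis=0), X.std(axis=0))  # population (1/N) std
    elif scheme == "minmax":
        stats = (X.min(axis=0), X.max(axis=0))
    elif scheme == "unitball":
        stats = (np.sqrt((X**2).sum(axis=0)),)
    else:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    return NormalizationParams(scheme, stats, epsilon)


def apply_normalizer(X: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Apply train-fitted statistics to any matrix with matching features."""
    X = np.asarray(X, float)
    d = params.stats[0].size
    if X.ndim != 2 or X.shape[1] != d:
        raise ValueError(f"expected {d} feature columns, got shape {X.shape}")
    eps = params.epsilon
    if params.scheme == "zscore":
        mean, std = params.stats
        return (X - mean) / (std + eps)
    if params.scheme == "minmax":
        lo, hi = params.stats
        return (X - lo) / (hi - lo + eps)
    if params.scheme == "unitball":
        (norm,) = params.stats
        return X / (norm + eps)
    raise ValueError(f"unknown scheme {params.scheme!r}")
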