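"""Classification protocol: weighting, linear SVMs, 10-fold CV, grid search.

The pipeline evaluated here mirrors a multimodal disease-prediction study:
features from up to four modalities (MRI, PET, CSF, SNP) are concatenated
in a canonical order, normalized with statistics fitted on the training
fold only (z-score for the continuous modalities, min-max for genotypes,
then unit-ball scaling of the concatenation), optionally pre-screened
(unsupervised top-k on the SNP block) and passed through one of the
feature-selection learners.  The learner's per-feature weights multiply
the features element-wise before a linear soft-margin SVM is trained.
Binary tasks report accuracy / sensitivity / specificity with the stated
positive class; the three-class task uses one-vs-rest scorers and assigns
each test subject to the class with the maximum decision value.

Grid search follows the protocol of reporting the best-performing
hyperparameter cell over the same 10-fold partition; an optional nested
mode re-selects hyperparameters inside every training fold instead (safer
against optimistic bias, slower).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datasets import CLASS_LEVELS, MODALITY_ORDER, MultimodalDataset
from .hgmfs import HGMFSProblem, hgmfs_fit
from .mkl import MKLProblem, mkl_fit
from .preprocessing import (
    LGDParams,
    apply_normalizer,
    fit_normalizer,
    lgd_score,
    select_top_k,
)
from .smml import SMMLProblem, smml_fit

METHODS = ("baseline", "MKL", "HGM-FS", "SMML")

#: The nine modality configurations evaluated in the protocol.
CONFIG_NAMES = (
    "MRI",
    "PET",
    "CSF",
    "SNP",
    "MRI+SNP",
    "PET+SNP",
    "CSF+SNP",
    "MRI+PET+CSF",
    "MRI+PET+CSF+SNP",
)

#: Continuous modalities are z-scored; genotypes are min-max scaled.
_SCHEME_BY_MODALITY = {"MRI": "zscore", "PET": "zscore", "CSF": "zscore", "SNP": "minmax"}


@dataclass(frozen=True)
class ModalityConfig:
    """An ordered subset of the four modalities used as the feature set."""

    name: str

    def __post_init__(self) -> None:
        members = self.members
        if not members:
            raise ValueError("configuration needs at least one modality")
        unknown = [m for m in members if m not in MODALITY_ORDER]
        if unknown:
            raise ValueError(f"unknown modalities {unknown}")
        canon = [m for m in MODALITY_ORDER if m in members]
        if list(members) != canon:
            raise ValueError(
                f"modalities must appear in canonical order {MODALITY_ORDER}"
            )

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(self.name.split("+"))


@dataclass(frozen=True)
class TaskSpec:
    """Binary contrast (positive vs negative class) or the 3-class task."""

    kind: str  # "binary" | "multiclass"
    positive: str | None = None
    negative: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "binary":
            if self.positive not in CLASS_LEVELS or self.negative not in CLASS_LEVELS:
                raise ValueError("binary task needs two valid class levels")
            if self.positive == self.negative:
                raise ValueError("positive and negative classes must differ")
        elif self.kind != "multiclass":
            raise ValueError("kind must be 'binary' or 'multiclass'")

    @property
    def label(self) -> str:
        if self.kind == "binary":
            return f"{self.positive}_vs_{self.negative}"
        return "AD_vs_MCI_vs_HC"


#: The four tasks of the study protocol: three binary contrasts (the first
#: named class is positive) plus the one-vs-rest multiclass task.
DEFAULT_TASKS = (
    TaskSpec("binary", "AD", "MCI"),
    TaskSpec("binary", "AD", "HC"),
    TaskSpec("binary", "MCI", "HC"),
    TaskSpec("multiclass"),
)


@dataclass
class CVResult:
    """Per-fold and aggregate cross-validation metrics (percent)."""

    method: str
    config: str
    task: str
    fold_accuracy: np.ndarray
    fold_sensitivity: np.ndarray
    fold_specificity: np.ndarray
    chosen_params: dict
    fold_weights: list[np.ndarray]
    feature_names: list[str]

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracy.mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.fold_accuracy.std())

    def summary(self) -> dict:
        def ms(a):
            a = a[np.isfinite(a)]
            return (float(a.mean()), float(a.std())) if a.size else (np.nan, np.nan)

        acc, sens, spec = (
            ms(self.fold_accuracy),
            ms(self.fold_sensitivity),
            ms(self.fold_specificity),
        )
        return {
            "method": self.method,
            "config": self.config,
            "task": self.task,
            "accuracy_mean": acc[0],
            "accuracy_std": acc[1],
            "sensitivity_mean": sens[0],
            "sensitivity_std": sens[1],
            "specificity_mean": spec[0],
            "specificity_std": spec[1],
            **{f"param_{k}": v for k, v in self.chosen_params.items()},
        }

    @property
    def mean_weights(self) -> np.ndarray:
        return np.mean(self.fold_weights, axis=0)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def apply_feature_weighting(X: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Element-wise product of every row with the learned weight vector."""
    X = np.asarray(X, float)
    weights = np.asarray(weights, float)
    if X.shape[1] != weights.size:
        raise ValueError(f"{X.shape[1]} columns vs {weights.size} weights")
    return X * weights


def train_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> SVC:
    """Soft-margin linear SVM (libsvm); decision value is ``w^T x + b``."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need both classes to train an SVM")
    svc = SVC(kernel="linear", C=C, tol=1e-6)
    svc.fit(np.asarray(X, float), y)
    return svc


def predict_multiclass(models: dict[str, SVC], X: np.ndarray) -> np.ndarray:
    """Argmax of the three one-vs-rest decision values, ties to class order."""
    missing = [c for c in CLASS_LEVELS if c not in models]
    if missing:
        raise ValueError(f"missing one-vs-rest scorer(s) for {missing}")
    scores = np.column_stack([models[c].decision_function(X) for c in CLASS_LEVELS])
    return np.argmax(scores, axis=1)  # first max wins -> HC < MCI < AD order


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, positive_class=1
) -> tuple[float, float, float]:
    """Accuracy, sensitivity, specificity in percent for a binary task.

    A contrast with no positive (or no negative) truth leaves the
    corresponding rate undefined: NaN is returned with a warning rather
    than silently reporting 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    pos = y_true == positive_class
    tp = int((pos & (y_pred == positive_class)).sum())
    tn = int((~pos & (y_pred != positive_class)).sum())
    fn = int(pos.sum()) - tp
    fp = int((~pos).sum()) - tn
    acc = 100.0 * (tp + tn) / y_true.size
    if tp + fn == 0:
        warnings.warn("no positive samples: sensitivity undefined", stacklevel=2)
        sens = np.nan
    else:
        sens = 100.0 * tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative samples: specificity undefined", stacklevel=2)
        spec = np.nan
    else:
        spec = 100.0 * tn / (tn + fp)
    return acc, sens, spec


def build_config_matrix(
    dataset: MultimodalDataset, config: ModalityConfig
) -> tuple[np.ndarray, list[str]]:
    """Concatenate the configuration's blocks in canonical modality order."""
    missing = [m for m in config.members if m not in dataset.blocks]
    if missing:
        raise ValueError(f"dataset lacks modalities {missing}")
    X = np.hstack([dataset.blocks[m] for m in config.members])
    names = [n for m in config.members for n in dataset.feature_names[m]]
    return X, names


# ---------------------------------------------------------------------------
# The cross-validated protocol
# ---------------------------------------------------------------------------

DEFAULT_GRIDS = {
    "baseline": {"C": [10.0**k for k in range(-3, 4)]},
    "MKL": {"C": [10.0**k for k in range(-3, 4)]},
    "HGM-FS": {
        "C": [1.0],
        "lam1": [10.0**k for k in range(-4, 2)],
        "lam2": [0.0, 1e-3, 1e-1],
        "lam3": [0.0, 1e-4],
    },
    "SMML": {
        "C": [1.0],
        "gam1": [10.0**k for k in range(-4, 2)],
        "gam2": [10.0**k for k in range(-4, 2)],
    },
}

QUICK_GRIDS = {
    "baseline": {"C": [0.1, 1.0, 10.0]},
    "MKL": {"C": [0.1, 1.0, 10.0]},
    "HGM-FS": {"C": [1.0], "lam1": [1e-3, 1e-2, 1e-1], "lam2": [0.0, 1e-2], "lam3": [0.0]},
    "SMML": {"C": [1.0], "gam1": [1e-3, 1e-1], "gam2": [1e-3, 1e-1]},
}


def _grid_cells(grid: dict) -> list[dict]:
    keys = sorted(grid)
    return [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]


class _FoldPipeline:
    """Train-fold-fitted preprocessing shared by all methods.

    Fits, on training rows only: the SNP pre-screen (LGD top-k), the
    per-modality normalizers, and the unit-ball normalizer of the
    concatenation; applies them unchanged to any matrix of rows.
    """

    def __init__(self, dataset, config, train_idx, snp_top_k, lgd_m=5):
        self.config = config
        self.snp_keep: np.ndarray | None = None
        self.normalizers = {}
        parts, names, kept_full = [], [], []
        offset = 0
        for m in config.members:
            block = dataset.blocks[m][train_idx]
            d_full = block.shape[1]
            fnames = list(dataset.feature_names[m])
            keep = np.arange(d_full)
            if m == "SNP" and snp_top_k and snp_top_k < d_full:
                mm = min(lgd_m, block.shape[0])
                scores = lgd_score(block.T, LGDParams(neighborhood_size=mm))
                keep = np.sort(select_top_k(scores, snp_top_k))
                self.snp_keep = keep
                block = block[:, keep]
                fnames = [fnames[i] for i in keep]
            params = fit_normalizer(block, _SCHEME_BY_MODALITY.get(m, "zscore"))
            self.normalizers[m] = params
            parts.append(apply_normalizer(block, params))
            names.extend(fnames)
            kept_full.append(offset + keep)
            offset += d_full
        concat = np.hstack(parts)
        self.unitball = fit_normalizer(concat, "unitball")
        self.feature_names = names
        #: indices of the kept columns within the full config concatenation
        self.kept_full_idx = np.concatenate(kept_full)
        self.full_dim = offset
        self.full_names = [
            n for m in config.members for n in dataset.feature_names[m]
        ]
        self.block_dims = [
            (m, self.normalizers[m].stats[0].size) for m in config.members
        ]

    def expand_weights(self, w: np.ndarray) -> np.ndarray:
        """Map kept-column weights back onto the full config layout."""
        full = np.zeros(self.full_dim)
        full[self.kept_full_idx] = w
        return full

    def transform(self, dataset, idx) -> np.ndarray:
        parts = []
        for m in self.config.members:
            block = dataset.blocks[m][idx]
            if m == "SNP" and self.snp_keep is not None:
                block = block[:, self.snp_keep]
            parts.append(apply_normalizer(block, self.normalizers[m]))
        return apply_normalizer(np.hstack(parts), self.unitball)

    def block_matrices(self, X: np.ndarray) -> list[np.ndarray]:
        out, start = [], 0
        for _, dq in self.block_dims:
            out.append(X[:, start : start + dq])
            start += dq
        return out


def _ovr_targets(y_codes: np.ndarray, classes: np.ndarray) -> np.ndarray:
    Y = -np.ones((classes.size, y_codes.size))
    for r, c in enumerate(classes):
        Y[r, y_codes == c] = 1.0
    return Y


def _method_weights(method, Xtr, ytr, classes, pipe, params):
    """Per-feature weight vector learned on the training fold.

    For multiclass, MKL is fitted per one-vs-rest task and the per-feature
    weights are averaged into a single vector shared by the three tasks;
    HGM-FS and SMML fit one multi-column model whose row norms are shared.
    """
    d = Xtr.shape[1]
    if method == "baseline":
        return np.ones(d)
    if method == "MKL":
        if classes.size == 2:
            y = np.where(ytr == classes[1], 1.0, -1.0)
            model = mkl_fit(MKLProblem(Xtr, y, C=params["C"]), max_iter=40)
            return model.feature_weights
        profiles = []
        for c in classes:
            y = np.where(ytr == c, 1.0, -1.0)
            model = mkl_fit(MKLProblem(Xtr, y, C=params["C"]), max_iter=40)
            profiles.append(model.feature_weights)
        return np.mean(profiles, axis=0)
    if method == "HGM-FS":
        if classes.size == 2:
            Y = np.where(ytr == classes[1], 1.0, -1.0)[None, :]
        else:
            Y = _ovr_targets(ytr, classes)
        prob = HGMFSProblem(Xtr.T, Y, (params["lam1"], params["lam2"], params["lam3"]))
        model = hgmfs_fit(prob, max_iter=300, rtol=1e-7)
        w = model.feature_weights
        w[np.abs(model.W).max(axis=1) <= model.select_tol] = 0.0
        return w
    if method == "SMML":
        Y = _ovr_targets(ytr, classes)
        blocks = pipe.block_matrices(Xtr)
        prob = SMMLProblem(blocks, Y, (params["gam1"], params["gam2"]),
                           block_names=[m for m, _ in pipe.block_dims])
        model = smml_fit(prob, smoothing_schedule=(1e-1, 1e-3, 1e-5))
        w = model.feature_weights
        w[w <= model.select_tol] = 0.0
        return w
    raise ValueError(f"unknown method {method!r}")


def _task_classes(task: TaskSpec):
    """(subject mask builder inputs) -> task label codes and positive code."""
    if task.kind == "binary":
        pos = CLASS_LEVELS.index(task.positive)
        neg = CLASS_LEVELS.index(task.negative)
        return np.array([neg, pos]), pos
    return np.arange(len(CLASS_LEVELS)), None


def _eval_fold(dataset, config, task, method, params, tr_idx, te_idx, snp_top_k):
    """Fit everything on the training rows, evaluate on the held-out rows."""
    classes, pos = _task_classes(task)
    pipe = _FoldPipeline(dataset, config, tr_idx, snp_top_k)
    Xtr = pipe.transform(dataset, tr_idx)
    Xte = pipe.transform(dataset, te_idx)
    ytr, yte = dataset.labels[tr_idx], dataset.labels[te_idx]
    w = _method_weights(method, Xtr, ytr, classes, pipe, params)
    Xtr_w = apply_feature_weighting(Xtr, w)
    Xte_w = apply_feature_weighting(Xte, w)
    if task.kind == "binary":
        svc = train_svm(Xtr_w, ytr, C=params["C"])
        pred = svc.predict(Xte_w)
        acc, sens, spec = compute_metrics(yte, pred, positive_class=pos)
    else:
        models = {}
        for c, lvl in enumerate(CLASS_LEVELS):
            yb = (ytr == c).astype(int)  # decision_function > 0 <=> class c
            models[lvl] = train_svm(Xtr_w, yb, C=params["C"])
        pred = predict_multiclass(models, Xte_w)
        acc = 100.0 * float((pred == yte).mean())
        sens = spec = np.nan
    return acc, sens, spec, pipe.expand_weights(w), pipe.full_names


def _run_cell(dataset, config, task, method, params, folds, sub_idx, snp_top_k):
    """One grid cell over all folds -> per-fold metrics and weights."""
    accs, senss, specs, weights = [], [], [], []
    names = None
    for tr, te in folds:
        acc, sens, spec, w, names = _eval_fold(
            dataset, config, task, method, params, sub_idx[tr], sub_idx[te], snp_top_k
        )
        accs.append(acc)
        senss.append(sens)
        specs.append(spec)
        weights.append(w)
    return np.array(accs), np.array(senss), np.array(specs), weights, names


def make_folds(y: np.ndarray, n_folds: int, seed: int):
    """Deterministic stratified folds over the label vector."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(y.size), y))


def run_cv(
    dataset: MultimodalDataset,
    config: ModalityConfig,
    task: TaskSpec,
    method: str,
    grid: dict | None = None,
    seed: int = 0,
    n_folds: int = 10,
    snp_top_k: int = 189,
    nested: bool = False,
) -> CVResult:
    """Grid-searched, stratified cross-validation of one method.

    Every fold refits the SNP pre-screen, the normalizers, the selector and
    the SVM on its training rows only.  By default the grid cell with the
    best mean CV accuracy over the shared fold partition is reported
    (ties: first cell in deterministic key order); this mirrors the
    best-reported-performance protocol and carries the usual optimistic
    bias.  ``nested=True`` instead re-selects the cell inside each
    training fold by an inner stratified CV before scoring the outer test
    fold.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    grid = grid if grid is not None else DEFAULT_GRIDS[method]
    cells = _grid_cells(grid)
    if not cells:
        raise ValueError("empty hyperparameter grid")

    classes, _ = _task_classes(task)
    if task.kind == "binary":
        mask = np.isin(dataset.labels, classes)
    else:
        mask = np.ones(dataset.n_subjects, bool)
    sub_idx = np.flatnonzero(mask)
    y_task = dataset.labels[sub_idx]
    present = np.bincount(y_task, minlength=len(CLASS_LEVELS))[np.unique(y_task)]
    if present.min() < n_folds:
        raise ValueError(
            f"smallest class has {present.min()} subjects < {n_folds} folds"
        )
    folds = make_folds(y_task, n_folds, seed)

    if nested:
        accs, senss, specs, weights = [], [], [], []
        names, chosen = None, []
        for tr, te in folds:
            tr_counts = np.bincount(y_task[tr], minlength=len(CLASS_LEVELS))
            inner_n = max(2, min(5, int(tr_counts[np.unique(y_task[tr])].min())))
            inner = make_folds(y_task[tr], inner_n, seed)
            best_cell, best_acc = None, -np.inf
            for params in cells:
                a, *_ = _run_cell(
                    dataset, config, task, method, params, inner,
                    sub_idx[tr], snp_top_k,
                )
                if a.mean() > best_acc + 1e-12:
                    best_acc, best_cell = a.mean(), params
            acc, sens, spec, w, names = _eval_fold(
                dataset, config, task, method, best_cell,
                sub_idx[tr], sub_idx[te], snp_top_k,
            )
            accs.append(acc)
            senss.append(sens)
            specs.append(spec)
            weights.append(w)
            chosen.append(best_cell)
        return CVResult(
            method=method,
            config=config.name,
            task=task.label,
            fold_accuracy=np.array(accs),
            fold_sensitivity=np.array(senss),
            fold_specificity=np.array(specs),
            chosen_params={"per_fold": chosen},
            fold_weights=weights,
            feature_names=names,
        )

    best = None
    for params in cells:
        accs, senss, specs, weights, names = _run_cell(
            dataset, config, task, method, params, folds, sub_idx, snp_top_k
        )
        mean_acc = accs.mean()
        if best is None or mean_acc > best[0] + 1e-12:
            best = (mean_acc, params, accs, senss, specs, weights, names)
    _, params, accs, senss, specs, weights, names = best
    return CVResult(
        method=method,
        config=config.name,
        task=task.label,
        fold_accuracy=accs,
        fold_sensitivity=senss,
        fold_specificity=specs,
        chosen_params=params,
        fold_weights=weights,
        feature_names=names,
    )
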