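"""Synthetic multimodal datasets with an ordered disease progression.

The generator emulates the statistical shape of a multimodal
neuroimaging-genetics study of Alzheimer's disease: three ordered diagnostic
classes (healthy controls HC, mild cognitive impairment MCI, Alzheimer's
disease AD), two continuous imaging modalities (regional MRI gray-matter
volumes and regional PET intensities), a small block of CSF protein markers,
and a genotype block of SNP minor-allele counts in {0, 1, 2}.

Class signal is ordinal: informative continuous features shift their mean
linearly along the HC -> MCI -> AD axis, and informative SNPs shift their
minor-allele frequency additively on the logit scale.  This makes the
extreme-class contrast (AD vs HC) easier than adjacent contrasts, mirroring
the clinical difficulty ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical modality order used everywhere downstream.
MODALITY_ORDER = ("MRI", "PET", "CSF", "SNP")

#: Ordered diagnostic classes (codes 0, 1, 2).
CLASS_LEVELS = ("HC", "MCI", "AD")

_DEFAULT_DIMS = {"MRI": 93, "PET": 93, "CSF": 3, "SNP": 189}
_DEFAULT_INFORMATIVE = {"MRI": 10, "PET": 10, "CSF": 3, "SNP": 10}


def _expit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic multimodal generator.

    Parameters
    ----------
    n_per_class
        Subject counts for the ordered classes (HC, MCI, AD).  Defaults to
        the cohort sizes typical of a single-site ADNI-style subset.
    modality_dims
        Feature count per modality.
    informative_counts
        Number of class-informative features planted in each modality.
    effect_sizes
        Standardized mean shift per class step (Cohen's-d-like, unitless)
        for each modality.  For SNPs the shift is applied on the logit of
        the minor-allele frequency.
    snp_maf_range
        Interval in (0, 0.5] from which per-SNP minor-allele frequencies
        are drawn uniformly.
    noise_sd
        Standard deviation of the Gaussian noise on continuous features.
    seed
        Seed of the global random stream; each modality draws from an
        independent child stream so the dataset is bit-reproducible.
    """

    n_per_class: tuple[int, int, int] = (47, 93, 49)
    modality_dims: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_DIMS))
    informative_counts: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_INFORMATIVE)
    )
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: {m: 1.0 for m in MODALITY_ORDER}
    )
    snp_maf_range: tuple[float, float] = (0.05, 0.5)
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_per_class) != len(CLASS_LEVELS):
            raise ValueError("n_per_class must give one count per class")
        if any(int(n) < 0 for n in self.n_per_class):
            raise ValueError("class counts must be >= 0")
        if sum(self.n_per_class) == 0:
            raise ValueError("at least one subject required")
        for m, d in self.modality_dims.items():
            if d <= 0:
                raise ValueError(f"modality {m!r} has non-positive dimension {d}")
            k = self.informative_counts.get(m, 0)
            if not 0 <= k <= d:
                raise ValueError(
                    f"informative_counts[{m!r}]={k} outside [0, {d}]"
                )
        lo, hi = self.snp_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("snp_maf_range must lie within (0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class MultimodalDataset:
    """Per-modality feature blocks plus ordered class labels.

    ``blocks`` maps modality name to a (subjects x features) array in the
    canonical modality order; the SNP block holds minor-allele counts in
    {0, 1, 2}.  ``labels`` are integer codes into :data:`CLASS_LEVELS`.
    ``informative_index_truth`` records the planted informative feature
    indices (synthetic data only).
    """

    blocks: dict[str, np.ndarray]
    labels: np.ndarray
    subject_ids: list[str]
    feature_names: dict[str, list[str]]
    informative_index_truth: dict[str, np.ndarray] | None = None
    snp_maf: np.ndarray | None = None  # baseline (class-HC) MAFs, synthetic only

    def validate(self) -> None:
        n = len(self.labels)
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length must match labels")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        if not set(np.unique(self.labels)) <= set(range(len(CLASS_LEVELS))):
            raise ValueError("labels contain unknown class codes")
        for m, X in self.blocks.items():
            if X.shape[0] != n:
                raise ValueError(f"block {m!r} row count != number of subjects")
            if X.shape[1] != len(self.feature_names[m]):
                raise ValueError(f"block {m!r} feature-name length mismatch")
            if m == "SNP" and not np.isin(X, (0, 1, 2)).all():
                raise ValueError("SNP genotypes must lie in {0, 1, 2}")

    @property
    def n_subjects(self) -> int:
        return len(self.labels)

    def class_counts(self) -> dict[str, int]:
        return {
            lvl: int((self.labels == c).sum()) for c, lvl in enumerate(CLASS_LEVELS)
        }


def _feature_names(modality: str, d: int) -> list[str]:
    width = max(3, len(str(d)))
    return [f"{modality}_{i + 1:0{width}d}" for i in range(d)]


def generate_multimodal(spec: SyntheticSpec) -> MultimodalDataset:
    """Draw a synthetic multimodal dataset under ``spec``.

    Continuous modalities: informative feature ``j`` in modality ``m`` has
    class-conditional mean ``c * effect_sizes[m] * noise_sd`` for class code
    ``c`` in {0, 1, 2}; all features carry independent Gaussian noise of
    standard deviation ``noise_sd``.  Non-informative features are pure
    noise.

    SNP modality: each SNP gets a minor-allele frequency ``p0`` drawn
    uniformly from ``snp_maf_range``; genotypes are Binomial(2, p_c) with
    ``logit(p_c) = logit(p0) + c * effect_sizes['SNP']`` for informative
    SNPs and ``p_c = p0`` otherwise.

    Identical ``spec`` (including ``seed``) yields a bit-identical dataset.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    # one independent child stream per modality, one for bookkeeping
    names = [m for m in MODALITY_ORDER if m in spec.modality_dims] + [
        m for m in spec.modality_dims if m not in MODALITY_ORDER
    ]
    children = root.spawn(len(names) + 1)
    streams = {m: np.random.Generator(np.random.PCG64(s)) for m, s in zip(names, children)}
    misc = np.random.Generator(np.random.PCG64(children[-1]))

    labels = np.repeat(np.arange(len(CLASS_LEVELS)), spec.n_per_class)
    n = labels.size
    subject_ids = [f"subj_{i + 1:04d}" for i in range(n)]

    blocks: dict[str, np.ndarray] = {}
    feature_names: dict[str, list[str]] = {}
    truth: dict[str, np.ndarray] = {}
    snp_maf = None
    for m in names:
        d = spec.modality_dims[m]
        k = int(spec.informative_counts.get(m, 0))
        eff = float(spec.effect_sizes.get(m, 0.0))
        rng = streams[m]
        idx = np.sort(rng.choice(d, size=k, replace=False)) if k else np.array([], int)
        if m == "SNP":
            maf = rng.uniform(*spec.snp_maf_range, size=d)
            snp_maf = maf
            shift = np.zeros((n, d))
            shift[:, idx] = labels[:, None] * eff
            p = _expit(_logit(maf)[None, :] + shift)
            X = rng.binomial(2, p).astype(float)
        else:
            mean = np.zeros((n, d))
            mean[:, idx] = labels[:, None] * eff * spec.noise_sd
            X = mean + rng.normal(0.0, spec.noise_sd, size=(n, d))
        blocks[m] = X
        feature_names[m] = _feature_names(m, d)
        truth[m] = idx
    del misc  # reserved stream keeps child layout stable if bookkeeping grows

    ds = MultimodalDataset(
        blocks=blocks,
        labels=labels,
        subject_ids=subject_ids,
        feature_names=feature_names,
        informative_index_truth=truth,
        snp_maf=snp_maf,
    )
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# On-disk layout: one CSV per modality (first column = subject id, header =
# feature names), a labels CSV, and a JSON sidecar with the generator spec
# and planted-truth indices.
# ---------------------------------------------------------------------------

def write_dataset(ds: MultimodalDataset, path: str | Path) -> None:
    """Write ``ds`` as per-modality CSVs + labels.csv + meta.json."""
    ds.validate()
    if ds.n_subjects == 0:
        raise ValueError("refusing to write a dataset with 0 subjects")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for m, X in ds.blocks.items():
        df = pd.DataFrame(X, columns=ds.feature_names[m])
        df.insert(0, "subject_id", ds.subject_ids)
        df.to_csv(path / f"{m}.csv", index=False)
    lab = pd.DataFrame(
        {"subject_id": ds.subject_ids, "label": [CLASS_LEVELS[c] for c in ds.labels]}
    )
    lab.to_csv(path / "labels.csv", index=False)
    meta = {
        "modalities": list(ds.blocks),
        "snp_maf": ds.snp_maf.tolist() if ds.snp_maf is not None else None,
        "informative_index_truth": (
            {m: np.asarray(v).tolist() for m, v in ds.informative_index_truth.items()}
            if ds.informative_index_truth is not None
            else None
        ),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def read_dataset(path: str | Path) -> MultimodalDataset:
    """Read a dataset written by :func:`write_dataset` (lossless round trip)."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    lab = pd.read_csv(path / "labels.csv", dtype={"subject_id": str})
    unknown = set(lab["label"]) - set(CLASS_LEVELS)
    if unknown:
        raise ValueError(f"unknown label level(s): {sorted(unknown)}")
    subject_ids = lab["subject_id"].tolist()
    labels = np.array([CLASS_LEVELS.index(v) for v in lab["label"]])
    blocks: dict[str, np.ndarray] = {}
    feature_names: dict[str, list[str]] = {}
    for m in meta["modalities"]:
        df = pd.read_csv(path / f"{m}.csv", dtype={"subject_id": str})
        if df["subject_id"].tolist() != subject_ids:
            raise ValueError(f"block {m!r} subject ids disagree with labels.csv")
        X = df.drop(columns="subject_id").to_numpy(float)
        blocks[m] = X
        feature_names[m] = [c for c in df.columns if c != "subject_id"]
    truth = meta.get("informative_index_truth")
    ds = MultimodalDataset(
        blocks=blocks,
        labels=labels,
        subject_ids=subject_ids,
        feature_names=feature_names,
        informative_index_truth=(
            {m: np.asarray(v, int) for m, v in truth.items()} if truth else None
        ),
        snp_maf=(
            np.asarray(meta["snp_maf"], float)
            if meta.get("snp_maf") is not None
            else None
        ),
    )
    ds.validate()
    return ds
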