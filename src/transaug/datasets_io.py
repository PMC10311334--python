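"""Expression-matrix I/O, a synthetic transcriptome simulator, normalization,
splitting, and the Gaussian-noise augmentation baseline.

The universal currency of the package is :class:`ExpressionDataset`: an
``n_samples x n_genes`` matrix of normalized expression together with a
per-sample covariate table (age, gender, tissue, cancer).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "ExpressionDataset",
    "SimConfig",
    "SplitSpec",
    "CovariateEncoder",
    "Normalizer",
    "simulate_transcriptome",
    "read_expression",
    "write_expression",
    "normalize",
    "split",
    "gaussian_noise_augment",
]

COVARIATE_COLUMNS = ("age", "gender", "tissue", "cancer")


class AlignmentError(ValueError):
    """Sample IDs of the expression and covariate tables do not match."""


class StratificationError(ValueError):
    """A stratification class has too few samples for the requested split."""


@dataclass
class ExpressionDataset:
    """Samples-by-genes expression matrix with optional covariates.

    ``values`` holds normalized expression (expected in ``[0, 1]`` after
    :func:`normalize`).  ``covariates`` is a DataFrame indexed like
    ``sample_ids`` with columns ``age`` (numeric), ``gender``, ``tissue``
    (categorical) and ``cancer`` (binary).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (samples x genes)")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain missing or non-finite entries")
        n, d = self.values.shape
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != d:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {d} columns")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.gene_ids)) != d:
            raise ValueError("gene_ids are not unique")
        if self.covariates is not None:
            if len(self.covariates) != n:
                raise AlignmentError(
                    f"covariate table has {len(self.covariates)} rows for {n} samples"
                )
            self.covariates = self.covariates.copy()
            self.covariates.index = pd.Index(self.sample_ids, name="sample_id")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset(self, indices: Sequence[int], suffix: str | None = None) -> "ExpressionDataset":
        """Row subset (with repetition allowed, e.g. bootstrap draws)."""
        indices = np.asarray(indices, dtype=np.intp)
        ids = [self.sample_ids[i] for i in indices]
        if suffix is not None or len(set(ids)) != len(ids):
            tag = suffix or "rep"
            ids = [f"{s}_{tag}{k}" for k, s in enumerate(ids)]
        cov = self.covariates.iloc[indices] if self.covariates is not None else None
        return ExpressionDataset(self.values[indices], list(self.gene_ids), ids, cov)

    def labels(self, task: str) -> np.ndarray:
        """Per-sample labels for ``task`` in ``{'binary', 'tissue'}``."""
        if self.covariates is None:
            raise ValueError("dataset carries no covariates")
        col = {"binary": "cancer", "tissue": "tissue"}.get(task, task)
        return self.covariates[col].to_numpy()

    def concat(self, other: "ExpressionDataset") -> "ExpressionDataset":
        if self.gene_ids != other.gene_ids:
            raise ValueError("gene sets differ")
        cov = None
        if self.covariates is not None and other.covariates is not None:
            cov = pd.concat([self.covariates, other.covariates], axis=0)
        ids = list(self.sample_ids)
        for s in other.sample_ids:
            ids.append(s if s not in ids else f"{s}_dup{len(ids)}")
        if cov is not None:
            cov.index = pd.Index(ids, name="sample_id")
        return ExpressionDataset(
            np.vstack([self.values, other.values]), list(self.gene_ids), ids, cov
        )


@dataclass
class SimConfig:
    """Configuration for :func:`simulate_transcriptome`.

    Tissues are Gaussian clusters; consecutive groups of ``block_size``
    genes share a latent factor giving within-block pairwise correlation
    ``block_rho``; cancer samples receive a mean shift of ``cancer_shift``
    on the first ``block_size`` genes.
    """

    n_samples: int = 300
    n_genes: int = 60
    n_tissues: int = 3
    block_size: int = 10
    block_rho: float = 0.5
    cancer_fraction: float = 0.3
    cancer_shift: float = 0.3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_tissues < 1:
            raise ValueError("n_tissues must be >= 1")
        if not (1 <= self.block_size <= self.n_genes):
            raise ValueError("need n_genes >= block_size >= 1")
        if not (0.0 <= self.block_rho < 1.0):
            raise ValueError("block_rho must lie in [0, 1)")
        if not (0.0 <= self.cancer_fraction <= 1.0):
            raise ValueError("cancer_fraction must lie in [0, 1]")


@dataclass
class SplitSpec:
    val_fraction: float = 1.0 / 6.0
    test_fraction: float = 1.0 / 6.0
    stratify_on: Optional[str] = "tissue"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.val_fraction < 1 and 0 < self.test_fraction < 1):
            raise ValueError("fractions must lie in (0, 1)")
        if self.val_fraction + self.test_fraction >= 1:
            raise ValueError("val_fraction + test_fraction must be < 1")


def simulate_transcriptome(config: SimConfig) -> ExpressionDataset:
    """Draw a TCGA-like synthetic dataset.

    Each tissue is a Gaussian cluster around a tissue-specific mean vector
    drawn in ``[0.25, 0.75]``; values are clipped to ``[0, 1]`` so the
    matrix is normalized by construction.  Fixed ``config.seed`` gives a
    bit-identical dataset across invocations.
    """
    rng = np.random.default_rng(config.seed)
    n, d, k = config.n_samples, config.n_genes, config.n_tissues

    tissue_means = rng.uniform(0.25, 0.75, size=(k, d))
    # balanced allocation: tissue sizes differ by at most one
    tissue = np.sort(np.arange(n) % k)
    cancer = (rng.random(n) < config.cancer_fraction).astype(int)

    n_blocks = int(np.ceil(d / config.block_size))
    block_of_gene = np.repeat(np.arange(n_blocks), config.block_size)[:d]
    factors = rng.normal(size=(n, n_blocks))
    eps = rng.normal(size=(n, d))
    rho = config.block_rho
    noise = np.sqrt(rho) * factors[:, block_of_gene] + np.sqrt(1.0 - rho) * eps

    values = tissue_means[tissue] + config.noise_sd * noise
    values[cancer == 1, : config.block_size] += config.cancer_shift
    values = np.clip(values, 0.0, 1.0)

    covariates = pd.DataFrame(
        {
            "age": np.round(np.clip(rng.normal(60.0, 12.0, size=n), 20, 95), 1),
            "gender": rng.choice(["female", "male"], size=n),
            "tissue": [f"tissue_{t}" for t in tissue],
            "cancer": cancer,
        }
    )
    gene_ids = [f"gene_{j}" for j in range(d)]
    sample_ids = [f"sample_{i}" for i in range(n)]
    return ExpressionDataset(values, gene_ids, sample_ids, covariates)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_expression(path, covariate_path=None) -> ExpressionDataset:
    """Read an expression table (and optionally covariates) from TSV/CSV.

    Layout: first column sample IDs, header row gene IDs, numeric body.
    The covariate table must carry exactly the same sample IDs.
    """
    frame = _read_table(path)
    try:
        values = frame.to_numpy(dtype=np.float64)
    except (TypeError, ValueError):
        for i, row in enumerate(frame.itertuples(index=False)):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric expression value {cell!r} at sample "
                        f"{frame.index[i]!r}, gene {frame.columns[j]!r}"
                    ) from None
        raise
    covariates = None
    if covariate_path is not None:
        cov = _read_table(covariate_path)
        missing = [s for s in frame.index.astype(str) if s not in cov.index.astype(str)]
        if missing:
            raise AlignmentError(
                f"{len(missing)} sample IDs missing from covariate table "
                f"(first: {missing[0]!r})"
            )
        covariates = cov.loc[frame.index].copy()
    return ExpressionDataset(
        values, list(frame.columns.astype(str)), list(frame.index.astype(str)), covariates
    )


def write_expression(dataset: ExpressionDataset, path, covariate_path=None) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.DataFrame(dataset.values, index=dataset.sample_ids, columns=dataset.gene_ids)
    frame.index.name = "sample_id"
    frame.to_csv(path, sep=sep)
    if covariate_path is not None:
        if dataset.covariates is None:
            raise ValueError("dataset has no covariates to write")
        csep = "," if str(covariate_path).endswith(".csv") else "\t"
        dataset.covariates.to_csv(covariate_path, sep=csep)


# ----------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------


class Normalizer:
    """log2(1+x) followed by per-gene min–max scaling to [0, 1].

    Statistics are fitted on one split (normally the training set) and
    reused to transform others; out-of-range values are clipped.  A gene
    with zero range on the fitting split maps to 0 with a warning.
    """

    def __init__(self):
        self.log_min_: np.ndarray | None = None
        self.log_range_: np.ndarray | None = None

    def fit(self, stats_from: ExpressionDataset) -> "Normalizer":
        logged = np.log2(1.0 + stats_from.values)
        self.log_min_ = logged.min(axis=0)
        self.log_range_ = logged.max(axis=0) - self.log_min_
        n_const = int((self.log_range_ == 0).sum())
        if n_const:
            warnings.warn(
                f"{n_const} constant gene(s) in the fitting split mapped to 0",
                UserWarning,
                stacklevel=2,
            )
        return self

    def _check(self):
        if self.log_min_ is None:
            raise RuntimeError("Normalizer not fitted")

    def transform(self, dataset: ExpressionDataset) -> ExpressionDataset:
        self._check()
        logged = np.log2(1.0 + dataset.values)
        rng_safe = np.where(self.log_range_ == 0, 1.0, self.log_range_)
        scaled = (logged - self.log_min_) / rng_safe
        scaled[:, self.log_range_ == 0] = 0.0
        scaled = np.clip(scaled, 0.0, 1.0)
        return ExpressionDataset(
            scaled, list(dataset.gene_ids), list(dataset.sample_ids), dataset.covariates
        )

    def inverse(self, dataset: ExpressionDataset) -> ExpressionDataset:
        self._check()
        logged = dataset.values * self.log_range_ + self.log_min_
        raw = np.exp2(logged) - 1.0
        return ExpressionDataset(
            raw, list(dataset.gene_ids), list(dataset.sample_ids), dataset.covariates
        )


def normalize(
    dataset: ExpressionDataset, stats_from: ExpressionDataset | None = None
) -> tuple[ExpressionDataset, Normalizer]:
    """Normalize ``dataset`` with statistics fitted on ``stats_from``.

    Returns the transformed dataset together with the fitted
    :class:`Normalizer` (needed for the inverse transformation).
    """
    norm = Normalizer().fit(stats_from if stats_from is not None else dataset)
    return norm.transform(dataset), norm


# ----------------------------------------------------------------------
# splitting
# ----------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split(
    dataset: ExpressionDataset, spec: SplitSpec
) -> tuple[ExpressionDataset, ExpressionDataset, ExpressionDataset]:
    """Disjoint train/val/test partition with round-to-nearest sizing.

    Validation and test sizes are ``round(n * fraction)``; the remainder
    goes to train.  When ``spec.stratify_on`` names a covariate, both
    held-out splits are stratified on it.
    """
    n = dataset.n_samples
    n_val = _round_half_up(n * spec.val_fraction)
    n_test = _round_half_up(n * spec.test_fraction)
    if n_val + n_test >= n:
        raise ValueError("no samples left for training")

    labels = None
    if spec.stratify_on:
        if dataset.covariates is None or spec.stratify_on not in dataset.covariates:
            raise ValueError(f"unknown stratification covariate {spec.stratify_on!r}")
        labels = dataset.covariates[spec.stratify_on].to_numpy()

    idx = np.arange(n)
    try:
        rest, test_idx = train_test_split(
            idx, test_size=n_test, stratify=labels, random_state=spec.seed
        )
        rest_labels = labels[rest] if labels is not None else None
        train_idx, val_idx = train_test_split(
            rest, test_size=n_val, stratify=rest_labels, random_state=spec.seed + 1
        )
    except ValueError as exc:
        if "least populated class" in str(exc):
            raise StratificationError(str(exc)) from exc
        raise
    return dataset.subset(train_idx), dataset.subset(val_idx), dataset.subset(test_idx)


def split_sizes(n: int, val_fraction: float, test_fraction: float) -> tuple[int, int, int]:
    """Train/val/test sizes under round-to-nearest held-out sizing."""
    n_val = _round_half_up(n * val_fraction)
    n_test = _round_half_up(n * test_fraction)
    return n - n_val - n_test, n_val, n_test


# ----------------------------------------------------------------------
# Gaussian-noise baseline
# ----------------------------------------------------------------------


def gaussian_noise_augment(
    train: ExpressionDataset, m: int, variance: float = 0.1, seed: int = 0,
    clip: bool = True,
) -> ExpressionDataset:
    """Noise-perturbed copies of training rows (the augmentation baseline).

    Draws ``m`` source rows with replacement and adds i.i.d. Gaussian noise
    of the given variance to every gene; covariates are copied from the
    source row and values are clipped back to ``[0, 1]`` unless
    ``clip=False``.
    """
    if m <= 0:
        raise ValueError("m must be a positive count")
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if train.n_samples == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    src = rng.integers(0, train.n_samples, size=m)
    noisy = train.values[src] + rng.normal(0.0, np.sqrt(variance), size=(m, train.n_genes))
    if clip:
        noisy = np.clip(noisy, 0.0, 1.0)
    ids = [f"noise_{k}_{train.sample_ids[i]}" for k, i in enumerate(src)]
    cov = train.covariates.iloc[src].copy() if train.covariates is not None else None
    return ExpressionDataset(noisy, list(train.gene_ids), ids, cov)


# ----------------------------------------------------------------------
# covariate encoding (conditioning vectors for the generative models)
# ----------------------------------------------------------------------


@dataclass
class CovariateEncoder:
    """Encode covariate rows as conditioning vectors.

    Age is z-scored with training statistics; gender, tissue and cancer
    are one-hot encoded.  Only covariate patterns observed on the fitting
    split are sampled when conditioning generated data.
    """

    age_mean_: float = 0.0
    age_sd_: float = 1.0
    categories_: dict = field(default_factory=dict)
    patterns_: pd.DataFrame | None = None

    def fit(self, covariates: pd.DataFrame) -> "CovariateEncoder":
        age = covariates["age"].to_numpy(dtype=float)
        self.age_mean_ = float(age.mean())
        self.age_sd_ = float(age.std()) or 1.0
        for col in ("gender", "tissue", "cancer"):
            self.categories_[col] = sorted(map(str, covariates[col].unique()))
        self.patterns_ = covariates.reset_index(drop=True)
        return self

    @property
    def dim(self) -> int:
        return 1 + sum(len(v) for v in self.categories_.values())

    def transform(self, covariates: pd.DataFrame) -> np.ndarray:
        cols = [
            ((covariates["age"].to_numpy(dtype=float) - self.age_mean_) / self.age_sd_)[
                :, None
            ]
        ]
        for col in ("gender", "tissue", "cancer"):
            cats = self.categories_[col]
            vals = covariates[col].astype(str).to_numpy()
            onehot = np.zeros((len(covariates), len(cats)))
            for j, c in enumerate(cats):
                onehot[:, j] = vals == c
            cols.append(onehot)
        return np.hstack(cols)

    def sample_patterns(self, m: int, rng: np.random.Generator) -> pd.DataFrame:
        """Draw ``m`` observed covariate patterns with replacement."""
        if self.patterns_ is None:
            raise RuntimeError("CovariateEncoder not fitted")
        idx = rng.integers(0, len(self.patterns_), size=m)
        return self.patterns_.iloc[idx].reset_index(drop=True)
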