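"""Unsupervised quality indicators for generated expression data.

Implements the Fréchet distance on classifier embeddings, manifold
precision/recall/F1 via k-NN balls, adversarial accuracy (1-NN
real-vs-generated), the gene–gene correlation score, the PCA
cumulative-variance spectrum, and a report aggregator producing
mean ± std over repeated runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .datasets_io import ExpressionDataset

__all__ = [
    "EmbeddingSpace",
    "MetricsReport",
    "frechet_distance",
    "fit_embedding",
    "precision_recall",
    "adversarial_accuracy",
    "correlation_score",
    "pca_spectrum",
    "compute_report",
]


@dataclass
class EmbeddingSpace:
    """Last-hidden-layer embedding of a task classifier."""

    embed: Callable[[np.ndarray], np.ndarray]
    task: str
    dimension: int

    def __call__(self, x: np.ndarray) -> np.ndarray:
        out = self.embed(np.asarray(x, dtype=np.float64))
        if out.shape[0] != np.asarray(x).shape[0]:
            raise RuntimeError("embedding must return one row per input sample")
        return out


def frechet_distance(true_embeddings, gen_embeddings) -> float:
    """Wasserstein-2 distance between Gaussian fits of two embeddings.

    ``||mu_t - mu_g||^2 + Tr(S_t + S_g - 2 (S_t S_g)^{1/2})``; the matrix
    square root is taken via eigendecomposition of the symmetrized
    product ``S_t^{1/2} S_g S_t^{1/2}`` with negative eigenvalues (from
    numerical error) truncated at zero.
    """
    xt = np.asarray(true_embeddings, dtype=np.float64)
    xg = np.asarray(gen_embeddings, dtype=np.float64)
    if xt.ndim == 1:
        xt = xt[:, None]
    if xg.ndim == 1:
        xg = xg[:, None]
    if xt.shape[1] != xg.shape[1]:
        raise ValueError(
            f"embedding dimensions differ: {xt.shape[1]} vs {xg.shape[1]}"
        )
    if xt.shape[0] < 2 or xg.shape[0] < 2:
        raise ValueError("need at least 2 samples per side")
    mu_t, mu_g = xt.mean(axis=0), xg.mean(axis=0)
    cov_t = np.cov(xt, rowvar=False, ddof=1)
    cov_g = np.cov(xg, rowvar=False, ddof=1)
    cov_t = np.atleast_2d(cov_t)
    cov_g = np.atleast_2d(cov_g)
    if not (np.isfinite(cov_t).all() and np.isfinite(cov_g).all()):
        raise FloatingPointError("non-finite covariance")

    # sqrt(cov_t) from the symmetric eigendecomposition
    w, v = np.linalg.eigh(cov_t)
    sqrt_t = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T
    inner = sqrt_t @ cov_g @ sqrt_t
    w2 = np.linalg.eigvalsh((inner + inner.T) / 2.0)
    tr_sqrt = np.sqrt(np.clip(w2, 0.0, None)).sum()
    fd = float(np.sum((mu_t - mu_g) ** 2) + np.trace(cov_t) + np.trace(cov_g) - 2.0 * tr_sqrt)
    return max(fd, 0.0)


def fit_embedding(train: ExpressionDataset, task: str, seed: int = 0) -> EmbeddingSpace:
    """Train the task classifier and expose its hidden layer as embedding.

    ``task`` is ``binary`` (cancer yes/no, hidden 256) or ``tissue``
    (hidden 64); hyperparameters come from the classifier specs of the
    evaluation module.
    """
    from .augmentation_eval import ClassifierSpec, train_classifier

    spec = ClassifierSpec.for_task(task)
    clf = train_classifier(train, spec, seed=seed)
    return EmbeddingSpace(embed=clf.hidden_activations, task=task, dimension=spec.hidden)


def _pairwise_sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aa = (a * a).sum(axis=1)[:, None]
    bb = (b * b).sum(axis=1)[None, :]
    return np.maximum(aa + bb - 2.0 * (a @ b.T), 0.0)


def _knn_radii(x: np.ndarray, k: int) -> np.ndarray:
    """Distance of each point to its k-th nearest neighbor (self excluded)."""
    d2 = _pairwise_sq_dists(x, x)
    np.fill_diagonal(d2, np.inf)
    part = np.partition(d2, k - 1, axis=1)[:, k - 1]
    return np.sqrt(part)


def precision_recall(true_x, gen_x, k: int = 50) -> tuple[float, float, float]:
    """Manifold precision/recall with k-NN balls (Euclidean distances).

    Precision = fraction of generated samples within distance
    ``r_k(t)`` of at least one true sample ``t`` (with ``r_k`` the
    within-set k-th-neighbor radius, self excluded); recall is the
    symmetric quantity; F1 is the harmonic mean (0 when both are 0).
    """
    true_x = np.asarray(true_x, dtype=np.float64)
    gen_x = np.asarray(gen_x, dtype=np.float64)
    for name, arr in (("true", true_x), ("generated", gen_x)):
        if arr.shape[0] <= k:
            raise ValueError(f"{name} side has {arr.shape[0]} samples; need > k={k}")
    r_true = _knn_radii(true_x, k)
    r_gen = _knn_radii(gen_x, k)
    d_gt = np.sqrt(_pairwise_sq_dists(gen_x, true_x))
    precision = float(np.mean((d_gt <= r_true[None, :]).any(axis=1)))
    recall = float(np.mean((d_gt.T <= r_gen[None, :]).any(axis=1)))
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def adversarial_accuracy(
    true_x, gen_x, subset_size: Optional[int] = 2000, seed: int = 0
) -> float:
    """Accuracy of the implicit 1-NN true-vs-generated classifier.

    For each true sample, scores whether its nearest generated sample is
    strictly farther than its nearest other true sample; symmetrically
    for generated samples; AA is the mean of the two fractions.  Ties
    (equal distances, e.g. exact copies) count as "not farther".  A
    seeded subset of at most ``subset_size`` true samples is used.
    """
    true_x = np.asarray(true_x, dtype=np.float64)
    gen_x = np.asarray(gen_x, dtype=np.float64)
    if true_x.shape[0] < 2 or gen_x.shape[0] < 2:
        raise ValueError("need at least 2 samples per side")
    if subset_size is not None and true_x.shape[0] > subset_size:
        rng = np.random.default_rng(seed)
        true_x = true_x[rng.choice(true_x.shape[0], size=subset_size, replace=False)]

    d_tt = _pairwise_sq_dists(true_x, true_x)
    np.fill_diagonal(d_tt, np.inf)
    d_gg = _pairwise_sq_dists(gen_x, gen_x)
    np.fill_diagonal(d_gg, np.inf)
    d_tg = _pairwise_sq_dists(true_x, gen_x)
    term_true = float(np.mean(d_tg.min(axis=1) > d_tt.min(axis=1)))
    term_gen = float(np.mean(d_tg.min(axis=0) > d_gg.min(axis=1)))
    return 0.5 * (term_true + term_gen)


def _correlation_matrix(x: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.corrcoef(x, rowvar=False)
    return np.nan_to_num(np.atleast_2d(m), nan=0.0)


def correlation_score(true_x, gen_x) -> float:
    """Cosine similarity of upper-triangular gene–gene correlations.

    Constant genes contribute zero correlations; fully constant data has
    no defined score and raises.
    """
    true_x = np.asarray(true_x, dtype=np.float64)
    gen_x = np.asarray(gen_x, dtype=np.float64)
    if true_x.shape[0] < 3 or gen_x.shape[0] < 3:
        raise ValueError("need at least 3 samples per side")
    if true_x.shape[1] != gen_x.shape[1]:
        raise ValueError("gene sets differ in size")
    iu = np.triu_indices(true_x.shape[1], k=1)
    ut = _correlation_matrix(true_x)[iu]
    ug = _correlation_matrix(gen_x)[iu]
    nt, ng = np.linalg.norm(ut), np.linalg.norm(ug)
    if nt == 0 or ng == 0:
        raise ValueError("correlation score undefined: a side has no varying gene pairs")
    return float(np.dot(ut, ug) / (nt * ng))


def pca_spectrum(x) -> np.ndarray:
    """Cumulative explained-variance curve CV(i), i = 1..min(n, d)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    centered = x - x.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    var = sv ** 2
    total = var.sum()
    if total == 0:
        return np.ones(min(x.shape))
    ratios = np.zeros(min(x.shape))
    ratios[: len(var)] = var / total
    return np.cumsum(ratios)


@dataclass
class MetricsReport:
    """Mean ± std of every indicator over repeated runs."""

    correlation_score: tuple
    precision: tuple
    recall: tuple
    f1: tuple
    fd_binary: tuple
    fd_tissue: tuple
    adversarial_accuracy: tuple
    k: int = 50
    n_true_reference: int = 0
    n_generated: int = 0
    n_runs: int = 1
    seeds: list = field(default_factory=list)

    FIELDS = (
        "correlation_score",
        "precision",
        "recall",
        "f1",
        "fd_binary",
        "fd_tissue",
        "adversarial_accuracy",
    )
    # orientation of each indicator (higher- or lower-is-better; AA targets 0.5)
    ARROWS = {
        "correlation_score": "up",
        "precision": "up",
        "recall": "up",
        "f1": "up",
        "fd_binary": "down",
        "fd_tissue": "down",
        "adversarial_accuracy": "mid",
    }

    def to_dict(self) -> dict:
        out = {}
        for name in self.FIELDS:
            mean, std = getattr(self, name)
            out[name] = {"mean": mean, "std": std, "orientation": self.ARROWS[name]}
        out["provenance"] = {
            "k": self.k,
            "n_true_reference": self.n_true_reference,
            "n_generated": self.n_generated,
            "n_runs": self.n_runs,
            "seeds": list(self.seeds),
        }
        return out


def compute_report(
    generated_source,
    true_train: ExpressionDataset,
    embeddings: dict[str, EmbeddingSpace] | None = None,
    k: int = 50,
    subset_size: Optional[int] = 2000,
    n_runs: int = 5,
    n_generated: int | None = None,
    seed: int = 0,
) -> MetricsReport:
    """All indicators, aggregated as mean ± std over ``n_runs`` runs.

    ``generated_source`` is either a trained generative model (fresh
    samples are drawn each run) or an :class:`ExpressionDataset` of
    pre-generated samples (bootstrap-resampled each run).  ``embeddings``
    maps ``binary``/``tissue`` to fitted embedding spaces; missing tasks
    yield NaN Fréchet distances.
    """
    from .generative_models import GenerativeModel, generate

    ss = np.random.SeedSequence(seed).spawn(n_runs)
    run_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    if n_generated is None:
        n_generated = (
            generated_source.n_samples
            if isinstance(generated_source, ExpressionDataset)
            else true_train.n_samples
        )

    values: dict[str, list] = {name: [] for name in MetricsReport.FIELDS}
    for run_seed in run_seeds:
        if isinstance(generated_source, GenerativeModel):
            gen = generate(generated_source, n_generated, true_train, seed=run_seed)
        else:
            rng = np.random.default_rng(run_seed)
            n_pool = generated_source.n_samples
            idx = rng.choice(n_pool, size=n_generated, replace=n_generated > n_pool)
            gen = generated_source.subset(idx, suffix=f"run{run_seed}")
        xt, xg = true_train.values, gen.values
        values["correlation_score"].append(correlation_score(xt, xg))
        p, r, f1 = precision_recall(xt, xg, k=k)
        values["precision"].append(p)
        values["recall"].append(r)
        values["f1"].append(f1)
        for task, key in (("binary", "fd_binary"), ("tissue", "fd_tissue")):
            emb = (embeddings or {}).get(task)
            values[key].append(
                frechet_distance(emb(xt), emb(xg)) if emb is not None else np.nan
            )
        values["adversarial_accuracy"].append(
            adversarial_accuracy(xt, xg, subset_size=subset_size, seed=run_seed)
        )

    agg = {
        name: (float(np.mean(vals)), float(np.std(vals))) for name, vals in values.items()
    }
    return MetricsReport(
        **agg,
        k=k,
        n_true_reference=true_train.n_samples,
        n_generated=n_generated,
        n_runs=n_runs,
        seeds=run_seeds,
    )
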