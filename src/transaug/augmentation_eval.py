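"""Supervised evaluation of augmentation: classifiers, gain curves,
reverse validation, schedules, and the benchmark orchestrator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from .datasets_io import (
    ExpressionDataset,
    SimConfig,
    SplitSpec,
    gaussian_noise_augment,
    simulate_transcriptome,
    split,
)

__all__ = [
    "ClassifierSpec",
    "Classifier",
    "AugmentationCurve",
    "AugmentationGain",
    "train_classifier",
    "accuracy",
    "augmentation_gain",
    "reverse_validation",
    "run_schedule",
    "benchmark",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """One-hidden-layer MLP hyperparameters for a prediction task."""

    task: str  # binary | tissue
    hidden: int
    learning_rate: float
    batch_size: int = 32
    epochs: int = 40
    activation: str = "relu"
    optimizer: str = "adam"

    @staticmethod
    def for_task(task: str) -> "ClassifierSpec":
        if task == "binary":
            return ClassifierSpec("binary", hidden=256, learning_rate=1e-3)
        if task == "tissue":
            return ClassifierSpec("tissue", hidden=64, learning_rate=5e-4)
        raise ValueError(f"unknown task {task!r}")

    @staticmethod
    def reverse_validation_spec(task: str = "binary") -> "ClassifierSpec":
        return ClassifierSpec(task, hidden=512, learning_rate=1e-4, epochs=35)


class Classifier:
    """Trained task classifier exposing predictions and the hidden layer."""

    def __init__(self, model: MLPClassifier, spec: ClassifierSpec):
        self._model = model
        self.spec = spec

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self._model.predict(np.asarray(x, dtype=np.float64))

    def hidden_activations(self, x: np.ndarray) -> np.ndarray:
        """Activations of the last hidden layer (the embedding space)."""
        h = np.asarray(x, dtype=np.float64)
        coefs, intercepts = self._model.coefs_, self._model.intercepts_
        for w, b in zip(coefs[:-1], intercepts[:-1]):
            h = np.maximum(h @ w + b, 0.0)
        return h


def train_classifier(
    data: ExpressionDataset, spec: ClassifierSpec, seed: int = 0
) -> Classifier:
    """Train the MLP of ``spec`` on ``data``; deterministic per seed."""
    labels = data.labels(spec.task)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data carries a single class")
    model = MLPClassifier(
        hidden_layer_sizes=(spec.hidden,),
        activation=spec.activation,
        solver=spec.optimizer,
        learning_rate_init=spec.learning_rate,
        batch_size=min(spec.batch_size, data.n_samples),
        max_iter=spec.epochs,
        n_iter_no_change=spec.epochs,  # no early stopping: fixed budget
        random_state=seed,
        tol=0.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(data.values, labels.astype(str))
    return Classifier(model, spec)


def accuracy(classifier: Classifier, test: ExpressionDataset) -> float:
    """Fraction of correct predictions on a held-out set."""
    if test.n_samples == 0:
        raise ValueError("empty test set")
    labels = test.labels(classifier.spec.task).astype(str)
    return float(np.mean(classifier.predict(test.values) == labels))


# ----------------------------------------------------------------------
# augmentation gain
# ----------------------------------------------------------------------

GeneratedSource = Union[ExpressionDataset, str, Callable]


@dataclass
class AugmentationGain:
    delta_acc: float
    acc_with: tuple  # (mean, std)
    acc_without: tuple
    n_true: int
    m_generated: int
    runs_with: list = field(default_factory=list)
    runs_without: list = field(default_factory=list)
    seeds: list = field(default_factory=list)


def _stratified_subsample(
    pool: ExpressionDataset, n: int, task: str, seed: int
) -> ExpressionDataset:
    if n > pool.n_samples:
        raise ValueError(f"requested {n} true samples from a pool of {pool.n_samples}")
    if n == pool.n_samples:
        return pool
    labels = pool.labels(task)
    idx = np.arange(pool.n_samples)
    try:
        keep, _ = train_test_split(
            idx, train_size=n, stratify=labels, random_state=seed
        )
    except ValueError:
        keep, _ = train_test_split(idx, train_size=n, random_state=seed)
    return pool.subset(keep)


def _draw_generated(
    source: GeneratedSource, subsample: ExpressionDataset, m: int, seed: int
) -> ExpressionDataset:
    from .generative_models import GenerativeModel, generate

    if isinstance(source, ExpressionDataset):
        if source.n_samples < m:
            raise ValueError(
                f"generated pool has {source.n_samples} samples; {m} requested"
            )
        rng = np.random.default_rng(seed)
        return source.subset(rng.choice(source.n_samples, size=m, replace=False))
    if isinstance(source, GenerativeModel):
        return generate(source, m, covariate_source=subsample, seed=seed)
    if source == "gaussian_noise":
        return gaussian_noise_augment(subsample, m, variance=0.1, seed=seed)
    if callable(source):
        return source(subsample, m, seed)
    raise TypeError(f"unsupported generated source: {source!r}")


def augmentation_gain(
    n_true: int,
    m_generated: int,
    true_pool: ExpressionDataset,
    generated_source: GeneratedSource,
    spec: ClassifierSpec,
    test: ExpressionDataset,
    n_runs: int = 5,
    seed: int = 0,
) -> AugmentationGain:
    """Test-accuracy gain of training with ``m`` generated samples.

    Per run: draw a stratified subsample of ``n_true`` true samples,
    train the classifier with and without the ``m_generated`` appended
    samples, and evaluate both on the fixed true test set.  The gain is
    ``mean Acc(n, m) - mean Acc(n, 0)``; with ``m_generated == 0`` both
    arms are the same training run, so the gain is exactly 0.
    """
    seeds = [seed + r for r in range(n_runs)]
    runs_with, runs_without = [], []
    for s in seeds:
        sub = _stratified_subsample(true_pool, n_true, spec.task, s)
        acc0 = accuracy(train_classifier(sub, spec, seed=s), test)
        runs_without.append(acc0)
        if m_generated == 0:
            runs_with.append(acc0)
            continue
        gen = _draw_generated(generated_source, sub, m_generated, s)
        acc_m = accuracy(train_classifier(sub.concat(gen), spec, seed=s), test)
        runs_with.append(acc_m)
    mean_with, mean_without = float(np.mean(runs_with)), float(np.mean(runs_without))
    return AugmentationGain(
        delta_acc=mean_with - mean_without,
        acc_with=(mean_with, float(np.std(runs_with))),
        acc_without=(mean_without, float(np.std(runs_without))),
        n_true=n_true,
        m_generated=m_generated,
        runs_with=runs_with,
        runs_without=runs_without,
        seeds=seeds,
    )


def reverse_validation(
    generated: ExpressionDataset,
    true_test: ExpressionDataset,
    seed: int = 0,
    task: str = "binary",
) -> float:
    """Accuracy on true data of a classifier trained on generated data only."""
    if generated.covariates is None:
        raise ValueError("generated data carries no task labels")
    spec = ClassifierSpec.reverse_validation_spec(task)
    clf = train_classifier(generated, spec, seed=seed)
    return accuracy(clf, true_test)


# ----------------------------------------------------------------------
# schedules
# ----------------------------------------------------------------------


@dataclass
class AugmentationCurve:
    """Accuracy as a function of (n_true, m_generated) for one source."""

    task: str
    augmentation_source: str
    points: list  # of (n_true, m_generated, mean_accuracy, std_accuracy)
    n_runs: int
    seeds: list = field(default_factory=list)


def run_schedule(
    schedule_kind: str,
    params: dict,
    sources: dict[str, GeneratedSource],
    spec: ClassifierSpec,
    n_runs: int = 5,
    seed: int = 0,
) -> list[AugmentationCurve]:
    """Sweep an augmentation schedule, one curve per source.

    ``fixed_generated``: fixed ``m_generated`` (default 8000), grid over
    ``n_true_grid``.  ``fixed_true``: fixed ``n_true`` (the paper uses 50
    and 100), grid over ``m_grid``.  ``params`` must carry ``true_pool``
    and ``test`` datasets plus the grid.
    """
    true_pool: ExpressionDataset = params["true_pool"]
    test: ExpressionDataset = params["test"]
    if schedule_kind == "fixed_generated":
        m_fixed = int(params.get("m_generated", 8000))
        grid = [(int(n), m_fixed) for n in params["n_true_grid"]]
    elif schedule_kind == "fixed_true":
        n_fixed = int(params.get("n_true", 50))
        grid = [(n_fixed, int(m)) for m in params["m_grid"]]
    else:
        raise ValueError(f"unknown schedule kind {schedule_kind!r}")

    curves = []
    for name, source in sources.items():
        points, seeds = [], []
        for n_true, m in grid:
            gain = augmentation_gain(
                n_true, m, true_pool, source, spec, test, n_runs=n_runs, seed=seed
            )
            points.append((n_true, m, gain.acc_with[0], gain.acc_with[1]))
            seeds.extend(gain.seeds)
        curves.append(
            AugmentationCurve(
                task=spec.task,
                augmentation_source=name,
                points=points,
                n_runs=n_runs,
                seeds=sorted(set(seeds)),
            )
        )
    return curves


# ----------------------------------------------------------------------
# benchmark orchestration
# ----------------------------------------------------------------------


def benchmark(config: dict) -> dict:
    """Run the full comparison described by a structured config.

    Config keys (all optional unless noted): ``sim`` (simulator
    parameters) or ``data``/``covariates`` paths; ``split``; ``models``
    — list of ``{"name", "kind", "mask", ...train overrides}``;
    ``include_gaussian_baseline``; ``metrics`` — ``k``, ``n_runs``,
    ``n_generated``, ``embeddings``; ``schedules``; ``seed``.  Failures
    of individual models are recorded and do not stop the run.
    """
    from . import attention_masks as am
    from . import generative_models as gm
    from . import quality_metrics as qm
    from .datasets_io import read_expression

    seed = int(config.get("seed", 0))
    if "data" in config:
        data = read_expression(config["data"], config.get("covariates"))
    else:
        data = simulate_transcriptome(SimConfig(**config.get("sim", {}), ))
    spec_cfg = dict(config.get("split", {}))
    spec_cfg.setdefault("seed", seed)
    train_set, val_set, test_set = split(data, SplitSpec(**spec_cfg))

    metrics_cfg = dict(config.get("metrics", {}))
    k = int(metrics_cfg.get("k", 50))
    metric_runs = int(metrics_cfg.get("n_runs", 5))
    n_generated = int(metrics_cfg.get("n_generated", train_set.n_samples))
    subset_size = metrics_cfg.get("subset_size", 2000)

    embeddings = {}
    if metrics_cfg.get("embeddings", True):
        for task in ("binary", "tissue"):
            try:
                embeddings[task] = qm.fit_embedding(train_set, task, seed=seed)
            except ValueError:
                pass  # single-class data: skip this embedding

    masks = {}

    def _mask_for(mode: str | None):
        if mode in (None, "none"):
            return None
        if mode not in masks:
            if mode == "coexp":
                masks[mode] = am.coexpression_mask(
                    train_set, threshold=float(config.get("coexp_threshold", 0.5))
                )
            elif mode == "ppi":
                masks[mode] = am.ppi_mask(
                    config["ppi_edges"], train_set.gene_ids,
                    min_score=float(config.get("ppi_min_score", 0.0)),
                )
            elif mode == "both":
                masks[mode] = am.merge_masks(_mask_for("coexp"), _mask_for("ppi"))
            else:
                raise ValueError(f"unknown mask mode {mode!r}")
        return masks[mode]

    sources: dict = {}
    if config.get("include_gaussian_baseline", True):
        sources["gaussian_noise"] = "gaussian_noise"

    reports, errors, model_seeds = {}, {}, {}
    for entry in config.get("models", []):
        entry = dict(entry)
        name = entry.pop("name", entry.get("kind", "model"))
        mask = _mask_for(entry.pop("mask", None))
        entry.setdefault("seed", seed)
        try:
            tc = gm.TrainConfig(model_kind=entry.pop("kind"), **entry)
            model = gm.train(train_set, tc, mask=mask)
            sources[name] = model
            model_seeds[name] = tc.seed
            reports[name] = qm.compute_report(
                model,
                train_set,
                embeddings=embeddings,
                k=min(k, train_set.n_samples - 1, n_generated - 1),
                subset_size=subset_size,
                n_runs=metric_runs,
                n_generated=n_generated,
                seed=seed,
            ).to_dict()
        except Exception as exc:  # noqa: BLE001 — keep remaining models running
            errors[name] = f"{type(exc).__name__}: {exc}"

    curves = []
    for sched in config.get("schedules", []):
        sched = dict(sched)
        kind = sched.pop("kind")
        task = sched.pop("task", "binary")
        params = {"true_pool": train_set, "test": test_set, **sched}
        curves.extend(
            run_schedule(
                kind,
                params,
                sources,
                ClassifierSpec.for_task(task),
                n_runs=int(sched.get("n_runs", 5)),
                seed=seed,
            )
        )

    return {
        "seed": seed,
        "split_sizes": [train_set.n_samples, val_set.n_samples, test_set.n_samples],
        "reports": reports,
        "errors": errors,
        "model_seeds": model_seeds,
        "curves": [
            {
                "task": c.task,
                "source": c.augmentation_source,
                "points": [list(p) for p in c.points],
                "n_runs": c.n_runs,
                "seeds": c.seeds,
            }
            for c in curves
        ],
        "sources": sorted(sources),
    }
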