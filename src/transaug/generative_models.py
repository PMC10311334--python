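"""Generator/critic architectures, adversarial objectives, and training.

Four model kinds are supported: ``gan`` (sigmoid discriminator,
non-saturating generator loss), ``wgan_gp`` (linear critic with gradient
penalty), ``attgan`` (WGAN-GP objective with a sparse softmin/L1
attention layer polishing the generator output) and ``rand_attgan``
(same, with the attention mask randomly relabelled — the lesion
control).  Conditioning concatenates encoded covariates to the inputs of
both networks; only covariate patterns observed during training are
sampled at generation time.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import engine as eg
from .attention_masks import AttentionMask, random_permutation_mask
from .datasets_io import CovariateEncoder, ExpressionDataset

__all__ = [
    "GanLosses",
    "WganGpLosses",
    "TrainConfig",
    "AttentionLayerParams",
    "GenerativeModel",
    "gan_losses",
    "wgan_gp_losses",
    "gradient_penalty",
    "sparse_attention",
    "build_generator",
    "build_discriminator",
    "train",
    "generate",
    "save_model",
    "load_model",
    "toy_config",
]

_EPS = 1e-7


# ----------------------------------------------------------------------
# losses (array-level contracts; the training loop mirrors them on tensors)
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class GanLosses:
    discriminator_loss: float
    generator_loss: float  # non-saturating: -E[log D(G(z))]
    saturating_generator_loss: float  # E[log(1 - D(G(z)))]
    value: float  # the min-max objective E[log D(x)] + E[log(1 - D(G(z)))]


def gan_losses(d_true, d_fake, eps: float = _EPS) -> GanLosses:
    """Binary-cross-entropy adversarial losses from discriminator outputs.

    ``d_true`` / ``d_fake`` are probabilities; values outside ``[0, 1]``
    raise, and values at the boundary are clamped by ``eps``.
    """
    d_true = np.asarray(d_true, dtype=np.float64).ravel()
    d_fake = np.asarray(d_fake, dtype=np.float64).ravel()
    for name, arr in (("d_true", d_true), ("d_fake", d_fake)):
        if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
            raise ValueError(f"{name} must contain probabilities in [0, 1]")
    d_true = np.clip(d_true, eps, 1 - eps)
    d_fake = np.clip(d_fake, eps, 1 - eps)
    value = float(np.mean(np.log(d_true)) + np.mean(np.log(1 - d_fake)))
    return GanLosses(
        discriminator_loss=-value,
        generator_loss=float(-np.mean(np.log(d_fake))),
        saturating_generator_loss=float(np.mean(np.log(1 - d_fake))),
        value=value,
    )


@dataclass(frozen=True)
class WganGpLosses:
    critic_loss: float  # E[D(fake)] - E[D(true)] + penalty (critic minimizes)
    generator_loss: float  # -E[D(fake)]
    wasserstein_estimate: float  # E[D(true)] - E[D(fake)]


def wgan_gp_losses(d_true, d_fake, penalty: float = 0.0) -> WganGpLosses:
    """WGAN-GP losses from unconstrained critic scores."""
    d_true = np.asarray(d_true, dtype=np.float64).ravel()
    d_fake = np.asarray(d_fake, dtype=np.float64).ravel()
    w = float(np.mean(d_true) - np.mean(d_fake))
    return WganGpLosses(
        critic_loss=-w + float(penalty),
        generator_loss=float(-np.mean(d_fake)),
        wasserstein_estimate=w,
    )


def gradient_penalty(
    critic: Callable[[eg.Tensor], eg.Tensor],
    x_true: np.ndarray,
    x_fake: np.ndarray,
    lam: float = 10.0,
    rng: np.random.Generator | int = 0,
) -> float:
    """``lam * E[(||grad_x D(x~)||_2 - 1)^2]`` at interpolates ``x~``.

    ``critic`` maps a batch tensor to per-sample scores; ``x~`` mixes
    each true/fake row pair with a per-sample uniform weight.
    """
    return gradient_penalty_tensor(critic, x_true, x_fake, lam, rng).item()


def gradient_penalty_tensor(critic, x_true, x_fake, lam, rng) -> eg.Tensor:
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    x_true = np.asarray(x_true, dtype=np.float64)
    x_fake = np.asarray(x_fake, dtype=np.float64)
    if x_true.shape != x_fake.shape:
        raise ValueError("true and fake batches must have the same shape")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    u = rng.uniform(size=(x_true.shape[0], 1))
    x_mix = eg.Tensor(u * x_true + (1.0 - u) * x_fake, requires_grad=True)
    score = critic(x_mix)
    g = eg.grad(score.sum(), [x_mix])[0]
    norm = ((g ** 2.0).sum(axis=1) + 1e-12) ** 0.5
    return ((norm - 1.0) ** 2.0).mean() * lam


# ----------------------------------------------------------------------
# sparse softmin/L1 attention
# ----------------------------------------------------------------------


@dataclass
class AttentionLayerParams:
    """Per-gene scalar key/query/value weights plus the mixing weight gamma.

    Attention is restricted to the masked pairs; the self pair is always
    included so the softmin is defined even for isolated genes.
    ``as_printed`` switches the aggregated value from the neighbor term
    ``w_v[j] * x_j`` (default) to the degenerate self term
    ``w_v[i] * x_i``.
    """

    w_k: np.ndarray
    w_q: np.ndarray
    w_v: np.ndarray
    gamma: float
    mask: AttentionMask
    as_printed: bool = False

    def __post_init__(self):
        self.w_k = np.asarray(self.w_k, dtype=np.float64)
        self.w_q = np.asarray(self.w_q, dtype=np.float64)
        self.w_v = np.asarray(self.w_v, dtype=np.float64)
        d = self.mask.n_genes
        for name, w in (("w_k", self.w_k), ("w_q", self.w_q), ("w_v", self.w_v)):
            if w.shape != (d,):
                raise ValueError(f"{name} must have length n_genes={d}")


def _attention_indices(mask: AttentionMask) -> tuple[np.ndarray, np.ndarray]:
    """Pair index arrays with self pairs appended."""
    i_idx, j_idx = mask.to_arrays()
    if (i_idx >= mask.n_genes).any() or (j_idx >= mask.n_genes).any():
        raise ValueError("mask index out of range")
    selfs = np.arange(mask.n_genes, dtype=np.intp)
    return np.concatenate([i_idx, selfs]), np.concatenate([j_idx, selfs])


def sparse_attention(x: np.ndarray, params: AttentionLayerParams) -> np.ndarray:
    """Apply the softmin/L1 attention layer to a vector or batch.

    For each gene i with neighborhood N(i) (masked partners plus i):
    ``e_ij = |w_k[i] x_i - w_q[j] x_j|``, ``alpha = softmin(e)`` over
    N(i), output ``x_i + gamma * sum_j alpha_ij v_j`` with
    ``v_j = w_v[j] x_j``.
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    d = params.mask.n_genes
    if x.shape[1] != d:
        raise ValueError(f"expected vectors of length {d}, got {x.shape[1]}")
    I, J = _attention_indices(params.mask)
    e = np.abs(params.w_k[I] * x[:, I] - params.w_q[J] * x[:, J])
    # softmin stabilization: subtract the per-neighborhood minimum score
    m = np.full((x.shape[0], d), np.inf)
    np.minimum.at(m, (slice(None), I), e)
    w = np.exp(-(e - m[:, I]))
    denom = np.zeros((x.shape[0], d))
    np.add.at(denom, (slice(None), I), w)
    alpha = w / denom[:, I]
    if params.as_printed:
        val = params.w_v[I] * x[:, I]
    else:
        val = params.w_v[J] * x[:, J]
    agg = np.zeros((x.shape[0], d))
    np.add.at(agg, (slice(None), I), alpha * val)
    out = x + params.gamma * agg
    return out[0] if single else out


class AttentionLayer:
    """Differentiable sparse attention (mirrors :func:`sparse_attention`)."""

    def __init__(
        self,
        mask: AttentionMask,
        rng: np.random.Generator,
        gamma_mode: str = "learned",
        gamma_init: float = 0.1,
        as_printed: bool = False,
    ):
        d = mask.n_genes
        self.mask = mask
        self.w_k = eg.Tensor(rng.normal(1.0, 0.1, size=d), requires_grad=True)
        self.w_q = eg.Tensor(rng.normal(1.0, 0.1, size=d), requires_grad=True)
        self.w_v = eg.Tensor(rng.normal(0.0, 0.1, size=d), requires_grad=True)
        self.gamma = eg.Tensor(np.array(gamma_init), requires_grad=gamma_mode == "learned")
        self.gamma_mode = gamma_mode
        self.as_printed = as_printed
        self._I, self._J = _attention_indices(mask)
        self.enabled = True

    def __call__(self, x: eg.Tensor) -> eg.Tensor:
        if not self.enabled:
            return x
        I, J = self._I, self._J
        d = self.mask.n_genes
        xi = eg.gather_cols(x, I)
        xj = eg.gather_cols(x, J)
        ki = eg.take(self.w_k, I)
        qj = eg.take(self.w_q, J)
        e = (ki * xi - qj * xj).abs()
        m = np.full((x.shape[0], d), np.inf)
        np.minimum.at(m, (slice(None), I), e.data)
        w = (-(e - eg.Tensor(m[:, I]))).exp()
        denom = eg.scatter_add_cols(w, I, d)
        alpha = w / eg.gather_cols(denom, I)
        if self.as_printed:
            val = eg.take(self.w_v, I) * xi
        else:
            val = eg.take(self.w_v, J) * xj
        agg = eg.scatter_add_cols(alpha * val, I, d)
        return x + self.gamma * agg

    def to_params(self) -> AttentionLayerParams:
        return AttentionLayerParams(
            self.w_k.data.copy(),
            self.w_q.data.copy(),
            self.w_v.data.copy(),
            float(self.gamma.data),
            self.mask,
            self.as_printed,
        )

    @property
    def parameters(self) -> list[eg.Tensor]:
        params = [self.w_k, self.w_q, self.w_v]
        if self.gamma.requires_grad:
            params.append(self.gamma)
        return params


# ----------------------------------------------------------------------
# architectures
# ----------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Training configuration (defaults follow the full-scale budgets;
    :func:`toy_config` scales them down for desk-size experiments)."""

    model_kind: str = "wgan_gp"  # gan | wgan_gp | attgan | rand_attgan
    epochs: int = 800
    batch_size: int = 64
    lr_g: float = 1e-4
    lr_d: float = 1e-4
    betas: tuple = (0.5, 0.9)
    lambda_gp: float = 10.0
    n_critic: int = 5
    gamma_mode: str = "learned"  # fixed | learned
    gamma_init: float = 0.1
    pretrain_epochs: int = 0
    d_z: int = 64
    hidden_g: tuple = (128, 128)
    hidden_d: tuple = (128, 128)
    conditional: bool = True
    max_steps: Optional[int] = None  # cap on generator updates
    seed: int = 0

    def __post_init__(self):
        if self.model_kind not in {"gan", "wgan_gp", "attgan", "rand_attgan"}:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lambda_gp < 0:
            raise ValueError("lambda_gp must be >= 0")
        if self.gamma_mode not in {"fixed", "learned"}:
            raise ValueError("gamma_mode must be 'fixed' or 'learned'")


def toy_config(model_kind: str = "wgan_gp", **overrides) -> TrainConfig:
    """Desk-scale profile: small nets, short budget, faster Adam."""
    defaults = dict(
        model_kind=model_kind,
        epochs=50,
        batch_size=64,
        lr_g=5e-4,
        lr_d=5e-4,
        d_z=32,
        hidden_g=(64, 64),
        hidden_d=(64, 64),
    )
    defaults.update(overrides)
    return TrainConfig(**defaults)


class Generator:
    def __init__(
        self,
        config: TrainConfig,
        n_genes: int,
        cond_dim: int,
        rng: np.random.Generator,
        attention: AttentionLayer | None = None,
    ):
        self.mlp = eg.MLP(
            config.d_z + cond_dim, config.hidden_g, n_genes, rng, out_activation="sigmoid"
        )
        self.attention = attention
        self.n_genes = n_genes
        self.cond_dim = cond_dim
        self.d_z = config.d_z

    def __call__(self, z: eg.Tensor, cond: eg.Tensor | None = None) -> eg.Tensor:
        h = eg.concat_cols([z, cond]) if cond is not None else z
        out = self.mlp(h)
        if self.attention is not None:
            out = self.attention(out).clip(0.0, 1.0)
        return out

    @property
    def parameters(self) -> list[eg.Tensor]:
        params = list(self.mlp.parameters)
        if self.attention is not None:
            params += self.attention.parameters
        return params


class Discriminator:
    def __init__(
        self, config: TrainConfig, n_genes: int, cond_dim: int, rng: np.random.Generator
    ):
        out_act = "sigmoid" if config.model_kind == "gan" else None
        self.mlp = eg.MLP(n_genes + cond_dim, config.hidden_d, 1, rng, out_activation=out_act)
        self.cond_dim = cond_dim

    def __call__(self, x: eg.Tensor, cond: eg.Tensor | None = None) -> eg.Tensor:
        h = eg.concat_cols([x, cond]) if cond is not None else x
        return self.mlp(h)

    @property
    def parameters(self) -> list[eg.Tensor]:
        return self.mlp.parameters


def build_generator(
    config: TrainConfig,
    n_genes: int,
    cond_dim: int = 0,
    mask: AttentionMask | None = None,
    rng: np.random.Generator | int = 0,
    attention_rng: np.random.Generator | None = None,
) -> Generator:
    """Generator mapping (z, covariates) to an expression vector in [0, 1]."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    attention = None
    if config.model_kind in {"attgan", "rand_attgan"}:
        if mask is None:
            raise ValueError(f"model_kind {config.model_kind!r} requires an attention mask")
        attention = AttentionLayer(
            mask,
            attention_rng if attention_rng is not None else rng,
            gamma_mode=config.gamma_mode,
            gamma_init=config.gamma_init,
        )
    return Generator(config, n_genes, cond_dim, rng, attention)


def build_discriminator(
    config: TrainConfig, n_genes: int, cond_dim: int = 0, rng: np.random.Generator | int = 0
) -> Discriminator:
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return Discriminator(config, n_genes, cond_dim, rng)


@dataclass
class GenerativeModel:
    """A trained generator/discriminator pair with its configuration."""

    generator: Generator
    discriminator: Discriminator
    config: TrainConfig
    gene_ids: list
    encoder: Optional[CovariateEncoder] = None
    mask: Optional[AttentionMask] = None
    history: dict = field(default_factory=dict)
    seed: int = 0


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------


def train(
    train_data: ExpressionDataset | np.ndarray,
    config: TrainConfig,
    mask: AttentionMask | None = None,
) -> GenerativeModel:
    """Adversarial training of the configured model on normalized data.

    Alternates ``n_critic`` discriminator updates per generator update
    (``n_critic`` is forced to 1 for the plain GAN).  With
    ``pretrain_epochs > 0`` the attention layer is disabled (gamma
    effectively 0) for the warm-up epochs.  Deterministic per
    ``config.seed``.
    """
    if isinstance(train_data, np.ndarray):
        train_data = ExpressionDataset(
            train_data,
            [f"gene_{j}" for j in range(train_data.shape[1])],
            [f"sample_{i}" for i in range(train_data.shape[0])],
        )
    x = train_data.values
    n, d = x.shape

    encoder = None
    cond = None
    if config.conditional and train_data.covariates is not None:
        encoder = CovariateEncoder().fit(train_data.covariates)
        cond = encoder.transform(train_data.covariates)
    cond_dim = 0 if cond is None else cond.shape[1]

    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng_g, rng_d, rng_att, rng_train = (np.random.default_rng(s) for s in ss)

    if config.model_kind == "rand_attgan":
        if mask is None:
            raise ValueError("rand_attgan requires a source attention mask")
        mask = random_permutation_mask(mask, seed=int(rng_att.integers(2 ** 31)))

    generator = build_generator(config, d, cond_dim, mask, rng_g, attention_rng=rng_att)
    discriminator = build_discriminator(config, d, cond_dim, rng_d)

    opt_g = eg.Adam(generator.parameters, lr=config.lr_g, betas=config.betas)
    opt_d = eg.Adam(discriminator.parameters, lr=config.lr_d, betas=config.betas)

    is_gan = config.model_kind == "gan"
    n_critic = 1 if is_gan else max(1, config.n_critic)
    batch = min(config.batch_size, n)

    history: dict = {"d_loss": [], "g_loss": []}
    history["saturating_g_loss" if is_gan else "wasserstein"] = []
    if generator.attention is not None:
        history["gamma"] = []

    gen_steps = 0
    critic_count = 0
    done = False
    for epoch in range(config.epochs):
        if generator.attention is not None:
            generator.attention.enabled = epoch >= config.pretrain_epochs
        order = rng_train.permutation(n)
        d_losses, g_losses, extras = [], [], []
        for start in range(0, n - batch + 1, batch):
            rows = order[start : start + batch]
            xb = x[rows]
            cb = eg.Tensor(cond[rows]) if cond is not None else None

            # --- discriminator / critic update
            z = rng_train.standard_normal((len(rows), config.d_z))
            x_fake = generator(eg.Tensor(z), cb).detach()
            d_true = discriminator(eg.Tensor(xb), cb)
            d_fake = discriminator(x_fake, cb)
            if is_gan:
                eps = _EPS
                loss_d = (
                    -(d_true.clip(eps, 1 - eps).log().mean())
                    - (1.0 - d_fake.clip(eps, 1 - eps)).log().mean()
                )
            else:
                critic_fn = (
                    (lambda xt: discriminator(xt, cb)) if cb is not None else discriminator
                )
                gp = gradient_penalty_tensor(
                    critic_fn, xb, x_fake.data, config.lambda_gp, rng_train
                )
                loss_d = d_fake.mean() - d_true.mean() + gp
                extras.append(float(d_true.data.mean() - d_fake.data.mean()))
            opt_d.zero_grad()
            loss_d.backward()
            opt_d.step()
            d_losses.append(loss_d.item())
            critic_count += 1

            # --- generator update every n_critic batches
            if critic_count % n_critic == 0:
                z = rng_train.standard_normal((batch, config.d_z))
                if cond is not None:
                    grows = rng_train.integers(0, n, size=batch)
                    cg = eg.Tensor(cond[grows])
                else:
                    cg = None
                x_gen = generator(eg.Tensor(z), cg)
                d_gen = discriminator(x_gen, cg)
                if is_gan:
                    eps = _EPS
                    dg = d_gen.clip(eps, 1 - eps)
                    loss_g = -(dg.log().mean())
                    extras.append(float(np.mean(np.log(1 - np.clip(d_gen.data, eps, 1 - eps)))))
                else:
                    loss_g = -(d_gen.mean())
                opt_g.zero_grad()
                loss_g.backward()
                opt_g.step()
                g_losses.append(loss_g.item())
                gen_steps += 1
                if config.max_steps is not None and gen_steps >= config.max_steps:
                    done = True
                    break
        history["d_loss"].append(float(np.mean(d_losses)) if d_losses else np.nan)
        history["g_loss"].append(float(np.mean(g_losses)) if g_losses else np.nan)
        key = "saturating_g_loss" if is_gan else "wasserstein"
        history[key].append(float(np.mean(extras)) if extras else np.nan)
        if generator.attention is not None:
            history["gamma"].append(float(generator.attention.gamma.data))
        for name, losses in (("d_loss", d_losses), ("g_loss", g_losses)):
            if losses and not np.isfinite(losses).all():
                raise RuntimeError(
                    f"non-finite {name} at epoch {epoch}: "
                    f"d_loss={history['d_loss'][-1]}, g_loss={history['g_loss'][-1]}"
                )
        if done:
            break

    if generator.attention is not None:
        generator.attention.enabled = True
    return GenerativeModel(
        generator=generator,
        discriminator=discriminator,
        config=config,
        gene_ids=list(train_data.gene_ids),
        encoder=encoder,
        mask=mask,
        history=history,
        seed=config.seed,
    )


def generate(
    model: GenerativeModel,
    m: int,
    covariate_source: ExpressionDataset | None = None,
    seed: int = 0,
) -> ExpressionDataset:
    """Draw ``m`` samples from a model, conditioning on observed patterns.

    Each sample draws one observed covariate pattern (with replacement)
    and one latent vector; generated rows carry the sampled covariates
    as labels and are clipped to ``[0, 1]``.
    """
    if m <= 0:
        raise ValueError("m must be a positive count")
    rng = np.random.default_rng(seed)
    encoder = model.encoder
    patterns = None
    cond = None
    if encoder is not None:
        if covariate_source is not None and covariate_source.covariates is not None:
            idx = rng.integers(0, covariate_source.n_samples, size=m)
            patterns = covariate_source.covariates.iloc[idx].reset_index(drop=True)
        else:
            patterns = encoder.sample_patterns(m, rng)
        cond = encoder.transform(patterns)
    z = rng.standard_normal((m, model.generator.d_z))
    out = np.empty((m, model.generator.n_genes))
    chunk = 1024
    for start in range(0, m, chunk):
        sl = slice(start, min(start + chunk, m))
        cb = eg.Tensor(cond[sl]) if cond is not None else None
        out[sl] = model.generator(eg.Tensor(z[sl]), cb).data
    out = np.clip(out, 0.0, 1.0)
    ids = [f"gen_{k}" for k in range(m)]
    cov = patterns.copy() if patterns is not None else None
    return ExpressionDataset(out, list(model.gene_ids), ids, cov)


# ----------------------------------------------------------------------
# checkpoints
# ----------------------------------------------------------------------


def save_model(model: GenerativeModel, path) -> None:
    """Serialize the model; a JSON sidecar records config and history."""
    with open(path, "wb") as fh:
        pickle.dump(model, fh)
    sidecar = {
        "config": asdict(model.config),
        "seed": model.seed,
        "history": model.history,
        "n_genes": len(model.gene_ids),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)


def load_model(path) -> GenerativeModel:
    with open(path, "rb") as fh:
        return pickle.load(fh)
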