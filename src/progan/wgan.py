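"""Wasserstein GAN with gradient penalty for rescaled expression profiles.

The generator maps a 100-dimensional latent vector to one expression profile
(one value per gene, on the [0, 1]-rescaled scale); the critic scores
profiles. Hidden widths default to 450 (generator) and 270 (critic), the
penalty weight to 10, and generator weights initialize uniformly in
[-0.3, 0.3].

The training unit is one generator update ("step"), preceded by
``critic_steps_per_gen`` critic updates (default 5). The latent prior is a
normal with mean 0.5 and standard deviation 1/3.918 truncated to [0, 1] —
matching the marginal of the rescaled training data — with a plain
Uniform(0, 1) alternative.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .nn import MLP, Adam, pearson_rows
from .preprocess import RESCALE_CONSTANT


@dataclass
class GanConfig:
    output_dim: int
    latent_dim: int = 100
    gen_hidden: int = 450
    critic_hidden: int = 270
    lrelu_slope: float = 0.3
    gp_lambda: float = 10.0
    lr: float = 1e-5
    betas: tuple[float, float] = (0.5, 0.9)
    batch_size: int = 32
    n_gen_steps: int = 5000
    critic_steps_per_gen: int = 5
    init_range: float = 0.3
    checkpoint_interval: int = 500
    latent_prior: str = "truncnorm"  # or "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("output_dim", "latent_dim", "gen_hidden", "critic_hidden",
                     "batch_size", "critic_steps_per_gen", "checkpoint_interval"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_gen_steps < 0:
            raise ValueError("n_gen_steps must be >= 0")
        if self.gp_lambda < 0:
            raise ValueError("gp_lambda must be >= 0")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.latent_prior not in ("truncnorm", "uniform"):
            raise ValueError(f"unknown latent_prior {self.latent_prior!r}")

    @property
    def gen_sizes(self) -> tuple[int, int, int, int]:
        return (self.latent_dim, self.gen_hidden, self.gen_hidden, self.output_dim)

    @property
    def critic_sizes(self) -> tuple[int, int, int, int]:
        return (self.output_dim, self.critic_hidden, self.critic_hidden, 1)


@dataclass
class GanModel:
    config: GanConfig
    generator: MLP
    critic: MLP
    step: int = 0


@dataclass
class Checkpoint:
    step: int
    generator_params: dict[str, np.ndarray]
    critic_loss: float
    generator_loss: float
    penalty: float


def init_model(config: GanConfig) -> GanModel:
    """Initialize generator and critic; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    gen = MLP(config.gen_sizes, config.lrelu_slope, config.init_range, rng)
    critic = MLP(config.critic_sizes, config.lrelu_slope, config.init_range, rng)
    return GanModel(config=config, generator=gen, critic=critic)


def sample_latent(config: GanConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw latent vectors from the configured prior."""
    if config.latent_prior == "uniform":
        return rng.random((n, config.latent_dim))
    mu, sd = 0.5, 1.0 / RESCALE_CONSTANT
    a, b = (0.0 - mu) / sd, (1.0 - mu) / sd
    return stats.truncnorm.rvs(
        a, b, loc=mu, scale=sd, size=(n, config.latent_dim), random_state=rng
    )


def generate(model: GanModel, latent_batch: np.ndarray) -> np.ndarray:
    """Decode latent vectors to profiles; pure function of (params, z)."""
    z = np.atleast_2d(np.asarray(latent_batch, dtype=float))
    if z.shape[1] != model.config.latent_dim:
        raise ValueError(
            f"latent dimension {z.shape[1]} != configured {model.config.latent_dim}"
        )
    return model.generator.forward(z)


def wgan_gp_losses(
    model: GanModel,
    real_batch: np.ndarray,
    latent_batch: np.ndarray,
    mix_coefficients: np.ndarray,
) -> tuple[float, float, float]:
    """Evaluate the WGAN-GP losses for one batch.

    ``critic_loss = mean D(fake) - mean D(real) + lambda * penalty`` with
    ``penalty = mean (||grad D(xhat)|| - 1)^2`` at
    ``xhat = eps*real + (1-eps)*fake``; ``generator_loss = -mean D(fake)``.
    """
    real = np.asarray(real_batch, dtype=float)
    z = np.asarray(latent_batch, dtype=float)
    eps = np.asarray(mix_coefficients, dtype=float).reshape(-1, 1)
    if real.shape[0] != z.shape[0] or real.shape[0] != eps.shape[0]:
        raise ValueError("real batch, latent batch and mix coefficients must agree in size")
    if np.any(eps < 0) or np.any(eps > 1):
        raise ValueError("mix coefficients must lie in [0, 1]")
    fake = generate(model, z)
    d_real = model.critic.forward(real)[:, 0]
    d_fake = model.critic.forward(fake)[:, 0]
    xhat = eps * real + (1.0 - eps) * fake
    penalty, _ = model.critic.gradient_penalty(xhat)
    critic_loss = float(d_fake.mean() - d_real.mean() + model.config.gp_lambda * penalty)
    gen_loss = float(-d_fake.mean())
    return critic_loss, gen_loss, float(penalty)


def _critic_update(model, opt, real, z, eps):
    cfg = model.config
    B = real.shape[0]
    fake = generate(model, z)
    _, cache_r = model.critic.forward(real, cache=True)
    _, cache_f = model.critic.forward(fake, cache=True)
    ones = np.ones((B, 1))
    grads_r, _ = model.critic.backward(cache_r, -ones / B)
    grads_f, _ = model.critic.backward(cache_f, ones / B)
    xhat = eps.reshape(-1, 1) * real + (1.0 - eps.reshape(-1, 1)) * fake
    penalty, pcache = model.critic.gradient_penalty(xhat)
    pgrads = model.critic.penalty_param_grads(pcache)
    grads = {k: grads_r[k] + grads_f[k] + cfg.gp_lambda * pgrads[k] for k in grads_r}
    opt.step(model.critic.params, grads)
    d_real = model.critic.forward(real)[:, 0].mean()
    d_fake = model.critic.forward(fake)[:, 0].mean()
    return float(d_fake - d_real + cfg.gp_lambda * penalty), float(penalty)


def _generator_update(model, opt, z):
    B = z.shape[0]
    fake, gcache = model.generator.forward(z, cache=True)
    _, ccache = model.critic.forward(fake, cache=True)
    # dL/d(D(fake)) for L = -mean D(fake)
    _, dfake = model.critic.backward(ccache, -np.ones((B, 1)) / B)
    grads, _ = model.generator.backward(gcache, dfake)
    opt.step(model.generator.params, grads)
    d_fake = model.critic.forward(model.generator.forward(z))[:, 0].mean()
    return float(-d_fake)


def train(
    model: GanModel,
    data: np.ndarray | pd.DataFrame,
    log_path=None,
) -> list[Checkpoint]:
    """Alternating critic/generator training on rescaled profiles.

    ``data`` is samples x genes (a rescaled matrix transposed to rows =
    samples is accepted as a DataFrame of genes x samples). Snapshots of the
    generator are taken every ``checkpoint_interval`` generator steps and at
    the final step. Deterministic given the config seed.
    """
    cfg = model.config
    if isinstance(data, pd.DataFrame):
        data = data.to_numpy().T  # genes x samples -> samples x genes
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != cfg.output_dim:
        raise ValueError(f"data shape {data.shape} incompatible with output_dim {cfg.output_dim}")
    if data.shape[0] < cfg.batch_size:
        raise ValueError(
            f"need at least batch_size={cfg.batch_size} samples, got {data.shape[0]}"
        )
    rng = np.random.default_rng((cfg.seed, 1))
    opt_c = Adam(model.critic.params, cfg.lr, cfg.betas)
    opt_g = Adam(model.generator.params, cfg.lr, cfg.betas)

    checkpoints: list[Checkpoint] = []
    log_rows = []
    c_loss = g_loss = penalty = float("nan")
    for step in range(1, cfg.n_gen_steps + 1):
        for _ in range(cfg.critic_steps_per_gen):
            idx = rng.choice(data.shape[0], size=cfg.batch_size, replace=False)
            z = sample_latent(cfg, cfg.batch_size, rng)
            eps = rng.random(cfg.batch_size)
            c_loss, penalty = _critic_update(model, opt_c, data[idx], z, eps)
        z = sample_latent(cfg, cfg.batch_size, rng)
        g_loss = _generator_update(model, opt_g, z)
        model.step = step
        if not (np.isfinite(c_loss) and np.isfinite(g_loss)):
            raise FloatingPointError(
                f"non-finite loss at step {step}: critic={c_loss}, generator={g_loss}"
            )
        if step % cfg.checkpoint_interval == 0 or step == cfg.n_gen_steps:
            if not checkpoints or checkpoints[-1].step != step:
                checkpoints.append(Checkpoint(
                    step=step,
                    generator_params=model.generator.copy_params(),
                    critic_loss=c_loss, generator_loss=g_loss, penalty=penalty,
                ))
            log_rows.append({
                "step": step, "critic_loss": c_loss, "generator_loss": g_loss,
                "penalty": penalty, "batch_size": cfg.batch_size,
                "gp_lambda": cfg.gp_lambda,
            })
    if log_path is not None:
        pd.DataFrame(
            log_rows,
            columns=["step", "critic_loss", "generator_loss", "penalty",
                     "batch_size", "gp_lambda"],
        ).to_csv(log_path, sep="\t", index=False)
    return checkpoints


def evaluate(
    model: GanModel,
    reference_samples: np.ndarray | pd.DataFrame,
    n_draws: int = 10_000,
    top_k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Max and top-k mean Pearson correlation of each reference sample
    against ``n_draws`` generated profiles.

    Constant reference profiles yield NaN with a warning.
    """
    import warnings

    if isinstance(reference_samples, pd.DataFrame):
        index = reference_samples.columns
        refs = reference_samples.to_numpy().T
    else:
        refs = np.atleast_2d(np.asarray(reference_samples, dtype=float))
        index = pd.RangeIndex(refs.shape[0])
    rng = np.random.default_rng((model.config.seed, 2, seed))
    z = sample_latent(model.config, n_draws, rng)
    fake = generate(model, z)
    r = pearson_rows(refs, fake)  # (n_refs, n_draws)
    if np.isnan(r).all(axis=1).any():
        warnings.warn("constant reference profile(s): correlation undefined, reported as NaN")
    order = np.argsort(-np.nan_to_num(r, nan=-2.0), axis=1)
    topk = np.take_along_axis(r, order[:, :top_k], axis=1)
    return pd.DataFrame(
        {"max_corr": r.max(axis=1), "topk_mean_corr": topk.mean(axis=1)},
        index=index,
    )


# -- checkpoint serialization ----------------------------------------------


def save_checkpoints(checkpoints: list[Checkpoint], config: GanConfig, path_prefix) -> None:
    """Write checkpoints as an .npz container plus a JSON manifest."""
    arrays = {}
    manifest = {"config": asdict(config), "steps": []}
    for ck in checkpoints:
        for k, v in ck.generator_params.items():
            arrays[f"step{ck.step}:{k}"] = v
        manifest["steps"].append({
            "step": ck.step, "critic_loss": ck.critic_loss,
            "generator_loss": ck.generator_loss, "penalty": ck.penalty,
        })
    np.savez(f"{path_prefix}.npz", **arrays)
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_checkpoints(path_prefix) -> tuple[list[Checkpoint], GanConfig]:
    with open(f"{path_prefix}.json") as fh:
        manifest = json.load(fh)
    cfg_d = manifest["config"]
    cfg_d["betas"] = tuple(cfg_d["betas"])
    config = GanConfig(**cfg_d)
    data = np.load(f"{path_prefix}.npz")
    checkpoints = []
    for entry in manifest["steps"]:
        step = entry["step"]
        params = {k: data[f"step{step}:{k}"]
                  for k in ("W1", "b1", "W2", "b2", "W3", "b3")}
        checkpoints.append(Checkpoint(
            step=step, generator_params=params,
            critic_loss=entry["critic_loss"],
            generator_loss=entry["generator_loss"], penalty=entry["penalty"],
        ))
    return checkpoints, config
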