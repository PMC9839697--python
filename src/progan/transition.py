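"""Latent matching, condition difference vectors, and four-way transition
curves.

For each augmented sample, the best-matching region of latent space is found
by decoding a large pool of latent draws, ranking the decoded profiles by
Pearson correlation with the sample, and averaging the top-k latents. The
per-condition mean of these matched latents defines difference vectors
``Delta = mean(z_end) - mean(z_start)``; moving every start latent along
``z(t, i) = z_start(i) + t * Delta`` and decoding gives, after averaging over
start latents, one transition curve ``T(t)`` per gene.

Four comparisons are extracted: TC1 (late phenotype, WT6M -> AD6M), TC2 (WT
maturation, WT3M -> WT6M), TC3 (early phenotype, WT3M -> AD3M) and TC4 (AD
maturation, AD3M -> AD6M). Curves can be averaged over several late-training
checkpoints, re-matching latents at each checkpoint.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GROUPS
from .nn import pearson_rows
from .preprocess import AugmentedSet, RescaledMatrix, ScalingParams, unrescale_array
from .wgan import Checkpoint, GanModel, generate, init_model, sample_latent

#: Comparison label -> (start group, end group).
COMPARISONS = {
    "TC1": ("WT6M", "AD6M"),
    "TC2": ("WT3M", "WT6M"),
    "TC3": ("WT3M", "AD3M"),
    "TC4": ("AD3M", "AD6M"),
}

DEFAULT_T_GRID = tuple(round(0.05 * k, 10) for k in range(21))


def _check_t_grid(t_grid) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or not np.all(np.diff(t) > 0):
        raise ValueError("t grid must be sorted and strictly increasing")
    if t[0] != 0.0 or t[-1] != 1.0:
        raise ValueError("t grid must start at 0 and end at 1")
    return t


@dataclass
class MatchedLatent:
    sample_id: str
    z_mean: np.ndarray  # averaged latent <z>
    profile: np.ndarray  # realized profile G(<z>)
    correlation: float  # Pearson corr of G(<z>) with the target


@dataclass
class DeltaVector:
    label: str
    start_group: str
    end_group: str
    delta: np.ndarray


def match_latents(
    model: GanModel,
    targets: np.ndarray,
    sample_ids=None,
    n_draws: int = 10_000,
    top_k: int = 10,
    seed: int = 0,
    latent_pool: np.ndarray | None = None,
) -> list[MatchedLatent]:
    """Match each target profile to an averaged latent.

    One shared pool of ``n_draws`` latents is decoded once and ranked against
    every target (ties broken by draw order); the top-``top_k`` latents per
    target are averaged and re-decoded. A pre-drawn ``latent_pool`` may be
    supplied to share draws across calls.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if sample_ids is None:
        sample_ids = [str(i) for i in range(targets.shape[0])]
    if top_k < 1 or n_draws < top_k:
        raise ValueError("need n_draws >= top_k >= 1")
    if np.any(targets.std(axis=1) == 0):
        raise ValueError("constant target profile: correlation undefined")
    if latent_pool is None:
        rng = np.random.default_rng((model.config.seed, 3, seed))
        latent_pool = sample_latent(model.config, n_draws, rng)
    fake = generate(model, latent_pool)
    r = pearson_rows(targets, fake)  # (n_targets, n_draws)
    # stable sort keeps draw order among ties
    order = np.argsort(-r, axis=1, kind="stable")[:, :top_k]
    out = []
    for i, sid in enumerate(sample_ids):
        z_mean = latent_pool[order[i]].mean(axis=0)
        profile = generate(model, z_mean[None, :])[0]
        corr = float(pearson_rows(targets[i][None, :], profile[None, :])[0, 0])
        out.append(MatchedLatent(sample_id=str(sid), z_mean=z_mean,
                                 profile=profile, correlation=corr))
    return out


def match_latent(model, target, n_draws: int = 10_000, top_k: int = 10,
                 seed: int = 0) -> MatchedLatent:
    """Single-target convenience wrapper around :func:`match_latents`."""
    return match_latents(model, np.atleast_2d(target), n_draws=n_draws,
                         top_k=top_k, seed=seed)[0]


def condition_latents(
    model: GanModel,
    augset_values: pd.DataFrame,
    group_samples: list[str],
    n_draws: int = 10_000,
    top_k: int = 10,
    seed: int = 0,
    latent_pool: np.ndarray | None = None,
) -> list[MatchedLatent]:
    """One matched latent per augmented sample of a group."""
    if not group_samples:
        raise ValueError("group has no samples")
    targets = augset_values.loc[:, group_samples].to_numpy().T
    return match_latents(model, targets, sample_ids=group_samples,
                         n_draws=n_draws, top_k=top_k, seed=seed,
                         latent_pool=latent_pool)


def delta(start_latents: list[MatchedLatent], end_latents: list[MatchedLatent],
          label: str) -> DeltaVector:
    """Difference vector: mean latent of the end minus the start condition."""
    if not start_latents or not end_latents:
        raise ValueError("start and end latent lists must be non-empty")
    zs = np.stack([m.z_mean for m in start_latents])
    ze = np.stack([m.z_mean for m in end_latents])
    if zs.shape[1] != ze.shape[1]:
        raise ValueError("latent dimension mismatch")
    start_group, end_group = COMPARISONS.get(label, ("", ""))
    return DeltaVector(label=label, start_group=start_group,
                       end_group=end_group, delta=ze.mean(axis=0) - zs.mean(axis=0))


def transition_curves(
    model: GanModel,
    start_latents: list[MatchedLatent],
    dv: DeltaVector,
    t_grid=DEFAULT_T_GRID,
) -> np.ndarray:
    """Curve block (genes x n_t): ``T(t) = mean_i G(z_start(i) + t*Delta)``."""
    t = _check_t_grid(t_grid)
    zs = np.stack([m.z_mean for m in start_latents])  # (n, latent)
    if zs.shape[1] != dv.delta.shape[0]:
        raise ValueError("latent dimension mismatch between starts and delta")
    out = np.empty((model.config.output_dim, len(t)))
    for j, tj in enumerate(t):
        profiles = generate(model, zs + tj * dv.delta)  # (n, genes)
        out[:, j] = profiles.mean(axis=0)
    return out


@dataclass
class TransitionCurveSet:
    """Per-gene curves for the four comparisons, optionally checkpoint-averaged."""

    gene_ids: pd.Index
    t_grid: np.ndarray
    values: np.ndarray  # (genes, 4, n_t), comparison order TC1..TC4
    n_checkpoints: int = 1
    checkpoint_steps: tuple[int, ...] = ()

    def comparison(self, label: str) -> np.ndarray:
        return self.values[:, list(COMPARISONS).index(label), :]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for ci, label in enumerate(COMPARISONS):
            df = pd.DataFrame(self.values[:, ci, :], index=self.gene_ids,
                              columns=self.t_grid)
            long = df.stack().rename("value").reset_index()
            long.columns = ["gene_id", "t", "value"]
            long.insert(1, "comparison", label)
            rows.append(long)
        return pd.concat(rows, ignore_index=True)

    def write(self, path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read(cls, path) -> "TransitionCurveSet":
        long = pd.read_csv(path, sep="\t")
        t_grid = np.array(sorted(long["t"].unique()))
        gene_ids = pd.Index(long["gene_id"].unique(), name="gene_id")
        values = np.empty((len(gene_ids), 4, len(t_grid)))
        for ci, label in enumerate(COMPARISONS):
            sub = long[long["comparison"] == label].pivot(
                index="gene_id", columns="t", values="value"
            )
            values[:, ci, :] = sub.reindex(index=gene_ids, columns=t_grid).to_numpy()
        return cls(gene_ids=gene_ids, t_grid=t_grid, values=values)


def fourway_tcs(
    checkpoints: list[Checkpoint],
    augset: AugmentedSet,
    rescaled: RescaledMatrix,
    t_grid=DEFAULT_T_GRID,
    n_draws: int = 10_000,
    top_k: int = 10,
    seed: int = 0,
    config=None,
    to_expression_scale: bool = True,
) -> TransitionCurveSet:
    """Checkpoint-averaged four-way transition curves.

    For every checkpoint the generator is restored, latents are re-matched for
    all four conditions, difference vectors and curves are computed, and the
    resulting (genes x 4 x n_t) blocks are averaged pointwise. If
    ``to_expression_scale`` is set, curves are mapped back from the [0, 1]
    rescaled range to the log-expression scale so that genes keep their
    distinct expression levels.
    """
    if not checkpoints:
        raise ValueError("need at least one checkpoint")
    t = _check_t_grid(t_grid)
    if config is None:
        raise ValueError("config is required to restore generators")
    gene_ids = rescaled.values.index
    total = np.zeros((len(gene_ids), 4, len(t)))
    steps = []
    for ck_i, ck in enumerate(checkpoints):
        model = init_model(config)
        model.generator.set_params(ck.generator_params)
        rng = np.random.default_rng((config.seed, 4, seed, ck.step))
        pool = sample_latent(config, n_draws, rng)
        matched = {
            grp: condition_latents(
                model, rescaled.values, augset.samples_in_group(grp),
                n_draws=n_draws, top_k=top_k, latent_pool=pool,
            )
            for grp in GROUPS
        }
        block = np.empty((len(gene_ids), 4, len(t)))
        for ci, (label, (start, end)) in enumerate(COMPARISONS.items()):
            dv = delta(matched[start], matched[end], label)
            block[:, ci, :] = transition_curves(model, matched[start], dv, t)
        total += block
        steps.append(ck.step)
    values = total / len(checkpoints)
    if values.min() < -0.5 or values.max() > 1.5:
        warnings.warn(
            "transition curves leave the [-0.5, 1.5] sanity band on the "
            "rescaled scale; the generator may be poorly trained"
        )
    if to_expression_scale:
        flat = values.reshape(len(gene_ids), -1)
        values = unrescale_array(flat, rescaled.params).reshape(values.shape)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite transition curve values")
    return TransitionCurveSet(
        gene_ids=gene_ids, t_grid=t, values=values,
        n_checkpoints=len(checkpoints), checkpoint_steps=tuple(steps),
    )


def late_window(checkpoints: list[Checkpoint], fraction: float = 1 / 6,
                minimum: int = 5) -> list[Checkpoint]:
    """Checkpoints from the final ``fraction`` of training (at least
    ``minimum`` of them, or all if fewer exist)."""
    if not checkpoints:
        return []
    last_step = checkpoints[-1].step
    cutoff = last_step * (1.0 - fraction)
    window = [c for c in checkpoints if c.step > cutoff]
    if len(window) < minimum:
        window = checkpoints[-minimum:]
    return window


def curves_from_group_means(
    group_means: pd.DataFrame, t_grid=DEFAULT_T_GRID
) -> TransitionCurveSet:
    """Idealized transition curves: straight lines between group means.

    A GAN-free reference used for noise-free recovery checks and for the
    reduced permutation pipeline: for each comparison the curve interpolates
    linearly from the start-group mean to the end-group mean.
    """
    t = _check_t_grid(t_grid)
    genes = group_means.index
    values = np.empty((len(genes), 4, len(t)))
    for ci, (label, (start, end)) in enumerate(COMPARISONS.items()):
        a = group_means[start].to_numpy()[:, None]
        b = group_means[end].to_numpy()[:, None]
        values[:, ci, :] = a + (b - a) * t[None, :]
    return TransitionCurveSet(gene_ids=genes, t_grid=t, values=values)
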