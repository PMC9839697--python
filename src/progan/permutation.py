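"""Permutation validation: shuffle sample labels, re-run a reduced pipeline,
and quantify the loss of pattern structure.

Samples are permuted in three ways: across all samples, within phenotypes
(ages shuffled inside WT and inside AD), and within age groups (phenotypes
shuffled inside 3M and inside 6M). Every mode preserves the overall multiset
of (phenotype, age) labels, so group sizes are unchanged. For each trial the
reduced pipeline recomputes transition curves under the permuted grouping,
reassigns pattern groups, and reports the fraction of planted genes whose
group is still recovered; trial 0 is always the unpermuted run.

The default reduced pipeline interpolates the permuted group means directly
(the GAN-free idealization of the transition curves); a full scaled-down GAN
pipeline can be requested per trial when time allows.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .patterns import assign_groups, cluster_tcs, recovery_fraction
from .transition import DEFAULT_T_GRID, curves_from_group_means, fourway_tcs, late_window
from . import preprocess, wgan

MODES = ("all", "within_phenotype", "within_age")


@dataclass
class PermutationPlan:
    mode: str = "all"
    n_trials: int = 20
    seed: int = 0
    pipeline: str = "direct"  # "direct" (group-mean curves) or "gan"
    t_grid: tuple = DEFAULT_T_GRID
    theta_strong: float = 0.5
    theta_even: float = 0.2
    gan_config: dict = field(default_factory=dict)  # overrides for pipeline="gan"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown permutation mode {self.mode!r}; expected one of {MODES}")
        if self.n_trials < 0:
            raise ValueError("n_trials must be >= 0")
        if self.pipeline not in ("direct", "gan"):
            raise ValueError(f"unknown pipeline {self.pipeline!r}")


def permute_labels(metadata: pd.DataFrame, mode: str,
                   rng: np.random.Generator | int) -> pd.DataFrame:
    """Permute the (phenotype, age) assignment among samples.

    ``all`` shuffles the label pairs across every sample; ``within_phenotype``
    shuffles them only among samples sharing a phenotype (so phenotypes are
    kept, ages move); ``within_age`` shuffles among samples sharing an age.
    The label multiset — hence every group size — is preserved.
    """
    if mode not in MODES:
        raise ValueError(f"unknown permutation mode {mode!r}; expected one of {MODES}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = metadata.copy()
    if mode == "all":
        strata = [np.arange(len(out))]
    elif mode == "within_phenotype":
        strata = [np.flatnonzero((out["phenotype"] == p).to_numpy())
                  for p in out["phenotype"].unique()]
    else:
        strata = [np.flatnonzero((out["age"] == a).to_numpy())
                  for a in out["age"].unique()]
    ph = out["phenotype"].to_numpy().copy()
    ag = out["age"].to_numpy().copy()
    for idx in strata:
        perm = rng.permutation(idx)
        ph[idx], ag[idx] = ph[perm], ag[perm]
    out["phenotype"], out["age"] = ph, ag
    return out


def _run_reduced_pipeline(matrix: ExpressionMatrix, plan: PermutationPlan,
                          trial_seed: int):
    """Transition curves -> clusters -> pattern groups for one (possibly
    permuted) labelling; returns (assignment, tcs)."""
    if plan.pipeline == "direct":
        tcs = curves_from_group_means(matrix.group_means(), plan.t_grid)
    else:
        augset = preprocess.augment(matrix)
        sr, params = preprocess.standardize(augset)
        rescaled = preprocess.rescale(sr, params)
        cfg = wgan.GanConfig(
            output_dim=len(matrix.gene_ids), seed=trial_seed,
            **plan.gan_config,
        )
        model = wgan.init_model(cfg)
        checkpoints = wgan.train(model, rescaled.values)
        tcs = fourway_tcs(
            late_window(checkpoints), augset, rescaled, t_grid=plan.t_grid,
            config=cfg, seed=trial_seed,
        )
    clusters = cluster_tcs(tcs, seed=trial_seed % (2**31))
    assignment = assign_groups(tcs, clusters, plan.theta_strong, plan.theta_even)
    return assignment, tcs


def _mean_abs_endpoint_contrast(tcs) -> float:
    nets = tcs.values[:, :, -1] - tcs.values[:, :, 0]
    return float(np.mean(np.abs(nets)))


def permutation_study(matrix: ExpressionMatrix, truth_labels: pd.Series,
                      plan: PermutationPlan) -> pd.DataFrame:
    """Run the permutation test; returns one summary row per trial.

    Trial 0 is the unpermuted run; trials 1..n_trials use independent
    permutations of the sample labels under ``plan.mode``. Each row reports
    the pattern-recovery fraction against the planted truth and the mean
    absolute endpoint contrast of the transition curves.
    """
    rows = []
    for trial in range(plan.n_trials + 1):
        trial_seed = plan.seed * 100_003 + trial
        if trial == 0:
            m = matrix
        else:
            md = permute_labels(matrix.metadata, plan.mode,
                                np.random.default_rng((plan.seed, trial)))
            _assert_valid_permutation(matrix.metadata, md, plan.mode)
            m = ExpressionMatrix(values=matrix.values, metadata=md)
        assignment, tcs = _run_reduced_pipeline(m, plan, trial_seed)
        rows.append({
            "trial": trial,
            "mode": "none" if trial == 0 else plan.mode,
            "seed": trial_seed,
            "recovery_fraction": recovery_fraction(assignment.groups, truth_labels),
            "mean_abs_endpoint_contrast": _mean_abs_endpoint_contrast(tcs),
        })
    return pd.DataFrame(rows)


def _assert_valid_permutation(before: pd.DataFrame, after: pd.DataFrame,
                              mode: str) -> None:
    pairs_b = sorted(zip(before["phenotype"], before["age"]))
    pairs_a = sorted(zip(after["phenotype"], after["age"]))
    if pairs_b != pairs_a:
        raise AssertionError("permutation changed the label multiset")
    if mode == "within_phenotype" and not (before["phenotype"] == after["phenotype"]).all():
        raise AssertionError("within_phenotype permutation moved phenotypes")
    if mode == "within_age" and not (before["age"] == after["age"]).all():
        raise AssertionError("within_age permutation moved ages")
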