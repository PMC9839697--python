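"""Augmentation by pairwise linear interpolation and standard-distribution-like
rescaling of log-scale expression values.

Augmentation forms, within each experimental group, every unordered pair of
samples and mixes them as ``x*s1 + (1-x)*s2`` for a grid of fractions
(default 0.1..0.9), so 5 samples per group become 5 + 10*9 = 95 and the
four-group study grows from 20 to 380 training samples.

Standardization centers each gene by its mean over all (augmented) samples
and divides by a robustified denominator: the geometric mean of the gene's
global standard deviation and its largest per-condition standard deviation,
clamped to the interquartile range [Q1, Q3] of that statistic's distribution
over genes.  The standardized values SR are then rescaled to
``SR / (3.918 * sigma_SR) + 0.5`` so that about 95% of values fall in [0, 1]
(3.918 is twice the two-sided 95% normal quantile, 2 x 1.959).
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, GROUPS

DEFAULT_FRACTIONS = tuple(round(0.1 * k, 10) for k in range(1, 10))
RESCALE_CONSTANT = 3.918


@dataclass
class AugmentedSet:
    """Originals plus within-group interpolations, with provenance.

    ``provenance`` has one row per column of ``values``: kind
    ("original"/"interpolated"), the source pair and fraction, and the group.
    """

    values: pd.DataFrame  # genes x augmented samples
    provenance: pd.DataFrame  # sample_id -> kind, s1, s2, x, group

    @property
    def groups(self) -> pd.Series:
        return self.provenance["group"]

    def samples_in_group(self, group: str) -> list[str]:
        g = self.groups
        return list(g.index[g == group])

    def write(self, values_path, provenance_path) -> None:
        df = self.values.copy()
        df.index.name = "gene_id"
        df.to_csv(values_path, sep="\t")
        prov = self.provenance.copy()
        prov.index.name = "sample_id"
        prov.to_csv(provenance_path, sep="\t")

    @classmethod
    def read(cls, values_path, provenance_path) -> "AugmentedSet":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        prov = pd.read_csv(provenance_path, sep="\t", index_col=0)
        return cls(values=values, provenance=prov)


def interpolate_pair(s1: np.ndarray, s2: np.ndarray, x: float) -> np.ndarray:
    """Convex combination ``x*s1 + (1-x)*s2`` of two same-group samples."""
    return x * np.asarray(s1) + (1.0 - x) * np.asarray(s2)


def augment(
    matrix: ExpressionMatrix, fractions: tuple[float, ...] = DEFAULT_FRACTIONS
) -> AugmentedSet:
    """Augment each group with all pairwise interpolations.

    Each unordered within-group pair contributes ``len(fractions)`` samples;
    originals are retained. Groups with fewer than 2 samples are rejected.
    """
    fractions = tuple(fractions)
    if not fractions:
        raise ValueError("fractions must be non-empty")
    for x in fractions:
        if not 0.0 < x < 1.0:
            raise ValueError(f"fraction {x} outside (0, 1)")
    matrix.require_all_groups()
    groups = matrix.groups

    cols: dict[str, np.ndarray] = {}
    prov_rows: list[dict] = []
    for sid in matrix.sample_ids:
        cols[sid] = matrix.values[sid].to_numpy()
        prov_rows.append(
            {"sample_id": sid, "kind": "original", "s1": "", "s2": "",
             "x": np.nan, "group": groups[sid]}
        )
    for grp in GROUPS:
        members = matrix.samples_in_group(grp)
        if len(members) < 2:
            raise ValueError(f"group {grp} has fewer than 2 samples; cannot augment")
        for s1, s2 in itertools.combinations(members, 2):
            v1, v2 = matrix.values[s1].to_numpy(), matrix.values[s2].to_numpy()
            for x in fractions:
                sid = f"{s1}|{s2}|x={x:g}"
                cols[sid] = interpolate_pair(v1, v2, x)
                prov_rows.append(
                    {"sample_id": sid, "kind": "interpolated", "s1": s1,
                     "s2": s2, "x": x, "group": grp}
                )
    values = pd.DataFrame(cols, index=matrix.gene_ids)
    provenance = pd.DataFrame(prov_rows).set_index("sample_id")
    return AugmentedSet(values=values, provenance=provenance)


@dataclass
class ScalingParams:
    """Per-gene standardization parameters and the global rescale state."""

    mu: pd.Series  # per-gene mean over all samples
    sigma: pd.Series  # per-gene std over all samples
    sigma_cond: pd.DataFrame  # genes x 4 conditions
    sigma_gm: pd.Series  # sqrt(sigma * max_k sigma_cond)
    q1: float
    q3: float
    sigma_iqr: pd.Series  # sigma_gm clamped to [q1, q3]
    sigma_sr: float | None = None  # std of pooled SR entries (set by rescale)
    c: float = RESCALE_CONSTANT

    def write(self, path) -> None:
        payload = {
            "q1": self.q1, "q3": self.q3, "sigma_sr": self.sigma_sr, "c": self.c,
            "gene_ids": list(self.mu.index),
            "mu": self.mu.to_list(),
            "sigma": self.sigma.to_list(),
            "sigma_cond": {g: self.sigma_cond[g].to_list() for g in self.sigma_cond},
            "sigma_gm": self.sigma_gm.to_list(),
            "sigma_iqr": self.sigma_iqr.to_list(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def read(cls, path) -> "ScalingParams":
        with open(path) as fh:
            p = json.load(fh)
        idx = pd.Index(p["gene_ids"], name="gene_id")
        return cls(
            mu=pd.Series(p["mu"], index=idx),
            sigma=pd.Series(p["sigma"], index=idx),
            sigma_cond=pd.DataFrame({g: pd.Series(v, index=idx)
                                     for g, v in p["sigma_cond"].items()}),
            sigma_gm=pd.Series(p["sigma_gm"], index=idx),
            q1=p["q1"], q3=p["q3"],
            sigma_iqr=pd.Series(p["sigma_iqr"], index=idx),
            sigma_sr=p["sigma_sr"], c=p["c"],
        )


def standardize(
    augset: AugmentedSet, ddof: int = 1
) -> tuple[pd.DataFrame, ScalingParams]:
    """Standardize each gene with the clamped geometric-mean denominator.

    ``SR[i, j] = (RLD[i, j] - mu[j]) / sigma_IQR[j]`` where ``mu``/``sigma``
    are over all samples (originals + interpolations), per-condition standard
    deviations are over each condition's samples, ``sigma_GM =
    sqrt(sigma * max_k sigma_cond)``, and ``sigma_IQR`` clamps ``sigma_GM``
    into the [Q1, Q3] interquartile band of its own distribution over genes.
    Constant genes are rejected.
    """
    X = augset.values
    groups = augset.groups
    present = set(groups)
    missing = [g for g in GROUPS if g not in present]
    if missing:
        raise ValueError(f"missing conditions: {missing}")

    mu = X.mean(axis=1)
    sigma = X.std(axis=1, ddof=ddof)
    # tolerance absorbs float residue from interpolating identical values
    tol = 1e-12 * np.maximum(1.0, mu.abs())
    const = sigma[sigma <= tol]
    if len(const):
        raise ValueError(f"constant genes (sigma=0): {list(const.index)}")
    sigma_cond = pd.DataFrame(
        {g: X.loc[:, augset.samples_in_group(g)].std(axis=1, ddof=ddof) for g in GROUPS}
    )
    sigma_gm = np.sqrt(sigma * sigma_cond.max(axis=1))
    q1, q3 = np.quantile(sigma_gm.to_numpy(), [0.25, 0.75])
    sigma_iqr = sigma_gm.clip(lower=q1, upper=q3)

    sr = X.sub(mu, axis=0).div(sigma_iqr, axis=0)
    params = ScalingParams(
        mu=mu, sigma=sigma, sigma_cond=sigma_cond, sigma_gm=sigma_gm,
        q1=float(q1), q3=float(q3), sigma_iqr=sigma_iqr,
    )
    return sr, params


@dataclass
class RescaledMatrix:
    """Rescaled values (~[0, 1]) with the parameters needed for inversion."""

    values: pd.DataFrame
    params: ScalingParams

    def write(self, path) -> None:
        df = self.values.copy()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", float_format="%.17g")


def rescale(sr: pd.DataFrame, params: ScalingParams) -> RescaledMatrix:
    """Map SR values to ``SR / (c * sigma_SR) + 0.5`` with c = 3.918."""
    sigma_sr = float(np.std(sr.to_numpy(), ddof=1))
    if sigma_sr == 0:
        raise ValueError("sigma_SR is zero; cannot rescale")
    params.sigma_sr = sigma_sr
    return RescaledMatrix(values=sr / (params.c * sigma_sr) + 0.5, params=params)


def unrescale(rescaled: RescaledMatrix) -> pd.DataFrame:
    """Invert rescale+standardize, recovering log-scale expression."""
    p = rescaled.params
    if p.sigma_sr is None:
        raise ValueError("sigma_sr not set; matrix was not produced by rescale()")
    sr = (rescaled.values - 0.5) * (p.c * p.sigma_sr)
    return sr.mul(p.sigma_iqr, axis=0).add(p.mu, axis=0)


def unrescale_array(values: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Array version of :func:`unrescale` for generator output (rows = genes)."""
    if params.sigma_sr is None:
        raise ValueError("sigma_sr not set")
    sr = (np.asarray(values) - 0.5) * (params.c * params.sigma_sr)
    return sr * params.sigma_iqr.to_numpy()[:, None] + params.mu.to_numpy()[:, None]


def union_deg_filter(
    stats_tables: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    min_abs_log2fc: float = 0.3,
) -> set[str]:
    """Union over comparisons of genes with ``padj < alpha`` and
    ``|log2fc| >= min_abs_log2fc`` (fold-change bound inclusive).

    Each table needs columns ``gene``, ``log2fc``, ``padj``; all tables must
    share one gene universe.
    """
    universes = {name: frozenset(t["gene"]) for name, t in stats_tables.items()}
    if len(set(universes.values())) > 1:
        raise ValueError("stats tables have mismatched gene universes")
    selected: set[str] = set()
    for t in stats_tables.values():
        hit = (t["padj"] < alpha) & (t["log2fc"].abs() >= min_abs_log2fc)
        selected.update(t.loc[hit, "gene"])
    return selected
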