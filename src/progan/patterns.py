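"""Clustering of transition curves and direction-pattern grouping.

Transition curves are clustered with affinity propagation; each cluster's mean
curves are classified per comparison on a five-level direction code

    D (strong down) < d (weak down) < 0 (even) < u (weak up) < U (strong up)

and the resulting quadruple over (TC1, TC2, TC3, TC4) is matched against the
eight canonical pattern templates. Clusters that match no template, or more
than one, are labelled ``undefined``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

#: Ordered code levels: strong down .. strong up.
CODE_LEVELS = {"D": -2, "d": -1, "0": 0, "u": 1, "U": 2}
LEVEL_CODES = {v: k for k, v in CODE_LEVELS.items()}

#: (sign, magnitude-class) per code; magnitude class 2 = strong, 1 = weak.
CODE_SIGN_MAGNITUDE = {
    "U": (1, 2), "u": (1, 1), "0": (0, 0), "d": (-1, 1), "D": (-1, 2),
}

#: The eight canonical pattern templates over (TC1, TC2, TC3, TC4).
TEMPLATES: dict[str, tuple[str, str, str, str]] = {
    "P1": ("U", "U", "u", "U"),
    "P2": ("U", "0", "0", "U"),
    "P3": ("U", "d", "U", "U"),
    "P4": ("u", "U", "d", "U"),
    "P5": ("D", "U", "D", "U"),
    "P6": ("D", "D", "U", "D"),
    "P7": ("D", "d", "d", "D"),
    "P8": ("D", "U", "D", "D"),
}

UNDEFINED = "undefined"


def classify_direction(
    curve: np.ndarray,
    amplitude: float,
    theta_strong: float = 0.5,
    theta_even: float = 0.2,
) -> str:
    """Five-level direction code of one curve from its net change T(1)-T(0).

    Thresholds are fractions of the gene's amplitude ``A`` (the largest
    absolute net change across its four comparisons): ``|d| >= theta_strong*A``
    is strong (U/D), ``theta_even*A <= |d| < theta_strong*A`` weak (u/d,
    lower bound inclusive), smaller is even (0).
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0 (all-flat genes are handled by the caller)")
    if not 0 < theta_even < theta_strong:
        raise ValueError("need 0 < theta_even < theta_strong")
    curve = np.asarray(curve, dtype=float)
    net = curve[-1] - curve[0]
    frac = abs(net) / amplitude
    if frac >= theta_strong:
        return "U" if net > 0 else "D"
    if frac >= theta_even:
        return "u" if net > 0 else "d"
    return "0"


def classify_quadruple(
    curves: np.ndarray, theta_strong: float = 0.5, theta_even: float = 0.2
) -> tuple[str, str, str, str] | None:
    """Direction codes for the four comparison curves of one gene/cluster.

    ``curves`` is (4, n_t). Returns ``None`` for an all-flat input
    (zero amplitude), which callers label ``undefined``.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] != 4:
        raise ValueError("expected a (4, n_t) curve block")
    nets = curves[:, -1] - curves[:, 0]
    amplitude = float(np.max(np.abs(nets)))
    if amplitude <= 0:
        return None
    return tuple(
        classify_direction(c, amplitude, theta_strong, theta_even) for c in curves
    )


def match_template(codes: tuple[str, str, str, str]) -> str:
    """Map a direction quadruple to a pattern group or ``undefined``.

    A template is *admissible* for a quadruple when every observed code is
    within one level of the template code, and every strong template position
    (U/D) receives a same-sign code of at least weak magnitude (U/u resp.
    D/d). Among admissible templates the nearest one — smallest total level
    distance — wins; no admissible template, or a tie for nearest, gives
    ``undefined``.
    """
    best: list[str] = []
    best_dist: int | None = None
    for label, tmpl in TEMPLATES.items():
        dist = 0
        admissible = True
        for obs, ref in zip(codes, tmpl):
            lo, lr = CODE_LEVELS[obs], CODE_LEVELS[ref]
            if abs(lo - lr) > 1:
                admissible = False
                break
            if abs(lr) == 2 and (np.sign(lo) != np.sign(lr) or abs(lo) < 1):
                admissible = False
                break
            dist += abs(lo - lr)
        if not admissible:
            continue
        if best_dist is None or dist < best_dist:
            best, best_dist = [label], dist
        elif dist == best_dist:
            best.append(label)
    return best[0] if len(best) == 1 else UNDEFINED


# -- clustering -------------------------------------------------------------


@dataclass
class ClusterResult:
    labels: pd.Series  # gene_id -> cluster id
    exemplars: np.ndarray  # indices of exemplar genes
    converged: bool


def curve_features(tcs) -> pd.DataFrame:
    """Concatenate the four raw curves of each gene into one feature vector."""
    vals = tcs.values  # (genes, 4, n_t)
    return pd.DataFrame(
        vals.reshape(vals.shape[0], -1), index=tcs.gene_ids
    )


def cluster_tcs(
    tcs,
    damping: float = 0.5,
    preference: float | None = None,
    max_iter: int = 500,
    convergence_iter: int = 15,
    seed: int = 0,
) -> ClusterResult:
    """Affinity propagation on concatenated raw transition curves.

    Similarity is the negative squared Euclidean distance; the preference
    defaults to the median similarity. Non-convergence at ``max_iter`` is
    reported via ``converged=False`` with the last iteration's labels.
    """
    feats = curve_features(tcs)
    if len(feats) < 2:
        raise ValueError("need at least 2 genes to cluster")
    ap = AffinityPropagation(
        damping=damping,
        preference=preference,
        max_iter=max_iter,
        convergence_iter=convergence_iter,
        random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ap.fit(feats.to_numpy())
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    labels = np.asarray(ap.labels_)
    exemplars = np.asarray(getattr(ap, "cluster_centers_indices_", []))
    if labels.min() < 0:
        # scikit-learn signals total failure with -1 labels; retry once with
        # heavier damping before falling back to a single flagged cluster.
        ap2 = AffinityPropagation(
            damping=0.9, preference=preference, max_iter=2 * max_iter,
            convergence_iter=convergence_iter, random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            ap2.fit(feats.to_numpy())
        if np.asarray(ap2.labels_).min() >= 0:
            labels, exemplars, converged = ap2.labels_, ap2.cluster_centers_indices_, False
        else:
            warnings.warn("affinity propagation failed to converge; single flagged cluster")
            labels = np.zeros(len(feats), dtype=int)
            exemplars = np.array([0])
            converged = False
    return ClusterResult(
        labels=pd.Series(labels, index=feats.index, name="cluster"),
        exemplars=np.asarray(exemplars),
        converged=converged,
    )


# -- grouping ---------------------------------------------------------------


@dataclass
class PatternAssignment:
    """Per-gene cluster, cluster-level direction codes and pattern group."""

    table: pd.DataFrame  # gene_id -> cluster, tc1..tc4, group
    cluster_codes: pd.DataFrame  # cluster -> tc1..tc4, group, n_genes

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def write(self, path) -> None:
        df = self.table.copy()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @staticmethod
    def read_groups(path) -> pd.Series:
        return pd.read_csv(path, sep="\t", index_col=0)["group"]


def assign_groups(
    tcs,
    clusters: ClusterResult,
    theta_strong: float = 0.5,
    theta_even: float = 0.2,
) -> PatternAssignment:
    """Code each cluster's mean curves and map the quadruple to P1..P8.

    Every gene inherits the label of its cluster; all-flat clusters and
    quadruples matching zero or multiple templates become ``undefined``.
    """
    vals = tcs.values
    gene_index = {g: i for i, g in enumerate(tcs.gene_ids)}
    rows = {}
    for cid, members in clusters.labels.groupby(clusters.labels).groups.items():
        idx = [gene_index[g] for g in members]
        mean_curves = vals[idx].mean(axis=0)  # (4, n_t)
        codes = classify_quadruple(mean_curves, theta_strong, theta_even)
        if codes is None:
            codes, group = ("0", "0", "0", "0"), UNDEFINED
        else:
            group = match_template(codes)
        rows[cid] = {
            "tc1": codes[0], "tc2": codes[1], "tc3": codes[2], "tc4": codes[3],
            "group": group, "n_genes": len(idx),
        }
    cluster_codes = pd.DataFrame.from_dict(rows, orient="index")
    cluster_codes.index.name = "cluster"

    table = pd.DataFrame({"cluster": clusters.labels})
    for col in ("tc1", "tc2", "tc3", "tc4", "group"):
        table[col] = cluster_codes[col].reindex(table["cluster"]).to_numpy()
    return PatternAssignment(table=table, cluster_codes=cluster_codes)


def recovery_fraction(assigned: pd.Series, truth: pd.Series) -> float:
    """Fraction of planted pattern genes (truth in P1..P8) recovered exactly."""
    planted = truth[truth.isin(TEMPLATES)]
    if len(planted) == 0:
        raise ValueError("no planted pattern genes in truth")
    got = assigned.reindex(planted.index)
    return float((got == planted).mean())


# -- eigengene & overlaps ---------------------------------------------------


def eigengene(submatrix: pd.DataFrame) -> tuple[pd.Series, float]:
    """First principal component of a gene set across samples.

    Genes are z-scored across samples first; the returned per-sample score is
    sign-fixed to correlate non-negatively with the mean standardized profile.
    Returns ``(scores, variance_explained)``.
    """
    X = submatrix.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("eigengene needs >= 2 genes and >= 2 samples")
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = list(submatrix.index[sd == 0])
        raise ValueError(f"zero-variance genes: {bad}")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    # samples x genes orientation: PC1 over samples
    U, S, Vt = np.linalg.svd(Z.T - Z.T.mean(axis=0), full_matrices=False)
    score = U[:, 0] * S[0]
    var_explained = float(S[0] ** 2 / np.sum(S**2))
    ref = Z.mean(axis=0)
    c = np.corrcoef(score, ref)[0, 1]
    if c < 0:
        score = -score
    return pd.Series(score, index=submatrix.columns, name="eigengene"), var_explained


def overlap_counts(assignment_a: pd.Series, assignment_b: pd.Series) -> pd.DataFrame:
    """Contingency table of two gene-level label assignments on shared genes."""
    shared = assignment_a.index.intersection(assignment_b.index)
    if len(shared) == 0:
        return pd.DataFrame()
    return pd.crosstab(assignment_a.loc[shared], assignment_b.loc[shared])
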