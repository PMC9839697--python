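"""Synthetic four-group expression data with genes planted into the eight
direction-pattern groups.

The generator emulates the structure of a small bulk RNA-seq study: two
phenotypes (WT, AD) x two ages (3M, 6M), five samples per group, a few hundred
genes on a variance-stabilized log scale. Each non-flat gene is planted into
one of the eight canonical pattern groups P1..P8, i.e. its four group means are
chosen so that the four comparison contrasts

    c1 = AD6M - WT6M   (late phenotype)
    c2 = WT6M - WT3M   (WT maturation)
    c3 = AD3M - WT3M   (early phenotype)
    c4 = AD6M - AD3M   (AD maturation)

carry the signs of that group's direction quadruple.

Because the four contrasts of any four group means obey the cycle identity
``c1 + c2 == c3 + c4``, the nominal code magnitudes (strong = +/-effect,
weak = +/-weak_fraction*effect, even = 0) are not jointly realizable for every
pattern.  We plant the least-squares projection of the nominal contrast vector
onto the consistency constraint; pattern P3 uses a hand-picked consistent
quadruple because its projection is ambiguous between the P2 and P3 templates.
With the default thresholds the noise-free codes of every planted gene still
recover their pattern uniquely (enforced by tests).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, GROUPS
from .patterns import TEMPLATES, CODE_SIGN_MAGNITUDE

PATTERN_LABELS = tuple(TEMPLATES) + ("flat",)

#: Contrast order matching (TC1, TC2, TC3, TC4).
CONTRAST_NAMES = ("TC1", "TC2", "TC3", "TC4")

# Consistent replacement for P3: projection of its nominal contrasts codes
# ambiguously, this quadruple codes as (U, D, u, u) and matches only P3.
_P3_CONTRASTS = np.array([1.0, -0.5, 0.25, 0.25])


def nominal_contrasts(label: str, effect_size: float, weak_fraction: float) -> np.ndarray:
    """Nominal (possibly inconsistent) contrast magnitudes for a template."""
    codes = TEMPLATES[label]
    return effect_size * np.array(
        [CODE_SIGN_MAGNITUDE[c][0] * (1.0 if CODE_SIGN_MAGNITUDE[c][1] == 2
                                      else weak_fraction if CODE_SIGN_MAGNITUDE[c][1] == 1
                                      else 0.0)
         for c in codes]
    )


def planted_contrasts(label: str, effect_size: float, weak_fraction: float) -> np.ndarray:
    """Design contrasts for a pattern: consistent (c1+c2 == c3+c4) and
    uniquely recoverable under the default direction thresholds."""
    if label == "flat":
        return np.zeros(4)
    if label == "P3":
        return effect_size * _P3_CONTRASTS
    c = nominal_contrasts(label, effect_size, weak_fraction)
    delta = c[0] + c[1] - c[2] - c[3]
    return c - (delta / 4.0) * np.array([1.0, 1.0, -1.0, -1.0])


def group_means_from_contrasts(baseline: float, c: np.ndarray) -> dict[str, float]:
    """Four group means realizing contrasts ``(c1, c2, c3, c4)``.

    Requires ``c1 + c2 == c3 + c4`` (checked to float tolerance).
    """
    if abs((c[0] + c[1]) - (c[2] + c[3])) > 1e-9:
        raise ValueError("inconsistent contrasts: c1 + c2 != c3 + c4")
    return {
        "WT3M": baseline,
        "WT6M": baseline + c[1],
        "AD3M": baseline + c[2],
        "AD6M": baseline + c[1] + c[0],
    }


@dataclass
class PatternDesign:
    """Design of a synthetic four-group study.

    Defaults follow the structure of the emulated study: 4 groups x 5 samples,
    8 patterns x 25 genes plus 50 flat genes, strong effects of 1.0 on the log
    scale, weak directions at 0.4 of the strong effect, Gaussian noise 0.1.
    """

    n_genes_per_group: dict[str, int] = field(
        default_factory=lambda: {**{p: 25 for p in TEMPLATES}, "flat": 50}
    )
    baseline_mean: float = 8.0
    baseline_spread: float = 0.25
    effect_size: float = 1.0
    weak_fraction: float = 0.4
    noise_sd: float = 0.1
    n_samples_per_group: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_genes_per_group) - set(PATTERN_LABELS)
        if unknown:
            raise ValueError(f"n_genes_per_group: unknown pattern labels {sorted(unknown)}")
        for label, n in self.n_genes_per_group.items():
            if n < 1:
                raise ValueError(f"n_genes_per_group[{label}] must be >= 1, got {n}")
        if self.n_samples_per_group < 1:
            raise ValueError(f"n_samples_per_group must be >= 1, got {self.n_samples_per_group}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0 < self.weak_fraction < 1:
            raise ValueError(f"weak_fraction must be in (0, 1), got {self.weak_fraction}")
        if self.baseline_spread < 0:
            raise ValueError(f"baseline_spread must be >= 0, got {self.baseline_spread}")
        if self.effect_size <= 0:
            raise ValueError(f"effect_size must be > 0, got {self.effect_size}")

    @property
    def n_genes(self) -> int:
        return sum(self.n_genes_per_group.values())

    @property
    def n_samples(self) -> int:
        return 4 * self.n_samples_per_group


def make_pattern_design(**overrides) -> PatternDesign:
    """Build a :class:`PatternDesign`, validating any field overrides."""
    known = set(PatternDesign.__dataclass_fields__)
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown design fields: {sorted(unknown)}")
    return PatternDesign(**overrides)


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic dataset: planted label and design means."""

    labels: pd.Series  # gene_id -> pattern label
    design_means: pd.DataFrame  # genes x 4 groups
    design_contrasts: pd.DataFrame  # genes x (TC1..TC4)

    def write(self, path) -> None:
        df = pd.DataFrame({"pattern": self.labels})
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @staticmethod
    def read_labels(path) -> pd.Series:
        return pd.read_csv(path, sep="\t", index_col=0)["pattern"]


def generate_expression(design: PatternDesign) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Sample a synthetic expression matrix from a design.

    Values are ``design mean + N(0, noise_sd^2)``; deterministic given
    ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)

    gene_ids, labels, means_rows, contrast_rows = [], [], [], []
    for label in PATTERN_LABELS:
        n = design.n_genes_per_group.get(label, 0)
        if n == 0:
            continue
        c = planted_contrasts(label, design.effect_size, design.weak_fraction)
        for i in range(n):
            baseline = design.baseline_mean + design.baseline_spread * (
                2.0 * rng.random() - 1.0
            )
            gene_ids.append(f"{label}_{i:04d}")
            labels.append(label)
            means_rows.append(group_means_from_contrasts(baseline, c))
            contrast_rows.append(c)

    means = pd.DataFrame(means_rows, index=gene_ids, columns=list(GROUPS))
    contrasts = pd.DataFrame(
        np.asarray(contrast_rows), index=gene_ids, columns=list(CONTRAST_NAMES)
    )

    sample_ids, phenos, ages = [], [], []
    for grp in GROUPS:
        for k in range(design.n_samples_per_group):
            sample_ids.append(f"{grp}_s{k + 1}")
            phenos.append(grp[:2])
            ages.append(grp[2:])
    metadata = pd.DataFrame(
        {"phenotype": phenos, "age": ages}, index=pd.Index(sample_ids, name="sample_id")
    )

    per_sample_mean = np.column_stack(
        [means[grp].to_numpy() for grp in GROUPS for _ in range(design.n_samples_per_group)]
    )
    noise = rng.normal(0.0, design.noise_sd, size=per_sample_mean.shape)
    values = pd.DataFrame(
        per_sample_mean + noise, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids
    )

    matrix = ExpressionMatrix(values=values, metadata=metadata)
    truth = SyntheticTruth(
        labels=pd.Series(labels, index=gene_ids, name="pattern"),
        design_means=means,
        design_contrasts=contrasts,
    )
    return matrix, truth
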