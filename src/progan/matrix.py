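"""Core containers: expression matrices with 2-phenotype x 2-timepoint metadata.

The pipeline operates on variance-stabilized (log-scale) expression values for
a four-group design: two phenotypes (WT, AD) crossed with two ages (3M, 6M).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHENOTYPES = ("WT", "AD")
AGES = ("3M", "6M")

#: The four experimental groups, in canonical order.
GROUPS = ("WT3M", "WT6M", "AD3M", "AD6M")


def group_label(phenotype: str, age: str) -> str:
    """Canonical group label, e.g. ``("WT", "3M") -> "WT3M"``."""
    return f"{phenotype}{age}"


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample ids.
    metadata
        DataFrame indexed by sample id with columns ``phenotype`` and ``age``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        bad_ph = set(self.metadata["phenotype"]) - set(PHENOTYPES)
        if bad_ph:
            raise ValueError(f"unknown phenotype values: {sorted(bad_ph)}")
        bad_age = set(self.metadata["age"]) - set(AGES)
        if bad_age:
            raise ValueError(f"unknown age values: {sorted(bad_age)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def groups(self) -> pd.Series:
        """Group label per sample (aligned with columns)."""
        md = self.metadata.loc[self.sample_ids]
        return pd.Series(
            [group_label(p, a) for p, a in zip(md["phenotype"], md["age"])],
            index=self.sample_ids,
            name="group",
        )

    def samples_in_group(self, group: str) -> list[str]:
        g = self.groups
        return list(g.index[g == group])

    def require_all_groups(self) -> None:
        counts = self.groups.value_counts()
        empty = [g for g in GROUPS if counts.get(g, 0) == 0]
        if empty:
            raise ValueError(f"empty experimental groups: {empty}")

    def group_means(self) -> pd.DataFrame:
        """Per-group mean expression, genes x 4 groups (canonical order)."""
        self.require_all_groups()
        g = self.groups
        out = {
            grp: self.values.loc[:, g.index[g == grp]].mean(axis=1)
            for grp in GROUPS
        }
        return pd.DataFrame(out, columns=list(GROUPS))

    # -- TSV round trip ----------------------------------------------------

    def write(self, values_path, metadata_path) -> None:
        df = self.values.copy()
        df.index.name = "gene_id"
        df.to_csv(values_path, sep="\t")
        md = self.metadata.copy()
        md.index.name = "sample_id"
        md.to_csv(metadata_path, sep="\t")

    @classmethod
    def read(cls, values_path, metadata_path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
        return cls(values=values, metadata=metadata)
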