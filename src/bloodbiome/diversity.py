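"""Alpha, beta and gamma diversity over abundance tables.

Alpha diversity is the inverse Simpson index 1 / sum(p_i^2) over the
relative abundances of assigned taxa; beta diversity is the Bray-Curtis
dissimilarity sum|x-y| / sum(x+y); gamma diversity is the count of
distinct taxa observed anywhere within a subject group. All three are
rank-agnostic: aggregate the table first to choose the rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .profiling import AbundanceTable


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, metric: str = "unknown") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(list(df.index), df.values, metric)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class DiversityResult:
    rank: str
    alpha: pd.Series
    beta: DistanceMatrix
    gamma: pd.Series | None = None


def inverse_simpson(p) -> float:
    """1 / sum(p_i^2). Scale-free: counts and proportions agree."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundance")
    tot = p.sum()
    if tot <= 0:
        raise ValueError("inverse Simpson undefined for an all-zero vector")
    p = p / tot
    return float(1.0 / (p**2).sum())


def bray_curtis(x, y) -> float:
    """sum|x_i - y_i| / sum(x_i + y_i), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must share the taxon axis")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative abundance")
    denom = (x + y).sum()
    if denom <= 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def alpha_series(table: AbundanceTable) -> pd.Series:
    """Per-sample inverse Simpson over assigned relative abundances."""
    vals = {}
    for sid, row in table.relative.iterrows():
        vals[sid] = inverse_simpson(row.values) if row.sum() > 0 else np.nan
    return pd.Series(vals, name="alpha").sort_index()


def beta_matrix(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis on relative abundances.

    Relative (not raw count) abundances are used so residual depth
    differences between samples do not leak into beta diversity.
    """
    rel = table.relative
    if len(rel) < 2:
        raise ValueError("need at least two samples")
    d = squareform(pdist(rel.values, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)  # pdist yields nan for two all-zero rows
    return DistanceMatrix(list(rel.index), d, "bray_curtis")


def gamma_richness(table: AbundanceTable, groups: pd.Series) -> pd.Series:
    """Distinct taxa observed in at least one sample of each group."""
    missing = [s for s in table.relative.index if s not in groups.index]
    if missing:
        raise ValueError(f"samples without group label: {missing[:3]}")
    out = {}
    for g, idx in groups.groupby(groups).groups.items():
        idx = [s for s in idx if s in table.relative.index]
        present = (table.relative.loc[idx] > 0).any(axis=0)
        out[g] = int(present.sum())
    return pd.Series(out, name="gamma")


def diversity_result(table: AbundanceTable, groups: pd.Series | None = None) -> DiversityResult:
    return DiversityResult(
        rank=table.rank,
        alpha=alpha_series(table),
        beta=beta_matrix(table),
        gamma=gamma_richness(table, groups) if groups is not None else None,
    )
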