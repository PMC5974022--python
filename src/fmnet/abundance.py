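"""Taxon abundance tables: ingestion, normalization, diversity, ordination.

The 16S side of the pipeline. Counts are depth-normalized by rarefaction
(subsampling without replacement to the depth of the least-rich sample),
converted to relative abundances, filtered at a mean relative abundance
threshold (default 0.5%), and summarized by alpha diversity (observed taxa,
Shannon), beta dissimilarity (Yue & Clayton theta, Bray-Curtis) and principal
coordinate analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from fmnet._utils import read_table, write_table

Kind = Literal["counts", "relative"]
Metric = Literal["yue_clayton", "bray_curtis"]


@dataclass
class AbundanceTable:
    """Samples x taxa matrix of counts or relative abundances.

    ``df`` rows are samples, columns taxa (OTU label, optionally with a
    species name).  ``kind`` is ``"counts"`` (non-negative integers) or
    ``"relative"`` (rows sum to 1).
    """

    df: pd.DataFrame
    kind: Kind = "counts"

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise ValueError("duplicate sample_ids")
        if self.df.columns.has_duplicates:
            raise ValueError("duplicate taxon_ids")
        vals = self.df.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("negative abundance values")
        if self.kind == "relative":
            # a filtered relative table is a subcomposition: rows may sum to
            # less than 1, never more
            sums = vals.sum(axis=1)
            if (sums > 1.0 + 1e-6).any():
                raise ValueError("relative table rows must sum to at most 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def write(self, path, header_comments: list[str] | None = None) -> None:
        write_table(self.df, path, header_comments)


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix in [0, 1]."""

    df: pd.DataFrame
    metric: Metric = "bray_curtis"

    def __post_init__(self) -> None:
        v = self.df.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1] or list(self.df.index) != list(self.df.columns):
            raise ValueError("distance matrix must be square with matching ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < -1e-12).any() or (v > 1 + 1e-9).any():
            raise ValueError("distances must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def write(self, path) -> None:
        write_table(self.df, path, [f"metric={self.metric}"])


def read_abundance_table(
    path,
    orientation: Literal["samples_by_taxa", "taxa_by_samples"] = "samples_by_taxa",
    kind: Kind | None = None,
) -> AbundanceTable:
    """Read a delimited abundance table.

    ``kind`` is inferred when not given: an all-integer table is treated as
    counts, anything else as relative abundances.
    """
    df = read_table(path)
    if orientation == "taxa_by_samples":
        df = df.T
    df.index.name = None
    df.columns.name = None
    if not np.issubdtype(df.to_numpy().dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
        raise ValueError(f"non-numeric columns in {path}: {list(bad)}")
    neg = np.argwhere(df.to_numpy(dtype=float) < 0)
    if len(neg):
        i, j = neg[0]
        raise ValueError(
            f"negative value at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
        )
    if kind is None:
        vals = df.to_numpy(dtype=float)
        kind = "counts" if np.allclose(vals, np.round(vals)) else "relative"
    return AbundanceTable(df, kind=kind)


def rarefy(table: AbundanceTable, depth: int | None = None, seed: int = 0) -> AbundanceTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Default depth is the minimum sample total (the least-rich sample), the
    usual normalization target for uneven 16S libraries.
    """
    if table.kind != "counts":
        raise ValueError("rarefy requires a counts table")
    counts = table.values.astype(np.int64)
    totals = counts.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    shallow = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if shallow:
        raise ValueError(f"samples shallower than depth {depth}: {shallow}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        if totals[i] == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return AbundanceTable(
        pd.DataFrame(out, index=table.df.index, columns=table.df.columns), kind="counts"
    )


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each row by its total. Idempotent on relative tables."""
    if table.kind == "relative":
        return table
    vals = table.values
    sums = vals.sum(axis=1)
    zero = np.asarray(table.sample_ids)[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero samples cannot be normalized: {list(zero)}")
    rel = vals / sums[:, None]
    return AbundanceTable(
        pd.DataFrame(rel, index=table.df.index, columns=table.df.columns), kind="relative"
    )


def filter_by_mean_abundance(table: AbundanceTable, threshold: float = 0.005) -> AbundanceTable:
    """Keep taxa whose across-sample mean relative abundance is >= ``threshold``.

    The bound is inclusive and the column order is preserved.
    """
    if table.kind != "relative":
        raise ValueError("filter_by_mean_abundance requires a relative table")
    keep = table.df.mean(axis=0) >= threshold
    if not keep.any():
        warnings.warn("mean-abundance filter removed every taxon", stacklevel=2)
    return AbundanceTable(table.df.loc[:, keep], kind="relative")


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample observed taxa and Shannon index.

    Shannon H = -sum p_i ln p_i over strictly positive proportions (natural
    log by default, matching the upstream amplicon toolchain).
    """
    vals = table.values
    sums = vals.sum(axis=1)
    if (sums == 0).any():
        bad = np.asarray(table.sample_ids)[sums == 0]
        raise ValueError(f"all-zero samples have undefined diversity: {list(bad)}")
    p = vals / sums[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return pd.DataFrame(
        {
            "observed_taxa": (vals > 0).sum(axis=1),
            "shannon": -plogp.sum(axis=1),
        },
        index=table.df.index,
    )


def _yue_clayton_condensed(x: np.ndarray) -> np.ndarray:
    """Condensed Yue & Clayton theta dissimilarity over rows of ``x``."""
    dots = x @ x.T
    sq = np.diag(dots)
    n = len(x)
    out = []
    for i in range(n - 1):
        for j in range(i + 1, n):
            denom = sq[i] + sq[j] - dots[i, j]
            out.append(1.0 - dots[i, j] / denom if denom > 0 else 0.0)
    return np.asarray(out)


def beta_dissimilarity(table: AbundanceTable, metric: Metric) -> DistanceMatrix:
    """Pairwise beta dissimilarity between samples of a relative table.

    yue_clayton: d = 1 - sum(a*b) / (sum a^2 + sum b^2 - sum(a*b))
    bray_curtis: d = sum |a - b| / sum (a + b)
    """
    if table.kind != "relative":
        raise ValueError("beta_dissimilarity requires a relative table")
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    x = table.values
    if metric == "bray_curtis":
        cond = pdist(x, metric="braycurtis")
    elif metric == "yue_clayton":
        cond = _yue_clayton_condensed(x)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    m = squareform(np.clip(cond, 0.0, 1.0))
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(
        pd.DataFrame(m, index=table.df.index, columns=table.df.index), metric=metric
    )


def within_group_mean_distance(dist: DistanceMatrix, groups: dict[str, str]) -> pd.DataFrame:
    """Mean and SEM of all unordered within-group pairwise distances."""
    missing = [s for s in dist.sample_ids if s not in groups]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    rows = {}
    labels = pd.Series({s: groups[s] for s in dist.sample_ids})
    for g in sorted(labels.unique()):
        members = labels.index[labels == g]
        if len(members) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        sub = dist.df.loc[members, members].to_numpy()
        iu = np.triu_indices(len(members), k=1)
        pairs = sub[iu]
        sem = pairs.std(ddof=1) / np.sqrt(len(pairs)) if len(pairs) > 1 else 0.0
        rows[g] = {"mean": pairs.mean(), "sem": sem, "n_pairs": len(pairs)}
    return pd.DataFrame(rows).T


def pcoa(dist: DistanceMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling (principal coordinate analysis).

    Double-centres -D**2/2, eigendecomposes, and returns the top-``k``
    positive-eigenvalue axes scaled by sqrt(eigenvalue). Axis signs follow a
    fixed convention: the largest-magnitude coordinate on each axis is
    positive, so repeated runs are comparable.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = len(dist.sample_ids)
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    d2 = dist.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(evals.max(), 1.0)
    n_pos = int(pos.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {n_pos} axes", stacklevel=2
        )
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    for a in range(k):
        if coords[np.argmax(np.abs(coords[:, a])), a] < 0:
            coords[:, a] = -coords[:, a]
    cols = [f"PCo{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=dist.df.index, columns=cols), evals[:k]
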