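"""Feature-clinical cross-correlation with FDR control and group tests.

Pearson correlations between every (feature, clinical parameter) pair are
pooled into one Benjamini-Hochberg family; cells with BH-adjusted q <= alpha
get the significance star. Univariate group differences use the Mann-Whitney
U test (two groups) or the Kruskal-Wallis test (more than two).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from fmnet._utils import write_table


@dataclass
class CrossCorrResult:
    """Feature x clinical-parameter correlation matrices with BH q-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    significant: pd.DataFrame
    alpha: float

    @property
    def row_ids(self) -> list[str]:
        return list(self.r.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.r.columns)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for f in self.r.index:
            for c in self.r.columns:
                rows.append(
                    {
                        "feature": f,
                        "parameter": c,
                        "r": self.r.loc[f, c],
                        "p": self.p.loc[f, c],
                        "q": self.q.loc[f, c],
                        "starred": bool(self.significant.loc[f, c]),
                    }
                )
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        write_table(self.to_long().set_index("feature"), path)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at 1;
    the transform is order-preserving and never produces q < p.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def crosscorrelate(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
) -> CrossCorrResult:
    """Pearson r/p for every (feature, parameter) pair, BH-corrected jointly.

    Missing clinical values are handled pairwise-complete; constant columns
    (undefined correlation) are excluded with a warning. The star mask is
    q <= alpha.
    """
    shared = [s for s in features.index if s in set(clinical.index)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    f = features.loc[shared].astype(float)
    c = clinical.loc[shared].select_dtypes(include=[np.number]).astype(float)
    drop = [col for col in c.columns if c[col].dropna().nunique() <= 1]
    drop_f = [col for col in f.columns if f[col].dropna().nunique() <= 1]
    if drop or drop_f:
        warnings.warn(
            f"excluding constant columns: {drop + drop_f}", stacklevel=2
        )
        c = c.drop(columns=drop)
        f = f.drop(columns=drop_f)
    if c.shape[1] == 0 or f.shape[1] == 0:
        raise ValueError("no usable columns to correlate")
    r = pd.DataFrame(np.nan, index=f.columns, columns=c.columns)
    p = pd.DataFrame(np.nan, index=f.columns, columns=c.columns)
    for fc in f.columns:
        for cc in c.columns:
            pair = pd.concat([f[fc], c[cc]], axis=1).dropna()
            if len(pair) < 3 or pair.iloc[:, 0].nunique() <= 1 or pair.iloc[:, 1].nunique() <= 1:
                continue
            res = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r.loc[fc, cc] = res.statistic
            p.loc[fc, cc] = res.pvalue
    flat = p.to_numpy().ravel()
    finite = np.isfinite(flat)
    qflat = np.full_like(flat, np.nan)
    if finite.any():
        qflat[finite] = bh_fdr(flat[finite])
    q = pd.DataFrame(qflat.reshape(p.shape), index=p.index, columns=p.columns)
    sig = (q <= alpha).fillna(False)
    return CrossCorrResult(r=r, p=p, q=q, significant=sig, alpha=alpha)


def group_compare(
    features: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    test: Literal["mann_whitney", "kruskal_wallis"] = "mann_whitney",
) -> pd.DataFrame:
    """Per-feature two-sided group test.

    Mann-Whitney U (exactly two groups) uses scipy's exact null distribution
    for small tie-free samples and the normal approximation otherwise
    (``method="auto"``); Kruskal-Wallis uses the chi-square approximation.
    """
    groups = pd.Series(groups)
    shared = [s for s in features.index if s in groups.index]
    if len(shared) < len(features.index):
        raise ValueError("every sample needs a group label")
    labels = groups.loc[features.index]
    by_group = [features.loc[labels == g] for g in labels.unique()]
    if any(len(g) == 0 for g in by_group):
        raise ValueError("empty group")
    if test == "mann_whitney":
        if len(by_group) != 2:
            raise ValueError("mann_whitney requires exactly 2 groups")
        rows = {
            f: stats.mannwhitneyu(
                by_group[0][f], by_group[1][f], alternative="two-sided", method="auto"
            )
            for f in features.columns
        }
    elif test == "kruskal_wallis":
        if len(by_group) < 2:
            raise ValueError("kruskal_wallis requires at least 2 groups")
        rows = {
            f: stats.kruskal(*[g[f] for g in by_group]) for f in features.columns
        }
    else:
        raise ValueError(f"unknown test {test!r}")
    return pd.DataFrame(
        {f: {"statistic": res.statistic, "p": res.pvalue} for f, res in rows.items()}
    ).T
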