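"""Differential methylation statistics across tissues.

Per CpG: classical one-way fixed-effects ANOVA across tissue groups,
Benjamini-Hochberg step-up FDR across all CpGs of the analysis batch
jointly (all selective subsets pooled), then Tukey's HSD on the
ANOVA-significant CpGs to attribute the difference to tissue pairs.  Two
effect sizes accompany each pair: the absolute difference of group mean
percents (delta) and the max/min ratio of group mean percents (rho >= 1,
orientation free).  CpGs that are Tukey-significant with delta below 5
points and rho below 1.1-fold are the "subtle" differential CpGs this
assay is designed to resolve.

The ANOVA is computed vectorized across rows (the operating-characteristic
simulations run hundreds of whole studies); it is cross-checked against
scipy.stats.f_oneway in the test suite.  Tukey p-values come from the
studentized range distribution (Tukey-Kramer for unequal n) and are
cross-checked against scipy.stats.tukey_hsd.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests
from skbio.tree import TreeNode

__all__ = [
    "anova_bh",
    "tukey_hsd",
    "subtle_filter",
    "zscore_pca_cluster",
    "ClusterResult",
]

_VARIANCE_FLOOR = 1e-12


def _group_columns(
    matrix: pd.DataFrame, groups: Mapping[str, str]
) -> dict[str, list[str]]:
    by_group: dict[str, list[str]] = {}
    for sample in matrix.columns:
        if sample not in groups:
            raise KeyError(f"sample {sample!r} has no group label")
        by_group.setdefault(groups[sample], []).append(sample)
    if len(by_group) < 2:
        raise ValueError("need >= 2 groups")
    for g, cols in by_group.items():
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    return by_group


def anova_bh(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA per row with BH FDR across all rows jointly.

    ``matrix``: rows = CpGs/peak bins, columns = samples, cells = percent
    methylation.  Returns a frame indexed like ``matrix`` with columns
    ``F``, ``p``, ``q``, ``significant`` (q <= alpha) and ``constant``
    (rows with no variance at all, reported with p = 1).  A tiny variance
    floor keeps F finite when groups are internally constant but differ
    from one another.
    """
    if matrix.empty:
        raise ValueError("empty matrix")
    by_group = _group_columns(matrix, groups)
    X = matrix.to_numpy(dtype=float)
    n_total = X.shape[1]
    k = len(by_group)

    grand = X.mean(axis=1)
    ss_between = np.zeros(len(X))
    ss_within = np.zeros(len(X))
    for cols in by_group.values():
        idx = [matrix.columns.get_loc(c) for c in cols]
        sub = X[:, idx]
        gmean = sub.mean(axis=1)
        ss_between += len(idx) * (gmean - grand) ** 2
        ss_within += ((sub - gmean[:, None]) ** 2).sum(axis=1)

    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within

    constant = (ss_between + ss_within) <= _VARIANCE_FLOOR
    F = ms_between / np.maximum(ms_within, _VARIANCE_FLOOR)
    F[constant] = 0.0
    p = stats.f.sf(F, df_between, df_within)
    p[constant] = 1.0
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "F": F,
            "p": p,
            "q": q,
            "significant": q <= alpha,
            "constant": constant,
        },
        index=matrix.index,
    )


def tukey_hsd(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    rows: Sequence | None = None,
    alpha: float = 0.05,
    ratio_floor: float = 0.1,
) -> pd.DataFrame:
    """Tukey HSD adjusted p and effect sizes for every group pair.

    Run on ``rows`` (default: all rows; the standard workflow passes the
    ANOVA-significant rows).  ``delta`` is the absolute difference of group
    mean percents; ``rho`` the max/min ratio of group mean percents with a
    floor of ``ratio_floor`` percentage points on the denominator.
    """
    by_group = _group_columns(matrix, groups)
    group_names = sorted(by_group)
    if rows is None:
        rows = matrix.index
    sub = matrix.loc[rows]
    X = sub.to_numpy(dtype=float)
    n_total = X.shape[1]
    k = len(by_group)
    df_within = n_total - k

    idx = {g: [matrix.columns.get_loc(c) for c in cols] for g, cols in by_group.items()}
    means = {g: X[:, idx[g]].mean(axis=1) for g in group_names}
    ss_within = sum(
        ((X[:, idx[g]] - means[g][:, None]) ** 2).sum(axis=1) for g in group_names
    )
    ms_within = np.maximum(ss_within / df_within, _VARIANCE_FLOOR)

    records = []
    for g1, g2 in combinations(group_names, 2):
        n1, n2 = len(idx[g1]), len(idx[g2])
        se = np.sqrt(ms_within / 2.0 * (1.0 / n1 + 1.0 / n2))
        diff = means[g1] - means[g2]
        qstat = np.abs(diff) / se
        padj = stats.studentized_range.sf(qstat, k, df_within)
        padj = np.clip(padj, 0.0, 1.0)
        padj[np.abs(diff) <= _VARIANCE_FLOOR] = 1.0
        hi = np.maximum(means[g1], means[g2])
        lo = np.minimum(means[g1], means[g2])
        rho = hi / np.maximum(lo, ratio_floor)
        rho = np.maximum(rho, 1.0)
        for i, row in enumerate(sub.index):
            records.append(
                (row, g1, g2, float(qstat[i]), float(padj[i]),
                 float(np.abs(diff[i])), float(rho[i]), bool(padj[i] <= alpha))
            )
    return pd.DataFrame(
        records,
        columns=["row", "group1", "group2", "q_stat", "p_adj", "delta", "rho",
                 "significant"],
    )


def subtle_filter(
    tukey_result: pd.DataFrame,
    max_delta: float = 5.0,
    max_ratio: float = 1.1,
) -> pd.DataFrame:
    """Tukey-significant pairs with small absolute and fold differences.

    These are the CpGs whose tissue differences are below ``max_delta``
    percentage points and below ``max_ratio``-fold yet statistically
    significant — the sensitivity frontier of the assay.
    """
    mask = (
        tukey_result["significant"]
        & (tukey_result["delta"] < max_delta)
        & (tukey_result["rho"] < max_ratio)
    )
    return tukey_result.loc[mask]


@dataclass
class ClusterResult:
    """z-scored matrix, PCA scores over samples, and UPGMA newick tree."""

    zmatrix: pd.DataFrame
    pca_scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    newick: str
    dropped_rows: list


def zscore_pca_cluster(matrix: pd.DataFrame, n_components: int | None = None) -> ClusterResult:
    """Row z-scores, sample PCA, and a UPGMA sample dendrogram.

    z-scores use the row mean and SD across all samples with the n-1
    denominator; rows with zero variance carry no pattern information and
    are dropped (returned in ``dropped_rows``).  PCA and UPGMA (average
    linkage on Euclidean distances) operate on samples in z-score space.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = list(matrix.index[~keep])
    if not keep.any():
        raise ValueError("all rows constant; nothing to analyze")
    Z = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    zmatrix = pd.DataFrame(Z, index=matrix.index[keep], columns=matrix.columns)

    n_samples = matrix.shape[1]
    if n_components is None:
        n_components = min(n_samples, 3)
    pca = PCA(n_components=min(n_components, n_samples - 1, Z.shape[0]))
    scores = pca.fit_transform(Z.T)
    pca_scores = pd.DataFrame(
        scores,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )

    dist = pdist(Z.T, metric="euclidean")
    link = linkage(dist, method="average")  # UPGMA
    tree = TreeNode.from_linkage_matrix(link, list(matrix.columns))
    newick = str(tree).strip()
    return ClusterResult(
        zmatrix=zmatrix,
        pca_scores=pca_scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        newick=newick,
        dropped_rows=dropped,
    )
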