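"""Effective number of independent protein traits and Bonferroni threshold.

Aptamer traits are heavily correlated, so a plain Bonferroni correction
over all traits is too severe.  Instead: Spearman correlation matrix ->
distance 1 - |r| -> complete-linkage dendrogram -> static cut at a fixed
height h.  Complete linkage makes the cut literal: every pair inside a
cluster has |r| >= 1 - h, so h = 0.2 collapses traits correlated at
|r| >= 0.8.  The number of clusters is the effective number of independent
traits m_eff, and the family-wise threshold is alpha / m_eff.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclasses.dataclass
class IndependenceCut:
    correlation: pd.DataFrame
    linkage: np.ndarray
    cut_height: float
    m_eff: int
    clusters: pd.Series  # aptamer -> cluster label
    representatives: list[str]  # one medoid aptamer per cluster
    threshold: float


def spearman_matrix(proteome_adj: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation matrix across protein traits."""
    if len(proteome_adj) < 3:
        raise ValueError("need at least 3 individuals for correlations")
    X = proteome_adj.to_numpy(dtype=float)
    const = np.ptp(X, axis=0) == 0
    if const.any():
        bad = proteome_adj.columns[const][0]
        raise ValueError(f"constant protein trait {bad!r}")
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    corr = np.corrcoef(ranks, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=proteome_adj.columns, columns=proteome_adj.columns)


def count_independent(
    correlation: pd.DataFrame,
    cut_height: float = 0.2,
    alpha_family: float = 0.05,
    linkage_method: str = "complete",
) -> IndependenceCut:
    """Cluster traits at distance 1 - |r| and cut the tree at ``cut_height``.

    Each resulting cluster counts once toward m_eff; the cluster's
    representative is its medoid (the trait with the highest mean |r| to
    its cluster-mates).  Absolute correlation is used so strongly
    negatively correlated aptamers also collapse.
    """
    if cut_height <= 0:
        raise ValueError("cut_height must be positive")
    corr = correlation.to_numpy(dtype=float)
    if corr.shape[0] != corr.shape[1] or not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    P = dist.shape[0]
    if P == 1:
        labels = np.array([1])
        link = np.empty((0, 4))
    else:
        link = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
        labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    clusters = pd.Series(labels, index=correlation.index, name="cluster")
    m_eff = int(clusters.nunique())

    reps: list[str] = []
    abs_corr = np.abs(corr)
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        block = abs_corr[np.ix_(members, members)]
        medoid = members[int(np.argmax(block.mean(axis=1)))]
        reps.append(correlation.index[medoid])

    return IndependenceCut(
        correlation=correlation,
        linkage=link,
        cut_height=cut_height,
        m_eff=m_eff,
        clusters=clusters,
        representatives=reps,
        threshold=bonferroni_threshold(alpha_family, m_eff),
    )


def bonferroni_threshold(alpha_family: float, m_eff: int) -> float:
    """Family-wise threshold alpha / m_eff (exact quotient)."""
    if m_eff < 1:
        raise ValueError("m_eff must be at least 1")
    if not 0 < alpha_family < 1:
        raise ValueError("alpha_family must be in (0, 1)")
    return alpha_family / m_eff
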