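"""Protein clustering and disease-class enrichment.

Proteins (not individuals) are embedded by PCA of the protein x individual
matrix, clustered by k-means over a scan of k, and each cluster's strength
of association with the exposure is summarised by the median |beta|/SE with
one-tailed rank-sum comparisons.  The cluster with the strongest effects is
tested for disease-class enrichment against the full measured background
using fold enrichment and the EASE score (a conservative one-tailed
hypergeometric tail computed after removing one member from the
list-in-class overlap), Bonferroni-corrected over classes tested.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .datamodel import AnnotationTable


@dataclasses.dataclass
class ProteinClustering:
    pc_scores: pd.DataFrame  # P x n_pcs
    explained_variance: np.ndarray  # fraction per PC, non-increasing
    k_scan: pd.DataFrame  # columns k, betweenness_over_totss
    chosen_k: int
    assignment: pd.Series  # aptamer -> cluster id (1-based)


@dataclasses.dataclass
class ClusterEffectStats:
    per_cluster: pd.DataFrame  # cluster, n, median_abs_beta_se, q25, q75, p_vs_overall
    pairwise: pd.DataFrame  # cluster_a, cluster_b, p  (one-tailed, a > b)
    overall_median: float
    overall_iqr: tuple[float, float]


def pca_proteins(proteome_adj: pd.DataFrame, n_pcs: int | str = "auto"):
    """PCA with proteins as observations and individuals as features.

    Each protein's row (its abundance profile across individuals) is
    centred, then the SVD gives protein scores and per-PC explained
    variance fractions.  ``n_pcs='auto'`` keeps PCs up to the largest drop
    in explained variance (the scree elbow).
    Returns (pc_scores P x n_pcs, explained_variance over all PCs,
    suggested_n_pcs).
    """
    if proteome_adj.shape[1] < 3:
        raise ValueError("need at least 3 proteins")
    A = proteome_adj.to_numpy(dtype=float).T  # P x n
    A = A - A.mean(axis=1, keepdims=True)
    if not np.all(np.isfinite(A)) or np.allclose(A, 0):
        raise ValueError("degenerate proteome matrix")
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    ev = S**2
    explained = ev / ev.sum()
    scores = U * S  # P x r

    drops = explained[:-1] - explained[1:]
    n_scan = min(len(drops), 20)
    suggested = int(np.argmax(drops[:n_scan])) + 1
    keep = suggested if n_pcs == "auto" else int(n_pcs)
    keep = max(1, min(keep, scores.shape[1]))
    pc_scores = pd.DataFrame(
        scores[:, :keep],
        index=proteome_adj.columns,
        columns=[f"PC{i+1}" for i in range(keep)],
    )
    return pc_scores, explained, suggested


def kmeans_scan(
    pc_scores: pd.DataFrame,
    k_range: tuple[int, int] = (2, 20),
    seed: int = 0,
    plateau_tol: float = 0.01,
    n_init: int = 10,
    force_k: int | None = None,
) -> ProteinClustering:
    """k-means over a range of k; choose the smallest k on the plateau.

    For each k the between-cluster sum of squares over the total sum of
    squares is recorded; the chosen k is the smallest whose ratio is within
    ``plateau_tol`` of the ratios at both k+1 and k+2 (i.e. adding clusters
    no longer explains variance).  If no plateau is found inside the scan,
    the k with the largest ratio is used.  ``force_k`` overrides the
    automatic choice while still emitting the full scan table.
    """
    X = pc_scores.to_numpy(dtype=float)
    P = X.shape[0]
    lo, hi = int(k_range[0]), int(k_range[1])
    if lo < 2 or hi > P - 1:
        raise ValueError("k_range must lie within [2, P-1]")
    tot_ss = float(((X - X.mean(axis=0)) ** 2).sum())

    ks = list(range(lo, hi + 1))
    ratios: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(X)
        ratios[k] = 1.0 - km.inertia_ / tot_ss
        fits[k] = labels

    chosen = None
    for k in ks:
        if k + 2 > hi:
            break
        if (ratios[k + 1] - ratios[k] <= plateau_tol
                and ratios[k + 2] - ratios[k] <= plateau_tol):
            chosen = k
            break
    if chosen is None:
        chosen = max(ks, key=lambda k: ratios[k])
    if force_k is not None:
        if force_k not in ratios:
            raise ValueError("force_k outside scanned range")
        chosen = int(force_k)

    k_scan = pd.DataFrame(
        {"k": ks, "betweenness_over_totss": [ratios[k] for k in ks]}
    )
    assignment = pd.Series(fits[chosen] + 1, index=pc_scores.index, name="cluster")
    # explained_variance of the embedding is not re-derivable here; caller
    # passes pca output when building reports
    return ProteinClustering(
        pc_scores=pc_scores,
        explained_variance=np.array([]),
        k_scan=k_scan,
        chosen_k=chosen,
        assignment=assignment,
    )


def cluster_effects(assignment: pd.Series, assoc: pd.DataFrame) -> ClusterEffectStats:
    """Per-cluster |beta|/SE summaries and one-tailed rank-sum tests.

    Each cluster is compared against the overall protein set (own members
    included) and pairwise against every other cluster, with the one-tailed
    Mann-Whitney alternative that the cluster's |beta|/SE values are larger.
    Clusters of size < 2 get no P-value (NaN) with a warning.
    """
    import logging

    log = logging.getLogger("protmr")
    df = assoc.set_index("aptamer")
    missing = assignment.index.difference(df.index)
    if len(missing):
        raise ValueError(f"association results missing for {len(missing)} proteins")
    ratio = (df.loc[assignment.index, "beta"].abs() / df.loc[assignment.index, "se"])
    overall = ratio.to_numpy()
    overall_median = float(np.median(overall))
    overall_iqr = (float(np.percentile(overall, 25)), float(np.percentile(overall, 75)))

    rows = []
    groups: dict[int, np.ndarray] = {}
    for lab, members in assignment.groupby(assignment):
        vals = ratio.loc[members.index].to_numpy()
        groups[lab] = vals
        if len(vals) < 2:
            log.warning("cluster %s has <2 members; rank-sum P omitted", lab)
            p = np.nan
        else:
            p = stats.mannwhitneyu(vals, overall, alternative="greater").pvalue
        rows.append(
            {
                "cluster": lab,
                "n": len(vals),
                "median_abs_beta_se": float(np.median(vals)),
                "q25": float(np.percentile(vals, 25)),
                "q75": float(np.percentile(vals, 75)),
                "p_vs_overall": p,
            }
        )

    pair_rows = []
    for a, b in itertools.permutations(sorted(groups), 2):
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            p = np.nan
        else:
            p = stats.mannwhitneyu(groups[a], groups[b], alternative="greater").pvalue
        pair_rows.append({"cluster_a": a, "cluster_b": b, "p": p})

    return ClusterEffectStats(
        per_cluster=pd.DataFrame(rows),
        pairwise=pd.DataFrame(pair_rows),
        overall_median=overall_median,
        overall_iqr=overall_iqr,
    )


def fold_enrichment(count: int, list_total: int, pop_hits: int, pop_total: int) -> float:
    """(count / list_total) / (pop_hits / pop_total)."""
    if min(count, list_total, pop_hits, pop_total) <= 0:
        if pop_hits == 0:
            raise ValueError("pop_hits must be positive")
        raise ValueError("all counts must be positive")
    if count > list_total or pop_hits > pop_total or count > pop_hits:
        raise ValueError("inconsistent contingency counts")
    return (count / list_total) / (pop_hits / pop_total)


def ease_p(count: int, list_total: int, pop_hits: int, pop_total: int) -> float:
    """EASE score: hypergeometric upper tail with the overlap reduced by 1.

    P(X >= count - 1) drawing list_total from a population of pop_total
    with pop_hits successes; count <= 1 gives P = 1 by construction.
    Always at least as large as the plain one-tailed Fisher P.
    """
    if count <= 1:
        return 1.0
    return float(stats.hypergeom.sf(count - 2, pop_total, pop_hits, list_total))


def enrich(
    list_ids,
    annotation: AnnotationTable,
    use_ease: bool = True,
) -> pd.DataFrame:
    """Disease-class enrichment of ``list_ids`` against the background.

    Totals count only proteins carrying at least one class annotation (the
    mappable universe), mirroring how category-enrichment tools report
    their List Total / Population Total.  Classes with no overlap in the
    list are skipped; Bonferroni multiplies by the number of classes
    tested, capped at 1.
    """
    list_ids = set(list_ids)
    bg = set(annotation.background)
    if not list_ids:
        raise ValueError("empty protein list")
    if not list_ids <= bg:
        raise ValueError("list contains ids outside the annotation background")

    annotated = set(annotation.mapping)
    list_total = len(list_ids & annotated)
    pop_total = len(bg & annotated)
    if list_total == 0:
        raise ValueError("no protein in the list carries any annotation")

    rows = []
    for label in annotation.classes:
        in_class = annotation.ids_in_class(label)
        pop_hits = len(in_class & bg & annotated)
        count = len(in_class & list_ids)
        if count == 0 or pop_hits == 0:
            continue
        fold = fold_enrichment(count, list_total, pop_hits, pop_total)
        if use_ease:
            p = ease_p(count, list_total, pop_hits, pop_total)
        else:
            p = float(stats.hypergeom.sf(count - 1, pop_total, pop_hits, list_total))
        rows.append(
            {
                "class": label,
                "count": count,
                "list_total": list_total,
                "pop_hits": pop_hits,
                "pop_total": pop_total,
                "fold_enrichment": fold,
                "ease_p": p,
            }
        )
    if not rows:
        raise ValueError("no annotated class overlaps the list")
    out = pd.DataFrame(rows).sort_values("ease_p", ignore_index=True)
    out["bonferroni_p"] = np.minimum(1.0, out["ease_p"] * len(out))
    return out
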