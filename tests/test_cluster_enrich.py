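import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import protmr
from protmr.cluster_enrich import (
    cluster_effects,
    ease_p,
    enrich,
    fold_enrichment,
    kmeans_scan,
    pca_proteins,
)


def _blocky_proteome(n_blocks=5, per_block=30, n=400, r=0.9, seed=0):
    rng = np.random.default_rng(seed)
    cols = []
    for b in range(n_blocks):
        f = rng.standard_normal((n, 1))
        cols.append(np.sqrt(r) * f + np.sqrt(1 - r) * rng.standard_normal((n, per_block)))
    X = np.hstack(cols)
    return pd.DataFrame(X, columns=[f"a{i}" for i in range(X.shape[1])])


def test_pca_explained_variance_sums_to_one():
    df = _blocky_proteome(seed=1)
    _, explained, _ = pca_proteins(df)
    assert explained.sum() == pytest.approx(1.0, abs=1e-10)
    assert (np.diff(explained) <= 1e-12).all()


def test_pca_separates_anticorrelated_groups():
    rng = np.random.default_rng(2)
    f = rng.standard_normal((300, 1))
    up = f + 0.1 * rng.standard_normal((300, 10))
    down = -f + 0.1 * rng.standard_normal((300, 10))
    df = pd.DataFrame(np.hstack([up, down]), columns=[f"a{i}" for i in range(20)])
    scores, explained, _ = pca_proteins(df, n_pcs=1)
    pc1 = scores["PC1"].to_numpy()
    assert explained[0] > 0.8
    assert (np.sign(pc1[:10]) != np.sign(pc1[10:])).all()


def test_pca_elbow_suggests_block_count():
    df = _blocky_proteome(n_blocks=5, seed=3)
    _, _, suggested = pca_proteins(df)
    assert suggested == 5


def test_kmeans_ratio_limits_and_conservation():
    """betweenness/totSS is 1 at k = #distinct points and non-decreasing."""
    pts = np.repeat(np.arange(6, dtype=float)[:, None] * 10, 4, axis=0)
    pc = pd.DataFrame(
        pts + 0.0, columns=["PC1"], index=[f"a{i}" for i in range(24)]
    )
    out = kmeans_scan(pc, k_range=(2, 8), seed=0)
    scan = out.k_scan.set_index("k")["betweenness_over_totss"]
    assert scan.loc[6] == pytest.approx(1.0, abs=1e-12)
    assert (scan.diff().dropna() >= -1e-9).all()
    assert (scan >= 0).all() and (scan <= 1 + 1e-12).all()


def test_kmeans_scan_deterministic_given_seed():
    df = _blocky_proteome(seed=4)
    pc, _, _ = pca_proteins(df, n_pcs=5)
    a = kmeans_scan(pc, k_range=(2, 10), seed=11)
    b = kmeans_scan(pc, k_range=(2, 10), seed=11)
    assert a.chosen_k == b.chosen_k
    assert (a.assignment == b.assignment).all()
    pd.testing.assert_frame_equal(a.k_scan, b.k_scan)


def test_kmeans_plateau_picks_block_count():
    df = _blocky_proteome(n_blocks=5, seed=5)
    pc, _, suggested = pca_proteins(df)
    out = kmeans_scan(pc, k_range=(2, 15), seed=0)
    assert suggested == 5
    assert out.chosen_k == 5


def test_kmeans_k_range_validation():
    pc = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)),
                      columns=["PC1", "PC2"])
    with pytest.raises(ValueError):
        kmeans_scan(pc, k_range=(2, 40))


def test_cluster_effects_rank_sum_matches_enumeration():
    """Pairwise one-tailed P equals exhaustive enumeration over C(6,3) splits."""
    vals = np.array([0.9, 2.1, 3.3, 0.4, 1.2, 0.7])
    a_idx = [0, 1, 2]
    assoc = pd.DataFrame(
        {"aptamer": [f"p{i}" for i in range(6)], "beta": vals, "se": 1.0,
         "p": 0.5, "model": "obs_model1", "n": 100}
    )
    assignment = pd.Series(
        [1, 1, 1, 2, 2, 2], index=[f"p{i}" for i in range(6)]
    )
    out = cluster_effects(assignment, assoc)
    p_impl = out.pairwise.query("cluster_a == 1 and cluster_b == 2")["p"].iloc[0]
    # enumeration oracle: distribution of the rank sum over all 3-subsets
    ranks = stats.rankdata(vals)
    obs_sum = ranks[a_idx].sum()
    sums = [sum(ranks[list(c)]) for c in itertools.combinations(range(6), 3)]
    p_exact = np.mean([s >= obs_sum for s in sums])
    assert p_impl == pytest.approx(p_exact, abs=1e-12)


def test_cluster_effects_flags_shifted_cluster():
    rng = np.random.default_rng(6)
    P = 120
    vals = np.abs(rng.standard_normal(P))
    vals[:30] += 1.0
    assoc = pd.DataFrame(
        {"aptamer": [f"p{i}" for i in range(P)], "beta": vals, "se": 1.0,
         "p": 0.5, "model": "obs_model1", "n": 100}
    )
    assignment = pd.Series(
        np.repeat([1, 2, 3, 4], 30), index=[f"p{i}" for i in range(P)]
    )
    out = cluster_effects(assignment, assoc)
    best = out.per_cluster.loc[out.per_cluster["p_vs_overall"].idxmin(), "cluster"]
    assert best == 1
    assert out.per_cluster.set_index("cluster").loc[1, "median_abs_beta_se"] > \
        out.overall_median


def test_cluster_effects_singleton_cluster_warns(caplog):
    assoc = pd.DataFrame(
        {"aptamer": ["p0", "p1", "p2", "p3"], "beta": [1.0, 2.0, 3.0, 4.0],
         "se": 1.0, "p": 0.5, "model": "m", "n": 10}
    )
    assignment = pd.Series([1, 2, 2, 2], index=["p0", "p1", "p2", "p3"])
    import logging

    with caplog.at_level(logging.WARNING, logger="protmr"):
        out = cluster_effects(assignment, assoc)
    row = out.per_cluster.set_index("cluster").loc[1]
    assert np.isnan(row["p_vs_overall"])


def test_fold_enrichment_printed_contingency_rows():
    assert fold_enrichment(439, 1024, 1023, 2723) == pytest.approx(1.14, abs=0.005)
    assert fold_enrichment(216, 1024, 472, 2723) == pytest.approx(1.22, abs=0.005)
    assert fold_enrichment(100, 200, 500, 1000) == 1.0
    with pytest.raises(ValueError):
        fold_enrichment(10, 20, 0, 100)
    with pytest.raises(ValueError):
        fold_enrichment(30, 20, 50, 100)


@given(
    st.integers(1, 50), st.integers(1, 50), st.integers(1, 50), st.integers(2, 20)
)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_fold_enrichment_scale_invariant(count, extra_list, extra_pop, c):
    list_total = count + extra_list
    pop_hits = count + extra_pop
    pop_total = pop_hits + list_total  # any consistent superset works
    base = fold_enrichment(count, list_total, pop_hits, pop_total)
    scaled = fold_enrichment(count * c, list_total * c, pop_hits * c, pop_total * c)
    assert scaled == pytest.approx(base, rel=1e-12)


def test_ease_is_conservative_fisher():
    """EASE decrements the overlap, so its tail P >= the plain Fisher P."""
    rng = np.random.default_rng(7)
    for _ in range(25):
        pop_total = int(rng.integers(50, 500))
        pop_hits = int(rng.integers(5, pop_total // 2))
        list_total = int(rng.integers(5, pop_total // 2))
        count = int(rng.integers(1, min(pop_hits, list_total)))
        fisher = stats.hypergeom.sf(count - 1, pop_total, pop_hits, list_total)
        assert ease_p(count, list_total, pop_hits, pop_total) >= fisher - 1e-12
    assert ease_p(1, 100, 50, 200) == 1.0


def test_enrich_whole_background_has_unit_fold():
    ids = [f"a{i}" for i in range(300)]
    tab = protmr.simulate_annotations(ids, ids[:50], ["cvd", "renal", "cancer"],
                                      1.0, seed=8)
    out = enrich(ids, tab)
    assert np.allclose(out["fold_enrichment"], 1.0)
    assert (out["bonferroni_p"] <= 1.0).all()


def test_enrich_recovers_built_in_fold():
    """A class seeded at twice the background rate in a 200/1000 cluster is
    recovered at its expected fold-enrichment statistic and flagged by EASE.

    The population rate includes the enriched list itself, so the expected
    statistic for a built-in rate ratio F over a cluster weight w is
    F / (w F + 1 - w), not F.
    """
    ids = [f"a{i}" for i in range(1000)]
    cluster = ids[:200]
    classes = ["cvd", "renal", "cancer", "metabolic", "catchall"]
    F, w = 2.0, 0.2
    expected = F / (w * F + 1 - w)  # 1.667
    folds, hits = [], 0
    for seed in (1, 2, 3, 4, 5):
        # catchall at unit rate keeps every protein annotated, so the
        # mappable-universe totals do not distort the built-in fold
        tab = protmr.simulate_annotations(
            ids, cluster, classes, F, background_rate=0.2,
            enriched_class="cvd", seed=seed,
        )
        for pid in ids:
            cur = tab.mapping.get(pid, frozenset())
            tab.mapping[pid] = cur | {"catchall"}
        out = enrich(cluster, tab).set_index("class")
        folds.append(out.loc["cvd", "fold_enrichment"])
        hits += out.loc["cvd", "ease_p"] < 0.05 / len(out)
    assert all(abs(f - expected) <= 0.25 for f in folds)
    assert hits >= 4


def test_enrich_input_validation():
    ids = ["a", "b", "c"]
    tab = protmr.AnnotationTable({"a": frozenset({"cvd"})}, background=tuple(ids))
    with pytest.raises(ValueError):
        enrich([], tab)
    with pytest.raises(ValueError):
        enrich(["zzz"], tab)
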