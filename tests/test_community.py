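"""Girvan-Newman clustering, modularity nulls, cluster composition tests."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from raidnet.community import (
    cluster_composition_test,
    girvan_newman,
    modularity,
    modularity_null,
    symmetrize,
)


def two_triangles(bridge=False):
    g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    if bridge:
        g.add_edge(2, 3)
    return g


def all_partitions(nodes):
    """Every set partition of the node list (Bell-number enumeration)."""
    nodes = list(nodes)
    if not nodes:
        yield []
        return
    first = nodes[0]
    for rest in all_partitions(nodes[1:]):
        for i in range(len(rest)):
            yield rest[:i] + [[first] + rest[i]] + rest[i + 1 :]
        yield [[first]] + rest


def brute_force_max_q(g):
    best = -1.0
    for part in all_partitions(list(g.nodes)):
        labels = {v: i for i, blk in enumerate(part) for v in blk}
        best = max(best, modularity(g, labels))
    return best


def test_single_cluster_has_zero_modularity():
    g = two_triangles()
    assert modularity(g, {v: 0 for v in g.nodes}) == pytest.approx(0.0)


def test_two_disjoint_triangles_q_half():
    g = two_triangles()
    labels = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
    assert modularity(g, labels) == pytest.approx(0.5)
    # brute force confirms 0.5 is the global optimum
    assert brute_force_max_q(g) == pytest.approx(0.5)


def test_modularity_empty_graph_errors():
    g = nx.Graph()
    g.add_nodes_from([0, 1])
    with pytest.raises(ValueError, match="no edges"):
        modularity(g, {0: 0, 1: 1})


def test_girvan_newman_removes_bridge_first():
    part = girvan_newman(two_triangles(bridge=True))
    assert part.n_clusters == 2
    assert part.labels[0] == part.labels[1] == part.labels[2]
    assert part.labels[3] == part.labels[4] == part.labels[5]
    # Q for the 2-triangle split of the bridged graph: 5/7 - ... via formula
    assert part.q == pytest.approx(modularity(two_triangles(bridge=True), part.labels))


def test_girvan_newman_keeps_disjoint_components_apart():
    part = girvan_newman(two_triangles())
    assert part.n_clusters == 2
    assert part.q == pytest.approx(0.5)


@pytest.mark.parametrize("seed", range(10))
def test_girvan_newman_against_exhaustive_oracle(seed):
    """On n<=7 random graphs: GN's Q never beats the brute-force optimum and
    never falls below the best partition on an independent GN chain."""
    g = nx.gnp_random_graph(7, 0.35, seed=seed)
    if g.number_of_edges() == 0:
        pytest.skip("empty random draw")
    ours = girvan_newman(g).q
    assert ours <= brute_force_max_q(g) + 1e-12
    # independent chain: networkx's own Girvan-Newman implementation
    best_nx = modularity(
        g, {v: i for i, c in enumerate(nx.connected_components(g)) for v in c}
    )
    for part in nx.algorithms.community.girvan_newman(g):
        labels = {v: i for i, c in enumerate(part) for v in c}
        best_nx = max(best_nx, modularity(g, labels))
    assert ours >= best_nx - 1e-12


def test_girvan_newman_deterministic():
    g = nx.gnp_random_graph(15, 0.2, seed=3)
    p1, p2 = girvan_newman(g), girvan_newman(g)
    assert p1.labels == p2.labels and p1.q == p2.q


def test_symmetrize_collapses_reciprocal_arcs():
    d = nx.DiGraph([("a", "b"), ("b", "a"), ("b", "c")])
    u = symmetrize(d)
    assert sorted(map(sorted, u.edges)) == [["a", "b"], ["b", "c"]]


def test_modularity_null_preserves_n_and_m_and_flat_on_complete_graph():
    g = nx.complete_graph(8)
    out = modularity_null(g, n_reps=20, seed=0)
    # complete graph: nothing to find; observed Q at the random-graph level
    assert out["q_obs"] <= out["null_mean"] + 3 * out["null_sd"] + 0.05
    assert out["p"] > 0.05
    # replicates preserve node and edge counts by construction of G(n, m)
    rep = nx.gnm_random_graph(8, g.number_of_edges(), seed=1)
    assert rep.number_of_nodes() == 8
    assert rep.number_of_edges() == g.number_of_edges()


def test_modularity_null_detects_planted_blocks():
    """A strongly blocked network scores far above the shuffled-edge null."""
    import raidnet as rn
    import raidnet.association as assoc

    ds = rn.generate_dataset(rn.PopulationConfig(seed=11, eps_between=0.02))
    m = assoc.build_association_matrix(ds.sightings, ds.attributes)
    m = m.subset(assoc.filter_focal_males(m))
    net = assoc.build_top_k_network(assoc.rank_associates(m), m, k=2)
    out = modularity_null(net, n_reps=60, seed=0)
    assert out["q_obs"] > 0.6
    assert out["p"] <= 1 / 60


def _table_layout():
    """58 individuals in clusters of sizes 8,10,12,12,9,7 with 21 raiders
    placed 1,6,5,1,3,5 across the clusters."""
    sizes = [8, 10, 12, 12, 9, 7]
    k_raiders = [1, 6, 5, 1, 3, 5]
    labels = np.repeat(np.arange(6), sizes)
    vals = np.concatenate(
        [np.r_[np.ones(k), np.zeros(s - k)] for s, k in zip(sizes, k_raiders)]
    )
    return labels, vals, sizes, k_raiders


def exact_two_sided_hypergeom_p(N, K, n, k_obs):
    """P(|X/n - E| >= |k_obs/n - E|) for X ~ Hypergeom(N, K, n)."""
    mean = n * K / N
    dev = abs(k_obs - mean)
    ks = np.arange(0, min(n, K) + 1)
    pmf = stats.hypergeom.pmf(ks, N, K, n)
    return float(pmf[np.abs(ks - mean) >= dev - 1e-9].sum())


def test_composition_null_mean_matches_global_proportion():
    labels, vals, sizes, _ = _table_layout()
    res = cluster_composition_test(labels, vals, "proportion", n_reps=1000, seed=1)
    for _, row in res.table.iterrows():
        assert row["null_mean"] == pytest.approx(21 / 58, abs=4 * row["null_se"] + 1e-3)


def test_composition_p_matches_exact_hypergeometric_oracle():
    labels, vals, sizes, k_raiders = _table_layout()
    res = cluster_composition_test(labels, vals, "proportion", n_reps=2000, seed=2)
    t = res.table.set_index("cluster")
    for c, (n_c, k_c) in enumerate(zip(sizes, k_raiders)):
        exact = exact_two_sided_hypergeom_p(58, 21, n_c, k_c)
        mc_se = np.sqrt(exact * (1 - exact) / 2000)
        assert t.loc[c, "p"] == pytest.approx(exact, abs=max(3 * mc_se, 0.01) + 0.015)


def test_composition_constant_attribute_gives_p_one():
    labels, _, _, _ = _table_layout()
    res = cluster_composition_test(labels, np.ones(58), "proportion", n_reps=100, seed=0)
    assert (res.table["p"] == 1.0).all()


def test_composition_mean_statistic_and_validation():
    labels, _, _, _ = _table_layout()
    rng = np.random.default_rng(0)
    ages = rng.integers(10, 55, size=58).astype(float)
    res = cluster_composition_test(labels, ages, "mean", n_reps=500, seed=3)
    grand = ages.mean()
    for _, row in res.table.iterrows():
        assert row["null_mean"] == pytest.approx(grand, abs=5 * row["null_se"] + 0.05)
    with pytest.raises(ValueError, match="binary"):
        cluster_composition_test(labels, ages, "proportion", n_reps=10, seed=0)
    with pytest.raises(ValueError, match="statistic"):
        cluster_composition_test(labels, ages, "median", n_reps=10, seed=0)


def test_composition_deterministic_under_seed():
    labels, vals, _, _ = _table_layout()
    r1 = cluster_composition_test(labels, vals, "proportion", n_reps=200, seed=9)
    r2 = cluster_composition_test(labels, vals, "proportion", n_reps=200, seed=9)
    assert r1.table.equals(r2.table)
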