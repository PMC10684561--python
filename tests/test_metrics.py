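import itertools

import networkx as nx
import numpy as np
import pytest

import likertnet as ln
from likertnet.metrics import (average_shortest_path_length,
                               bootstrap_partial_metrics, clustering_coefficient,
                               compare_conditions, modularity_max)

from .conftest import random_symmetric


# -- brute-force oracles ----------------------------------------------------

def brute_cc(G):
    vals = {}
    for v in G.nodes:
        nbrs = list(G.neighbors(v))
        k = len(nbrs)
        if k < 2:
            vals[v] = 0.0
            continue
        tri = sum(1 for a, b in itertools.combinations(nbrs, 2) if G.has_edge(a, b))
        vals[v] = 2 * tri / (k * (k - 1))
    return vals, float(np.mean(list(vals.values())))


def brute_aspl(G):
    nodes = list(G.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for u, v in G.edges:
        D[idx[u], idx[v]] = D[idx[v], idx[u]] = 1.0
    for k in range(n):           # Floyd-Warshall
        D = np.minimum(D, D[:, [k]] + D[[k], :])
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    return float(D[finite].mean()) if finite.any() else None


def brute_best_modularity(G):
    """Exhaustive max over all partitions (set partitions of the nodes)."""
    nodes = list(G.nodes)

    def parts(seq):
        if not seq:
            yield []
            return
        first, rest = seq[0], seq[1:]
        for p in parts(rest):
            for i in range(len(p)):
                yield p[:i] + [[first] + p[i]] + p[i + 1:]
            yield [[first]] + p

    adj = nx.to_numpy_array(G, nodelist=nodes)
    best = -np.inf
    for p in parts(nodes):
        member = np.empty(len(nodes), dtype=int)
        for cid, block in enumerate(p):
            for v in block:
                member[nodes.index(v)] = cid
        best = max(best, ln.modularity(adj, member))
    return best


# -- clustering coefficient -------------------------------------------------

def test_cc_triangle_and_star():
    tri = nx.complete_graph(3)
    assert clustering_coefficient(tri)[1] == pytest.approx(1.0)
    star = nx.star_graph(4)
    assert clustering_coefficient(star)[1] == pytest.approx(0.0)


def test_cc_hand_enumerated_five_node_graph():
    G = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("d", "e")])
    per_node, mean = clustering_coefficient(G)
    assert per_node == pytest.approx({"a": 1, "b": 1, "c": 1 / 3, "d": 0, "e": 0})
    assert mean == pytest.approx(7 / 15)


def test_cc_and_aspl_match_brute_force_on_small_graphs():
    rng = np.random.default_rng(12)
    for trial in range(100):
        n = int(rng.integers(3, 9))
        G = nx.gnp_random_graph(n, rng.uniform(0.2, 0.9), seed=int(rng.integers(2**31)))
        _, cc = clustering_coefficient(G)
        _, cc_oracle = brute_cc(G)
        assert cc == pytest.approx(cc_oracle, abs=1e-12)
        expected = brute_aspl(G)
        if expected is None:
            with pytest.raises(ValueError):
                average_shortest_path_length(G)
        else:
            assert average_shortest_path_length(G) == pytest.approx(expected, abs=1e-12)


# -- ASPL -------------------------------------------------------------------

def test_aspl_examples():
    path = nx.path_graph(3)
    assert average_shortest_path_length(path) == pytest.approx(4 / 3)
    assert average_shortest_path_length(nx.complete_graph(5)) == pytest.approx(1.0)
    two_edges = nx.Graph([(0, 1), (2, 3)])  # unreachable pairs excluded
    assert average_shortest_path_length(two_edges) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="ASPL undefined"):
        average_shortest_path_length(nx.empty_graph(4))


# -- modularity maximization ------------------------------------------------

def test_modularity_two_disconnected_triangles_is_exhaustive_optimum():
    G = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
    part, q = modularity_max(G, n_restarts=5, seed=0)
    assert q == pytest.approx(0.5)
    assert part.n_communities == 2
    assert q == pytest.approx(brute_best_modularity(G))


def test_modularity_k4_best_is_single_community():
    G = nx.complete_graph(4)
    _, q = modularity_max(G, n_restarts=5, seed=0)
    assert q == pytest.approx(0.0, abs=1e-12)
    assert brute_best_modularity(G) == pytest.approx(0.0, abs=1e-12)


def test_best_q_dominates_trivial_partitions():
    rng = np.random.default_rng(4)
    for _ in range(10):
        G = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
        if G.number_of_edges() == 0:
            continue
        adj = nx.to_numpy_array(G)
        _, q = modularity_max(G, n_restarts=5, seed=1)
        assert q >= ln.modularity(adj, np.zeros(12, dtype=int)) - 1e-12
        assert q >= ln.modularity(adj, np.arange(12)) - 1e-12


def test_q_stable_across_seeds_on_planted_tmfg(four_block_partition):
    cfg = ln.SyntheticConfig(n_items=75, n_participants_per_condition=300,
                             n_conditions=1, planted_partition=four_block_partition,
                             within_block_corr=0.6, between_block_corr=0.1, seed=5)
    tables, _ = ln.generate_ratings(cfg)
    net = ln.binarize_network(ln.tmfg_filter(ln.cosine_similarity_matrix(
        tables["condition_1"])))
    qs = [modularity_max(net, n_restarts=3, seed=s)[1] for s in range(25)]
    assert np.std(qs) < 0.01


# -- bootstrap --------------------------------------------------------------

def test_bootstrap_single_realization_reproducible(default_networks):
    sims, _ = default_networks
    sim = sims["aesthetic"]
    a = bootstrap_partial_metrics(sim, n_nodes=20, n_real=1, seed=9)
    b = bootstrap_partial_metrics(sim, n_nodes=20, n_real=1, seed=9)
    for m in ("CC", "ASPL", "Q"):
        assert a[m].values == pytest.approx(b[m].values)
        assert len(a[m].values) == 1


def test_bootstrap_validations(default_networks):
    sims, _ = default_networks
    sim = sims["aesthetic"]
    with pytest.raises(ValueError, match=">= 4"):
        bootstrap_partial_metrics(sim, n_nodes=3)
    with pytest.raises(ValueError, match="< n"):
        bootstrap_partial_metrics(sim, n_nodes=75)
    with pytest.raises(ValueError, match="partial_mode"):
        bootstrap_partial_metrics(sim, n_nodes=10, n_real=1, partial_mode="nope")


def test_bootstrap_mean_approaches_full_network_value(default_networks):
    """|bootstrap mean - full-network ASPL| shrinks as the subsample grows."""
    sims, nets = default_networks
    sim, net = sims["aesthetic"], nets["aesthetic"]
    full = average_shortest_path_length(net)
    gaps = []
    for n_nodes in (20, 37, 60):
        d = bootstrap_partial_metrics(sim, n_nodes=n_nodes, n_real=60, seed=17)
        gaps.append(abs(float(np.mean(d["ASPL"].values)) - full))
    assert gaps[0] > gaps[1] > gaps[2]


def test_induced_mode_differs_from_refit_mode(default_networks):
    sims, _ = default_networks
    sim = sims["consumer"]
    a = bootstrap_partial_metrics(sim, n_nodes=37, n_real=20, seed=3, partial_mode="tmfg")
    b = bootstrap_partial_metrics(sim, n_nodes=37, n_real=20, seed=3, partial_mode="induced")
    # refit keeps 3n-6 edges so is denser than the induced subgraph
    assert float(np.mean(a["CC"].values)) > float(np.nanmean(b["CC"].values))


# -- condition comparison ---------------------------------------------------

def test_compare_conditions_reports_and_degenerate_flag():
    from likertnet.metrics import BootstrapDistribution
    const = {c: BootstrapDistribution("CC", c, np.ones(50), 10, 0) for c in "abc"}
    rep = compare_conditions(const)
    assert rep["anova"].degenerate
    with pytest.raises(ValueError, match="at least 2"):
        compare_conditions({"a": const["a"]})


def test_cohens_d_recovers_unit_effect():
    from likertnet.metrics import BootstrapDistribution
    rng = np.random.default_rng(8)
    d1 = BootstrapDistribution("Q", "a", rng.normal(0, 1, 1000), 10, 0)
    d2 = BootstrapDistribution("Q", "b", rng.normal(1, 1, 1000), 10, 0)
    rep = compare_conditions({"a": d1, "b": d2})
    t = rep["pairwise"][("a", "b")]
    assert abs(t.effect_size) == pytest.approx(1.0, abs=0.1)
    assert t.df == (1998,)
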