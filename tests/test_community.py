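import itertools

import networkx as nx
import numpy as np
import pytest

import likertnet as ln
from likertnet.community import (ConsensusLouvain, Partition, _louvain_labels,
                                 adjusted_rand_index, community_profile,
                                 consensus_partition, louvain, rand_index)


# -- oracles ----------------------------------------------------------------

def brute_rand(p1: Partition, p2: Partition) -> float:
    nodes = sorted(p1.labels, key=str)
    agree = total = 0
    for a, b in itertools.combinations(nodes, 2):
        same1 = p1.labels[a] == p1.labels[b]
        same2 = p2.labels[a] == p2.labels[b]
        agree += same1 == same2
        total += 1
    return agree / total


def all_partitions(nodes):
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for p in all_partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [[first] + p[i]] + p[i + 1:]
        yield [[first]] + p


def as_partition(blocks):
    labels = {}
    for cid, block in enumerate(blocks, start=1):
        for v in block:
            labels[v] = cid
    return Partition(labels)


# -- Rand index -------------------------------------------------------------

def test_rand_examples():
    p1 = as_partition([[1, 2], [3]])
    p2 = as_partition([[1], [2, 3]])
    assert rand_index(p1, p2) == pytest.approx(1 / 3)
    assert rand_index(p1, p1) == 1.0
    singles = as_partition([[i] for i in range(5)])
    lump = as_partition([list(range(5))])
    assert rand_index(singles, lump) == 0.0
    assert adjusted_rand_index(p1, p1) == 1.0


def test_rand_matches_brute_force_exhaustively_small_n():
    nodes = list(range(5))
    parts = [as_partition(b) for b in all_partitions(nodes)]
    for p1, p2 in itertools.product(parts, repeat=2):
        assert rand_index(p1, p2) == pytest.approx(brute_rand(p1, p2), abs=1e-12)


def test_rand_matches_brute_force_sampled_n6_n7():
    rng = np.random.default_rng(21)
    for n in (6, 7):
        for _ in range(300):
            p1 = Partition({i: int(v) for i, v in enumerate(rng.integers(0, 3, n))})
            p2 = Partition({i: int(v) for i, v in enumerate(rng.integers(0, 4, n))})
            assert rand_index(p1, p2) == pytest.approx(brute_rand(p1, p2), abs=1e-12)


def test_rand_node_set_mismatch():
    with pytest.raises(ValueError, match="node sets"):
        rand_index(as_partition([[1, 2]]), as_partition([[1, 3]]))


# -- Louvain ----------------------------------------------------------------

def test_two_disconnected_triangles_any_seed():
    G = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
    for seed in range(10):
        p = louvain(G, seed=seed)
        assert p.n_communities == 2
        assert p.labels[0] == p.labels[1] == p.labels[2]
        assert p.labels[3] == p.labels[4] == p.labels[5]


def test_ring_of_cliques_recovers_four_communities():
    G = nx.ring_of_cliques(4, 5)
    hits = sum(louvain(G, seed=s).n_communities == 4 for s in range(100))
    assert hits >= 95


def test_single_edge_single_community():
    p = louvain(nx.Graph([("a", "b")]), seed=0)
    # Q(one community) = 0 beats Q(split) = -0.5
    assert p.n_communities == 1
    assert p.provenance["modularity"] == pytest.approx(0.0)


def test_louvain_phase_modularity_never_decreases():
    rng = np.random.default_rng(31)
    for _ in range(20):
        G = nx.gnp_random_graph(25, 0.15, seed=int(rng.integers(2**31)))
        if G.number_of_edges() == 0:
            continue
        adj = nx.to_numpy_array(G)
        _, phase_q = _louvain_labels(adj, 1.0, np.random.default_rng(int(rng.integers(2**31))))
        assert all(b >= a - 1e-12 for a, b in zip(phase_q, phase_q[1:]))


def test_louvain_quality_comparable_to_networkx():
    rng = np.random.default_rng(41)
    for s in range(5):
        G = nx.gnp_random_graph(40, 0.12, seed=s)
        ours = max(louvain(G, seed=k).provenance["modularity"] for k in range(5))
        import networkx.algorithms.community as nxc
        theirs = nxc.modularity(G, nxc.louvain_communities(G, seed=s))
        assert ours >= theirs - 0.02


def test_empty_graph_rejected():
    with pytest.raises(ValueError, match="at least one edge"):
        louvain(nx.empty_graph(5))


# -- consensus --------------------------------------------------------------

def test_unanimous_graph_converges_in_one_round():
    G = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    p = consensus_partition(G, n_iter=50, seed=1)
    assert p.n_communities == 2
    assert p.provenance["rounds"] == 1


def test_consensus_reproducible_and_idempotent():
    rng = np.random.default_rng(5)
    W = rng.random((30, 30))
    W = (W + W.T) / 2
    G = ln.binarize_network(ln.tmfg_filter(W))
    p1 = consensus_partition(G, n_iter=100, seed=7)
    p2 = consensus_partition(G, n_iter=100, seed=7)
    assert p1.labels == p2.labels
    # idempotence: re-cluster the block graph induced by the consensus
    n = 30
    nodes = list(G.nodes)
    member = p1.member_ids(nodes)
    block_adj = (member[:, None] == member[None, :]).astype(float)
    np.fill_diagonal(block_adj, 0.0)
    est = ConsensusLouvain(n_iter=50, random_state=3).fit(block_adj)
    again = Partition.from_ids(nodes, est.labels_)
    assert rand_index(p1, again) == 1.0


def test_consensus_recovers_planted_blocks(four_block_partition):
    cfg = ln.SyntheticConfig(n_items=75, n_participants_per_condition=300,
                             n_conditions=1, planted_partition=four_block_partition,
                             within_block_corr=0.6, between_block_corr=0.1, seed=19)
    tables, planted = ln.generate_ratings(cfg)
    net = ln.binarize_network(ln.tmfg_filter(
        ln.cosine_similarity_matrix(tables["condition_1"])))
    cons = consensus_partition(net, n_iter=300, seed=4)
    assert rand_index(cons, planted) >= 0.9


def test_consensus_estimator_validations():
    with pytest.raises(ValueError, match="square"):
        ConsensusLouvain().fit(np.ones((3, 4)))
    with pytest.raises(ValueError, match="at least one edge"):
        ConsensusLouvain().fit(np.zeros((4, 4)))


# -- community profiles -----------------------------------------------------

def test_profile_planted_low_block_is_lowest_everywhere(default_tables):
    tables, planted = default_tables
    profile, anova = community_profile(tables, planted)
    by = profile.groupby(["condition", "community"])["mean_rating"].mean().unstack()
    low_block = 4  # the planted low-endorsement block
    for cond in by.index:
        assert by.loc[cond].idxmin() == low_block
    # printed df shapes for 3 conditions x 5 communities x 75 items/condition
    assert anova["condition"].df == (2, 210)
    assert anova["community"].df == (4, 210)
    assert anova["condition:community"].df == (8, 210)
    assert anova["condition:community"].statistic > 0


def test_profile_constant_ratings_flagged_degenerate(default_tables):
    import pandas as pd
    from likertnet.synthetic import RatingsTable
    _, planted = default_tables
    items = list(planted.labels)
    flat = {c: RatingsTable(c, pd.DataFrame(3, index=[f"{c}{i}" for i in range(5)],
                                            columns=items)) for c in ("x", "y")}
    _, anova = community_profile(flat, planted)
    assert all(rep.degenerate for rep in anova.values())


def test_profile_missing_items_rejected(default_tables):
    tables, planted = default_tables
    keep = [k for k, v in planted.labels.items() if v != 5]
    with pytest.raises(ValueError, match="missing"):
        community_profile({"a": tables["aesthetic"].data[keep]}, planted)
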