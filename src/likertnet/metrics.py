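"""Macro-level network measures and the without-replacement node bootstrap.

Three global measures summarize a binarized item network: the mean
clustering coefficient CC (how often two neighbors of a node are
themselves connected), the average shortest path length ASPL (mean BFS
distance over reachable node pairs), and the modularity Q of the best
partition found by Louvain maximization.

A single network yields a single value per measure, so conditions are
compared with a without-replacement bootstrap: each realization samples
half of the items (default 37 of 75), builds the partial network for
those items, and records CC/ASPL/Q.  The resulting per-condition
distributions are compared by one-way ANOVA and pairwise t-tests.

Two partial-network constructions are exposed: re-running the TMFG
filter on the sampled similarity submatrix (default; keeps the 3n - 6
edge count so conditions stay directly comparable) or taking the induced
subgraph of the full filtered network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from . import stats as _stats
from .community import Partition, _louvain_labels, modularity
from .tmfg import tmfg_edge_list

__all__ = [
    "MacroMetrics", "BootstrapDistribution", "clustering_coefficient",
    "average_shortest_path_length", "modularity_max", "macro_metrics",
    "bootstrap_partial_metrics", "compare_conditions",
]

MEASURES = ("CC", "ASPL", "Q")


@dataclass
class MacroMetrics:
    cc: float
    aspl: float
    q: float
    condition: str | None = None

    def to_dict(self) -> dict:
        return {"condition": self.condition, "CC": self.cc, "ASPL": self.aspl, "Q": self.q}


@dataclass
class BootstrapDistribution:
    """Replicate values of one measure for one condition."""

    measure: str
    condition: str | None
    values: np.ndarray
    n_nodes: int
    seed: int | None
    partial_mode: str = "tmfg"

    @property
    def n_real(self) -> int:
        return len(self.values)

    def summary(self) -> dict:
        return {"measure": self.measure, "condition": self.condition,
                "mean": float(np.nanmean(self.values)), "sd": float(np.nanstd(self.values, ddof=1)),
                "n_real": self.n_real, "n_nodes": self.n_nodes, "partial_mode": self.partial_mode}


def _binary_adjacency(net) -> np.ndarray:
    if isinstance(net, nx.Graph):
        A = nx.to_numpy_array(net, weight=None)
    else:
        A = np.asarray(net, dtype=float)
    A = (A > 0).astype(float)
    np.fill_diagonal(A, 0.0)
    return A


def clustering_coefficient(net):
    """Per-node binary clustering coefficients and their unweighted mean.

    c_i = 2 * t_i / (k_i (k_i - 1)) with t_i the number of triangles
    through node i; nodes of degree < 2 contribute 0.
    """
    A = _binary_adjacency(net)
    k = A.sum(axis=1)
    tri = np.einsum("ij,jk,ki->i", A, A, A) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    nodes = list(net.nodes) if isinstance(net, nx.Graph) else list(range(A.shape[0]))
    return dict(zip(nodes, c)), float(c.mean())


def average_shortest_path_length(net) -> float:
    """Mean BFS distance over reachable ordered node pairs.

    Unreachable pairs are excluded, so the measure stays defined on
    disconnected bootstrap subgraphs; a graph with no edges has no
    reachable pairs and raises.
    """
    A = _binary_adjacency(net)
    if A.sum() == 0:
        raise ValueError("ASPL undefined: graph has no edges")
    D = shortest_path(A, method="D", unweighted=True, directed=False)
    off = ~np.eye(A.shape[0], dtype=bool)
    finite = np.isfinite(D) & off
    if not finite.any():
        raise ValueError("ASPL undefined: no reachable pairs")
    return float(D[finite].mean())


def modularity_max(net, gamma: float = 1.0, n_restarts: int = 10, seed=None):
    """Best Louvain partition and its modularity Q over seeded restarts."""
    if isinstance(net, nx.Graph):
        if net.number_of_edges() == 0:
            raise ValueError("modularity undefined for a graph with no edges")
        nodes = list(net.nodes)
        adj = nx.to_numpy_array(net, weight="weight")
    else:
        adj = np.asarray(net, dtype=float)
        nodes = list(range(adj.shape[0]))
        if adj.sum() <= 0:
            raise ValueError("modularity undefined for a graph with no edges")
    seeds = np.random.SeedSequence(seed).generate_state(n_restarts)
    best_q, best_member = -np.inf, None
    for s in seeds:
        member, phase_q = _louvain_labels(adj, gamma, np.random.default_rng(int(s)))
        if phase_q[-1] > best_q:
            best_q, best_member = phase_q[-1], member
    part = Partition.from_ids(nodes, best_member, algorithm="louvain_best_of",
                              n_restarts=n_restarts, gamma=gamma, seed=seed)
    return part, float(best_q)


def macro_metrics(net, gamma: float = 1.0, n_restarts: int = 10, seed=None) -> MacroMetrics:
    """CC, ASPL and Q of one binarized network."""
    _, cc = clustering_coefficient(net)
    aspl = average_shortest_path_length(net)
    _, q = modularity_max(net, gamma=gamma, n_restarts=n_restarts, seed=seed)
    cond = net.graph.get("condition") if isinstance(net, nx.Graph) else None
    return MacroMetrics(cc, aspl, q, cond)


def _partial_metrics(W: np.ndarray, idx: np.ndarray, partial_mode: str,
                     full_edges: list | None, gamma: float, q_restarts: int, q_seed: int):
    if partial_mode == "tmfg":
        sub = W[np.ix_(idx, idx)]
        A = np.zeros_like(sub)
        for i, j in tmfg_edge_list(sub):
            A[i, j] = A[j, i] = 1.0
    elif partial_mode == "induced":
        keep = set(idx.tolist())
        n = len(idx)
        pos = {v: p for p, v in enumerate(idx.tolist())}
        A = np.zeros((n, n))
        for i, j in full_edges:
            if i in keep and j in keep:
                A[pos[i], pos[j]] = A[pos[j], pos[i]] = 1.0
    else:
        raise ValueError(f"unknown partial_mode {partial_mode!r}")
    k = A.sum(axis=1)
    tri = np.einsum("ij,jk,ki->i", A, A, A) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = float(np.where(denom > 0, tri / denom, 0.0).mean())
    if A.sum() == 0:
        aspl = np.nan
        q = np.nan
        return cc, aspl, q
    D = shortest_path(A, method="D", unweighted=True, directed=False)
    off = ~np.eye(A.shape[0], dtype=bool)
    finite = np.isfinite(D) & off
    aspl = float(D[finite].mean()) if finite.any() else np.nan
    best_q = -np.inf
    for s in np.random.SeedSequence(q_seed).generate_state(q_restarts):
        _, phase_q = _louvain_labels(A, gamma, np.random.default_rng(int(s)))
        best_q = max(best_q, phase_q[-1])
    return cc, aspl, float(best_q)


def bootstrap_partial_metrics(sim, n_nodes: int = 37, n_real: int = 1000,
                              partial_mode: str = "tmfg", seed=None,
                              gamma: float = 1.0, q_restarts: int = 1,
                              condition: str | None = None) -> dict[str, BootstrapDistribution]:
    """Without-replacement bootstrap of CC/ASPL/Q on partial networks.

    Each of ``n_real`` realizations draws ``n_nodes`` items without
    replacement from the similarity matrix, builds the partial network
    (re-filtered TMFG by default, or the induced subgraph of the full
    TMFG), and records the three measures.  Fully seeded: the node
    samples and every Louvain restart derive from ``seed``.
    """
    if isinstance(sim, pd.DataFrame):
        condition = condition or sim.attrs.get("condition")
        W = sim.to_numpy(dtype=float)
    else:
        W = np.asarray(sim, dtype=float)
    n = W.shape[0]
    if n_nodes < 4:
        raise ValueError("n_nodes must be >= 4 (TMFG needs at least 4 nodes)")
    if n_nodes >= n:
        raise ValueError(f"n_nodes must be < n = {n}")
    full_edges = tmfg_edge_list(W) if partial_mode == "induced" else None

    root = np.random.SeedSequence(seed)
    sample_rng = np.random.default_rng(root.spawn(1)[0])
    q_seeds = root.spawn(1)[0].generate_state(n_real)
    vals = {m: np.empty(n_real) for m in MEASURES}
    for r in range(n_real):
        idx = sample_rng.choice(n, size=n_nodes, replace=False)
        cc, aspl, q = _partial_metrics(W, idx, partial_mode, full_edges,
                                       gamma, q_restarts, int(q_seeds[r]))
        vals["CC"][r], vals["ASPL"][r], vals["Q"][r] = cc, aspl, q
    return {m: BootstrapDistribution(m, condition, vals[m], n_nodes, seed, partial_mode)
            for m in MEASURES}


def compare_conditions(dists: dict[str, BootstrapDistribution]) -> dict:
    """Compare one measure's bootstrap distributions across conditions.

    ``dists`` maps condition label -> BootstrapDistribution (same
    measure, equal replicate counts).  Returns a dict with the one-way
    ANOVA report and all pairwise Student t-tests with Cohen's d.
    """
    if len(dists) < 2:
        raise ValueError("need at least 2 conditions to compare")
    names = list(dists)
    measures = {d.measure for d in dists.values()}
    if len(measures) != 1:
        raise ValueError(f"mixed measures in comparison: {measures}")
    sizes = {d.n_real for d in dists.values()}
    if len(sizes) != 1:
        raise ValueError("replicate counts differ across conditions")
    groups = [np.asarray(dists[n].values, dtype=float) for n in names]
    groups = [g[np.isfinite(g)] for g in groups]
    report = {
        "measure": measures.pop(),
        "anova": _stats.one_way_anova(groups, names),
        "pairwise": {},
    }
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            report["pairwise"][(names[i], names[j])] = _stats.t_test_independent(
                groups[i], groups[j], pooled=True, names=(names[i], names[j]))
    return report
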