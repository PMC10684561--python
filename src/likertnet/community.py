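"""Meso-level community analysis.

Community structure is found by modularity maximization with the Louvain
algorithm: repeated sweeps of greedy single-node moves in a random node
order, followed by aggregation of communities into super-nodes, until
modularity stops improving.  Because Louvain is stochastic, the analysis
is repeated many times (default 1000) and summarized by a consensus
partition: runs are collected into a node x node agreement matrix (the
fraction of runs in which two nodes share a community), the matrix is
thresholded, and the thresholded agreement graph is re-clustered until
every pair of nodes is either always or never co-assigned.

Partitions are compared with the unadjusted Rand index - the fraction of
node pairs classified the same way (together in both or apart in both) -
with the adjusted-for-chance variant available as a secondary output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import adjusted_rand_score, rand_score

from . import stats as _stats

__all__ = [
    "Partition", "ConsensusLouvain", "louvain", "consensus_partition",
    "modularity", "rand_index", "adjusted_rand_index", "community_profile",
]


class ConsensusError(RuntimeError):
    """Consensus clustering failed to converge; carries diagnostics."""


@dataclass(frozen=True)
class Partition:
    """A hard assignment of node labels to communities (ids 1..k)."""

    labels: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict, compare=False)

    @classmethod
    def from_ids(cls, nodes, ids, **provenance) -> "Partition":
        """Build a partition from parallel node/id sequences, renumbering
        community ids to be contiguous from 1 in order of first appearance."""
        remap: dict = {}
        labels = {}
        for node, cid in zip(nodes, ids):
            if cid not in remap:
                remap[cid] = len(remap) + 1
            labels[node] = remap[cid]
        return cls(labels, dict(provenance))

    @property
    def nodes(self) -> list:
        return list(self.labels)

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def communities(self) -> dict:
        out: dict = {}
        for node, cid in self.labels.items():
            out.setdefault(cid, set()).add(node)
        return out

    def member_ids(self, nodes) -> np.ndarray:
        return np.array([self.labels[n] for n in nodes])

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, name="community")


# ---------------------------------------------------------------------------
# modularity and Louvain (dense-adjacency implementation)
# ---------------------------------------------------------------------------

def modularity(adj: np.ndarray, member: np.ndarray, gamma: float = 1.0) -> float:
    """Newman modularity Q of a labeling on a (possibly weighted) adjacency.

    Q = (1/2m) * sum_ij [A_ij - gamma * k_i k_j / (2m)] * delta(c_i, c_j),
    computed from per-community totals.  Diagonal entries of ``adj`` are
    treated as twice the self-loop weight (the aggregation convention).
    """
    adj = np.asarray(adj, dtype=float)
    two_m = adj.sum()
    if two_m <= 0:
        raise ValueError("modularity undefined for a graph with no edges")
    member = np.asarray(member)
    _, inv = np.unique(member, return_inverse=True)
    nc = inv.max() + 1
    M = np.zeros((len(member), nc))
    M[np.arange(len(member)), inv] = 1.0
    B = M.T @ adj @ M
    sigma_in = np.diag(B)                    # within weight, both directions
    sigma_tot = B.sum(axis=1)                # total degree per community
    return float(np.sum(sigma_in / two_m - gamma * (sigma_tot / two_m) ** 2))


def _louvain_sweep(adj, member, degrees, two_m, gamma, rng):
    """One pass of local moves; returns number of moves made."""
    n = len(member)
    moves = 0
    for i in rng.permutation(n):
        ci = member[i]
        ki = degrees[i]
        nc = member.max() + 1
        w = np.bincount(member, weights=adj[i], minlength=nc)
        w[ci] -= adj[i, i]  # links to own community excluding self
        sig = np.bincount(member, weights=degrees, minlength=nc)
        sig[ci] -= ki       # community totals with i removed
        # move criterion: argmax_c [ w_ic - gamma * k_i * sigma_tot_c / 2m ]
        score = w - gamma * ki * sig / two_m
        best = int(np.argmax(score))
        if score[best] > score[ci] + 1e-12 and best != ci:
            member[i] = best
            moves += 1
    return moves


def _louvain_labels(adj: np.ndarray, gamma: float, rng: np.random.Generator):
    """Full two-phase Louvain on a dense adjacency.

    Returns (membership array, list of modularity values after each
    aggregation phase).  The phase trace is non-decreasing by
    construction; it is exposed so tests can assert monotonicity.
    """
    n0 = adj.shape[0]
    node_member = np.arange(n0)
    cur_adj = np.asarray(adj, dtype=float).copy()
    phase_q: list[float] = []
    while True:
        n = cur_adj.shape[0]
        member = np.arange(n)
        degrees = cur_adj.sum(axis=1)
        two_m = cur_adj.sum()
        while _louvain_sweep(cur_adj, member, degrees, two_m, gamma, rng) > 0:
            pass
        _, inv = np.unique(member, return_inverse=True)
        node_member = inv[node_member]
        phase_q.append(modularity(adj, node_member, gamma))
        if inv.max() + 1 == n:  # no aggregation happened
            break
        nc = inv.max() + 1
        M = np.zeros((n, nc))
        M[np.arange(n), inv] = 1.0
        cur_adj = M.T @ cur_adj @ M
    return node_member, phase_q


def _as_adjacency(net, nodes=None):
    if isinstance(net, nx.Graph):
        nodelist = list(net.nodes) if nodes is None else list(nodes)
        if net.number_of_edges() == 0:
            raise ValueError("community detection requires at least one edge")
        return nx.to_numpy_array(net, nodelist=nodelist, weight="weight"), nodelist
    adj = np.asarray(net, dtype=float)
    if adj.sum() <= 0:
        raise ValueError("community detection requires at least one edge")
    nodelist = list(range(adj.shape[0])) if nodes is None else list(nodes)
    return adj, nodelist


def louvain(net, gamma: float = 1.0, seed=None) -> Partition:
    """A single stochastic Louvain run; the randomness is the node order."""
    adj, nodes = _as_adjacency(net)
    rng = np.random.default_rng(seed)
    member, phase_q = _louvain_labels(adj, gamma, rng)
    return Partition.from_ids(nodes, member, algorithm="louvain", gamma=gamma,
                              seed=seed, modularity=phase_q[-1])


class ConsensusLouvain(ClusterMixin, BaseEstimator):
    """Consensus community detection over repeated Louvain runs.

    Fits on a precomputed adjacency matrix (or networkx graph via the
    :func:`consensus_partition` wrapper).  Each round runs ``n_iter``
    seeded Louvain realizations, builds the co-assignment (agreement)
    matrix, zeroes entries below ``tau``, and re-clusters the resulting
    weighted agreement graph; rounds repeat until the agreement matrix is
    binary (all runs agree).  Nodes isolated by thresholding are kept
    attached through their single strongest agreement so that the final
    partition covers every node.

    Parameters
    ----------
    n_iter : int
        Louvain realizations per round (default 1000).
    tau : float
        Agreement threshold in [0, 1) (default 0.5).
    gamma : float
        Modularity resolution (default 1).
    max_rounds : int
        Rounds before declaring non-convergence (default 50).
    random_state : int or None
        Master seed for all realizations.

    Attributes
    ----------
    labels_ : ndarray of community ids (1..k) aligned with input rows.
    agreement_ : first-round agreement matrix.
    n_rounds_ : rounds used to converge.
    modularity_ : Q of the consensus labeling on the original adjacency.
    """

    def __init__(self, n_iter: int = 1000, tau: float = 0.5, gamma: float = 1.0,
                 max_rounds: int = 50, random_state=None):
        self.n_iter = n_iter
        self.tau = tau
        self.gamma = gamma
        self.max_rounds = max_rounds
        self.random_state = random_state

    def fit(self, X, y=None):
        adj = np.asarray(X, dtype=float)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("X must be a square adjacency matrix")
        if adj.sum() <= 0:
            raise ValueError("consensus clustering requires at least one edge")
        n = adj.shape[0]
        root = np.random.SeedSequence(self.random_state)
        cur = adj.copy()
        self.agreement_ = None
        for round_no in range(1, self.max_rounds + 1):
            seeds = root.spawn(1)[0].generate_state(self.n_iter)
            agree = np.zeros((n, n))
            first = None
            unanimous = True
            for s in seeds:
                member, _ = _louvain_labels(cur, self.gamma, np.random.default_rng(int(s)))
                agree += member[:, None] == member[None, :]
                if first is None:
                    first = member
                elif unanimous and not _same_partition(first, member):
                    unanimous = False
            agree /= self.n_iter
            if self.agreement_ is None:
                self.agreement_ = agree.copy()
            off = ~np.eye(n, dtype=bool)
            binary = np.all((agree[off] < 1e-9) | (agree[off] > 1 - 1e-9))
            if unanimous or binary:
                member = first if unanimous else _components_of(agree > 0.5)
                _, inv = np.unique(member, return_inverse=True)
                self.labels_ = inv + 1
                self.n_rounds_ = round_no
                self.modularity_ = modularity(adj, self.labels_, self.gamma)
                return self
            thr = np.where(agree >= self.tau, agree, 0.0)
            np.fill_diagonal(thr, 0.0)
            isolated = np.flatnonzero(thr.sum(axis=1) == 0)
            for v in isolated:
                row = agree[v].copy()
                row[v] = -1
                u = int(np.argmax(row))
                thr[v, u] = thr[u, v] = agree[v, u]
            cur = thr
        raise ConsensusError(
            f"consensus did not converge in {self.max_rounds} rounds "
            f"(n_iter={self.n_iter}, tau={self.tau}); the agreement matrix "
            "still has fractional entries")

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    return rand_score(a, b) == 1.0


def _components_of(mask: np.ndarray) -> np.ndarray:
    from scipy.sparse.csgraph import connected_components
    _, member = connected_components(mask, directed=False)
    return member


def consensus_partition(net, n_iter: int = 1000, tau: float = 0.5, gamma: float = 1.0,
                        seed=None, max_rounds: int = 50) -> Partition:
    """Consensus partition of a network; see :class:`ConsensusLouvain`."""
    adj, nodes = _as_adjacency(net)
    est = ConsensusLouvain(n_iter=n_iter, tau=tau, gamma=gamma,
                           max_rounds=max_rounds, random_state=seed).fit(adj)
    return Partition.from_ids(
        nodes, est.labels_, algorithm="consensus_louvain", n_iter=n_iter,
        tau=tau, gamma=gamma, seed=seed, rounds=est.n_rounds_,
        modularity=est.modularity_)


# ---------------------------------------------------------------------------
# partition comparison
# ---------------------------------------------------------------------------

def _aligned_ids(p1: Partition, p2: Partition):
    if set(p1.labels) != set(p2.labels):
        raise ValueError("partitions are over different node sets")
    nodes = sorted(p1.labels, key=str)
    return p1.member_ids(nodes), p2.member_ids(nodes)


def rand_index(p1: Partition, p2: Partition) -> float:
    """Unadjusted Rand index: the fraction of node pairs on which the two
    partitions agree (co-assigned in both, or separated in both)."""
    a, b = _aligned_ids(p1, p2)
    return float(rand_score(a, b))


def adjusted_rand_index(p1: Partition, p2: Partition) -> float:
    """Chance-corrected Rand index (secondary output)."""
    a, b = _aligned_ids(p1, p2)
    return float(adjusted_rand_score(a, b))


# ---------------------------------------------------------------------------
# community rating profiles
# ---------------------------------------------------------------------------

def community_profile(ratings_by_condition: dict, partition: Partition):
    """Average Likert rating per community per condition, with a
    community x condition factorial ANOVA on item-level means.

    Each observation is one item's mean rating within one condition; the
    reference partition (typically the consensus partition of the focal
    condition's network) supplies the community factor.

    Returns ``(profile, anova)``: a tidy DataFrame with one row per
    item x condition, and the dict of StatsReports from
    :func:`likertnet.stats.two_way_anova`.
    """
    comms = partition.communities()
    if any(len(m) == 0 for m in comms.values()):
        raise ValueError("partition contains an empty community")
    rows = []
    for cond, table in ratings_by_condition.items():
        frame = table.data if hasattr(table, "data") else table
        missing = set(partition.labels) - set(frame.columns)
        if missing:
            raise ValueError(f"items missing from condition {cond!r}: {sorted(missing)[:5]}")
        item_means = frame[list(partition.labels)].mean(axis=0)
        for item, m in item_means.items():
            rows.append({"item": item, "condition": cond,
                         "community": partition.labels[item], "mean_rating": float(m)})
    profile = pd.DataFrame(rows)
    anova = _stats.two_way_anova(profile, "mean_rating", "condition", "community")
    return profile, anova
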