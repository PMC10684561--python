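"""Triangulated Maximally Filtered Graph (TMFG).

The TMFG reduces a dense similarity matrix to a maximal planar subgraph
with exactly 3n - 6 edges.  Construction is greedy: a seed tetrahedron
(the 4-node clique with the largest total pairwise weight) is placed
first, then the remaining nodes are inserted one at a time.  Each
insertion is a T2 move: a node is placed inside one of the current
triangular faces, connected to that face's three vertices, and the face
is replaced by three new faces.  At every step the (node, face) pair
with the maximum gain - the sum of the three new edge weights - is
chosen.  The result is a planar clique tree of 4-cliques glued on
3-cliques; planarity is guaranteed structurally because every move
subdivides a triangular face.

Ties are broken deterministically: lower node index first, then lower
face creation order, and the lexicographically smallest seed clique.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["TMFGFilter", "tmfg_filter", "binarize_network", "tmfg_edge_list"]


@lru_cache(maxsize=4)
def _four_subsets(n: int) -> np.ndarray:
    """All 4-subsets of range(n) in lexicographic order, shape (C(n,4), 4)."""
    flat = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), 4)),
        dtype=np.int32,
    )
    return flat.reshape(-1, 4)


def _seed_clique(W: np.ndarray) -> np.ndarray:
    """The 4 nodes maximizing the sum of their 6 pairwise weights.

    Exhaustive over all 4-subsets; ties resolved to the lexicographically
    smallest subset (argmax returns the first maximum and subsets are
    generated in lexicographic order).
    """
    combos = _four_subsets(W.shape[0])
    a, b, c, d = combos[:, 0], combos[:, 1], combos[:, 2], combos[:, 3]
    totals = (W[a, b] + W[a, c] + W[a, d] + W[b, c] + W[b, d] + W[c, d])
    return combos[int(np.argmax(totals))]


def tmfg_edge_list(W: np.ndarray) -> list[tuple[int, int]]:
    """Run the TMFG construction on a symmetric weight matrix.

    Returns the 3n - 6 retained edges as (i, j) index pairs with i < j,
    in insertion order (seed clique edges first).
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if n < 4:
        raise ValueError(f"TMFG requires at least 4 nodes, got {n}")
    if not np.allclose(W, W.T, atol=1e-8):
        raise ValueError("weight matrix must be symmetric")
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)

    seed = _seed_clique(W)
    edges: list[tuple[int, int]] = [tuple(sorted(p)) for p in itertools.combinations(seed.tolist(), 2)]

    in_graph = np.zeros(n, dtype=bool)
    in_graph[seed] = True
    if n == 4:
        return edges

    # Active triangular faces, in creation order; gains[f, v] = sum of
    # weights from v to face f's three vertices.
    faces: list[tuple[int, int, int]] = [tuple(sorted(f)) for f in itertools.combinations(seed.tolist(), 3)]
    max_faces = 3 * n - 8  # faces ever created: 4 seed faces + 3 per insertion
    gains = np.full((max_faces, n), -np.inf)
    active = np.zeros(max_faces, dtype=bool)
    for fi, (a, b, c) in enumerate(faces):
        gains[fi] = W[a] + W[b] + W[c]
        active[fi] = True

    for _ in range(n - 4):
        cand = gains[: len(faces)].copy()
        cand[~active[: len(faces)]] = -np.inf
        cand[:, in_graph] = -np.inf
        best = cand.max()
        # tie-break: lowest node index, then lowest face creation order
        face_ids, node_ids = np.nonzero(cand == best)
        order = np.lexsort((face_ids, node_ids))
        fi, v = int(face_ids[order[0]]), int(node_ids[order[0]])

        a, b, c = faces[fi]
        edges.extend([tuple(sorted((v, a))), tuple(sorted((v, b))), tuple(sorted((v, c)))])
        in_graph[v] = True
        active[fi] = False
        for tri in ((a, b, v), (a, c, v), (b, c, v)):
            tri = tuple(sorted(tri))
            faces.append(tri)
            fj = len(faces) - 1
            gains[fj] = W[tri[0]] + W[tri[1]] + W[tri[2]]
            active[fj] = True

    return edges


class TMFGFilter(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: similarity matrix in, TMFG adjacency out.

    Parameters
    ----------
    binarize : bool
        If True (default), ``transform`` returns the filtered adjacency
        with all retained edges set to weight 1; otherwise retained edges
        keep their similarity weights.

    Attributes
    ----------
    edges_ : list of (i, j) index pairs retained by the filter.
    adjacency_ : the filtered (weighted) adjacency matrix.
    """

    def __init__(self, binarize: bool = True):
        self.binarize = binarize

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.edges_ = tmfg_edge_list(X)
        n = X.shape[0]
        A = np.zeros((n, n))
        for i, j in self.edges_:
            A[i, j] = A[j, i] = X[i, j]
        self.adjacency_ = A
        self.n_nodes_ = n
        return self

    def transform(self, X) -> np.ndarray:
        self.fit(X)
        if self.binarize:
            return (self.adjacency_ > 0).astype(float)
        return self.adjacency_.copy()


def tmfg_filter(sim, labels=None, condition=None) -> nx.Graph:
    """Filter a similarity matrix to its weighted TMFG as a networkx graph.

    ``sim`` may be a labeled DataFrame (labels taken from its index) or a
    plain array.  Node labels are preserved; graph attributes record
    provenance (condition, mode) when available on the input.
    """
    if isinstance(sim, pd.DataFrame):
        labels = list(sim.index) if labels is None else list(labels)
        condition = condition or sim.attrs.get("condition")
        mode = sim.attrs.get("mode")
        W = sim.to_numpy(dtype=float)
    else:
        W = np.asarray(sim, dtype=float)
        mode = None
        if labels is None:
            labels = list(range(W.shape[0]))
    edges = tmfg_edge_list(W)
    G = nx.Graph(condition=condition, mode=mode, filter="tmfg")
    G.add_nodes_from(labels)
    idx = {i: lab for i, lab in enumerate(labels)}
    for i, j in edges:
        G.add_edge(idx[i], idx[j], weight=float(W[i, j]))
    return G


def binarize_network(net: nx.Graph) -> nx.Graph:
    """Return a copy of the network with every edge weight set to 1.

    Idempotent; topology is untouched.
    """
    G = net.copy()
    for _, _, d in G.edges(data=True):
        d["weight"] = 1.0
    G.graph["binarized"] = True
    return G
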