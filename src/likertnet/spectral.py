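"""Spectral network comparison via Von Neumann entropy.

A graph is represented by a density matrix: the combinatorial Laplacian
L = D - A rescaled by c = 1 / sum(A) so that its trace is exactly 1.
Its eigenvalues then form a probability distribution, whose Shannon
entropy (base 2) is the Von Neumann graph entropy

    h = -sum_i lambda_i * log2(lambda_i).

Two graphs on the same node set are compared by the quantum
Jensen-Shannon divergence

    D_JS(rho || sigma) = h(mu) - [h(rho) + h(sigma)] / 2,  mu = (rho + sigma)/2,

whose square root is a distance bounded in [0, 1]: 0 for identical
structures, values toward 1 for increasingly dissimilar ones.  Note that
the mixture mu is formed on the density matrices themselves (and then
eigendecomposed), not on the spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["DensityMatrix", "rescaled_laplacian", "von_neumann_entropy",
           "jensen_shannon_distance", "distance_table"]

_EIG_TOL = 1e-10


@dataclass
class DensityMatrix:
    """Trace-one rescaled Laplacian with its eigenvalues and node order."""

    matrix: np.ndarray
    eigenvalues: np.ndarray
    nodes: tuple

    def entropy(self) -> float:
        return von_neumann_entropy(self)


def _clip_spectrum(lam: np.ndarray) -> np.ndarray:
    if lam.min() < -_EIG_TOL:
        raise FloatingPointError(
            f"density matrix has eigenvalue {lam.min():.3e} below -{_EIG_TOL}")
    return np.clip(lam, 0.0, None)


def _density_from_adjacency(A: np.ndarray, nodes) -> DensityMatrix:
    total = A.sum()  # sum over all entries = twice the total edge weight
    if total <= 0:
        raise ValueError("density matrix undefined: graph has no edges")
    L = (np.diag(A.sum(axis=1)) - A) / total
    lam = _clip_spectrum(np.linalg.eigvalsh(L))
    return DensityMatrix(L, lam, tuple(nodes))


def rescaled_laplacian(net, nodes=None) -> DensityMatrix:
    """Density matrix of a network: (D - A) / sum(A), trace exactly 1.

    Node order is the sorted node labels unless ``nodes`` is given.
    """
    if isinstance(net, nx.Graph):
        nodelist = sorted(net.nodes, key=str) if nodes is None else list(nodes)
        A = nx.to_numpy_array(net, nodelist=nodelist, weight="weight")
    else:
        A = np.asarray(net, dtype=float)
        nodelist = list(range(A.shape[0])) if nodes is None else list(nodes)
    return _density_from_adjacency(A, nodelist)


def von_neumann_entropy(dm) -> float:
    """Base-2 Shannon entropy of the density-matrix spectrum, in bits.

    Zero eigenvalues contribute 0 (the 0 * log 0 convention); the result
    lies in [0, log2(n)].
    """
    lam = dm.eigenvalues if isinstance(dm, DensityMatrix) else _clip_spectrum(np.asarray(dm, dtype=float))
    pos = lam[lam > 0]
    return float(-(pos * np.log2(pos)).sum())


def jensen_shannon_distance(net_a, net_b) -> float:
    """Spectral Jensen-Shannon distance between two aligned networks.

    Both networks must be over the same node labels; nodes are aligned
    by label (no silent reordering).  Returns sqrt(D_JS) in [0, 1].
    """
    if isinstance(net_a, nx.Graph) and isinstance(net_b, nx.Graph):
        if set(net_a.nodes) != set(net_b.nodes):
            raise ValueError("networks have different node sets")
        order = sorted(net_a.nodes, key=str)
        rho = rescaled_laplacian(net_a, nodes=order)
        sigma = rescaled_laplacian(net_b, nodes=order)
    else:
        rho = net_a if isinstance(net_a, DensityMatrix) else rescaled_laplacian(net_a)
        sigma = net_b if isinstance(net_b, DensityMatrix) else rescaled_laplacian(net_b)
        if rho.nodes != sigma.nodes:
            raise ValueError("density matrices have different node orders")
    mu = (rho.matrix + sigma.matrix) / 2.0
    h_mu = von_neumann_entropy(_clip_spectrum(np.linalg.eigvalsh(mu)))
    djs = h_mu - 0.5 * (von_neumann_entropy(rho) + von_neumann_entropy(sigma))
    return float(np.sqrt(max(djs, 0.0)))


def distance_table(networks: dict) -> pd.DataFrame:
    """Pairwise Jensen-Shannon distances between named networks."""
    names = list(networks)
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = jensen_shannon_distance(networks[a], networks[b])
            out.loc[a, b] = out.loc[b, a] = d
    return out
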