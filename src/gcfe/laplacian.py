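"""Matrix representations of a visibility graph.

Four dense N x N matrices are built per graph: the weighted adjacency A
(edge weights), the unweighted adjacency S (0/1), the degree matrix D
(diagonal of unweighted degrees), and the modified weighted Laplacian

    L = D - A.

L is "modified" because D holds UNWEIGHTED degrees while A is weighted.
For epochs normalized to [0, 1] every weight is at most 1 + epsilon, so
each diagonal entry D_ii dominates its row's absolute off-diagonal sum up
to an N*epsilon inflation, and L is (near-)diagonally dominant, hence its
spectrum is confined to tight Gershgorin disks. Dense storage is the
deliberate choice: N is an epoch length (tens to ~1024) and the feature
extraction needs only row reductions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .visibility import VisibilityGraph

__all__ = [
    "GraphMatrices",
    "weighted_adjacency",
    "unweighted_adjacency",
    "degree_matrix",
    "mwl_matrix",
    "graph_matrices",
]


@dataclass(frozen=True)
class GraphMatrices:
    A: np.ndarray  # weighted adjacency
    S: np.ndarray  # unweighted adjacency
    D: np.ndarray  # degree (diagonal, unweighted)
    L: np.ndarray  # modified weighted Laplacian D - A


def weighted_adjacency(g: VisibilityGraph) -> np.ndarray:
    n = g.n_nodes
    a = np.zeros((n, n))
    a[g.i - 1, g.j - 1] = g.w
    a[g.j - 1, g.i - 1] = g.w
    return a


def unweighted_adjacency(g: VisibilityGraph) -> np.ndarray:
    n = g.n_nodes
    s = np.zeros((n, n))
    s[g.i - 1, g.j - 1] = 1.0
    s[g.j - 1, g.i - 1] = 1.0
    return s


def degree_matrix(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("adjacency must be square")
    return np.diag(s.sum(axis=1))


def mwl_matrix(d: np.ndarray, a: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    a = np.asarray(a, dtype=float)
    if d.shape != a.shape:
        raise ValueError("degree and adjacency shapes differ")
    return d - a


def graph_matrices(g: VisibilityGraph) -> GraphMatrices:
    """Assemble A, S, D and L = D - A for one graph."""
    a = weighted_adjacency(g)
    s = unweighted_adjacency(g)
    d = degree_matrix(s)
    return GraphMatrices(A=a, S=s, D=d, L=mwl_matrix(d, a))


def save_matrix(m: np.ndarray, path) -> None:
    """Write a matrix as delimited text at full (round-trippable) precision."""
    np.savetxt(path, m, fmt="%.17g", delimiter="\t")


def load_matrix(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))
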