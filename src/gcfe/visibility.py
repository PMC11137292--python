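"""Weighted visibility graphs of epochs.

Two samples ``x < y`` of an epoch see each other when every intermediate
sample lies strictly below the straight line joining ``(x, q[x])`` and
``(y, q[y])`` — the natural-visibility criterion. Each visible pair gets
the weight

    w(i, j) = |q[i] - q[j]| / |i - j| + 1e-8

with time measured in sample indices, i.e. the absolute slope between the
two points plus a small epsilon that keeps flat segments at a nonzero
weight. The dual-perspective graph (WDPVG) is the union of the visibility
graph of the signal and that of its reflection about the amplitude
midline, capturing visibility from both above and below the curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import Epoch

__all__ = [
    "EPSILON",
    "VisibilityGraph",
    "is_visible",
    "edge_weight",
    "build_wvg",
    "reflect_epoch",
    "build_wdpvg",
]

#: additive floor on every edge weight; guarantees strictly positive weights
EPSILON = 1e-8


@dataclass(frozen=True)
class VisibilityGraph:
    """Weighted undirected graph over nodes 1..N in time order.

    Edges are stored as parallel arrays ``(i, j, w)`` with ``i < j``
    (1-based node indices). Adjacent samples are always mutually visible,
    so for N >= 2 the graph is connected.
    """

    n_nodes: int
    i: np.ndarray
    j: np.ndarray
    w: np.ndarray

    @property
    def n_edges(self) -> int:
        return self.i.size

    def edge_set(self) -> set[tuple[int, int]]:
        return set(zip(self.i.tolist(), self.j.tolist()))

    def to_edgelist(self, path) -> None:
        """Write a three-column (i, j, w) delimited edge list."""
        np.savetxt(
            path,
            np.column_stack([self.i, self.j, self.w]),
            fmt=("%d", "%d", "%.17g"),
            delimiter="\t",
        )


def _check_index(n: int, k: int, name: str) -> None:
    if not 1 <= k <= n:
        raise IndexError(f"{name}={k} out of range for epoch of length {n}")


def is_visible(q: np.ndarray, x: int, y: int) -> bool:
    """Natural-visibility test for 1-based indices ``x < y``.

    True iff every intermediate sample is strictly below the chord from
    ``(x, q[x])`` to ``(y, q[y])``; vacuously true for adjacent samples.
    A collinear intermediate point blocks visibility.
    """
    q = np.asarray(q, dtype=float)
    n = q.size
    _check_index(n, x, "x")
    _check_index(n, y, "y")
    if not x < y:
        raise ValueError("require x < y")
    if y == x + 1:
        return True
    z = np.arange(x + 1, y)
    chord = q[y - 1] + (q[x - 1] - q[y - 1]) * (y - z) / (y - x)
    return bool(np.all(q[z - 1] < chord))


def edge_weight(q: np.ndarray, i: int, j: int) -> float:
    """Absolute slope between samples i and j (1-based) plus the epsilon."""
    q = np.asarray(q, dtype=float)
    _check_index(q.size, i, "i")
    _check_index(q.size, j, "j")
    if i == j:
        raise ValueError("edge weight undefined for i == j")
    return abs(q[i - 1] - q[j - 1]) / abs(i - j) + EPSILON


def _visible_pairs(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All visible pairs (i, j), i < j, in O(N^2).

    For a fixed left endpoint x, node y is visible iff the slope of the
    chord (x, y) strictly exceeds the running maximum of the slopes from x
    to every intermediate sample — a prefix-max scan per row.
    """
    n = q.size
    ii: list[np.ndarray] = []
    jj: list[np.ndarray] = []
    dt = np.arange(1, n)
    for x in range(n - 1):
        slopes = (q[x + 1 :] - q[x]) / dt[: n - 1 - x]
        # prefix max over intermediates, exclusive: blocker[k] = max slope
        # among samples strictly between x and x+1+k
        blocker = np.empty_like(slopes)
        blocker[0] = -np.inf
        if slopes.size > 1:
            np.maximum.accumulate(slopes[:-1], out=blocker[1:])
        vis = slopes > blocker
        ys = np.flatnonzero(vis) + x + 1
        ii.append(np.full(ys.size, x))
        jj.append(ys)
    return np.concatenate(ii), np.concatenate(jj)


def build_wvg(epoch: Epoch) -> VisibilityGraph:
    """Weighted visibility graph of an epoch."""
    q = epoch.q
    n = q.size
    i0, j0 = _visible_pairs(q)
    w = np.abs(q[i0] - q[j0]) / (j0 - i0) + EPSILON
    return VisibilityGraph(n_nodes=n, i=i0 + 1, j=j0 + 1, w=w)


def reflect_epoch(epoch: Epoch) -> Epoch:
    """Mirror the epoch about its amplitude midline: q' = max+min-q.

    An involution that keeps q' inside [min(q), max(q)], hence inside the
    normalized range. A constant epoch is a fixed point.
    """
    q = epoch.q
    return Epoch(q=(q.max() + q.min()) - q, index=epoch.index, label=epoch.label)


def _negate_epoch(epoch: Epoch) -> np.ndarray:
    return -epoch.q


def build_wdpvg(epoch: Epoch, reflection: str = "midline") -> VisibilityGraph:
    """Dual-perspective graph: union of the WVG and the reflected-signal WVG.

    An edge found in both graphs keeps its single weight — |q[i]-q[j]| is
    reflection-invariant, so the two candidate weights coincide and the
    union stays a simple graph. ``reflection`` selects the operator:
    ``"midline"`` mirrors about (max+min)/2, ``"negate"`` flips the sign;
    both are affine, so the resulting edge sets are identical.
    """
    if reflection == "midline":
        q_ref = (epoch.q.max() + epoch.q.min()) - epoch.q
    elif reflection == "negate":
        q_ref = _negate_epoch(epoch)
    else:
        raise ValueError(f"unknown reflection {reflection!r}")

    q = epoch.q
    n = q.size
    i0, j0 = _visible_pairs(q)
    i1, j1 = _visible_pairs(q_ref)
    keys = set(zip(i0.tolist(), j0.tolist())) | set(zip(i1.tolist(), j1.tolist()))
    ii = np.array(sorted(keys))
    i0, j0 = ii[:, 0], ii[:, 1]
    w = np.abs(q[i0] - q[j0]) / (j0 - i0) + EPSILON
    return VisibilityGraph(n_nodes=n, i=i0 + 1, j=j0 + 1, w=w)


def build_graph(epoch: Epoch, kind: str = "wvg", reflection: str = "midline") -> VisibilityGraph:
    """Dispatch on graph kind: ``"wvg"`` or ``"wdpvg"``."""
    if kind == "wvg":
        return build_wvg(epoch)
    if kind == "wdpvg":
        return build_wdpvg(epoch, reflection=reflection)
    raise ValueError(f"unknown graph kind {kind!r}")
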