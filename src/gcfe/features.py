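"""Gershgorin-circle feature extraction (GCFE).

The Gershgorin circle theorem places every eigenvalue of a square matrix
inside at least one disk centered at a diagonal entry c_i = L_ii with
radius r_i equal to that row's absolute off-diagonal sum. GCFE uses the
disks themselves — not the eigenvalues — as the feature representation of
an epoch: the modified weighted Laplacian of the epoch's visibility graph
is reduced to the length-2N vector [r_1..r_N, c_1..c_N]. The radii are
row sums of edge weights (local slope energy around each sample); the
centers are unweighted node degrees (how far each sample can see). Both
are O(N^2) row reductions, with no eigendecomposition anywhere.

Features are emitted at full floating precision; three-decimal values in
worked examples are display rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .laplacian import graph_matrices
from .preprocess import Epoch
from .visibility import build_graph

__all__ = [
    "GCFeatures",
    "gershgorin_radii",
    "gershgorin_centers",
    "assemble_feature_vector",
    "extract_features",
    "extract_features_batch",
]


@dataclass(frozen=True)
class GCFeatures:
    """Paired Gershgorin radii and centers of one epoch's mWL matrix."""

    radii: np.ndarray
    centers: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        """Length-2N feature vector: radii first, then centers."""
        return assemble_feature_vector(self.radii, self.centers)


def _check_square(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    return m


def gershgorin_radii(L: np.ndarray) -> np.ndarray:
    """r_i = sum_{j != i} |L_ij| — absolute off-diagonal row sums."""
    L = _check_square(L)
    return np.abs(L).sum(axis=1) - np.abs(np.diag(L))


def gershgorin_centers(L: np.ndarray) -> np.ndarray:
    """c_i = L_ii — the diagonal."""
    return np.diag(_check_square(L)).copy()


def assemble_feature_vector(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    c = np.asarray(c, dtype=float)
    if r.shape != c.shape:
        raise ValueError("radii and centers lengths differ")
    return np.concatenate([r, c])


def extract_features(epoch: Epoch, graph_kind: str = "wvg") -> GCFeatures:
    """Epoch -> visibility graph -> mWL -> Gershgorin disks.

    Deterministic: identical epochs yield bit-identical features.
    """
    mats = graph_matrices(build_graph(epoch, kind=graph_kind))
    return GCFeatures(
        radii=gershgorin_radii(mats.L), centers=gershgorin_centers(mats.L)
    )


def extract_features_batch(
    epochs: list[Epoch], graph_kind: str = "wvg", n: int | None = None
) -> pd.DataFrame:
    """Feature table: one row per epoch, columns r1..rN, c1..cN [, label].

    All epochs must share the same length. An empty collection is allowed
    only when ``n`` declares the epoch length, and yields an empty table
    with the right columns.
    """
    if not epochs:
        if n is None:
            raise ValueError("empty epoch collection without declared length")
        cols = [f"r{i+1}" for i in range(n)] + [f"c{i+1}" for i in range(n)]
        return pd.DataFrame(columns=cols)
    n = len(epochs[0])
    if any(len(e) != n for e in epochs):
        raise ValueError("epochs have mixed lengths")
    rows = np.stack([extract_features(e, graph_kind).vector for e in epochs])
    cols = [f"r{i+1}" for i in range(n)] + [f"c{i+1}" for i in range(n)]
    df = pd.DataFrame(rows, columns=cols)
    if any(e.label is not None for e in epochs):
        df["label"] = [e.label for e in epochs]
    return df
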