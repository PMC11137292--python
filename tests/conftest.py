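"""Shared fixtures and the brute-force visibility oracle.

The oracle deliberately re-derives visibility the slow way — checking the
chord inequality for every pair against every intermediate sample — so it
shares no code path with the package's O(N^2) scan.
"""

import numpy as np
import pytest

from gcfe import EPSILON, Epoch

#: the five-sample series used in the worked example throughout
Q_EXAMPLE = [0.6, 0.4, 0.1, 0.5, 0.7]


def brute_force_edges(q) -> set[tuple[int, int]]:
    """All visible pairs (1-based, i<j) by direct O(N^3) enumeration."""
    q = np.asarray(q, dtype=float)
    n = q.size
    edges = set()
    for x in range(n):
        for y in range(x + 1, n):
            ok = True
            for z in range(x + 1, y):
                chord = q[y] + (q[x] - q[y]) * (y - z) / (y - x)
                if not q[z] < chord:
                    ok = False
                    break
            if ok:
                edges.add((x + 1, y + 1))
    return edges


def brute_force_weights(q, edges) -> dict[tuple[int, int], float]:
    q = np.asarray(q, dtype=float)
    return {(i, j): abs(q[i - 1] - q[j - 1]) / (j - i) + EPSILON for i, j in edges}


@pytest.fixture
def example_epoch() -> Epoch:
    return Epoch(q=Q_EXAMPLE)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_epoch(rng: np.random.Generator, n: int) -> Epoch:
    return Epoch(q=rng.random(n))
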