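import itertools

import numpy as np
import pytest


def graph_from_edges(n, edges, weight=1.0):
    A = np.zeros((n, n))
    for e in edges:
        i, j = e[:2]
        w = e[2] if len(e) > 2 else weight
        A[i, j] = A[j, i] = w
    return A


@pytest.fixture
def two_triangles():
    """Two disjoint unit-weight triangles on 6 nodes."""
    return graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


@pytest.fixture
def barbell():
    """Two unit-weight K5s joined by the single edge (4, 5)."""
    A = np.zeros((10, 10))
    A[:5, :5] = 1.0
    A[5:, 5:] = 1.0
    np.fill_diagonal(A, 0.0)
    A[4, 5] = A[5, 4] = 1.0
    return A


@pytest.fixture
def k4():
    return np.ones((4, 4)) - np.eye(4)


def set_partitions(items):
    """All partitions of a collection (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1 :]
        yield [[first]] + smaller


def best_partition_exhaustive(A, gamma=1.0):
    """Global max-Q partition by enumerating all partitions (n <= ~8)."""
    from bcnet.community import modularity_q

    n = len(A)
    best_q, best_assign = -np.inf, None
    for part in set_partitions(range(n)):
        assign = np.empty(n, dtype=int)
        for label, block in enumerate(part):
            assign[block] = label
        q = modularity_q(A, assign, gamma)
        if q > best_q:
            best_q, best_assign = q, assign
    return best_q, best_assign


def random_weighted_graph(n, rng, density=0.5, max_w=5):
    """Random symmetric integer-weight graph with zero diagonal."""
    A = rng.integers(1, max_w + 1, size=(n, n)) * (rng.random((n, n)) < density)
    A = np.triu(A, 1).astype(float)
    return A + A.T


@pytest.fixture
def fast_cohort_spec():
    """Small, quick synthetic-cohort spec for pipeline tests."""
    from bcnet.synthetic import SyntheticCohortSpec

    return SyntheticCohortSpec(n_pwa=6, n_controls=6, n_pnt=5, bc_n_opt=6, seed=11)
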