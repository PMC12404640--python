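"""Hierarchical boundary-controllability (BC) ranking of network nodes.

A *boundary* node has at least one positive-weight edge to a node in a
different community.  BC ranks every node of a weighted network by its
position in a hierarchy of boundary sets:

1. a consensus partition of the full network is computed at a fixed
   resolution gamma (ensemble of seeded optimizer runs + agreement-matrix
   consensus);
2. level-0 boundary nodes are those straddling the top-level communities;
3. each community's induced subgraph is re-partitioned at the same gamma;
   if it splits, its internal boundary nodes (not already classified at a
   shallower level) form the next level, and recursion continues inside the
   sub-communities until a subgraph no longer splits or has fewer than
   ``min_recurse`` nodes;
4. ranks are assigned top-down: level-0 nodes take the top |B0| ranks,
   level-1 the next block, and so on; nodes never classified as boundary
   (the terminal interior set) take the lowest ranks.

Within a level the ordering is, by default, the magnitude of each node's
loading in the leading eigenvector of that level's boundary coupling
matrix — the adjacency restricted to cross-community edges — so nodes that
mediate more of the inter-community weight rank higher.  Only the integer
ranks (1..N, higher = stronger boundary controller) are meant to be
compared across subjects; the raw eigenvector scalars are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .community import (
    Partition,
    _as_weight_matrix,
    consensus_partition,
    louvain_partition,
    subseed,
)

__all__ = ["BCRanking", "boundary_nodes", "bc_rank", "node_strength"]

#: subgraphs smaller than this are not re-partitioned
MIN_RECURSE = 4


def node_strength(weights, node: int | None = None):
    """Sum of edge weights incident to a node (row sum); all nodes if None."""
    A = _as_weight_matrix(weights)
    k = A.sum(axis=1)
    if node is None:
        return k
    if not 0 <= node < len(A):
        raise IndexError(f"node {node} out of range for {len(A)} nodes")
    return float(k[node])


def boundary_nodes(weights, assignment) -> set[int]:
    """Nodes with at least one positive-weight edge into another community."""
    A = _as_weight_matrix(weights)
    c = np.asarray(assignment)
    if len(c) != len(A):
        raise ValueError("assignment length does not match matrix size")
    cross = (A > 0) & (c[:, None] != c[None, :])
    return set(np.flatnonzero(cross.any(axis=1)).tolist())


@dataclass
class BCRanking:
    """Boundary-controllability ranks plus the hierarchy that produced them.

    ``rank[i]`` is an integer in 1..N; higher means stronger boundary
    controller.  ``boundary_levels[d]`` is the set of nodes first
    classified as boundary at hierarchy depth ``d``; ``interior`` holds the
    nodes never classified as boundary.
    """

    rank: np.ndarray
    boundary_levels: list[set[int]]
    interior: set[int]
    gamma_used: float
    partition: Partition = field(repr=False, default=None)

    def __post_init__(self):
        n = len(self.rank)
        if sorted(self.rank.tolist()) != list(range(1, n + 1)):
            raise ValueError("ranks must be a permutation of 1..N")
        seen: set[int] = set()
        for level in self.boundary_levels:
            if level & seen:
                raise ValueError("node classified at more than one boundary level")
            seen |= level
        if seen & self.interior or (seen | self.interior) != set(range(n)):
            raise ValueError("boundary levels + interior must partition the nodes")

    def __len__(self) -> int:
        return len(self.rank)


def _coupling_loadings(A: np.ndarray, c: np.ndarray) -> np.ndarray:
    """|loading| of each node in the leading eigenvector of the coupling matrix."""
    C = np.where(c[:, None] != c[None, :], A, 0.0)
    if C.sum() == 0:
        return np.zeros(len(A))
    vals, vecs = np.linalg.eigh(C)
    return np.abs(vecs[:, int(np.argmax(vals))])


def _cross_strength(A: np.ndarray, c: np.ndarray) -> np.ndarray:
    C = np.where(c[:, None] != c[None, :], A, 0.0)
    return C.sum(axis=1)


def _consensus_at(A, gamma, n_opt, seed_seq_key, master_seed):
    ens = [
        louvain_partition(
            A, gamma=gamma, seed=np.random.default_rng(subseed(master_seed, *seed_seq_key, r))
        )
        for r in range(n_opt)
    ]
    return consensus_partition(ens, seed=int(subseed(master_seed, *seed_seq_key, 9999).generate_state(1)[0] % 2**31))


def bc_rank(
    weights,
    gamma: float,
    n_opt: int = 100,
    seed: int = 0,
    within_block_order: str = "eigenvector",
    min_recurse: int = MIN_RECURSE,
) -> BCRanking:
    """Hierarchical boundary-controllability ranking of every node.

    Parameters
    ----------
    weights : array-like
        Symmetric nonnegative adjacency matrix.
    gamma : float
        Resolution used for every (re-)partitioning step, normally the
        subject's stability-selected value.
    n_opt : int
        Ensemble size for each consensus partition.
    seed : int
        Master seed; all ensemble sub-seeds derive from it.
    within_block_order : {"eigenvector", "cross_strength"}
        Ordering rule inside a rank block: leading-eigenvector loading of
        the level's coupling matrix, or total cross-community strength.
    """
    A = _as_weight_matrix(weights)
    n = len(A)
    if within_block_order not in ("eigenvector", "cross_strength"):
        raise ValueError(f"unknown within_block_order: {within_block_order!r}")

    top = _consensus_at(A, gamma, n_opt, (0,), seed)
    classified: set[int] = set()
    levels: list[set[int]] = []
    ordered_blocks: list[list[int]] = []

    # frontier: (global node indices, assignment restricted to them)
    frontier: list[tuple[np.ndarray, np.ndarray]] = [
        (np.arange(n), np.asarray(top.assignment))
    ]
    depth = 0
    while frontier:
        scored: list[tuple[float, int]] = []  # (-score, global index)
        level_nodes: set[int] = set()
        next_frontier: list[tuple[np.ndarray, np.ndarray]] = []
        for branch_id, (idx, assign) in enumerate(frontier):
            sub = A[np.ix_(idx, idx)]
            bnd_local = boundary_nodes(sub, assign)
            new_global = {int(idx[i]) for i in bnd_local} - classified
            if new_global:
                if within_block_order == "eigenvector":
                    scores = _coupling_loadings(sub, assign)
                else:
                    scores = _cross_strength(sub, assign)
                for i in bnd_local:
                    g = int(idx[i])
                    if g in new_global:
                        scored.append((-float(scores[i]), g))
                level_nodes |= new_global
            # recurse into each community of this branch
            for comm in np.unique(assign):
                members = idx[assign == comm]
                if len(members) < min_recurse or len(members) == len(idx):
                    continue
                subsub = A[np.ix_(members, members)]
                if subsub.sum() <= 0:
                    continue
                part = _consensus_at(
                    subsub, gamma, n_opt, (depth + 1, branch_id, int(comm)), seed
                )
                if part.n_communities > 1:
                    next_frontier.append((members, np.asarray(part.assignment)))
        if level_nodes:
            scored.sort()  # descending score, ties by ascending node index
            ordered_blocks.append([g for _, g in scored])
            levels.append(level_nodes)
            classified |= level_nodes
        frontier = next_frontier
        depth += 1

    interior = set(range(n)) - classified
    strengths = A.sum(axis=1)
    interior_order = sorted(interior, key=lambda i: (-strengths[i], i))

    rank = np.empty(n, dtype=np.int64)
    next_rank = n
    for block in ordered_blocks + [interior_order]:
        for g in block:
            rank[g] = next_rank
            next_rank -= 1

    return BCRanking(
        rank=rank,
        boundary_levels=levels,
        interior=interior,
        gamma_used=float(gamma),
        partition=top,
    )
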