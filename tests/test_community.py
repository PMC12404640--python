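import numpy as np
import pytest

from bcnet.community import (
    canonicalize,
    consensus_partition,
    default_gamma_grid,
    gamma_sweep,
    louvain_partition,
    mean_pairwise_zrand,
    modularity_q,
    zrand,
    zrand_null_moments,
)
from conftest import best_partition_exhaustive, graph_from_edges, random_weighted_graph


class TestModularity:
    def test_hand_values_two_triangles(self, two_triangles):
        assert modularity_q(two_triangles, [0, 0, 0, 1, 1, 1], 1.0) == pytest.approx(0.5)
        assert modularity_q(two_triangles, [0] * 6, 1.0) == pytest.approx(0.0)
        assert modularity_q(two_triangles, range(6), 1.0) == pytest.approx(-1 / 6)

    def test_one_community_is_zero_at_gamma_one(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            A = random_weighted_graph(8, rng)
            assert modularity_q(A, [0] * 8, 1.0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_label_and_node_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        A = random_weighted_graph(9, rng)
        assign = rng.integers(0, 3, size=9)
        q = modularity_q(A, assign, 1.3)
        # permute community labels
        relab = rng.permutation(3)[assign]
        assert modularity_q(A, relab, 1.3) == pytest.approx(q, abs=1e-12)
        # permute node order consistently
        perm = rng.permutation(9)
        assert modularity_q(A[np.ix_(perm, perm)], assign[perm], 1.3) == pytest.approx(
            q, abs=1e-12
        )

    def test_gamma_derivative_matches_closed_form(self):
        rng = np.random.default_rng(3)
        A = random_weighted_graph(10, rng)
        assign = rng.integers(0, 3, size=10)
        m2 = A.sum()
        k_c = np.array([A.sum(1)[assign == c].sum() for c in range(3)])
        expected = -(k_c**2).sum() / m2**2  # dQ/dgamma for a fixed partition
        h = 1e-6
        num = (modularity_q(A, assign, 1.0 + h) - modularity_q(A, assign, 1.0 - h)) / (2 * h)
        assert num == pytest.approx(expected, rel=1e-5)
        assert expected <= 0

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError, match="total weight"):
            modularity_q(np.zeros((4, 4)), [0, 0, 1, 1])


class TestLouvain:
    def test_recovers_two_triangles(self, two_triangles):
        for seed in range(5):
            p = louvain_partition(two_triangles, 1.0, seed=seed)
            assert p.q == pytest.approx(0.5)
            np.testing.assert_array_equal(p.assignment, [0, 0, 0, 1, 1, 1])

    def test_k4_single_community(self, k4):
        p = louvain_partition(k4, 1.0, seed=0)
        assert p.n_communities == 1
        assert p.q == pytest.approx(0.0, abs=1e-12)

    def test_best_of_runs_matches_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = int(rng.integers(4, 8))
            A = random_weighted_graph(n, rng, density=0.7)
            if A.sum() == 0:
                continue
            q_star, _ = best_partition_exhaustive(A, 1.0)
            q_best = max(
                louvain_partition(A, 1.0, seed=s).q for s in range(50)
            )
            assert q_best == pytest.approx(q_star, abs=1e-12)

    def test_final_q_dominates_trivial_partitions(self):
        rng = np.random.default_rng(11)
        for seed in range(5):
            A = random_weighted_graph(12, rng, density=0.4)
            if A.sum() == 0:
                continue
            p = louvain_partition(A, 1.0, seed=seed)
            assert p.q >= modularity_q(A, [0] * 12, 1.0) - 1e-12
            assert p.q >= modularity_q(A, range(12), 1.0) - 1e-12

    def test_node_permutation_equivariance_on_unique_optimum(self, two_triangles):
        rng = np.random.default_rng(5)
        base = louvain_partition(two_triangles, 1.0, seed=0).assignment
        for seed in range(5):
            perm = rng.permutation(6)
            Ap = two_triangles[np.ix_(perm, perm)]
            pp = louvain_partition(Ap, 1.0, seed=seed).assignment
            # communities must map through the permutation
            np.testing.assert_array_equal(
                canonicalize(pp), canonicalize(base[perm])
            )

    def test_low_gamma_connected_graph_single_community(self):
        rng = np.random.default_rng(13)
        A = random_weighted_graph(10, rng, density=0.8)
        p = louvain_partition(A, 0.01, seed=0)
        assert p.n_communities == 1

    def test_invalid_inputs(self, k4):
        with pytest.raises(ValueError):
            louvain_partition(k4, gamma=0.0)
        with pytest.raises(ValueError):
            louvain_partition(np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestZRand:
    def test_self_similarity_positive(self):
        p = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert zrand(p, p) > 0

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            p1 = rng.integers(0, 3, size=12)
            p2 = rng.integers(0, 4, size=12)
            try:
                assert zrand(p1, p2) == pytest.approx(zrand(p2, p1))
            except ValueError:
                continue  # degenerate draw

    def test_degenerate_error_and_sentinel(self):
        p = np.array([0, 0, 1, 1])
        singles = np.arange(4)
        with pytest.raises(ValueError, match="degenerate"):
            zrand(p, singles)
        assert np.isnan(zrand(p, singles, degenerate="nan"))
        assert np.isnan(zrand(np.zeros(4, int), p, degenerate="nan"))

    def test_label_invariance(self):
        p1 = np.array([0, 0, 1, 1, 2, 2])
        p2 = np.array([2, 2, 0, 0, 1, 1])  # same partition, different labels
        q = np.array([0, 1, 1, 0, 2, 2])
        assert zrand(p1, q) == pytest.approx(zrand(p2, q))

    def test_permutation_null_moments(self):
        """Analytic mean/SD of the pair count match a Monte-Carlo null."""
        rng = np.random.default_rng(42)
        p1 = np.array([0] * 5 + [1] * 5)
        p2 = np.array([0, 0, 0, 0, 1, 1, 1, 2, 2, 2])
        mu, sd = zrand_null_moments(p1, p2)
        n_draws = 20000
        ws = np.empty(n_draws)
        for t in range(n_draws):
            perm = rng.permutation(10)
            b = p2[perm]
            key = p1 * 3 + b
            nij = np.bincount(key, minlength=6)
            ws[t] = (nij * (nij - 1) // 2).sum()
        assert abs(ws.mean() - mu) <= 3 * ws.std() / np.sqrt(n_draws)
        assert sd == pytest.approx(ws.std(), rel=0.03)


class TestGammaSweep:
    def test_default_grid(self):
        grid = default_gamma_grid()
        assert len(grid) == 31
        assert grid[0] == 1.0 and grid[-1] == 4.0
        assert np.allclose(np.diff(grid), 0.1)

    def test_n_opt_below_two_errors(self, two_triangles):
        with pytest.raises(ValueError, match="n_opt"):
            gamma_sweep(two_triangles, n_opt=1)

    def test_planted_two_block_peak_stability(self):
        rng = np.random.default_rng(0)
        n = 16
        A = np.where(
            (np.arange(n)[:, None] < 8) == (np.arange(n)[None, :] < 8), 10.0, 1.0
        ) * (1 + 0.01 * rng.random((n, n)))
        A = np.triu(A, 1)
        A = A + A.T
        res = gamma_sweep(
            A, gamma_grid=[1.0, 1.5, 2.0, 2.5, 3.0], n_opt=8, seed=4,
            zrand_degenerate="nan",
        )
        sel = res.selected_partitions
        counts = [p.n_communities for p in sel]
        assert max(set(counts), key=counts.count) == 2
        sel_mean = res.mean_zrand[res.selected_index]
        finite = res.mean_zrand[~np.isnan(res.mean_zrand)]
        assert all(sel_mean >= m for m in finite)

    def test_deterministic_given_seed(self, two_triangles):
        r1 = gamma_sweep(two_triangles, gamma_grid=[1.0, 2.0], n_opt=4, seed=9)
        r2 = gamma_sweep(two_triangles, gamma_grid=[1.0, 2.0], n_opt=4, seed=9)
        np.testing.assert_array_equal(r1.mean_zrand, r2.mean_zrand)
        assert r1.selected_gamma == r2.selected_gamma


class TestConsensus:
    def test_unanimous_input_returned(self):
        p = np.array([0, 0, 1, 1, 2, 2])
        parts = [p.copy() for _ in range(100)]
        out = consensus_partition(parts, seed=0)
        np.testing.assert_array_equal(out.assignment, canonicalize(p))

    def test_single_partition_unchanged(self):
        p = np.array([1, 1, 0, 0])
        out = consensus_partition([p], seed=0)
        np.testing.assert_array_equal(out.assignment, canonicalize(p))

    def test_mixed_lengths_error(self):
        with pytest.raises(ValueError, match="length"):
            consensus_partition([np.zeros(4, int), np.zeros(5, int)])

    def test_recovers_planted_partition_under_label_noise(self):
        """5% flipped labels in a 100-partition ensemble: planted structure
        is recovered (up to relabeling) in at least 95% of seeded trials."""
        planted = np.repeat([0, 1, 2], [7, 7, 6])  # 20 nodes, 3 communities
        n_trials, hits = 50, 0
        for trial in range(n_trials):
            rng = np.random.default_rng(1000 + trial)
            ensemble = []
            for _ in range(100):
                p = planted.copy()
                flip = rng.random(20) < 0.05
                p[flip] = rng.integers(0, 3, size=flip.sum())
                ensemble.append(p)
            out = consensus_partition(ensemble, seed=trial)
            if np.array_equal(canonicalize(out.assignment), canonicalize(planted)):
                hits += 1
        assert hits >= int(0.95 * n_trials)


class TestExternalCrossChecks:
    """Independent implementations (networkx) as oracles, never the route."""

    def test_modularity_matches_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(17)
        for _ in range(5):
            A = random_weighted_graph(12, rng, density=0.5)
            if A.sum() == 0:
                continue
            assign = rng.integers(0, 3, size=12)
            G = nx.from_numpy_array(A)
            comms = [set(np.flatnonzero(assign == c)) for c in range(3)]
            comms = [c for c in comms if c]
            for gamma in (1.0, 1.7):
                expect = nx.community.modularity(G, comms, weight="weight",
                                                 resolution=gamma)
                assert modularity_q(A, assign, gamma) == pytest.approx(expect, abs=1e-12)

    def test_optimizer_reaches_networkx_louvain_quality(self):
        import networkx as nx

        rng = np.random.default_rng(23)
        for _ in range(3):
            A = random_weighted_graph(20, rng, density=0.4)
            G = nx.from_numpy_array(A)
            nx_comms = nx.community.louvain_communities(G, weight="weight", seed=1)
            nx_q = nx.community.modularity(G, nx_comms, weight="weight")
            ours = max(louvain_partition(A, 1.0, seed=s).q for s in range(20))
            assert ours >= nx_q - 1e-9


def test_mean_pairwise_zrand_identical_ensemble():
    p = np.array([0, 0, 1, 1, 2, 2, 0, 1])
    val = mean_pairwise_zrand([p, p, p])
    assert val == pytest.approx(zrand(p, p))
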