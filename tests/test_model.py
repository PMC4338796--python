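"""Model layer: dd-CRP prior, block statistics, and the NIchi2 marginal."""

import math

import numpy as np
import pytest

from ddparcel.core import ConnectivityMatrix, LinkState, Parcellation, SpatialGraph
from ddparcel.model import (
    EMPTY_BLOCK,
    BlockStats,
    Hyperparams,
    block_stats,
    log_ddcrp_prior,
    log_marginal_block,
    log_model,
    merge_block_stats,
    stats_of,
)
from ddparcel.synthetic import sample_connectivity

from conftest import enumerate_link_states, quad_log_marginal, random_matrix


HYPER = Hyperparams(sigma0_sq=1.0)


class TestPrior:
    def test_single_element_weights(self):
        """An element with 4 neighbors and alpha=10 links to itself with
        probability 10/14 and to each neighbor with probability 1/14."""
        g = SpatialGraph.grid(3, 3)  # center element 4 has 4 neighbors
        h = Hyperparams(sigma0_sq=1.0, alpha=10.0)
        base = np.arange(9)
        lp_self = log_ddcrp_prior(LinkState(base), g, h)
        other = base.copy()
        other[4] = 1
        lp_nbr = log_ddcrp_prior(LinkState(other), g, h)
        assert lp_nbr - lp_self == pytest.approx(math.log(1.0 / 10.0))

    def test_non_neighbor_link_has_zero_probability(self, path4):
        assert log_ddcrp_prior(LinkState(np.array([3, 1, 2, 3])), path4, HYPER) == -math.inf

    def test_alpha_zero_self_link(self, path3):
        h = Hyperparams(sigma0_sq=1.0, alpha=0.0)
        assert log_ddcrp_prior(LinkState(np.arange(3)), path3, h) == -math.inf

    def test_prior_normalizes_by_enumeration(self, path3):
        h = Hyperparams(sigma0_sq=1.0, alpha=1.0)
        total = sum(
            math.exp(log_ddcrp_prior(ls, path3, h)) for ls in enumerate_link_states(path3)
        )
        assert total == pytest.approx(1.0, abs=1e-12)


class TestBlockStats:
    def test_symmetric_single_parcel(self):
        V = np.zeros((3, 3))
        V[0, 1] = V[1, 0] = 1.0
        V[0, 2] = V[2, 0] = 2.0
        V[1, 2] = V[2, 1] = 4.0
        D = ConnectivityMatrix(V, symmetric=True)
        z = Parcellation(np.ones(3, dtype=int), 1)
        b = block_stats(D, z)[(1, 1)]
        assert b.count == 3
        assert b.mean == pytest.approx(7.0 / 3.0)
        assert b.ss_dev == pytest.approx(14.0 / 3.0)

    def test_singleton_cross_block_asymmetric(self):
        rng = np.random.default_rng(0)
        D = random_matrix(3, rng, symmetric=False)
        z = Parcellation(np.arange(1, 4), 3)
        bs = block_stats(D, z)
        b = bs[(1, 2)]
        assert b.count == 1 and b.ss_dev == 0.0
        assert b.mean == D.values[0, 1]

    @pytest.mark.parametrize("symmetric", [True, False])
    def test_counts_partition_included_entries(self, symmetric):
        rng = np.random.default_rng(1)
        D = random_matrix(9, rng, symmetric=symmetric)
        z = Parcellation.from_raw_labels(rng.integers(0, 3, size=9))
        bs = block_stats(D, z)
        assert sum(b.count for b in bs.values()) == D.included_mask().sum()

    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_direct_computation(self, symmetric):
        """Grouped-pass statistics equal per-block brute force."""
        rng = np.random.default_rng(2)
        D = random_matrix(12, rng, symmetric=symmetric)
        z = Parcellation.from_raw_labels(rng.integers(0, 4, size=12))
        members = z.members()
        for (m, n), b in block_stats(D, z).items():
            I, J = members[m - 1], members[n - 1]
            vals = []
            for i in I:
                for j in (I if m == n else J):
                    if i == j:
                        continue
                    if m == n and symmetric and i > j:
                        continue
                    vals.append(D.values[i, j])
            direct = stats_of(np.array(vals)) if vals else EMPTY_BLOCK
            assert b.count == direct.count
            assert b.mean == pytest.approx(direct.mean, abs=1e-12)
            assert b.ss_dev == pytest.approx(direct.ss_dev, abs=1e-10)


class TestMarginal:
    def test_empty_block_is_log_one(self):
        assert log_marginal_block(EMPTY_BLOCK, HYPER) == 0.0

    def test_quadrature_example(self):
        """Closed form matches the 2-D integral for the diffuse-mean case."""
        h = Hyperparams(sigma0_sq=1.0, alpha=10.0, mu0=0.0, kappa0=1e-4, nu0=1.0)
        b = stats_of(np.array([-1.0, 0.0, 1.0]))
        assert b == BlockStats(3, 0.0, 2.0)
        cf = log_marginal_block(b, h)
        q = quad_log_marginal([-1.0, 0.0, 1.0], h)
        assert cf == pytest.approx(q, rel=1e-6)

    def test_mean_shift_penalized_with_tight_prior(self):
        """With a tight mean prior, moving dbar away from mu0 at fixed L and s
        strictly lowers the marginal."""
        h = Hyperparams(sigma0_sq=1.0, alpha=10.0, mu0=0.0, kappa0=100.0, nu0=1.0)
        vals = [log_marginal_block(BlockStats(5, d, 1.0), h) for d in (0.0, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestMergeStats:
    def test_merge_with_empty(self):
        b = BlockStats(4, 1.0, 2.0)
        assert merge_block_stats(b, EMPTY_BLOCK) == b
        assert merge_block_stats(EMPTY_BLOCK, b) == b

    def test_matches_direct_concatenation(self):
        b1 = stats_of(np.array([1.0, 2.0]))
        b2 = stats_of(np.array([4.0]))
        merged = merge_block_stats(b1, b2)
        assert merged.count == 3
        assert merged.mean == pytest.approx(7.0 / 3.0, abs=1e-12)
        assert merged.ss_dev == pytest.approx(14.0 / 3.0, abs=1e-12)

    def test_commutative_associative_and_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            xs = [rng.normal(size=rng.integers(1, 8)) for _ in range(3)]
            b = [stats_of(x) for x in xs]
            direct = stats_of(np.concatenate(xs))
            ab = merge_block_stats(b[0], b[1])
            ba = merge_block_stats(b[1], b[0])
            assert ab.mean == pytest.approx(ba.mean, abs=1e-12)
            assert ab.ss_dev == pytest.approx(ba.ss_dev, abs=1e-10)
            abc = merge_block_stats(ab, b[2])
            bca = merge_block_stats(merge_block_stats(b[1], b[2]), b[0])
            for got in (abc, bca):
                assert got.count == direct.count
                assert got.mean == pytest.approx(direct.mean, abs=1e-10)
                assert got.ss_dev == pytest.approx(direct.ss_dev, abs=1e-10)


class TestLogModel:
    def test_sum_of_blocks_and_relabel_invariance(self):
        rng = np.random.default_rng(4)
        D = random_matrix(10, rng, symmetric=True)
        z = Parcellation.from_raw_labels(rng.integers(0, 3, size=10))
        total = sum(log_marginal_block(b, HYPER) for b in block_stats(D, z).values())
        assert log_model(D, z, HYPER) == pytest.approx(total, abs=1e-12)
        # relabeled copy scores identically
        relabeled = Parcellation.from_raw_labels(10 - z.labels)
        assert log_model(D, relabeled, HYPER) == pytest.approx(
            log_model(D, z, HYPER), abs=1e-9
        )

    def test_truth_ranks_highest_among_contiguous_splits(self):
        """Exhaustive oracle on a 6-element path: with near-noiseless
        two-block data the generating split has the best likelihood among all
        contiguous 2-parcellations."""
        g = SpatialGraph.from_edges(6, [(i, i + 1) for i in range(5)])
        truth = Parcellation(np.array([1, 1, 1, 2, 2, 2]), 2)
        ds = sample_connectivity(g, truth, 0.01, 7)
        h = Hyperparams(sigma0_sq=0.01)
        scores = {}
        for cut in range(1, 6):
            labels = np.array([1] * cut + [2] * (6 - cut))
            scores[cut] = log_model(ds.D, Parcellation(labels, 2), h)
        assert max(scores, key=scores.get) == 3

    def test_incremental_merge_reproduces_full_model(self):
        """Pooling two parcels' blocks via merge_block_stats reproduces the
        from-scratch log model of the merged partition."""
        rng = np.random.default_rng(5)
        for symmetric in (True, False):
            D = random_matrix(10, rng, symmetric=symmetric)
            z = Parcellation.from_raw_labels(np.repeat([0, 1, 2], [3, 3, 4]))
            merged_z = Parcellation.from_raw_labels(np.repeat([0, 1, 1], [3, 3, 4]))
            bs = block_stats(D, z)

            def get(a, b):
                if symmetric and a > b:
                    a, b = b, a
                return bs.get((a, b), EMPTY_BLOCK)

            # merge parcels 2 and 3 block-by-block
            new_blocks = []
            if symmetric:
                new_blocks.append(merge_block_stats(get(1, 2), get(1, 3)))
                within = merge_block_stats(merge_block_stats(get(2, 2), get(3, 3)), get(2, 3))
                new_blocks.append(within)
                new_blocks.append(get(1, 1))
            else:
                new_blocks.append(merge_block_stats(get(1, 2), get(1, 3)))
                new_blocks.append(merge_block_stats(get(2, 1), get(3, 1)))
                within = EMPTY_BLOCK
                for key in [(2, 2), (3, 3), (2, 3), (3, 2)]:
                    within = merge_block_stats(within, get(*key))
                new_blocks.append(within)
                new_blocks.append(get(1, 1))
            incremental = sum(log_marginal_block(b, HYPER) for b in new_blocks)
            assert incremental == pytest.approx(log_model(D, merged_z, HYPER), abs=1e-8)
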