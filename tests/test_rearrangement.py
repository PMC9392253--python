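"""Inversion distance, block construction and rearrangement rates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import all_circular_signed_perms, bounded_bfs_distance, circular_bfs_distances
from mitostructkit.rearrangement import (
    SignedPermutation,
    blocks_from_anchors,
    branch_rate,
    canonicalize_circular,
    inversion_distance,
    pairwise_rate,
    relative_distance,
    tree_rates,
)
from mitostructkit.sequences import revcomp
from mitostructkit.simulate import SimulationConfig, gen_circular_genome, gen_rearranged_pair


class TestInversionDistance:
    def test_identity_is_zero(self):
        assert inversion_distance((1, 2, 3, 4)) == 0

    def test_single_inversion(self):
        assert inversion_distance((1, -2, 3, 4)) == 1

    def test_rotation_and_reflection_are_identity(self):
        assert inversion_distance((3, 4, 1, 2)) == 0
        assert inversion_distance((-4, -3, -2, -1)) == 0

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_exhaustive_bfs_agreement_small(self, n):
        """HP distance equals exhaustive BFS for every circular permutation."""
        bfs = circular_bfs_distances(n)
        for p in all_circular_signed_perms(n):
            assert inversion_distance(p) == bfs[canonicalize_circular(p)]

    def test_invalid_permutation_rejected(self):
        with pytest.raises(ValueError):
            inversion_distance((1, 2, 2))
        with pytest.raises(ValueError):
            SignedPermutation((0, 1, 2))

    @given(st.permutations(list(range(2, 8))), st.lists(st.booleans(), min_size=6, max_size=6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_inverse_and_reflection_invariance(self, rest, flips):
        blocks = (1,) + tuple((-x if f else x) for x, f in zip(rest, flips))
        d = inversion_distance(blocks)
        reflected = tuple(-x for x in reversed(blocks))
        assert inversion_distance(reflected) == d
        # inverse permutation: position of block i in blocks, signed
        inv = [0] * len(blocks)
        for pos, x in enumerate(blocks, start=1):
            inv[abs(x) - 1] = pos if x > 0 else -pos
        assert inversion_distance(tuple(inv)) == d

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)

        def rand_perm(n=7):
            vals = rng.permutation(np.arange(1, n + 1))
            signs = rng.choice([-1, 1], size=n)
            return SignedPermutation(tuple(int(v * s) for v, s in zip(vals, signs)))

        a, b, c = rand_perm(), rand_perm(), rand_perm()
        assert relative_distance(a, c) <= relative_distance(a, b) + relative_distance(b, c)


class TestScrambledPairs:
    def test_k0_is_identity(self):
        ident, scrambled, k = gen_rearranged_pair(6, 0, seed=1)
        assert scrambled.blocks == ident.blocks
        assert inversion_distance(scrambled) == 0

    def test_one_inversion_distance_one(self):
        for seed in range(10):
            _, scrambled, _ = gen_rearranged_pair(6, 1, seed=seed)
            assert inversion_distance(scrambled) == 1

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_distance_bounded_by_k_and_matches_bfs(self, k):
        """Planted scrambles: distance <= k always, equal to the BFS optimum."""
        for seed in range(25):
            _, scrambled, _ = gen_rearranged_pair(7, k, seed=seed)
            d = inversion_distance(scrambled)
            assert d <= k
            assert bounded_bfs_distance(scrambled.blocks, k) == d


class TestBlocksFromAnchors:
    def test_self_is_identity_full_shared(self, small_genome):
        _, genome, _ = small_genome
        A = genome.seq
        perm, shared = blocks_from_anchors(A, A)
        assert inversion_distance(perm) == 0
        assert shared.percent > 99.0

    def test_single_inversion_detected(self, small_genome):
        _, genome, _ = small_genome
        cfg = SimulationConfig(seed=77, genome_length=40_000, repeat_spec=())
        g, _ = gen_circular_genome(cfg)
        A = g.seq
        B = A[:15_000] + revcomp(A[15_000:25_000]) + A[25_000:]
        perm, shared = blocks_from_anchors(A, B)
        assert inversion_distance(perm) == 1
        assert sum(1 for x in perm.blocks if x < 0) == 1
        assert shared.percent > 95.0

    def test_rotation_is_identity(self, small_genome):
        _, genome, _ = small_genome
        A = genome.seq
        B = A[7000:] + A[:7000]
        perm, _ = blocks_from_anchors(A, B)
        assert inversion_distance(perm) == 0

    def test_no_homology_raises(self):
        rng = np.random.default_rng(0)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        A = bases[rng.integers(0, 4, 5000)].tobytes().decode()
        B = bases[rng.integers(0, 4, 5000)].tobytes().decode()
        with pytest.raises(ValueError, match="no homology"):
            blocks_from_anchors(A, B)


class TestRates:
    def test_pairwise_rate_halves_time(self):
        assert pairwise_rate(0, 5.0).rate == 0.0
        assert pairwise_rate(4, 1.0).rate == 2.0
        assert pairwise_rate(6, 0.6).rate == pytest.approx(5.0)

    def test_branch_rate(self):
        assert branch_rate(6, 0.05).rate == pytest.approx(120.0)
        assert branch_rate(0, 1.0).rate == 0.0
        assert branch_rate(9, 1.73).rate == pytest.approx(9 / 1.73)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            pairwise_rate(1, 0.0)
        with pytest.raises(ValueError):
            branch_rate(1, -1.0)

    def test_tree_rates(self):
        import dendropy

        tree = dendropy.Tree.get(data="((A:0.5,B:0.5)N1:1.0,C:1.5)root;", schema="newick")
        ident = SignedPermutation((1, 2, 3, 4), genome_id="x")
        one_inv = SignedPermutation((1, -2, 3, 4), genome_id="y")
        orders = {"A": one_inv, "B": ident, "C": ident, "N1": ident, "root": ident}
        rates = tree_rates(tree, orders)
        by_child = {r["child"]: r for r in rates}
        assert by_child["A"]["events"] == 1
        assert by_child["A"]["rate"] == pytest.approx(2.0)
        assert by_child["B"]["events"] == 0
        assert by_child["C"]["rate"] == 0.0

    def test_tree_rates_missing_order(self):
        import dendropy

        tree = dendropy.Tree.get(data="(A:1.0,B:1.0)root;", schema="newick")
        ident = SignedPermutation((1, 2, 3), genome_id="x")
        with pytest.raises(KeyError, match="B"):
            tree_rates(tree, {"A": ident, "root": ident})
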