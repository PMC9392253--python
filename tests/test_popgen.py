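"""Variant filtering, windowed diversity/F_ST and sweep calling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mitostructkit.popgen import (
    VariantMatrix,
    call_sweeps,
    filter_variants,
    read_vcf,
    site_fst_components,
    site_pi,
    window_table,
    windowed_fst,
    windowed_pi,
    write_vcf,
)
from mitostructkit.simulate import SimulationConfig, gen_population_variants


def _vm(positions, genotypes, pops=None, L=10_000):
    gt = np.asarray(genotypes, dtype=np.int8)
    samples = [f"s{i}" for i in range(gt.shape[1])]
    if pops is None:
        half = gt.shape[1] // 2
        pops = {s: ("wild" if i < half else "cultivated") for i, s in enumerate(samples)}
    return VariantMatrix(samples, pops, np.asarray(positions), gt, L)


class TestFilter:
    def test_singleton_below_maf_removed(self):
        gt = np.zeros((1, 139), dtype=np.int8)
        gt[0, 0] = 1  # MAF = 1/139 ~ 0.0072
        vm = filter_variants(_vm([100], gt))
        assert vm.n_sites == 0

    def test_high_missing_removed(self):
        gt = np.tile([0, 1], (1, 10)).astype(np.int8)  # 20 samples, MAF 0.5
        gt[0, :3] = -1  # 15% missing
        vm = filter_variants(_vm([100], gt))
        assert vm.n_sites == 0

    def test_passing_matrix_unchanged(self):
        rng = np.random.default_rng(0)
        gt = rng.integers(0, 2, size=(30, 40)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 5000), 30, replace=False))
        before = _vm(pos, gt)
        after = filter_variants(before)
        # i.i.d. 0/1 calls at n=40 essentially never fail MAF/missing filters
        assert np.array_equal(after.genotypes, gt)
        assert np.array_equal(after.positions, pos)


class TestPi:
    def test_monomorphic_zero(self):
        assert site_pi(np.zeros(10, dtype=np.int8)) == 0.0

    def test_two_haplotypes_single_difference(self):
        gt = np.array([[0, 1]], dtype=np.int8)
        vm = _vm([50], gt, pops={"s0": "wild", "s1": "wild"}, L=1000)
        pw = windowed_pi(vm, "wild", window=1000, step=1000)
        assert pw["pi"].iloc[0] == pytest.approx(1 / 1000)

    def test_equals_pairwise_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            calls = rng.integers(-1, 3, size=10).astype(np.int8)
            called = calls[calls >= 0]
            n = len(called)
            if n < 2:
                continue
            diffs = sum(1 for a, b in itertools.combinations(called, 2) if a != b)
            assert site_pi(calls) == pytest.approx(diffs / (n * (n - 1) / 2))

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        calls = rng.integers(0, 2, size=20).astype(np.int8)
        assert site_pi(calls) == site_pi(calls[::-1])


class TestFst:
    def test_fixed_difference_is_one(self):
        num, den = site_fst_components(np.zeros(20, dtype=np.int8), np.ones(20, dtype=np.int8))
        assert num / den == pytest.approx(1.0)

    def test_single_site_component_formulas(self):
        # hand-computed Weir-Cockerham pieces for p1=0.8 (n1=10), p2=0.2 (n2=10)
        a = np.array([1] * 8 + [0] * 2, dtype=np.int8)
        b = np.array([1] * 2 + [0] * 8, dtype=np.int8)
        n1 = n2 = 10
        N = 20
        nc = (N - (n1**2 + n2**2) / N) / 1
        expected_num = expected_den = 0.0
        for p1, p2 in ((0.8, 0.2), (0.2, 0.8)):  # both alleles
            pbar = 0.5 * (p1 + p2)
            msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
            msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 + n2 - 2)
            expected_num += msp - msg
            expected_den += msp + (nc - 1) * msg
        num, den = site_fst_components(a, b)
        assert num == pytest.approx(expected_num)
        assert den == pytest.approx(expected_den)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(9)
        gt = rng.integers(0, 2, size=(60, 80)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 2000), 60, replace=False))
        vm = _vm(pos, gt, L=2000)
        f = windowed_fst(vm, "wild", "cultivated", window=2000, step=2000)
        assert abs(f["fst"].iloc[0]) < 0.05


class TestSweeps:
    def _windows(self, rows):
        return pd.DataFrame(rows, columns=["start", "end", "pi_wild", "pi_cul", "fst", "ratio"])

    def test_threshold_logic(self):
        w = self._windows(
            [
                (0, 1000, 0.01, 0.002, 0.05, 5.0),  # fails fst
                (500, 1500, 0.01, 0.003, 0.3, 3.0),  # flagged
                (1000, 2000, 0.01, 0.01, 0.3, 1.0),  # fails ratio
            ]
        )
        flagged, regions = call_sweeps(w)
        assert list(flagged["sweep"]) == [False, True, False]
        assert regions == [(500, 1500)]

    def test_adjacent_windows_merge(self):
        w = self._windows(
            [(0, 1000, 0.01, 0.001, 0.3, 10.0), (500, 1500, 0.01, 0.001, 0.3, 10.0), (3000, 4000, 0.01, 0.001, 0.3, 10.0)]
        )
        _, regions = call_sweeps(w)
        assert regions == [(0, 1500), (3000, 4000)]

    def test_monotone_in_thresholds(self):
        vm, _ = gen_population_variants(SimulationConfig(seed=40))
        w = window_table(filter_variants(vm))
        base, _ = call_sweeps(w)
        for fst_min, ratio_min in ((0.2, 2.0), (0.1, 4.0), (0.3, 5.0)):
            stricter, _ = call_sweeps(w, fst_min=fst_min, ratio_min=ratio_min)
            assert (stricter["sweep"] <= base["sweep"]).all()

    def test_zero_cultivated_pi_not_flagged_by_default(self):
        w = self._windows([(0, 1000, 0.01, 0.0, 0.5, np.nan)])
        flagged, _ = call_sweeps(w)
        assert not flagged["sweep"].iloc[0]
        flagged2, _ = call_sweeps(w, allow_infinite_ratio=True)
        assert flagged2["sweep"].iloc[0]

    def test_overlapping_step_only_adds_flags(self):
        vm, _ = gen_population_variants(SimulationConfig(seed=41))
        vm = filter_variants(vm)
        coarse, _ = call_sweeps(window_table(vm, window=1000, step=1000))
        fine, _ = call_sweeps(window_table(vm, window=1000, step=500))
        assert fine["sweep"].sum() >= coarse["sweep"].sum()


class TestVcfRoundTrip:
    def test_round_trip(self, tmp_path):
        vm, _ = gen_population_variants(SimulationConfig(seed=42, genome_length=5000))
        path = tmp_path / "x.vcf"
        write_vcf(vm, path)
        back = read_vcf(path, vm.populations, vm.reference_length)
        assert back.samples == vm.samples
        assert np.array_equal(back.positions, vm.positions)
        assert np.array_equal(back.genotypes, vm.genotypes)
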