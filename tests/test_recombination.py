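"""Recombinant-form construction, read assignment and activity summaries."""

import math

import pytest

from mitostructkit.recombination import (
    RecombAssay,
    activity_percent,
    activity_summary,
    assign_reads,
    build_mito_read_set,
    build_recombinant_references,
    recombination_frequency,
)
from mitostructkit.repeats import RepeatPair
from mitostructkit.sequences import revcomp
from mitostructkit.simulate import SimulationConfig, gen_circular_genome, sim_long_reads


@pytest.fixture(scope="module")
def exact_assay():
    cfg = SimulationConfig(
        seed=31,
        genome_length=20_000,
        repeat_spec=((2000, 100.0, 1),),
        recomb_fraction=0.4,
        read_length_mean=3000,
        read_length_sd=800,
        coverage=100,
    )
    genome, truth = gen_circular_genome(cfg)
    assay = build_recombinant_references(genome, truth[0])
    reads = sim_long_reads(genome, truth[0], cfg)
    return cfg, genome, truth[0], assay, reads


class TestFormConstruction:
    def test_identical_copies_two_forms(self, exact_assay):
        *_, assay, _ = exact_assay
        assert len(assay.reference_forms) == 2
        assert len(assay.recombinant_forms) == 2

    def test_diverged_copies_six_forms(self):
        cfg = SimulationConfig(seed=32, genome_length=20_000, repeat_spec=((1000, 98.0, 1),))
        genome, truth = gen_circular_genome(cfg)
        assay = build_recombinant_references(genome, truth[0])
        assert len(assay.recombinant_forms) == 6
        # combinatorial identity: 2*2*2 flank/repeat choices minus 2 references
        assert 2 * 2 * 2 - len(assay.reference_forms) == 6

    def test_forms_are_flank_repeat_flank(self, exact_assay):
        _, genome, pair, assay, _ = exact_assay
        expect = 2 * assay.flank + pair.length
        for form in (*assay.reference_forms.values(), *assay.recombinant_forms.values()):
            assert len(form) == expect

    def test_copies_too_close_rejected(self):
        genome, _ = gen_circular_genome(
            SimulationConfig(seed=33, genome_length=20_000, repeat_spec=())
        )
        # copies only 100 bp apart: a 200-bp flank would run into the other copy
        pair = RepeatPair((1000, 1500), (1600, 2100), 500, 100.0, "direct")
        with pytest.raises(ValueError, match="too close"):
            build_recombinant_references(genome, pair, flank=200)


class TestAssignment:
    def test_exact_recombinant_read_counted(self, exact_assay):
        *_, assay, _ = exact_assay
        read = assay.recombinant_forms["rec_abf"]
        out = assign_reads([read], assay)
        assert (out.n_ref, out.n_recomb, out.n_uninformative) == (0, 1, 0)

    def test_read_inside_repeat_uninformative(self, exact_assay):
        _, genome, pair, assay, _ = exact_assay
        read = genome.fetch(pair.locusA[0] + 10, pair.locusA[1] - 10)
        out = assign_reads([read], assay)
        assert out.n_uninformative == 1 and out.n_ref == 0 and out.n_recomb == 0

    def test_counts_partition_reads(self, exact_assay):
        *_, assay, reads = exact_assay
        out = assign_reads(reads, assay)
        assert out.n_ref + out.n_recomb + out.n_uninformative == len(reads)

    def test_reverse_complement_invariance(self, exact_assay):
        *_, assay, reads = exact_assay
        sub = reads[:80]
        fwd = assign_reads(sub, assay)
        rc = assign_reads([revcomp(r.seq) for r in sub], assay)
        assert (fwd.n_ref, fwd.n_recomb, fwd.n_uninformative) == (rc.n_ref, rc.n_recomb, rc.n_uninformative)

    def test_mixture_recovers_fraction(self, exact_assay):
        *_, assay, reads = exact_assay
        out = assign_reads(reads, assay)
        n = out.n_ref + out.n_recomb
        assert n >= 30
        freq = recombination_frequency(out) / 100.0
        se = math.sqrt(0.4 * 0.6 / n)
        assert abs(freq - 0.4) < 3 * se


class TestFrequency:
    def test_arithmetic(self):
        a = RecombAssay(None, 200, {}, {}, n_ref=70, n_recomb=30)
        assert recombination_frequency(a) == pytest.approx(30.0)
        b = RecombAssay(None, 200, {}, {}, n_ref=50, n_recomb=0)
        assert recombination_frequency(b) == 0.0

    def test_degenerate_is_nan(self):
        a = RecombAssay(None, 200, {}, {})
        assert math.isnan(recombination_frequency(a))


@pytest.fixture(scope="module")
def refs():
    mito, _ = gen_circular_genome(SimulationConfig(seed=34, genome_length=20_000, repeat_spec=()))
    plastid, _ = gen_circular_genome(SimulationConfig(seed=35, genome_length=15_000, repeat_spec=()))
    return mito, plastid


class TestReadFilter:
    def test_plastid_read_dropped(self, refs):
        mito, plastid = refs
        read = plastid.seq[2000:6000]
        assert build_mito_read_set([read], mito, plastid) == []

    def test_mito_read_kept(self, refs):
        mito, plastid = refs
        read = mito.seq[2000:6000]
        assert build_mito_read_set([read], mito, plastid) == [read]

    def test_half_chimera_kept(self, refs):
        mito, plastid = refs
        read = mito.seq[1000:3000] + plastid.seq[1000:3000]
        assert build_mito_read_set([read], mito, plastid) == [read]

    def test_empty_set_warns(self, refs):
        mito, plastid = refs
        with pytest.warns(UserWarning, match="empty"):
            assert build_mito_read_set([], mito, plastid) == []


class TestActivitySummary:
    def test_percent_arithmetic(self):
        # the published totals: 164 of 6707 short repeats and 33 of 38 long
        assert activity_percent(164, 6707) == 2.45
        assert activity_percent(33, 38) == 86.84
        assert activity_percent(0, 10) == 0.0
        assert math.isnan(activity_percent(0, 0))

    def _assay(self, length, n_ref, n_recomb):
        pair = RepeatPair((0, length), (10_000, 10_000 + length), length, 100.0, "direct")
        return RecombAssay(pair, 200, {}, {}, n_ref=n_ref, n_recomb=n_recomb)

    def test_summary_classes_and_bands(self):
        assays = [
            self._assay(2000, 10, 30),  # >1000, active, 75%
            self._assay(2000, 50, 0),  # >1000, inactive
            self._assay(80, 400, 1),  # <100, active, 0.25%
            self._assay(300, 60, 40),  # 100-500, active, 40%
        ]
        summ = activity_summary(assays)
        table = summ.per_class.set_index("class")
        assert table.loc[">1000", "n_active"] == 1
        assert table.loc[">1000", "n_total"] == 2
        assert table.loc[">1000", "percent_active"] == 50.0
        assert summ.n_freq_lt1 == 1
        assert summ.n_freq_gt20 == 2
        assert summ.n_freq_gt50 == 1

    def test_min_support_threshold(self):
        assays = [self._assay(2000, 10, 1)]
        assert activity_summary(assays, min_support=2).per_class["n_active"].sum() == 0
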