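"""Read typing: anchor criteria, intron measurement, Jenks allele
calling, the five sample filters, reference-read simulation and the
artifact blacklist."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import build_gene, random_seq
from dotstutter.alignment import ANCHOR_SCHEME, bit_score
from dotstutter.annotation import GenomeAssembly, revcomp
from dotstutter.read_typing import (
    Allele,
    AnchorCriteria,
    SampleAlleleCall,
    apply_sample_filters,
    build_simulation_blacklist,
    call_alleles,
    call_sample,
    find_anchor,
    intron_regions,
    jenks_two_break,
    measure_intron,
    measure_reads,
    simulate_reference_reads,
)


def jenks_oracle(values):
    """Exhaustive evaluation of every split point on the sorted list:
    the minimum within-class sum of squared deviations partition."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 1 or xs[0] == xs[-1]:
        return xs, []

    def ssd(chunk):
        if len(chunk) <= 1:
            return 0.0
        mu = sum(chunk) / len(chunk)
        return sum((x - mu) ** 2 for x in chunk)

    best = min(range(1, n), key=lambda k: ssd(xs[:k]) + ssd(xs[k:]))
    return xs[:best], xs[best:]


class TestFindAnchor:
    def test_exact_exon_inside_read(self):
        rng = random.Random(1)
        exon = random_seq(120, rng)
        read = random_seq(2000, rng) + exon + random_seq(2000, rng)
        hit = find_anchor(read, exon)
        assert hit is not None
        assert hit.subject_range == (2000, 2120)
        assert hit.aligned_length == 120

    def test_bit_score_just_below_threshold_rejected(self):
        # a perfect 28 bp exon scores 49.2 bits < 50; 29 bp scores 50.9
        rng = random.Random(2)
        short, ok = random_seq(28, rng), random_seq(29, rng)
        assert bit_score(28, ANCHOR_SCHEME) < 50 < bit_score(29, ANCHOR_SCHEME)
        read = random_seq(500, rng) + short + random_seq(100, rng) + ok + random_seq(500, rng)
        assert find_anchor(read, short) is None
        assert find_anchor(read, ok) is not None

    def test_truncated_alignment_fails_length_rule(self):
        # only 75% of the exon present in the read -> deviation 25% > 20%
        rng = random.Random(3)
        exon = random_seq(120, rng)
        read = random_seq(800, rng) + exon[:90] + random_seq(800, rng)
        assert find_anchor(read, exon) is None

    def test_exon_below_min_length_ignored(self):
        read = random_seq(500, 4)
        assert find_anchor(read, "ACGTACGTA") is None  # 9 bp < 10

    def test_ties_break_leftmost(self):
        rng = random.Random(5)
        exon = random_seq(60, rng)
        read = random_seq(100, rng) + exon + random_seq(100, rng) + exon + random_seq(100, rng)
        hit = find_anchor(read, exon)
        assert hit.subject_range[0] == 100


class TestMeasureIntron:
    def _gene_read(self, intron_len=1500, seed=6):
        rng = random.Random(seed)
        exon_l, exon_r = random_seq(150, rng), random_seq(150, rng)
        intron = random_seq(intron_len, rng)
        read = random_seq(200, rng) + exon_l + intron + exon_r + random_seq(200, rng)
        return exon_l, exon_r, read

    def test_error_free_read_exact_length(self):
        exon_l, exon_r, read = self._gene_read(1500)
        lh, rh = find_anchor(read, exon_l), find_anchor(read, exon_r)
        assert measure_intron(read, lh, rh) == 1500

    def test_reverse_complement_read_same_length(self):
        exon_l, exon_r, read = self._gene_read(1500)
        rc = revcomp(read)
        lh, rh = find_anchor(rc, exon_l), find_anchor(rc, exon_r)
        assert lh.strand == rh.strand == "-"
        assert measure_intron(rc, lh, rh) == 1500

    def test_net_insertions_shift_measurement(self):
        # +30 bp inserted mid-intron -> measured 1530
        rng = random.Random(7)
        exon_l, exon_r = random_seq(150, rng), random_seq(150, rng)
        intron = random_seq(1500, rng)
        bumped = intron[:700] + random_seq(30, rng) + intron[700:]
        read = exon_l + bumped + exon_r
        lh, rh = find_anchor(read, exon_l), find_anchor(read, exon_r)
        assert measure_intron(read, lh, rh) == 1530

    def test_opposite_orientations_rejected(self):
        exon_l, exon_r, read = self._gene_read()
        lh, rh = find_anchor(read, exon_l), find_anchor(read, exon_r)
        rh.strand = "-"
        assert measure_intron(read, lh, rh) is None

    def test_overlapping_anchors_skipped(self):
        exon_l, exon_r, read = self._gene_read()
        lh, rh = find_anchor(read, exon_l), find_anchor(read, exon_r)
        rh.subject_range = (lh.subject_range[1] - 50, lh.subject_range[1] + 100)
        assert measure_intron(read, lh, rh) is None


class TestCallAlleles:
    def test_zero_variance_single_allele(self):
        call = call_alleles([1500] * 5)
        assert len(call.alleles) == 1
        assert call.alleles[0].mean_length == 1500
        assert call.alleles[0].read_count == 5

    def test_two_well_separated_alleles(self):
        call = call_alleles([1000, 1010, 990, 2000, 2020])
        assert len(call.alleles) == 2
        assert call.alleles[0].mean_length == pytest.approx(1000.0)
        assert sorted(call.alleles[0].member_lengths) == [990, 1000, 1010]
        assert call.alleles[1].mean_length == pytest.approx(2010.0)

    def test_close_clusters_merge_to_one(self):
        call = call_alleles([1000, 1005, 1010, 1015])
        assert len(call.alleles) == 1
        assert call.alleles[0].mean_length == pytest.approx(1007.5)

    def test_single_observation(self):
        call = call_alleles([1234])
        assert len(call.alleles) == 1 and call.alleles[0].read_count == 1

    @given(
        st.lists(st.integers(50, 5000), min_size=1, max_size=200),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_jenks_matches_exhaustive_oracle(self, values, _):
        lo, hi = jenks_two_break(values)
        olo, ohi = jenks_oracle(values)

        def ssd(chunk):
            if len(chunk) <= 1:
                return 0.0
            mu = sum(chunk) / len(chunk)
            return sum((x - mu) ** 2 for x in chunk)

        assert ssd(lo) + ssd(hi) == pytest.approx(ssd(olo) + ssd(ohi))


def _call(alleles, **kw):
    return SampleAlleleCall("s", "i", alleles, **kw)


class TestSampleFilters:
    def test_min_length_filter(self):
        call = apply_sample_filters(_call([Allele(90.0, 10, [90] * 10)]))
        assert not call.passed_filters and "min_length" in call.fail_reasons
        ok = apply_sample_filters(_call([Allele(101.0, 10, [101] * 10)]))
        assert ok.passed_filters

    def test_min_reads_needs_more_than_four(self):
        call = apply_sample_filters(_call([Allele(500.0, 4, [500] * 4)]))
        assert "min_reads" in call.fail_reasons
        ok = apply_sample_filters(_call([Allele(500.0, 5, [500] * 5)]))
        assert ok.passed_filters

    def test_count_ratio_filter(self):
        bad = _call([Allele(500.0, 22, [500] * 22), Allele(900.0, 2, [900] * 2)])
        assert "count_ratio" in apply_sample_filters(bad).fail_reasons
        ok = _call([Allele(500.0, 20, [500] * 20), Allele(900.0, 2, [900] * 2)])
        assert apply_sample_filters(ok).passed_filters

    def test_member_deviation_filter(self):
        members = [1000] * 9 + [1120]  # mean 1012, max deviation ~10.7%
        bad = _call([Allele(float(np.mean(members)), 10, members)])
        assert "member_deviation" in apply_sample_filters(bad).fail_reasons

    def test_simulated_blacklist_filter(self):
        call = apply_sample_filters(
            _call([Allele(500.0, 10, [500] * 10)]), in_simulated_blacklist=True
        )
        assert call.fail_reasons == ["simulated_blacklist"]

    @given(st.floats(0.5, 20.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_member_deviation_is_scale_free(self, factor, seed):
        rng = random.Random(seed)
        members = [rng.randint(900, 1100) for _ in range(8)]
        base = _call([Allele(float(np.mean(members)), 8, members)])
        scaled_members = [m * factor for m in members]
        scaled = _call([Allele(float(np.mean(scaled_members)), 8, scaled_members)])
        assert (
            apply_sample_filters(base).passed_filters
            == apply_sample_filters(scaled).passed_filters
        )


class TestReferenceSimulation:
    def test_read_lengths_in_range_and_count(self):
        genome = GenomeAssembly("t", {"c1": random_seq(60_000, 1)})
        reads = simulate_reference_reads(genome, seed=3, min_len=5_000, max_len=50_000,
                                         coverage=10.0)
        assert len(reads) == round(10.0 * 60_000 / 27_500)
        assert all(5_000 <= len(seq) <= 50_000 for _, seq in reads)

    def test_short_chromosome_sampled_whole(self):
        genome = GenomeAssembly("t", {"tiny": random_seq(3_000, 2)})
        reads = simulate_reference_reads(genome, seed=1, coverage=5.0)
        assert all(len(seq) == 3_000 for _, seq in reads)

    def test_unique_genes_yield_empty_blacklist(self):
        rng = random.Random(9)
        genome, gene = build_gene(
            [random_seq(150, rng), random_seq(150, rng)], [random_seq(1200, rng)], seed=9
        )
        blacklist = build_simulation_blacklist(
            genome, [gene], seed=0, min_len=2_000, max_len=2_000, coverage=30.0
        )
        assert blacklist == set()

    def test_paralogous_genes_enter_blacklist(self):
        # two genes share exon sequences but differ in intron length:
        # cross-anchoring makes the haploid reference look heterozygous
        rng = random.Random(10)
        exon_l, exon_r = random_seq(150, rng), random_seq(150, rng)
        chrom = (
            random_seq(100, rng)
            + exon_l + random_seq(1000, rng) + exon_r
            + random_seq(400, rng)
            + exon_l + random_seq(1400, rng) + exon_r
            + random_seq(100, rng)
        )
        genome = GenomeAssembly("t", {"c": chrom})
        from dotstutter.annotation import GeneModel

        g1 = GeneModel("p1", "c", "+", [(100, 250), (1250, 1400)])
        g2 = GeneModel("p2", "c", "+", [(1800, 1950), (3350, 3500)])
        # reads cover one paralog each; identical exons cross-anchor the
        # other paralog's intron length into this region's list
        blacklist = build_simulation_blacklist(
            genome, [g1, g2], seed=0, min_len=1_800, max_len=1_800, coverage=60.0
        )
        assert blacklist == {"p1.i0", "p2.i0"}


class TestEndToEndSample:
    def test_heterozygote_recovery_from_noisy_reads(self):
        """Diploid with 1200/1800 bp alleles at one intron: two alleles
        called with means within 10% of truth."""
        rng = random.Random(20)
        exon_l, exon_r = random_seq(150, rng), random_seq(150, rng)
        intron_a = random_seq(1200, rng)
        intron_b = intron_a[:600] + random_seq(600, rng) + intron_a[600:]
        genome, gene = build_gene([exon_l, exon_r], [intron_a], seed=20)
        regions = intron_regions([gene])

        def noisy(seq, rng):
            out = []
            for ch in seq:
                if rng.random() < 0.015:  # deletion
                    continue
                out.append(ch)
                if rng.random() < 0.015:  # insertion
                    out.append(rng.choice("ACGT"))
            return "".join(out)

        reads = []
        for k in range(30):
            hap = intron_a if k % 2 == 0 else intron_b
            template = exon_l + hap + exon_r
            reads.append((f"r{k}", noisy(template, rng)))
        ms = measure_reads(reads, regions, genome, "s1")
        calls = call_sample(ms, "s1")
        assert len(calls) == 1
        call = calls[0]
        assert call.passed_filters
        assert len(call.alleles) == 2
        means = sorted(a.mean_length for a in call.alleles)
        assert abs(means[0] - 1200) <= 120
        assert abs(means[1] - 1800) <= 180
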