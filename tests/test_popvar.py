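"""Population aggregation: unique alleles, Hurlbert rarefaction,
heterozygosity, classification tallies and log-linear category models."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dotstutter.popvar import (
    PopulationAlleleTable,
    UniqueAllele,
    aggregate_unique_alleles,
    build_population_table,
    classify_and_tabulate,
    fit_category_model,
    heterozygosity,
    rarefy_monte_carlo,
    rarefy_richness,
)
from dotstutter.read_typing import Allele, SampleAlleleCall


def het_call(iid, a, b, sample="s", passed=True):
    alleles = (
        [Allele(float(a), 5, [a] * 5)]
        if a == b
        else [Allele(float(a), 5, [a] * 5), Allele(float(b), 5, [b] * 5)]
    )
    call = SampleAlleleCall(sample, iid, alleles)
    call.passed_filters = passed
    return call


class TestAggregateUniqueAlleles:
    def test_close_alleles_cluster(self):
        calls = [het_call("i", 1000, 2000, "s1"), het_call("i", 1005, 2000, "s2")]
        uniques = aggregate_unique_alleles(calls)
        assert len(uniques) == 2
        assert uniques[0].mean_length == pytest.approx(1002.5)
        assert uniques[1].mean_length == pytest.approx(2000.0)
        assert sum(u.draw_count for u in uniques) == 4

    def test_fifteen_percent_apart_stay_unique(self):
        calls = [het_call("i", 1000, 1150, "s1")]
        assert len(aggregate_unique_alleles(calls)) == 2

    def test_chained_near_threshold_alleles_greedy(self):
        # greedy centroid execution: 1000 joins; 1090 joins (|1090-1000|
        # <= 109); centroid 1045; 1180 opens a new cluster (135 > 118)
        calls = [
            het_call("i", 1000, 1000, "s1"),
            het_call("i", 1090, 1090, "s2"),
            het_call("i", 1180, 1180, "s3"),
        ]
        uniques = aggregate_unique_alleles(calls)
        assert [round(u.mean_length, 1) for u in uniques] == [1045.0, 1180.0]
        assert [u.draw_count for u in uniques] == [4, 2]

    def test_homozygote_contributes_two_draws(self):
        uniques = aggregate_unique_alleles([het_call("i", 1500, 1500)])
        assert uniques[0].draw_count == 2

    def test_failed_calls_excluded(self):
        calls = [het_call("i", 1000, 1000, passed=False)]
        assert aggregate_unique_alleles(calls) == []

    def test_permutation_invariant(self):
        rng = random.Random(3)
        calls = [
            het_call("i", rng.randint(500, 3000), rng.randint(500, 3000), f"s{k}")
            for k in range(8)
        ]
        a = aggregate_unique_alleles(calls)
        rng.shuffle(calls)
        b = aggregate_unique_alleles(calls)
        assert [(u.mean_length, u.draw_count) for u in a] == [
            (u.mean_length, u.draw_count) for u in b
        ]


class TestRarefaction:
    def test_single_allele(self):
        ar, n_eff = rarefy_richness([6], 6)
        assert ar == 1.0 and n_eff == 6

    def test_subsample_exhausts_population(self):
        ar, _ = rarefy_richness([3, 3], 6)
        assert ar == pytest.approx(2.0)

    def test_hurlbert_closed_form(self):
        expected = (1 - math.comb(10, 6) / math.comb(12, 6)) + (
            1 - math.comb(2, 6) / math.comb(12, 6) if 2 >= 6 else 1 - 0
        )
        # C(2,6) = 0: the rare allele term is exactly 1
        expected = (1 - math.comb(10, 6) / math.comb(12, 6)) + 1.0
        ar, _ = rarefy_richness([10, 2], 6)
        assert ar == pytest.approx(expected)

    def test_fewer_draws_than_n_flagged(self):
        ar, n_eff = rarefy_richness([2, 2], 6)
        assert n_eff == 4
        assert ar == pytest.approx(2.0)

    def test_no_draws_raises(self):
        with pytest.raises(ValueError):
            rarefy_richness([], 6)

    @given(
        st.lists(st.integers(1, 12), min_size=1, max_size=6),
        st.integers(0, 10_000),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_bounds_and_label_invariance(self, counts, seed):
        ar, n_eff = rarefy_richness(counts, 6)
        k = len(counts)
        assert 1.0 - 1e-9 <= ar <= min(k, 6) + 1e-9
        if sum(counts) == 6:
            assert ar == pytest.approx(float(k))
        rng = random.Random(seed)
        shuffled = counts[:]
        rng.shuffle(shuffled)
        assert rarefy_richness(shuffled, 6)[0] == pytest.approx(ar)

    def test_monte_carlo_agrees(self):
        rng = random.Random(5)
        for _ in range(5):
            counts = [rng.randint(1, 8) for _ in range(rng.randint(1, 5))]
            exact, _ = rarefy_richness(counts, 6)
            mc = rarefy_monte_carlo(counts, 6, n_resamples=40_000, seed=1)
            assert abs(exact - mc) < 0.02


class TestHeterozygosity:
    def test_all_homozygous(self):
        calls = [het_call("i", 1000, 1000, f"s{k}") for k in range(4)]
        assert heterozygosity(calls) == 0.0

    def test_all_heterozygous(self):
        calls = [het_call("i", 1000, 2000, f"s{k}") for k in range(4)]
        assert heterozygosity(calls) == 1.0

    def test_three_of_seven(self):
        calls = [
            het_call("i", 1000, 2000 if k < 3 else 1000, f"s{k}") for k in range(7)
        ]
        assert heterozygosity(calls) == pytest.approx(3 / 7)

    def test_no_passing_samples_raises(self):
        with pytest.raises(ValueError):
            heterozygosity([het_call("i", 1000, 1000, passed=False)])


class TestBuildAndTabulate:
    def test_stable_vs_variable_classification(self):
        calls_by_intron = {
            "a.i0": [het_call("a.i0", 1000, 1000, f"s{k}") for k in range(3)],
            "b.i0": [het_call("b.i0", 1000, 2000, f"s{k}") for k in range(3)],
        }
        tables = build_population_table(
            calls_by_intron, {"a.i0": "macro", "b.i0": "dot"}, ["b.i0"]
        )
        by_id = {t.intron_id: t for t in tables}
        assert by_id["a.i0"].classification == "stable"
        assert by_id["a.i0"].Ar == 1.0
        assert by_id["b.i0"].classification == "variable"
        assert by_id["b.i0"].Ar == pytest.approx(2.0)
        assert by_id["b.i0"].heterozygosity == 1.0
        assert by_id["b.i0"].exon_stuttering

        tab = classify_and_tabulate(tables)
        assert tab["n_introns"] == 2
        assert tab["n_variable"] == 1
        assert tab["per_class"]["dot"] == {"stable": 0, "variable": 1}
        assert tab["venn"]["variable_dot_stutter"] == 1

    def test_short_draw_introns_excluded_from_headline(self):
        calls_by_intron = {"a.i0": [het_call("a.i0", 1000, 1000, "s1")]}  # 2 draws
        tables = build_population_table(calls_by_intron)
        tab = classify_and_tabulate(tables)
        assert tab["n_introns"] == 0
        assert tab["n_excluded_short"] == 1

    def test_no_variable_introns_all_zero(self):
        calls_by_intron = {
            f"g.i{k}": [het_call(f"g.i{k}", 900, 900, f"s{j}") for j in range(3)]
            for k in range(4)
        }
        tab = classify_and_tabulate(build_population_table(calls_by_intron))
        assert tab["n_variable"] == 0
        assert tab["venn"]["variable_only"] == 0


class TestCategoryModel:
    def test_identical_groups_beta_zero(self):
        y = [10.0] * 10 + [10.0] * 10
        g = [True] * 10 + [False] * 10
        res = fit_category_model(y, g)
        assert res.beta == pytest.approx(0.0, abs=1e-12)

    def test_exact_e_fold_change(self):
        # no within-group noise: residuals vanish, p collapses toward 0
        rng = np.random.default_rng(1)
        base = [5.0 * (1 + e) for e in rng.normal(0, 1e-9, 6)]
        y = base + [v * math.e for v in base]
        g = [False] * 6 + [True] * 6
        res = fit_category_model(y, g)
        assert res.beta == pytest.approx(1.0)
        assert res.p_value < 1e-12

    def test_matches_two_sample_t_on_logs(self):
        rng = np.random.default_rng(8)
        a = np.exp(rng.normal(1.0, 0.4, 20))
        b = np.exp(rng.normal(1.5, 0.4, 20))
        res = fit_category_model(np.concatenate([a, b]), [False] * 20 + [True] * 20)
        la, lb = np.log(a), np.log(b)
        beta_hand = lb.mean() - la.mean()
        sp2 = ((la.var(ddof=1) * 19) + (lb.var(ddof=1) * 19)) / 38
        t_hand = beta_hand / math.sqrt(sp2 * (1 / 20 + 1 / 20))
        from scipy import stats

        p_hand = 2 * stats.t.sf(abs(t_hand), 38)
        assert res.beta == pytest.approx(beta_hand)
        assert res.p_value == pytest.approx(p_hand)
        assert res.n_category == res.n_reference == 20

    def test_nonpositive_response_rejected(self):
        with pytest.raises(ValueError):
            fit_category_model([1.0, 0.0], [True, False])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fit_category_model([1.0, 2.0], [True, True])
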