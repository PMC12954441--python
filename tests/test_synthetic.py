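"""Synthetic-data generator: determinism, engineered truth consistency,
divergence enforcement, population structure, read simulation."""

import random

import edlib
import pytest

from dotstutter.read_typing import call_sample, intron_regions, measure_reads
from dotstutter.repeat_coverage import RepeatTrack, intron_repeat_fraction
from dotstutter.synthetic import (
    PopulationConfig,
    ReadModel,
    SyntheticConfig,
    _mutate_unit,
    make_genome,
    make_population,
    simulate_reads,
    write_bundle,
)


def small_config(**kw):
    defaults = dict(
        seed=5,
        n_genes=6,
        copies_range=(3, 8),
        intron_len_range=(400, 1000),
        chrom_plan=(("dot1", "dot"), ("macro1", "macro")),
        stutter_fraction=0.6,
        population=PopulationConfig(n_individuals=4, alleles_per_intron=(1, 3)),
        read_model=ReadModel(length_range=(3000, 6000), coverage=20.0),
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestMakeGenome:
    def test_deterministic_given_seed(self):
        a1, g1, l1, _ = make_genome(small_config())
        a2, g2, l2, _ = make_genome(small_config())
        assert a1.sequences == a2.sequences
        assert [g.exons for g in g1] == [g.exons for g in g2]
        assert set(l1.introns) == set(l2.introns)

    def test_negative_control_has_no_stutter(self):
        _, _, ledger, _ = make_genome(small_config(stutter_fraction=0.0))
        assert not any(t.stuttered for t in ledger.introns.values())

    def test_stutter_restricted_to_dot_chromosomes(self):
        _, _, ledger, _ = make_genome(small_config())
        for t in ledger.introns.values():
            if t.stuttered:
                assert t.chrom == "dot1"

    def test_fixed_unit_and_copies_arithmetic(self):
        cfg = small_config(
            seed=9, copies_range=(5, 5), unit_len_range=(40, 40),
            unit_divergence=0.0, exon_stutter_fraction=0.0, stutter_fraction=1.0,
        )
        _, _, ledger, _ = make_genome(cfg)
        stuttered = [t for t in ledger.introns.values() if t.stuttered]
        assert stuttered
        for t in stuttered:
            ts, te = t.tandem_interval
            assert te - ts == 5 * 40  # divergence 0: copies expand exactly
            assert t.copies == 5

    def test_exon_stutter_unit_spans_border(self):
        cfg = small_config(stutter_fraction=1.0, exon_stutter_fraction=1.0)
        genome, genes, ledger, _ = make_genome(cfg)
        by_id = {g.gene_id: g for g in genes}
        checked = 0
        for t in ledger.introns.values():
            if not t.exon_stutter:
                continue
            gene = by_id[t.gene_id]
            exon_seq = genome.fetch(gene.chrom, *gene.exons[t.source_exon_index])
            # unit starts with the exon's terminal fragment
            frag = t.unit_consensus[:20]
            assert frag in exon_seq[-100:]
            checked += 1
        assert checked > 0

    def test_infeasible_config_names_the_intron(self):
        cfg = small_config(
            stutter_fraction=1.0, copies_range=(30, 44), unit_len_range=(150, 200),
            exon_stutter_fraction=0.0, max_intron_len=1000,
        )
        with pytest.raises(ValueError, match=r"\.i\d"):
            make_genome(cfg)

    def test_genome_and_ledger_lengths_agree(self):
        genome, genes, ledger, layout = make_genome(small_config())
        for gene in genes:
            for i, (s, e) in enumerate(gene.introns):
                truth = ledger.introns[f"{gene.gene_id}.i{i}"]
                assert truth.ref_length == e - s


class TestMutateUnit:
    @pytest.mark.parametrize("seed", range(10))
    def test_divergence_bounded_by_twenty_percent(self, seed):
        rng = random.Random(seed)
        unit = "".join(rng.choice("ACGT") for _ in range(rng.randint(20, 200)))
        for _ in range(10):
            copy = _mutate_unit(rng, unit, 0.20)
            dist = edlib.align(copy, unit)["editDistance"]
            assert dist <= 0.20 * len(unit)

    def test_zero_divergence_identity(self):
        rng = random.Random(1)
        unit = "ACGTTGCA" * 5
        assert _mutate_unit(rng, unit, 0.0) == unit


class TestPopulation:
    def test_monomorphic_when_one_allele(self):
        cfg = small_config(population=PopulationConfig(4, (1, 1)))
        _, _, ledger, layout = make_genome(cfg)
        inds = make_population(layout, ledger, cfg, seed=2)
        assert all(len(t.alleles) == 1 for t in ledger.introns.values())
        # every haplotype identical across individuals
        ref = inds[0].haplotypes[0]
        for ind in inds:
            for hap in ind.haplotypes:
                assert hap == ref

    def test_allele_lengths_respect_min_gap(self):
        cfg = small_config(stutter_fraction=1.0)
        _, _, ledger, layout = make_genome(cfg)
        make_population(layout, ledger, cfg, seed=3)
        for t in ledger.introns.values():
            lens = sorted(a.length for a in t.alleles)
            for a, b in zip(lens, lens[1:]):
                assert (b - a) / b >= 0.13  # ~min_allele_gap with rounding

    def test_two_equifrequent_alleles_expected_het_half(self):
        cfg = small_config(
            n_genes=10, stutter_fraction=1.0,
            population=PopulationConfig(n_individuals=40, alleles_per_intron=(2, 2)),
        )
        _, _, ledger, layout = make_genome(cfg)
        inds = make_population(layout, ledger, cfg, seed=4)
        het_rates = []
        for iid, t in ledger.introns.items():
            if len(t.alleles) != 2:
                continue
            het = sum(
                1 for ind in inds if ind.intron_truth[iid][0] != ind.intron_truth[iid][1]
            ) / len(inds)
            het_rates.append(het)
        mean_het = sum(het_rates) / len(het_rates)
        assert abs(mean_het - 0.5) < 0.1  # binomial expectation across draws

    def test_long_intron_allele_mimics_kb_scale_span(self):
        # population alleles spanning ~1.6 to ~2.9 kb for one intron
        cfg = small_config(
            seed=21, n_genes=2, chrom_plan=(("dot1", "dot"),),
            stutter_fraction=1.0, intron_len_range=(1600, 1600),
            population=PopulationConfig(2, (2, 2), min_allele_gap=0.8),
        )
        _, _, ledger, layout = make_genome(cfg)
        make_population(layout, ledger, cfg, seed=5)
        spans = [
            (min(a.length for a in t.alleles), max(a.length for a in t.alleles))
            for t in ledger.introns.values()
            if t.stuttered
        ]
        assert any(lo >= 1600 and hi >= 1.8 * lo for lo, hi in spans)


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self):
        cfg = small_config(
            read_model=ReadModel((2000, 4000), 0.0, 0.0, 0.0, coverage=5.0)
        )
        _, _, ledger, layout = make_genome(cfg)
        inds = make_population(layout, ledger, cfg, seed=6)
        reads = simulate_reads(inds[0], cfg.read_model, seed=7, ledger=ledger, layout=layout)
        genomes = [
            "".join(h[c] for c in sorted(h)) for h in inds[0].haplotypes
        ]
        from dotstutter.annotation import revcomp

        for rid, seq in reads[:20]:
            truth = ledger.reads[rid]
            hap = inds[0].haplotypes[truth.haplotype][truth.chrom]
            expected = hap[truth.ref_start : truth.ref_end]
            assert seq == (expected if truth.strand == "+" else revcomp(expected))

    def test_read_count_follows_coverage_arithmetic(self):
        cfg = small_config(read_model=ReadModel((2000, 4000), coverage=12.0))
        _, _, ledger, layout = make_genome(cfg)
        inds = make_population(layout, ledger, cfg, seed=8)
        reads = simulate_reads(inds[0], cfg.read_model, seed=9)
        genome_len = sum(len(s) for s in inds[0].haplotypes[0].values())
        assert len(reads) == round(12.0 * genome_len / 3000)

    def test_net_indel_ledger_matches_error_free_expectation(self):
        cfg = small_config(read_model=ReadModel((3000, 5000), 0.0, 0.0, 0.0, 10.0))
        _, _, ledger, layout = make_genome(cfg)
        inds = make_population(layout, ledger, cfg, seed=10)
        reads = simulate_reads(inds[0], cfg.read_model, seed=11, ledger=ledger, layout=layout)
        nets = [
            v for rid, _ in reads for v in ledger.reads[rid].net_indel_by_intron.values()
        ]
        assert nets and all(v == 0 for v in nets)

    def test_rates_validated(self):
        with pytest.raises(ValueError):
            ReadModel(mismatch_rate=0.5)


class TestTypingConsistency:
    def test_error_free_typing_recovers_exact_lengths(self):
        """Engineered intron alleles, typed from error-free reads, yield
        their ledger lengths exactly."""
        cfg = small_config(
            seed=13, read_model=ReadModel((3000, 6000), 0.0, 0.0, 0.0, 25.0)
        )
        genome, genes, ledger, layout = make_genome(cfg)
        inds = make_population(layout, ledger, cfg, seed=14)
        regions = intron_regions(genes)
        ind = inds[0]
        reads = simulate_reads(ind, cfg.read_model, seed=15)
        ms = measure_reads(reads, regions, genome, ind.individual_id)
        assert ms
        for m in ms:
            true_pair = sorted(ind.intron_lengths[m.intron_id])
            assert m.length_bp in true_pair


def test_dot_introns_have_higher_simple_repeat_fraction():
    cfg = small_config(seed=17, stutter_fraction=0.8)
    genome, genes, ledger, _ = make_genome(cfg)
    track = RepeatTrack(
        {
            t.chrom: []
            for t in ledger.introns.values()
        }
    )
    for t in ledger.introns.values():
        if t.stuttered and t.tandem_interval:
            track.intervals[t.chrom].append((*t.tandem_interval, "trf"))
    fractions = {"dot": [], "other": []}
    for g in genes:
        cls = "dot" if genome.chrom_class[g.chrom] == "dot" else "other"
        for iv in g.introns:
            fractions[cls].append(intron_repeat_fraction(iv, g.chrom, track))
    mean = lambda xs: sum(xs) / len(xs)
    assert mean(fractions["dot"]) > mean(fractions["other"])


def test_bundle_determinism(tmp_path):
    cfg = small_config(
        n_genes=3, population=PopulationConfig(2, (1, 2)),
        read_model=ReadModel((2000, 3000), coverage=3.0),
    )
    p1 = write_bundle(tmp_path / "a", cfg)
    p2 = write_bundle(tmp_path / "b", cfg)
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key
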