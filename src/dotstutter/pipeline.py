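"""End-to-end orchestration of the two screens.

``run_stutter_pipeline`` takes a genome, annotation and repeat tracks to
an exon-stuttering report (interact track, expansion summaries,
per-chromosome counts, noise-threshold report).

``run_variability_pipeline`` takes a genome, annotation and one read set
per sample to per-sample allele calls, the population allele table,
classification tallies and category models.

All randomness flows from a single top-level seed; every effective
parameter is logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import annotation as anno
from . import popvar, read_typing, repeat_coverage
from .alignment import SCREEN_SCHEME, ScoringScheme
from .stutter_screen import (
    ScreenConfig,
    StutterHit,
    count_stuttering_introns_by_chromosome,
    estimate_noise_threshold,
    screen_gene,
    summaries_to_frame,
    summarize_expansions,
    write_interact,
)

log = logging.getLogger(__name__)


@dataclass
class StutterPipelineResult:
    threshold: float
    threshold_median: float | None
    hits: list[StutterHit]
    summaries: list
    per_chromosome: object
    n_genes_screened: int
    n_candidate_genes: int


def load_inputs(
    genome_path: str | Path,
    gtf_path: str | Path,
    class_table: str | Path | None = None,
):
    for p in (genome_path, gtf_path, class_table):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    genome = anno.GenomeAssembly.from_fasta(genome_path, class_table)
    genes = anno.merge_overlapping(anno.parse_gene_annotation(gtf_path))
    if not genes:
        raise ValueError(f"no genes parsed from {gtf_path}")
    return genome, genes


def run_stutter_pipeline(
    genome: anno.GenomeAssembly,
    genes: Sequence[anno.GeneModel],
    rm_out: str | Path | None = None,
    config: ScreenConfig | None = None,
    scheme: ScoringScheme = SCREEN_SCHEME,
    exclusion_list: Sequence[str] = (),
    outdir: str | Path | None = None,
) -> StutterPipelineResult:
    config = config or ScreenConfig()
    exon_records = None
    if rm_out is not None:
        track = repeat_coverage.parse_repeatmasker_out(rm_out)
        interspersed = track.by_class(
            repeat_coverage.EXCLUDED_INTERSPERSED, invert=True
        )
        records = anno.flag_repeat_free_exons(genes, interspersed)
        exon_records = {}
        for r in records:
            exon_records.setdefault(r.gene_id, []).append(r)
        n_masked = sum(1 for r in records if not r.repeat_free)
        log.info("repeat-masked exons excluded: %d / %d", n_masked, len(records))

    median = None
    if config.bit_threshold is None:
        noise = estimate_noise_threshold(
            genes, genome, seed=config.shuffle_seed, scheme=scheme,
            min_hit_len=config.min_hit_len, exon_records=exon_records,
        )
        config.bit_threshold = noise.max_bit
        median = noise.median_bit
        log.info(
            "shuffled-control threshold: max bit %.1f (median %.1f, %d hits)",
            noise.max_bit, noise.median_bit, noise.n_hits,
        )
    else:
        log.info("fixed bit threshold %.1f; threshold estimation skipped", config.bit_threshold)

    hits: list[StutterHit] = []
    for gene in genes:
        hits.extend(screen_gene(gene, genome, config, scheme, exon_records))
    summaries = summarize_expansions(hits, genes, exclusion_list)
    pre_genes = {h.gene_id for h in hits}
    post_genes = {s.gene_id for s in summaries}
    log.info(
        "candidate genes: %d pre-exclusion, %d post-exclusion", len(pre_genes), len(post_genes)
    )
    table = count_stuttering_introns_by_chromosome(summaries, genome.chrom_class)
    result = StutterPipelineResult(
        threshold=config.bit_threshold,
        threshold_median=median,
        hits=hits,
        summaries=summaries,
        per_chromosome=table,
        n_genes_screened=len(genes),
        n_candidate_genes=len(post_genes),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_interact(outdir / "stutter_hits.interact", hits)
        summaries_to_frame(summaries).to_csv(outdir / "expansions.tsv", sep="\t", index=False)
        table.to_csv(outdir / "introns_per_chromosome.tsv", sep="\t", index=False)
        anno.write_bed(
            outdir / "stuttering_introns.bed",
            sorted({(s.chrom, *s.intron_interval, s.intron_id) for s in summaries}),
        )
        (outdir / "threshold.json").write_text(
            json.dumps(
                {
                    "bit_threshold": config.bit_threshold,
                    "control_median_bit": median,
                    "min_hit_len": config.min_hit_len,
                    "shuffle_seed": config.shuffle_seed,
                },
                indent=1,
            )
        )
    return result


@dataclass
class VariabilityPipelineResult:
    calls_by_sample: dict[str, list]
    tables: list
    tabulation: dict
    blacklist: set[str] = field(default_factory=set)
    models: dict = field(default_factory=dict)


def intron_chrom_classes(
    genes: Sequence[anno.GeneModel], genome: anno.GenomeAssembly
) -> dict[str, str]:
    out = {}
    for g in genes:
        for i in range(len(g.introns)):
            out[anno.intron_id(g, i)] = genome.chrom_class.get(g.chrom, "unknown")
    return out


def run_variability_pipeline(
    genome: anno.GenomeAssembly,
    genes: Sequence[anno.GeneModel],
    reads_by_sample: Mapping[str, Sequence[tuple[str, str]]],
    seed: int = 0,
    stutter_flags: Sequence[str] = (),
    rarefy_n: int = popvar.RAREFY_N,
    criteria: read_typing.AnchorCriteria = read_typing.AnchorCriteria(),
    simulate_blacklist: bool = True,
    sim_kwargs: dict | None = None,
    outdir: str | Path | None = None,
) -> VariabilityPipelineResult:
    regions = read_typing.intron_regions(genes)
    blacklist: set[str] = set()
    if simulate_blacklist:
        blacklist = read_typing.build_simulation_blacklist(
            genome, genes, seed=seed, criteria=criteria, **(sim_kwargs or {})
        )
        log.info("simulated-reference blacklist: %d introns", len(blacklist))

    calls_by_sample: dict[str, list] = {}
    calls_by_intron: dict[str, list] = {}
    for sample_id, reads in reads_by_sample.items():
        ms = read_typing.measure_reads(reads, regions, genome, sample_id, criteria)
        calls = read_typing.call_sample(ms, sample_id, blacklist)
        calls_by_sample[sample_id] = calls
        for c in calls:
            calls_by_intron.setdefault(c.intron_id, []).append(c)
        log.info(
            "sample %s: %d reads, %d measurements, %d introns called",
            sample_id, len(reads), len(ms), len(calls),
        )

    classes = intron_chrom_classes(genes, genome)
    tables = popvar.build_population_table(
        calls_by_intron, classes, stutter_flags, rarefy_n
    )
    tabulation = popvar.classify_and_tabulate(tables, rarefy_n)

    models = {}
    variable = [t for t in tables if t.variable and t.rarefied_at >= rarefy_n]
    for cat_name, flag in (
        ("dots", lambda t: t.chrom_class == "dot"),
        ("exon_stuttering", lambda t: t.exon_stuttering),
    ):
        is_cat = [flag(t) for t in variable]
        if any(is_cat) and not all(is_cat):
            models[cat_name] = popvar.fit_category_model(
                [t.Ar for t in variable], is_cat, cat_name
            )

    result = VariabilityPipelineResult(
        calls_by_sample, tables, tabulation, blacklist, models
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample_id, calls in calls_by_sample.items():
            read_typing.calls_to_frame(calls).to_csv(
                outdir / f"calls_{sample_id}.tsv", sep="\t", index=False
            )
        popvar.tables_to_frame(tables).to_csv(
            outdir / "population_alleles.tsv", sep="\t", index=False
        )
        summary = dict(tabulation)
        summary["models"] = {
            k: {
                "beta": m.beta,
                "p_value": m.p_value,
                "n_category": m.n_category,
                "n_reference": m.n_reference,
            }
            for k, m in models.items()
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return result
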