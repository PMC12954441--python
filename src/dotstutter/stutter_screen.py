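"""The exon-stuttering screen.

Each repeat-free exon of a gene is aligned as a query against every
intron of the same gene. A shuffled-intron control run establishes a
noise bit-score threshold (the maximum control bit score); confident
hits must be strictly above it and at least 20 aligned bases long.
Hits are labelled *proximal* when the target intron is immediately
adjacent to the source exon, *distal* otherwise, and intronic target
regions matched by more than one source exon are discarded.

Confident hits are summarised per (exon, intron) pair into expansion
records: copy count, the genomic span covering all copies plus the
source footprint, and the distance of the copied exon fragment from the
exon border facing the target intron.
"""

from __future__ import annotations

import logging
import random
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment import AlignmentHit, ScoringScheme, SCREEN_SCHEME, local_align, shuffle_sequence
from .annotation import ExonRecord, GeneModel, GenomeAssembly, intron_id


log = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """Screen parameters; defaults are the published values."""

    min_hit_len: int = 20
    bit_threshold: float | None = None  # None = derive from shuffled control
    proximal_only: bool = False
    shuffle_seed: int = 0
    max_hits_per_pair: int = 200


@dataclass
class StutterHit:
    """A confident exon→intron alignment with screen annotations."""

    gene_id: str
    exon_index: int
    intron_index: int
    hit: AlignmentHit  # subject_range in genomic coordinates
    proximal: bool
    source_border_distance: int
    source_genomic_range: tuple[int, int] = (0, 0)
    #: genomic position of the exon edge facing the target intron
    border_pos: int = 0


@dataclass
class ExpansionSummary:
    """Per (exon, intron) aggregate over all confident copies."""

    gene_id: str
    exon_index: int
    intron_index: int
    copy_count: int
    span_bp: int
    hit_lengths: list[int] = field(default_factory=list)
    min_border_distance: int = 0
    proximal: bool = True
    chrom: str = ""
    intron_interval: tuple[int, int] = (0, 0)

    @property
    def intron_id(self) -> str:
        return f"{self.gene_id}.i{self.intron_index}"


@dataclass
class NoiseEstimate:
    """Shuffled-control bit score distribution summary."""

    max_bit: float
    median_bit: float
    n_hits: int


def _border_distance(exon: tuple[int, int], intron: tuple[int, int], q_range: tuple[int, int]) -> int:
    """Distance (bp) of the query range from the exon edge facing the intron."""
    exon_len = exon[1] - exon[0]
    if intron[0] >= exon[1]:  # intron to the genomic right
        return exon_len - q_range[1]
    return q_range[0]


def _gene_exon_records(
    gene: GeneModel, exon_records: Mapping[str, Sequence[ExonRecord]] | None
) -> list[ExonRecord]:
    if exon_records is not None and gene.gene_id in exon_records:
        return [r for r in exon_records[gene.gene_id] if r.repeat_free]
    return [
        ExonRecord(gene.gene_id, i, gene.chrom, iv, True)
        for i, iv in enumerate(gene.exons)
    ]


def screen_gene(
    gene: GeneModel,
    genome: GenomeAssembly,
    config: ScreenConfig | None = None,
    scheme: ScoringScheme = SCREEN_SCHEME,
    exon_records: Mapping[str, Sequence[ExonRecord]] | None = None,
) -> list[StutterHit]:
    """Align every repeat-free exon against every intron of the gene.

    Returns hits with aligned_length >= min_hit_len, with
    proximal/distal labels and border distances; target regions matched
    by more than one source exon are discarded, and when
    ``config.bit_threshold`` is set, hits at or below it are dropped.
    """
    config = config or ScreenConfig()
    if not gene.introns:
        return []
    exons = _gene_exon_records(gene, exon_records)
    raw_hits: list[StutterHit] = []
    for rec in exons:
        exon_iv = rec.interval
        exon_seq = genome.fetch(gene.chrom, *exon_iv)
        neighbors = set(gene.neighbor_introns(rec.index)) if rec.index < len(gene.exons) else set()
        for ii, intron_iv in enumerate(gene.introns):
            intron_seq = genome.fetch(gene.chrom, *intron_iv)
            for h in local_align(
                exon_seq,
                intron_seq,
                scheme,
                query_id=f"{gene.gene_id}.e{rec.index}",
                subject_id=intron_id(gene, ii),
                max_hits=config.max_hits_per_pair,
            ):
                if h.aligned_length < config.min_hit_len:
                    continue
                g_range = (intron_iv[0] + h.subject_range[0], intron_iv[0] + h.subject_range[1])
                genomic_hit = AlignmentHit(
                    h.query_id, h.query_range, gene.chrom, g_range, h.strand,
                    h.raw_score, h.bit_score, h.aligned_length, h.identity,
                )
                raw_hits.append(
                    StutterHit(
                        gene_id=gene.gene_id,
                        exon_index=rec.index,
                        intron_index=ii,
                        hit=genomic_hit,
                        proximal=ii in neighbors,
                        source_border_distance=_border_distance(exon_iv, intron_iv, h.query_range),
                        source_genomic_range=(
                            exon_iv[0] + h.query_range[0],
                            exon_iv[0] + h.query_range[1],
                        ),
                        border_pos=exon_iv[1] if intron_iv[0] >= exon_iv[1] else exon_iv[0],
                    )
                )

    # sub-threshold discard first so that noise hits cannot drag true
    # single-source copy clusters into the multi-source discard
    if config.bit_threshold is not None:
        raw_hits = [h for h in raw_hits if h.hit.bit_score > config.bit_threshold]
    hits = _discard_multi_source(raw_hits)
    if config.proximal_only:
        hits = [h for h in hits if h.proximal]
    return hits


def _discard_multi_source(hits: list[StutterHit]) -> list[StutterHit]:
    """Drop intronic target regions matched by more than one source exon.

    Overlapping target ranges within one intron are clustered; a cluster
    fed by two or more distinct exons is ambiguous and removed wholesale.
    """
    by_intron: dict[int, list[StutterHit]] = {}
    for h in hits:
        by_intron.setdefault(h.intron_index, []).append(h)
    kept: list[StutterHit] = []
    for group in by_intron.values():
        group.sort(key=lambda h: h.hit.subject_range)
        clusters: list[list[StutterHit]] = []
        cur_end = -1
        for h in group:
            s, e = h.hit.subject_range
            if clusters and s < cur_end:
                clusters[-1].append(h)
                cur_end = max(cur_end, e)
            else:
                clusters.append([h])
                cur_end = e
        for cl in clusters:
            if len({h.exon_index for h in cl}) == 1:
                kept.extend(cl)
    kept.sort(key=lambda h: (h.gene_id, h.exon_index, h.intron_index, h.hit.subject_range))
    return kept


def estimate_noise_threshold(
    genes: Sequence[GeneModel],
    genome: GenomeAssembly,
    seed: int = 0,
    scheme: ScoringScheme = SCREEN_SCHEME,
    min_hit_len: int = 20,
    exon_records: Mapping[str, Sequence[ExonRecord]] | None = None,
    n_shuffles: int = 10,
) -> NoiseEstimate:
    """Shuffled-control screen: exons vs shuffled introns of their gene.

    The returned ``max_bit`` is the confidence threshold (confident hits
    must be strictly above it); the median is diagnostic. Each intron is
    shuffled ``n_shuffles`` times so that the control covers several
    times more comparisons than the real screen — the control maximum
    then stochastically dominates the real noise maximum, which a
    same-size control cannot guarantee at desk scale (at genome scale a
    single shuffle per intron suffices).
    """
    if not any(g.introns for g in genes):
        raise ValueError("no gene has introns; cannot estimate a noise threshold")
    rng = random.Random(seed)
    bits: list[float] = []
    for gene in genes:
        exons = _gene_exon_records(gene, exon_records)
        if not gene.introns or not exons:
            continue
        exon_seqs = [genome.fetch(gene.chrom, *rec.interval) for rec in exons]
        for _rep in range(max(1, n_shuffles)):
            shuffled = [
                shuffle_sequence(genome.fetch(gene.chrom, *iv), rng)
                for iv in gene.introns
            ]
            for exon_seq in exon_seqs:
                for intron_seq in shuffled:
                    for h in local_align(exon_seq, intron_seq, scheme):
                        if h.aligned_length >= min_hit_len:
                            bits.append(h.bit_score)
    if not bits:
        raise ValueError(
            "shuffled control produced no hits; supply a fixed bit_threshold"
        )
    return NoiseEstimate(max(bits), statistics.median(bits), len(bits))


def summarize_expansions(
    hits: Iterable[StutterHit],
    genes: Mapping[str, GeneModel] | Sequence[GeneModel],
    exclusion_list: Iterable[str] = (),
) -> list[ExpansionSummary]:
    """One summary per (gene, exon, intron) pair with >=1 confident hit.

    ``exclusion_list`` stands in for manual curation: those gene ids are
    dropped. Span runs from the leftmost to the rightmost base over all
    copies plus the source exon border facing the target intron (the
    expansion area including its source).
    """
    if not isinstance(genes, Mapping):
        genes = {g.gene_id: g for g in genes}
    excluded = set(exclusion_list)
    by_pair: dict[tuple[str, int, int], list[StutterHit]] = {}
    for h in hits:
        if h.gene_id in excluded:
            continue
        by_pair.setdefault((h.gene_id, h.exon_index, h.intron_index), []).append(h)
    summaries = []
    for (gid, ei, ii), group in sorted(by_pair.items()):
        gene = genes[gid]
        starts = [h.hit.subject_range[0] for h in group] + [h.border_pos for h in group]
        ends = [h.hit.subject_range[1] for h in group] + [h.border_pos for h in group]
        summaries.append(
            ExpansionSummary(
                gene_id=gid,
                exon_index=ei,
                intron_index=ii,
                copy_count=len(group),
                span_bp=max(ends) - min(starts),
                hit_lengths=[h.hit.aligned_length for h in group],
                min_border_distance=min(h.source_border_distance for h in group),
                proximal=any(h.proximal for h in group),
                chrom=gene.chrom,
                intron_interval=gene.introns[ii],
            )
        )
    return summaries


def count_stuttering_introns_by_chromosome(
    summaries: Iterable[ExpansionSummary],
    chrom_class: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Distinct stuttering introns per chromosome (and size class)."""
    seen: dict[str, set[str]] = {}
    for s in summaries:
        seen.setdefault(s.chrom, set()).add(s.intron_id)
    rows = [
        {
            "chrom": chrom,
            "chrom_class": (chrom_class or {}).get(chrom, "unknown"),
            "n_stuttering_introns": len(ids),
        }
        for chrom, ids in sorted(seen.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "chrom_class", "n_stuttering_introns"])


def write_interact(path: str | Path, hits: Iterable[StutterHit]) -> None:
    """UCSC interact records: source exon fragment ↔ intronic copy."""
    with open(path, "w") as fh:
        for h in hits:
            ss, se = h.source_genomic_range
            ts, te = h.hit.subject_range
            chrom = h.hit.subject_id
            start, end = min(ss, ts), max(se, te)
            name = f"{h.gene_id}.e{h.exon_index}->i{h.intron_index}"
            score = min(1000, int(round(h.hit.bit_score * 10)))
            fh.write(
                "\t".join(
                    [
                        chrom, str(start), str(end), name, str(score),
                        f"{h.hit.bit_score:.1f}", ".", "0",
                        chrom, str(ss), str(se), f"{h.gene_id}.e{h.exon_index}", "+",
                        chrom, str(ts), str(te), f"{h.gene_id}.i{h.intron_index}",
                        h.hit.strand,
                    ]
                )
                + "\n"
            )


def summaries_to_frame(summaries: Iterable[ExpansionSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "gene_id": s.gene_id,
                "chrom": s.chrom,
                "exon_index": s.exon_index,
                "intron_index": s.intron_index,
                "intron_id": s.intron_id,
                "intron_start": s.intron_interval[0],
                "intron_end": s.intron_interval[1],
                "copy_count": s.copy_count,
                "span_bp": s.span_bp,
                "min_border_distance": s.min_border_distance,
                "proximal": s.proximal,
                "hit_lengths": ",".join(map(str, s.hit_lengths)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "exon_index", "intron_index", "intron_id",
            "intron_start", "intron_end", "copy_count", "span_bp",
            "min_border_distance", "proximal", "hit_lengths",
        ],
    )
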