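"""Dot-plot hit segments: self-similarity and cDNA-vs-genomic.

Uses the word-28 scheme of the printed dot-plot command; a stuttered
region shows as a filled rectangular block of off-diagonal hits, a
clean sequence as the main diagonal only. Output is a plain segment
table (x/y ranges, strand, bit score); rendering is a thin optional
raster on top.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .alignment import AlignmentHit, DOTPLOT_SCHEME, ScoringScheme, bit_score, local_align
from .annotation import GeneModel, GenomeAssembly, revcomp


def self_hits(
    seq: str,
    scheme: ScoringScheme = DOTPLOT_SCHEME,
    max_hits: int = 2000,
) -> list[AlignmentHit]:
    """All self-alignment hits of ``seq`` on both strands, symmetrized.

    The trivial main diagonal is always present (and maximal-scoring);
    for sequences shorter than the word size it is the only hit.
    """
    n = len(seq)
    diag = AlignmentHit(
        "x", (0, n), "y", (0, n), "+", n, bit_score(n, scheme), n, 1.0
    )
    if n < scheme.word_size:
        return [diag]
    hits = local_align(seq, seq, scheme, query_id="x", subject_id="y", max_hits=max_hits)
    out: dict[tuple, AlignmentHit] = {}
    for h in hits + [diag]:
        for g in (h, replace(h, query_range=h.subject_range, subject_range=h.query_range)):
            key = (g.query_range, g.subject_range, g.strand)
            if key not in out or g.raw_score > out[key].raw_score:
                out[key] = g
    return sorted(out.values(), key=lambda h: (-h.raw_score, h.query_range, h.subject_range))


def spliced_cdna(gene: GeneModel, genome: GenomeAssembly) -> str:
    """Virtual splice: exon sequences concatenated in transcript order."""
    if not gene.exons:
        raise ValueError(f"gene {gene.gene_id} has no exons; cDNA undefined")
    parts = [genome.fetch(gene.chrom, s, e) for s, e in gene.exons]
    cdna = "".join(parts)
    return revcomp(cdna) if gene.strand == "-" else cdna


def cdna_vs_genomic_hits(
    gene: GeneModel,
    genome: GenomeAssembly,
    scheme: ScoringScheme = DOTPLOT_SCHEME,
    max_hits: int = 2000,
) -> tuple[list[AlignmentHit], list[tuple[int, int]]]:
    """cDNA query vs the gene's genomic span, plus exon x-positions.

    Returns (hits, exon positions in cDNA coordinates) for overlay; hit
    subject coordinates are relative to the gene span start.
    """
    cdna = spliced_cdna(gene, genome)
    span = gene.span
    genomic = genome.fetch(gene.chrom, *span)
    hits = local_align(cdna, genomic, scheme, query_id="cdna", subject_id="genomic", max_hits=max_hits)
    positions = []
    offset = 0
    order = gene.exons if gene.strand == "+" else list(reversed(gene.exons))
    for s, e in order:
        positions.append((offset, offset + (e - s)))
        offset += e - s
    return hits, positions


def hits_to_frame(hits: Sequence[AlignmentHit]) -> pd.DataFrame:
    rows = [
        {
            "x_start": h.query_range[0],
            "x_end": h.query_range[1],
            "y_start": h.subject_range[0],
            "y_end": h.subject_range[1],
            "strand": h.strand,
            "bit_score": h.bit_score,
            "identity": h.identity,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=["x_start", "x_end", "y_start", "y_end", "strand", "bit_score", "identity"],
    )


def write_segments(path: str | Path, hits: Sequence[AlignmentHit]) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def render_png(path: str | Path, hits: Sequence[AlignmentHit], size: int | None = None) -> None:
    """Optional raster: one line per hit segment."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for h in hits:
        xs = h.query_range
        ys = h.subject_range if h.strand == "+" else (h.subject_range[1], h.subject_range[0])
        ax.plot(xs, ys, color="black", linewidth=0.7)
    ax.set_xlabel("x (bp)")
    ax.set_ylabel("y (bp)")
    if size:
        ax.set_xlim(0, size)
        ax.set_ylim(0, size)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
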