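"""Shared fixtures: handcrafted genes/genomes assembled from explicit
exon and intron sequences, so expected coordinates are known exactly."""

from __future__ import annotations

import random

import pytest

from dotstutter.annotation import GeneModel, GenomeAssembly


def random_seq(n: int, seed: int | random.Random = 0) -> str:
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def build_gene(
    exon_seqs: list[str],
    intron_seqs: list[str],
    gene_id: str = "g1",
    chrom: str = "chr1",
    strand: str = "+",
    flank: int = 50,
    chrom_class: str = "dot",
    seed: int = 99,
) -> tuple[GenomeAssembly, GeneModel]:
    """Assemble exon1 intron1 exon2 ... on one chromosome with flanks."""
    assert len(intron_seqs) == len(exon_seqs) - 1
    rng = random.Random(seed)
    parts = [random_seq(flank, rng)]
    pos = flank
    exons = []
    for i, ex in enumerate(exon_seqs):
        exons.append((pos, pos + len(ex)))
        parts.append(ex)
        pos += len(ex)
        if i < len(intron_seqs):
            parts.append(intron_seqs[i])
            pos += len(intron_seqs[i])
    parts.append(random_seq(flank, rng))
    seq = "".join(parts)
    genome = GenomeAssembly("test", {chrom: seq}, {chrom: chrom_class})
    return genome, GeneModel(gene_id, chrom, strand, exons)


@pytest.fixture
def rng():
    return random.Random(1234)
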