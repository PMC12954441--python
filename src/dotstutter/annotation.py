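"""Genome and gene-annotation layer.

Parses genome FASTA and exon-level GTF annotation (the UCSC xenoRefGene
dialect: one exon chain per gene id, no isoform structure), derives
introns as inter-exon gaps of length >= 10, merges overlapping genes,
and flags exons free of interspersed repeats.

Internal coordinates are 0-based half-open throughout; GTF (1-based
inclusive) is converted on read, BED is written natively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq

from .intervals import Interval, gaps_between, merge_intervals, total_overlap

log = logging.getLogger(__name__)

MIN_INTRON_LEN = 10

CHROM_CLASSES = ("macro", "micro", "dot")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeAssembly:
    """A named assembly: chromosome sequences plus a size-class map.

    ``chrom_class`` partitions (a subset of) chromosomes into the three
    avian size classes: macro-, micro- and dot chromosomes.
    """

    name: str
    sequences: dict[str, str]
    chrom_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("assembly has no sequences")
        for chrom, cls in self.chrom_class.items():
            if chrom not in self.sequences:
                raise ValueError(f"chrom_class names unknown chromosome {chrom!r}")
            if cls not in CHROM_CLASSES:
                raise ValueError(f"unknown chromosome class {cls!r} for {chrom!r}")
        for chrom, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {chrom!r}")

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Extract [start, end); reverse-complemented for strand '-'."""
        seq = self.sequences[chrom][start:end].upper()
        return revcomp(seq) if strand == "-" else seq

    @classmethod
    def from_fasta(
        cls,
        fasta: str | Path,
        class_table: str | Path | None = None,
        name: str | None = None,
    ) -> "GenomeAssembly":
        sequences = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")
        }
        classes = read_chrom_class_table(class_table) if class_table else {}
        classes = {c: k for c, k in classes.items() if c in sequences}
        return cls(name or Path(fasta).stem, sequences, classes)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")


def derive_introns(exons: Sequence[Interval], min_len: int = MIN_INTRON_LEN) -> list[Interval]:
    """Introns = maximal gaps of length >= min_len between consecutive exons.

    ``exons`` must be sorted and non-overlapping (merge first); anything
    else is a caller bug and raises.
    """
    for (s1, e1), (s2, _) in zip(exons, exons[1:]):
        if s2 < s1 or s2 < e1:
            raise ValueError("exons must be sorted and non-overlapping")
    return gaps_between(list(exons), min_len=min_len)


@dataclass
class GeneModel:
    """One gene's ordered exon chain and derived introns on a genome.

    Pre-merge models may carry overlapping raw exon intervals; introns
    are always derived from the merged-exon view. ``merged_from``
    records the source gene ids after :func:`merge_overlapping`.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    introns: list[Interval] = field(default_factory=list)
    merged_from: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        if not self.merged_from:
            self.merged_from = [self.gene_id]
        if not self.introns:
            self.introns = derive_introns(merge_intervals(self.exons))

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], max(e for _, e in self.exons))

    def exon_seq(self, genome: GenomeAssembly, index: int) -> str:
        s, e = self.exons[index]
        return genome.fetch(self.chrom, s, e)

    def intron_seq(self, genome: GenomeAssembly, index: int) -> str:
        s, e = self.introns[index]
        return genome.fetch(self.chrom, s, e)

    def neighbor_introns(self, exon_index: int) -> list[int]:
        """Indices of the (at most two) introns flanking an exon.

        With merged, sorted exons, intron ``i`` lies between exons ``i``
        and ``i+1``; exon ``e`` neighbours introns ``e-1`` and ``e``
        where those exist.
        """
        out = []
        for i in (exon_index - 1, exon_index):
            if 0 <= i < len(self.introns):
                s, e = self.introns[i]
                xs, xe = self.exons[exon_index]
                if e <= xs or s >= xe:  # guard: raw exon chains may differ
                    out.append(i)
        return out


@dataclass
class ExonRecord:
    """An exon with its position in the gene and a repeat-overlap flag."""

    gene_id: str
    index: int
    chrom: str
    interval: Interval
    repeat_free: bool = True


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, val = part.partition(" ")
            attrs[key] = val.strip().strip('"')
    return attrs


def parse_gene_annotation(
    gtf: str | Path | TextIO | Iterable[str],
    attribute: str = "gene_id",
) -> list[GeneModel]:
    """Read exon features from GTF into per-gene models (pre-merge).

    1-based inclusive GTF coordinates become 0-based half-open. Malformed
    records are skipped with a warning. A gene id spanning several
    chromosomes is split into per-chromosome models with suffixed ids.
    """
    if isinstance(gtf, (str, Path)):
        with open(gtf) as fh:
            return parse_gene_annotation(fh, attribute=attribute)

    by_gene: dict[tuple[str, str], dict] = {}
    for lineno, line in enumerate(gtf, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            log.warning("GTF line %d: %d fields, need 9 — skipped", lineno, len(fields))
            continue
        if fields[2] != "exon":
            continue
        try:
            start = int(fields[3]) - 1
            end = int(fields[4])
        except ValueError:
            log.warning("GTF line %d: non-numeric coordinates — skipped", lineno)
            continue
        if end <= start:
            log.warning("GTF line %d: empty/inverted interval — skipped", lineno)
            continue
        attrs = _parse_gtf_attributes(fields[8])
        gene_id = attrs.get(attribute)
        if gene_id is None:
            log.warning("GTF line %d: missing %s attribute — skipped", lineno, attribute)
            continue
        key = (gene_id, fields[0])
        rec = by_gene.setdefault(key, {"chrom": fields[0], "strand": fields[6], "exons": []})
        rec["exons"].append((start, end))

    # split multi-chromosome gene ids with suffixes
    chrom_counts: dict[str, int] = {}
    for gid, _ in by_gene:
        chrom_counts[gid] = chrom_counts.get(gid, 0) + 1

    genes = []
    for (gid, chrom), rec in sorted(by_gene.items()):
        name = gid if chrom_counts[gid] == 1 else f"{gid}__{chrom}"
        strand = rec["strand"] if rec["strand"] in ("+", "-") else "+"
        genes.append(GeneModel(name, chrom, strand, sorted(set(rec["exons"]))))
    return genes


def merge_overlapping(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Union genes whose spans overlap on the same chromosome.

    Overlapping genes become a single model whose exons are the interval
    union of all constituent exons; introns are re-derived afterwards,
    so the >=10 bp rule applies post-merge. Idempotent.
    """
    out: list[GeneModel] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda g: g.span)
        cluster: list[GeneModel] = []
        cluster_end = -1
        for g in group + [None]:  # type: ignore[list-item]
            if g is not None and cluster and g.span[0] < cluster_end:
                cluster.append(g)
                cluster_end = max(cluster_end, g.span[1])
                continue
            if cluster:
                if len(cluster) == 1:
                    src = cluster[0]
                    out.append(
                        GeneModel(
                            src.gene_id, src.chrom, src.strand,
                            merge_intervals(src.exons),
                            merged_from=sorted(src.merged_from),
                        )
                    )
                else:
                    sources = sorted({m for c in cluster for m in c.merged_from})
                    exons = merge_intervals([iv for c in cluster for iv in c.exons])
                    # strand of the longest constituent wins
                    lead = max(cluster, key=lambda c: c.span[1] - c.span[0])
                    out.append(
                        GeneModel(
                            "+".join(g.gene_id for g in cluster), chrom,
                            lead.strand, exons, merged_from=sources,
                        )
                    )
            if g is None:
                break
            cluster = [g]
            cluster_end = g.span[1]
    return out


def flag_repeat_free_exons(
    genes: Sequence[GeneModel],
    interspersed_repeats: Mapping[str, Sequence[Interval]],
) -> list[ExonRecord]:
    """Mark each exon repeat_free iff it has zero overlap with the repeats.

    ``interspersed_repeats`` maps chromosome -> intervals (RepeatMasker
    classes other than Simple_repeat / Low_complexity).
    """
    merged = {c: merge_intervals(ivs) for c, ivs in interspersed_repeats.items()}
    records = []
    for gene in genes:
        track = merged.get(gene.chrom, [])
        for i, iv in enumerate(gene.exons):
            free = total_overlap(iv, track) == 0
            records.append(ExonRecord(gene.gene_id, i, gene.chrom, iv, free))
    return records


def read_chrom_class_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV: chromosome name, class in {macro, micro, dot}."""
    classes = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, cls = line.split("\t")[:2]
            if cls not in CHROM_CLASSES:
                raise ValueError(f"unknown chromosome class {cls!r} for {chrom!r}")
            classes[chrom] = cls
    return classes


def write_bed(
    path: str | Path,
    records: Iterable[tuple[str, int, int, str]],
    score: int = 0,
    strand: str | None = None,
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in records:
            row = [chrom, str(start), str(end), name]
            if strand is not None:
                row += [str(score), strand]
            fh.write("\t".join(row) + "\n")


def read_bed(path: str | Path) -> Iterator[tuple[str, int, int, str]]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else "."
            yield f[0], int(f[1]), int(f[2]), name


def intron_id(gene: GeneModel, index: int) -> str:
    return f"{gene.gene_id}.i{index}"
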