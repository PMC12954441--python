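"""Synthetic genomes, stuttered genes, diploid populations and noisy reads.

The generator emulates the statistical structure the screens assume:

* chromosomes in the three avian size classes, with GC-rich background
  on dot chromosomes (GC 0.60 vs 0.42 elsewhere);
* genes whose dot-chromosome introns carry imperfect tandem repeat
  clusters — units of tens to hundreds of bases, each emitted copy
  within 20% edit distance of its consensus (enforced by rejection);
* a configurable subset of clusters seeded from an exon-border
  fragment: the repeated unit is the terminal 20–60 bp of the adjacent
  exon plus 0–40 bp of intron, so the source spans the splice border;
* diploid individuals whose variable introns differ by unit copy
  number (1–4 population alleles, Hardy–Weinberg draws);
* long reads with uniform length distribution and indel-dominated
  i.i.d. per-base errors.

Every engineered fact (units, copies, true intron lengths per allele,
per-read provenance and net indel inside each intron) is recorded in a
ground-truth ledger so downstream recovery is checkable exactly.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import edlib

from .annotation import GeneModel, GenomeAssembly, revcomp

BASES = "ACGT"


@dataclass
class ReadModel:
    """Long-read simulation parameters (rates are per base)."""

    length_range: tuple[int, int] = (5_000, 50_000)
    mismatch_rate: float = 0.01
    insertion_rate: float = 0.015
    deletion_rate: float = 0.015
    coverage: float = 30.0

    def __post_init__(self) -> None:
        for r in (self.mismatch_rate, self.insertion_rate, self.deletion_rate):
            if not 0 <= r <= 0.1:
                raise ValueError("error rates must be in [0, 0.1]")


@dataclass
class PopulationConfig:
    n_individuals: int = 11
    alleles_per_intron: tuple[int, int] = (1, 4)
    min_allele_gap: float = 0.15  # relative length gap between alleles


@dataclass
class SyntheticConfig:
    """Study conditions for the generator; defaults mirror the screens'
    assumptions (unit 20–200 bp, 1–44 copies, divergence <= 0.20)."""

    seed: int = 0
    n_genes: int = 12
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len_range: tuple[int, int] = (80, 250)
    intron_len_range: tuple[int, int] = (500, 2_000)
    intergenic_range: tuple[int, int] = (200, 800)
    stutter_fraction: float = 0.5
    exon_stutter_fraction: float = 0.5
    unit_len_range: tuple[int, int] = (20, 200)
    copies_range: tuple[int, int] = (1, 44)
    unit_divergence: float = 0.20
    exon_border_fragment: tuple[int, int] = (20, 60)
    intron_prefix_range: tuple[int, int] = (0, 40)
    dot_gc: float = 0.60
    background_gc: float = 0.42
    max_intron_len: int | None = None
    chrom_plan: tuple[tuple[str, str], ...] = (
        ("macro1", "macro"),
        ("micro1", "micro"),
        ("dot1", "dot"),
    )
    population: PopulationConfig = field(default_factory=PopulationConfig)
    read_model: ReadModel = field(default_factory=ReadModel)

    def __post_init__(self) -> None:
        if not 0 <= self.unit_divergence <= 0.20:
            raise ValueError("unit_divergence must be <= 0.20")


@dataclass
class AlleleTruth:
    length: int
    copies: int
    sequence: str = ""


@dataclass
class IntronTruth:
    intron_id: str
    gene_id: str
    intron_index: int
    chrom: str
    ref_length: int
    stuttered: bool = False
    exon_stutter: bool = False
    source_exon_index: int | None = None
    unit_consensus: str = ""
    copies: int = 0
    tandem_interval: tuple[int, int] | None = None  # genomic, on reference
    alleles: list[AlleleTruth] = field(default_factory=list)


@dataclass
class ReadTruth:
    read_id: str
    individual: str
    haplotype: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    net_indel_by_intron: dict[str, int] = field(default_factory=dict)


@dataclass
class GroundTruthLedger:
    seed: int
    introns: dict[str, IntronTruth] = field(default_factory=dict)
    genotypes: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)
    reads: dict[str, ReadTruth] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "introns": {k: asdict(v) for k, v in self.introns.items()},
            "genotypes": self.genotypes,
            "reads": {k: asdict(v) for k, v in self.reads.items()},
        }
        Path(path).write_text(json.dumps(data, indent=1))


def _random_seq(rng: random.Random, n: int, gc: float = 0.5) -> str:
    w = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices(BASES, weights=w, k=n))


def _mutate_unit(rng: random.Random, unit: str, divergence: float) -> str:
    """A copy of ``unit`` within ``divergence`` edit-distance fraction
    of the consensus (rejection-sampled; divergence <= 0.20 guaranteed)."""
    limit = int(0.20 * len(unit))
    budget = int(rng.uniform(0, divergence) * len(unit))
    for _ in range(50):
        chars = list(unit)
        for _ in range(budget):
            op = rng.random()
            pos = rng.randrange(len(chars)) if chars else 0
            if op < 0.5 or not chars:
                chars[pos] = rng.choice(BASES)
            elif op < 0.75:
                chars.insert(pos, rng.choice(BASES))
            elif len(chars) > 1:
                del chars[pos]
        copy = "".join(chars)
        if edlib.align(copy, unit)["editDistance"] <= limit:
            return copy
    return unit


@dataclass
class _Segment:
    kind: str  # "fix" | "intron"
    seq: str
    intron_id: str = ""


def make_genome(
    config: SyntheticConfig,
    seed: int | None = None,
) -> tuple[GenomeAssembly, list[GeneModel], GroundTruthLedger, dict]:
    """Build the reference assembly, gene models and ground truth.

    Returns (assembly, genes, ledger, layout); ``layout`` maps each
    chromosome to its ordered segment list (fixed sequence vs intron
    slots) so that per-haplotype genomes can be reassembled with
    alternative intron alleles.
    """
    rng = random.Random(config.seed if seed is None else seed)
    ledger = GroundTruthLedger(seed=config.seed if seed is None else seed)
    n_chroms = len(config.chrom_plan)
    genes_per_chrom = [
        config.n_genes // n_chroms + (1 if i < config.n_genes % n_chroms else 0)
        for i in range(n_chroms)
    ]

    sequences: dict[str, str] = {}
    chrom_class: dict[str, str] = {}
    genes: list[GeneModel] = []
    layout: dict[str, list[_Segment]] = {}
    gene_no = 0

    for (chrom, cls), n_genes_here in zip(config.chrom_plan, genes_per_chrom):
        gc = config.dot_gc if cls == "dot" else config.background_gc
        segments: list[_Segment] = []
        pos = 0

        def emit_fix(seq: str) -> None:
            nonlocal pos
            segments.append(_Segment("fix", seq))
            pos += len(seq)

        emit_fix(_random_seq(rng, rng.randint(*config.intergenic_range), gc))
        for _ in range(n_genes_here):
            gene_id = f"g{gene_no:03d}"
            gene_no += 1
            n_exons = rng.randint(*config.exons_per_gene)
            strand = rng.choice("+-")
            exon_ivs: list[tuple[int, int]] = []
            exon_seqs = [
                _random_seq(rng, rng.randint(*config.exon_len_range), 0.5)
                for _ in range(n_exons)
            ]
            for xi in range(n_exons):
                exon_start = pos
                emit_fix(exon_seqs[xi])
                exon_ivs.append((exon_start, pos))
                if xi == n_exons - 1:
                    break
                iid = f"{gene_id}.i{xi}"
                target_len = rng.randint(*config.intron_len_range)
                truth = IntronTruth(
                    iid, gene_id, xi, chrom, ref_length=target_len
                )
                stutter = cls == "dot" and rng.random() < config.stutter_fraction
                if stutter:
                    exon_borne = rng.random() < config.exon_stutter_fraction
                    copies = rng.randint(*config.copies_range)
                    if exon_borne:
                        a = rng.randint(*config.exon_border_fragment)
                        b = rng.randint(*config.intron_prefix_range)
                        prefix = _random_seq(rng, b, gc)
                        unit = exon_seqs[xi][-a:] + prefix
                        tandem = prefix + "".join(
                            _mutate_unit(rng, unit, config.unit_divergence)
                            for _ in range(copies)
                        )
                        truth.exon_stutter = True
                        truth.source_exon_index = xi
                    else:
                        unit = _random_seq(rng, rng.randint(*config.unit_len_range), gc)
                        tandem = "".join(
                            _mutate_unit(rng, unit, config.unit_divergence)
                            for _ in range(copies)
                        )
                    filler_len = max(50, target_len - len(tandem))
                    intron_seq = tandem + _random_seq(rng, filler_len, gc)
                    if (
                        config.max_intron_len is not None
                        and len(intron_seq) > config.max_intron_len
                    ):
                        raise ValueError(
                            f"intron {iid}: engineered tandem ({len(tandem)} bp, "
                            f"{copies} copies) exceeds max_intron_len "
                            f"{config.max_intron_len}"
                        )
                    truth.stuttered = True
                    truth.unit_consensus = unit
                    truth.copies = copies
                    truth.tandem_interval = (pos, pos + len(tandem))
                else:
                    intron_seq = _random_seq(rng, target_len, gc)
                truth.ref_length = len(intron_seq)
                truth.alleles = [AlleleTruth(len(intron_seq), truth.copies, intron_seq)]
                ledger.introns[iid] = truth
                segments.append(_Segment("intron", intron_seq, iid))
                pos += len(intron_seq)
            genes.append(
                GeneModel(gene_id, chrom, strand, exon_ivs)
            )
            emit_fix(_random_seq(rng, rng.randint(*config.intergenic_range), gc))
        sequences[chrom] = "".join(s.seq for s in segments)
        chrom_class[chrom] = cls
        layout[chrom] = segments

    assembly = GenomeAssembly("synthetic", sequences, chrom_class)
    return assembly, genes, ledger, layout


@dataclass
class Individual:
    individual_id: str
    haplotypes: list[dict[str, str]]  # two chrom -> sequence maps
    intron_truth: dict[str, tuple[int, int]] = field(default_factory=dict)
    intron_lengths: dict[str, tuple[int, int]] = field(default_factory=dict)


def make_population(
    layout: dict[str, list[_Segment]],
    ledger: GroundTruthLedger,
    config: SyntheticConfig,
    seed: int = 1,
) -> list[Individual]:
    """Realize population alleles and draw diploid individuals.

    Every stuttered intron receives 1–4 population alleles built by
    adding whole unit copies so consecutive allele lengths differ by at
    least ``min_allele_gap``; individuals draw two alleles uniformly
    (Hardy–Weinberg). Non-stuttered introns stay monomorphic.
    """
    rng = random.Random(seed)
    pop = config.population
    for truth in ledger.introns.values():
        if not truth.stuttered or not truth.unit_consensus:
            continue
        n_alleles = rng.randint(*pop.alleles_per_intron)
        unit = truth.unit_consensus
        ts, te = truth.tandem_interval or (0, 0)
        base_seq = truth.alleles[0].sequence
        # tandem block is a prefix of the intron sequence by construction
        tandem_len = (te - ts) if truth.tandem_interval else 0
        prev_len = truth.ref_length
        for _ in range(1, n_alleles):
            need = int(pop.min_allele_gap * prev_len) + 1
            delta = max(1, -(-need // len(unit)))
            extra = "".join(
                _mutate_unit(rng, unit, config.unit_divergence) for _ in range(delta)
            )
            seq = base_seq[:tandem_len] + extra + base_seq[tandem_len:]
            prev_copies = truth.alleles[-1].copies
            truth.alleles.append(AlleleTruth(len(seq), prev_copies + delta, seq))
            base_seq, prev_len = seq, len(seq)

    individuals = []
    for k in range(pop.n_individuals):
        ind_id = f"ind{k:02d}"
        genotype: dict[str, tuple[int, int]] = {}
        for iid, truth in ledger.introns.items():
            n = len(truth.alleles)
            genotype[iid] = (rng.randrange(n), rng.randrange(n))
        ledger.genotypes[ind_id] = genotype
        haplotypes = []
        lengths: dict[str, list[int]] = {}
        for h in (0, 1):
            chroms = {}
            for chrom, segments in layout.items():
                parts = []
                for seg in segments:
                    if seg.kind == "intron":
                        ai = genotype[seg.intron_id][h]
                        parts.append(ledger.introns[seg.intron_id].alleles[ai].sequence)
                    else:
                        parts.append(seg.seq)
                chroms[chrom] = "".join(parts)
            haplotypes.append(chroms)
        ind = Individual(ind_id, haplotypes)
        ind.intron_truth = genotype
        ind.intron_lengths = {
            iid: tuple(ledger.introns[iid].alleles[a].length for a in pair)
            for iid, pair in genotype.items()
        }
        individuals.append(ind)
    return individuals


def _corrupt(
    rng: random.Random, seq: str, model: ReadModel
) -> tuple[str, list[int]]:
    """Apply i.i.d. per-base errors; returns (read, per-ref-pos net indel)."""
    out = []
    net = [0] * len(seq)
    for i, base in enumerate(seq):
        if rng.random() < model.deletion_rate:
            net[i] -= 1
            continue
        if rng.random() < model.mismatch_rate:
            out.append(rng.choice([b for b in BASES if b != base]))
        else:
            out.append(base)
        if rng.random() < model.insertion_rate:
            out.append(rng.choice(BASES))
            net[i] += 1
    return "".join(out), net


def _haplotype_intron_intervals(
    layout: dict[str, list[_Segment]],
    ledger: GroundTruthLedger,
    genotype: dict[str, tuple[int, int]],
    hap: int,
) -> dict[str, list[tuple[str, int, int]]]:
    """chrom -> [(intron_id, start, end)] in haplotype coordinates."""
    out: dict[str, list[tuple[str, int, int]]] = {}
    for chrom, segments in layout.items():
        pos = 0
        ivs = []
        for seg in segments:
            if seg.kind == "intron":
                ai = genotype[seg.intron_id][hap]
                n = ledger.introns[seg.intron_id].alleles[ai].length
                ivs.append((seg.intron_id, pos, pos + n))
                pos += n
            else:
                pos += len(seg.seq)
        out[chrom] = ivs
    return out


def simulate_reads(
    individual: Individual,
    model: ReadModel,
    seed: int = 2,
    ledger: GroundTruthLedger | None = None,
    layout: dict[str, list[_Segment]] | None = None,
    read_prefix: str | None = None,
) -> list[tuple[str, str]]:
    """Noisy reads from a diploid individual, uniform start positions.

    Read count is coverage × diploid genome length ÷ mean read length;
    half the reads are reverse-complemented. With ``ledger`` and
    ``layout`` supplied, per-read truth (source haplotype, span, net
    indel within each fully covered intron) is recorded in the ledger.
    """
    rng = random.Random(seed)
    prefix = read_prefix or individual.individual_id
    hap_lens = [sum(len(s) for s in h.values()) for h in individual.haplotypes]
    mean_len = sum(model.length_range) / 2.0
    n_reads = max(1, round(model.coverage * sum(hap_lens) / 2.0 / mean_len))
    intron_maps = None
    if ledger is not None and layout is not None:
        genotype = individual.intron_truth
        intron_maps = [
            _haplotype_intron_intervals(layout, ledger, genotype, h) for h in (0, 1)
        ]
    reads = []
    for k in range(n_reads):
        hap = rng.randrange(2)
        chroms = sorted(individual.haplotypes[hap])
        weights = [len(individual.haplotypes[hap][c]) for c in chroms]
        chrom = rng.choices(chroms, weights=weights)[0]
        L = len(individual.haplotypes[hap][chrom])
        rlen = min(rng.randint(*model.length_range), L)
        start = rng.randint(0, L - rlen)
        template = individual.haplotypes[hap][chrom][start : start + rlen]
        read, net = _corrupt(rng, template, model)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            read = revcomp(read)
        read_id = f"{prefix}_r{k}"
        if intron_maps is not None and ledger is not None:
            truth = ReadTruth(
                read_id, individual.individual_id, hap, chrom, start, start + rlen, strand
            )
            for iid, s, e in intron_maps[hap][chrom]:
                if s >= start and e <= start + rlen:
                    truth.net_indel_by_intron[iid] = sum(net[s - start : e - start])
            ledger.reads[read_id] = truth
        reads.append((read_id, read))
    return reads


def write_reads_fastq(path: str | Path, reads: Sequence[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_gtf(path: str | Path, genes: Sequence[GeneModel], source: str = "dotstutter") -> None:
    """Exon features, 1-based inclusive, gene_id attribute."""
    with open(path, "w") as fh:
        for g in genes:
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f'gene_id "{g.gene_id}";\n'
                )


def write_chrom_classes(path: str | Path, chrom_class: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for chrom, cls in sorted(chrom_class.items()):
            fh.write(f"{chrom}\t{cls}\n")


def write_trf_bed(path: str | Path, ledger: GroundTruthLedger) -> None:
    """TRF-style BED of the engineered tandem clusters (reference coords)."""
    rows = []
    for truth in ledger.introns.values():
        if truth.stuttered and truth.tandem_interval:
            rows.append((truth.chrom, *truth.tandem_interval, truth.intron_id))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, s, e, name in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def write_repeatmasker_out(
    path: str | Path,
    assembly: GenomeAssembly,
    genes: Sequence[GeneModel],
    ledger: GroundTruthLedger,
    seed: int = 3,
    n_decoys_per_chrom: int = 3,
) -> None:
    """RepeatMasker-style .out: interspersed decoy annotations placed in
    intergenic space (never on exons of stuttered source genes) plus the
    engineered tandems as Simple_repeat rows."""
    rng = random.Random(seed)
    lines = [
        "   SW  perc perc perc  query      position in query           matching"
        "       repeat              position in  repeat",
        "score  div. del. ins.  sequence    begin     end    (left)    repeat"
        "         class/family         begin  end (left)   ID",
        "",
    ]
    row = 0
    for chrom, seq in sorted(assembly.sequences.items()):
        for _ in range(n_decoys_per_chrom):
            L = len(seq)
            w = rng.randint(150, 400)
            s = rng.randint(0, max(0, L - w))
            row += 1
            lines.append(
                f"  250  10.0  0.0  0.0  {chrom}  {s + 1}  {s + w}  ({L - s - w})"
                f"  +  CR1-like  LINE/CR1  1  {w}  (0)  {row}"
            )
    for truth in sorted(ledger.introns.values(), key=lambda t: t.intron_id):
        if truth.stuttered and truth.tandem_interval:
            s, e = truth.tandem_interval
            L = len(assembly.sequences[truth.chrom])
            row += 1
            lines.append(
                f"  200  12.0  0.0  0.0  {truth.chrom}  {s + 1}  {e}  ({L - e})"
                f"  +  ({truth.unit_consensus[:6]})n  Simple_repeat  1  {e - s}  (0)  {row}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bundle(
    outdir: str | Path,
    config: SyntheticConfig,
) -> dict[str, Path]:
    """Generate a full artifact bundle (FASTA/GTF/BED/.out/TSV/ledger)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assembly, genes, ledger, layout = make_genome(config)
    individuals = make_population(layout, ledger, config, seed=config.seed + 1)
    paths = {
        "genome": outdir / "genome.fa",
        "gtf": outdir / "genes.gtf",
        "classes": outdir / "chrom_classes.tsv",
        "trf": outdir / "tandem_repeats.bed",
        "rmout": outdir / "repeatmasker.out",
        "ledger": outdir / "ground_truth.json",
    }
    assembly.to_fasta(paths["genome"])
    write_gtf(paths["gtf"], genes)
    write_chrom_classes(paths["classes"], assembly.chrom_class)
    write_trf_bed(paths["trf"], ledger)
    write_repeatmasker_out(paths["rmout"], assembly, genes, ledger, seed=config.seed + 2)
    for i, ind in enumerate(individuals):
        reads = simulate_reads(
            ind, config.read_model, seed=config.seed + 100 + i, ledger=ledger, layout=layout
        )
        p = outdir / f"reads_{ind.individual_id}.fastq"
        write_reads_fastq(p, reads)
        paths[f"reads_{ind.individual_id}"] = p
    ledger.to_json(paths["ledger"])
    return paths
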