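"""Per-sample intron length measurement from long reads and allele calling.

For every intron, the two flanking exons serve as anchors: each is
searched in each read (bit score > 50, alignment length within 20% of
the exon length). Where both anchors land in the same orientation, the
read-space distance between their intron-facing ends is one length
observation. Per intron, observations are cut into two classes with
Jenks optimization (the exact minimum within-class sum-of-squares split
at k = 2); classes whose means differ by no more than 10% of the larger
are merged, giving one or two length alleles per sample.

Five staged filters then remove false positives: minimum allele length,
minimum read support, allele read-count balance, within-allele length
coherence, and a blacklist of introns that show spurious variability
when the haploid reference itself is resequenced in silico.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alignment import ANCHOR_SCHEME, AlignmentHit, ScoringScheme, local_align
from .annotation import GeneModel, GenomeAssembly, intron_id

log = logging.getLogger(__name__)

MIN_ANCHOR_EXON_LEN = 10


@dataclass(frozen=True)
class AnchorCriteria:
    """Acceptance rules for an exon anchor inside a read."""

    min_bit_score: float = 50.0
    max_length_deviation: float = 0.20
    min_exon_len: int = MIN_ANCHOR_EXON_LEN

    def __post_init__(self) -> None:
        if not 0 < self.max_length_deviation < 1:
            raise ValueError("max_length_deviation must be in (0, 1)")


@dataclass
class ReadIntronMeasurement:
    sample_id: str
    read_id: str
    intron_id: str
    length_bp: int
    left_anchor: AlignmentHit
    right_anchor: AlignmentHit
    orientation: str


@dataclass
class Allele:
    mean_length: float
    read_count: int
    member_lengths: list[int] = field(default_factory=list)


@dataclass
class SampleAlleleCall:
    sample_id: str
    intron_id: str
    alleles: list[Allele]
    passed_filters: bool = True
    fail_reasons: list[str] = field(default_factory=list)


def find_anchor(
    read: str,
    exon_seq: str,
    criteria: AnchorCriteria = AnchorCriteria(),
    scheme: ScoringScheme = ANCHOR_SCHEME,
    all_hits: bool = False,
) -> AlignmentHit | list[AlignmentHit] | None:
    """Best exon hit in the read passing the anchor criteria, or None.

    Ties on bit score break toward the leftmost read coordinate. With
    ``all_hits`` every passing hit is returned (chimera detection).
    """
    if len(exon_seq) < criteria.min_exon_len:
        return [] if all_hits else None
    passing = [
        h
        for h in local_align(exon_seq, read, scheme, query_id="exon", subject_id="read")
        if h.bit_score > criteria.min_bit_score
        and abs(h.aligned_length - len(exon_seq)) <= criteria.max_length_deviation * len(exon_seq)
    ]
    if all_hits:
        return sorted(passing, key=lambda h: (-h.bit_score, h.subject_range[0]))
    if not passing:
        return None
    return min(passing, key=lambda h: (-h.bit_score, h.subject_range[0]))


def measure_intron(
    read: str,
    left_exon_hit: AlignmentHit,
    right_exon_hit: AlignmentHit,
) -> int | None:
    """Read-space distance between the intron-facing anchor ends.

    ``left``/``right`` refer to genomic order (left exon precedes the
    intron). On a reverse-complement read the left exon lies to the
    right in read coordinates; orientation is normalized away. Returns
    None for inconsistent or overlapping anchors.
    """
    if left_exon_hit.strand != right_exon_hit.strand:
        return None
    if left_exon_hit.strand == "+":
        gap = right_exon_hit.subject_range[0] - left_exon_hit.subject_range[1]
    else:
        gap = left_exon_hit.subject_range[0] - right_exon_hit.subject_range[1]
    if gap < 0:
        log.debug("overlapping anchors (gap %d); read skipped", gap)
        return None
    return gap


def jenks_two_break(lengths: Sequence[float]) -> tuple[list[float], list[float]]:
    """Exact Jenks natural-breaks partition at k = 2.

    Over all splits of the sorted values into a low and a high class,
    pick the one minimizing the within-class sum of squared deviations
    (prefix-sum evaluation, O(n) after sorting). The second class may be
    empty (zero-variance input).
    """
    xs = sorted(float(x) for x in lengths)
    n = len(xs)
    if n == 0:
        raise ValueError("no lengths")
    if n == 1 or xs[0] == xs[-1]:
        return xs, []
    a = np.asarray(xs)
    c1 = np.cumsum(a)
    c2 = np.cumsum(a * a)

    def ssd(lo: int, hi: int) -> float:  # [lo, hi) within-class SSD
        if hi - lo <= 1:
            return 0.0
        s = c1[hi - 1] - (c1[lo - 1] if lo else 0.0)
        s2 = c2[hi - 1] - (c2[lo - 1] if lo else 0.0)
        return float(s2 - s * s / (hi - lo))

    best_k, best = 1, float("inf")
    for k in range(1, n):
        v = ssd(0, k) + ssd(k, n)
        if v < best - 1e-12:
            best, best_k = v, k
    return xs[:best_k], xs[best_k:]


def call_alleles(
    lengths: Sequence[int | float],
    merge_threshold: float = 0.10,
    sample_id: str = "",
    intron_id_: str = "",
) -> SampleAlleleCall:
    """Jenks two-class split, then merge classes closer than 10% in mean."""
    lo, hi = jenks_two_break(lengths)
    groups = [g for g in (lo, hi) if g]
    if len(groups) == 2:
        m1, m2 = (float(np.mean(g)) for g in groups)
        larger = max(m1, m2)
        if larger == 0 or abs(m2 - m1) <= merge_threshold * larger:
            groups = [groups[0] + groups[1]]
    alleles = [
        Allele(float(np.mean(g)), len(g), [int(x) for x in g]) for g in groups
    ]
    alleles.sort(key=lambda al: al.mean_length)
    return SampleAlleleCall(sample_id, intron_id_, alleles)


MIN_ALLELE_LENGTH = 100
MIN_READS = 4  # strict: need > 4
MAX_COUNT_RATIO = 10.0
MAX_MEMBER_DEVIATION = 0.10


def apply_sample_filters(
    call: SampleAlleleCall,
    in_simulated_blacklist: bool = False,
) -> SampleAlleleCall:
    """The five staged false-positive filters, applied in order:

    (i) at least one allele longer than 100 bp, (ii) more than 4
    supporting reads in total, (iii) allele read counts within 10× of
    each other, (iv) every member length within 10% of its allele mean,
    (v) intron absent from the simulated-reference blacklist.
    """
    reasons = []
    if not any(al.mean_length > MIN_ALLELE_LENGTH for al in call.alleles):
        reasons.append("min_length")
    if sum(al.read_count for al in call.alleles) <= MIN_READS:
        reasons.append("min_reads")
    if len(call.alleles) == 2:
        c1, c2 = (al.read_count for al in call.alleles)
        if max(c1, c2) > MAX_COUNT_RATIO * min(c1, c2):
            reasons.append("count_ratio")
    for al in call.alleles:
        if al.mean_length > 0 and any(
            abs(x - al.mean_length) > MAX_MEMBER_DEVIATION * al.mean_length
            for x in al.member_lengths
        ):
            reasons.append("member_deviation")
            break
    if in_simulated_blacklist:
        reasons.append("simulated_blacklist")
    call.fail_reasons = reasons
    call.passed_filters = not reasons
    return call


@dataclass
class IntronRegion:
    """An intron plus its two flanking anchor exons."""

    intron_id: str
    gene_id: str
    chrom: str
    interval: tuple[int, int]
    left_exon: tuple[int, int]
    right_exon: tuple[int, int]


def intron_regions(
    genes: Sequence[GeneModel],
    min_exon_len: int = MIN_ANCHOR_EXON_LEN,
) -> list[IntronRegion]:
    """Anchor regions for every intron whose flanking exons are usable.

    Exons shorter than ``min_exon_len`` are ignored: the nearest long
    enough exon on each side anchors the measurement, so the measured
    span can include short interleaved exons (rare; logged).
    """
    regions = []
    for gene in genes:
        exons = gene.exons
        for ii, (is_, ie) in enumerate(gene.introns):
            left = [iv for iv in exons if iv[1] <= is_ and iv[1] - iv[0] >= min_exon_len]
            right = [iv for iv in exons if iv[0] >= ie and iv[1] - iv[0] >= min_exon_len]
            if not left or not right:
                log.debug("intron %s lacks usable anchor exons", intron_id(gene, ii))
                continue
            lx = max(left, key=lambda iv: iv[1])
            rx = min(right, key=lambda iv: iv[0])
            if lx[1] != is_ or rx[0] != ie:
                log.debug("intron %s anchored by non-adjacent exons", intron_id(gene, ii))
            regions.append(
                IntronRegion(intron_id(gene, ii), gene.gene_id, gene.chrom, (is_, ie), lx, rx)
            )
    return regions


def measure_reads(
    reads: Iterable[tuple[str, str]],
    regions: Sequence[IntronRegion],
    genome: GenomeAssembly,
    sample_id: str = "sample",
    criteria: AnchorCriteria = AnchorCriteria(),
    scheme: ScoringScheme = ANCHOR_SCHEME,
) -> list[ReadIntronMeasurement]:
    """Type every read against every intron region.

    A read contributes at most one measurement per intron; reads with
    more than one candidate anchor pair for the same intron (chimeras)
    are discarded for that intron.
    """
    exon_seqs: dict[tuple[str, tuple[int, int]], str] = {}
    for r in regions:
        for iv in (r.left_exon, r.right_exon):
            key = (r.chrom, iv)
            if key not in exon_seqs:
                exon_seqs[key] = genome.fetch(r.chrom, *iv)
    measurements = []
    for read_id, seq in reads:
        anchor_cache: dict[tuple[str, tuple[int, int]], list[AlignmentHit]] = {}

        def anchors(region_chrom: str, exon_iv: tuple[int, int]) -> list[AlignmentHit]:
            key = (region_chrom, exon_iv)
            if key not in anchor_cache:
                anchor_cache[key] = find_anchor(
                    seq, exon_seqs[key], criteria, scheme, all_hits=True
                )
            return anchor_cache[key]

        for region in regions:
            left = anchors(region.chrom, region.left_exon)
            if not left:
                continue
            right = anchors(region.chrom, region.right_exon)
            if not right:
                continue
            pairs = []
            for lh in left:
                for rh in right:
                    if lh.strand == rh.strand:
                        gap = measure_intron(seq, lh, rh)
                        if gap is not None:
                            pairs.append((lh, rh, gap))
            if len(pairs) != 1:
                if len(pairs) > 1:
                    log.debug("read %s chimeric for %s; skipped", read_id, region.intron_id)
                continue
            lh, rh, gap = pairs[0]
            measurements.append(
                ReadIntronMeasurement(
                    sample_id, read_id, region.intron_id, gap, lh, rh, lh.strand
                )
            )
    return measurements


def call_sample(
    measurements: Iterable[ReadIntronMeasurement],
    sample_id: str = "sample",
    blacklist: Iterable[str] = (),
    merge_threshold: float = 0.10,
) -> list[SampleAlleleCall]:
    """Group measurements per intron, call alleles, apply the filters."""
    blk = set(blacklist)
    by_intron: dict[str, list[int]] = {}
    for m in measurements:
        by_intron.setdefault(m.intron_id, []).append(m.length_bp)
    calls = []
    for iid, lengths in sorted(by_intron.items()):
        call = call_alleles(lengths, merge_threshold, sample_id, iid)
        calls.append(apply_sample_filters(call, in_simulated_blacklist=iid in blk))
    return calls


def read_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Load reads from FASTA or FASTQ (quality ignored)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def simulate_reference_reads(
    genome: GenomeAssembly,
    seed: int = 0,
    min_len: int = 5_000,
    max_len: int = 50_000,
    coverage: float = 100.0,
) -> list[tuple[str, str]]:
    """Error-free reads sampled uniformly from the haploid reference.

    Lengths are uniform on [min_len, max_len]; the read count is
    coverage × genome length ÷ mean read length. Chromosomes shorter
    than min_len are emitted whole (logged). Used to build the artifact
    blacklist: the reference is haploid, so any intron typed with two
    alleles from these reads is a method artifact.
    """
    rng = random.Random(seed)
    chroms = sorted(genome.sequences)
    lens = {c: len(genome.sequences[c]) for c in chroms}
    total = sum(lens.values())
    mean_len = (min_len + max_len) / 2.0
    n_reads = max(1, round(coverage * total / mean_len))
    weights = [lens[c] / total for c in chroms]
    reads = []
    for k in range(n_reads):
        chrom = rng.choices(chroms, weights=weights)[0]
        L = lens[chrom]
        if L <= min_len:
            log.info("chromosome %s shorter than %d bp; sampled whole", chrom, min_len)
            reads.append((f"sim_{k}", genome.sequences[chrom]))
            continue
        rlen = min(rng.randint(min_len, max_len), L)
        start = rng.randint(0, L - rlen)
        seq = genome.sequences[chrom][start : start + rlen]
        if rng.random() < 0.5:
            from .annotation import revcomp

            seq = revcomp(seq)
        reads.append((f"sim_{k}", seq))
    return reads


def build_simulation_blacklist(
    genome: GenomeAssembly,
    genes: Sequence[GeneModel],
    seed: int = 0,
    criteria: AnchorCriteria = AnchorCriteria(),
    scheme: ScoringScheme = ANCHOR_SCHEME,
    **sim_kwargs,
) -> set[str]:
    """Introns showing >1 allele when the haploid reference is re-typed."""
    reads = simulate_reference_reads(genome, seed=seed, **sim_kwargs)
    regions = intron_regions(genes)
    measurements = measure_reads(reads, regions, genome, "simulated", criteria, scheme)
    blacklist = set()
    by_intron: dict[str, list[int]] = {}
    for m in measurements:
        by_intron.setdefault(m.intron_id, []).append(m.length_bp)
    for iid, lengths in by_intron.items():
        if len(call_alleles(lengths).alleles) > 1:
            blacklist.add(iid)
    return blacklist


def calls_to_frame(calls: Iterable[SampleAlleleCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        for k, al in enumerate(c.alleles):
            rows.append(
                {
                    "sample_id": c.sample_id,
                    "intron_id": c.intron_id,
                    "allele": k,
                    "mean_length": al.mean_length,
                    "read_count": al.read_count,
                    "passed_filters": c.passed_filters,
                    "fail_reasons": ";".join(c.fail_reasons),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "intron_id", "allele", "mean_length",
            "read_count", "passed_filters", "fail_reasons",
        ],
    )
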