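# Methods

## Coordinates, annotation and gene models

All internal coordinates are 0-based half-open; GTF (1-based inclusive)
is converted on read and BED is written natively, so only one
convention exists inside the package. The gene annotation is treated
the way cross-species mRNA alignment tracks (xenoRefGene-style) are
structured: one exon chain per gene id, no isoform modelling. Introns
are the maximal gaps of length ≥ 10 bp between consecutive merged
exons; overlapping genes (by genomic span, transitively) are merged
into a single model whose exons are the interval union, and the ≥ 10 bp
intron rule is applied after merging. A gene id mapped to several
chromosomes is split into per-chromosome models with suffixed ids,
preserving the locality of the per-gene screen. Exon/intron order is
by genomic start regardless of strand; minus-strand sequence is
reverse-complemented at extraction time only.

The two screens hold separate exon filters: the stuttering screen uses
only exons with zero overlap with interspersed repeats (every
RepeatMasker class except Simple_repeat and Low_complexity), while
read anchoring ignores exons shorter than 10 bp but does not apply the
repeat filter.

## Alignment engine

Scoring is match +1, mismatch −2, gap open 0 / gap extend 2 — i.e. a
linear gap cost of 2 per gap position. Raw scores map to bit scores via
(λS − ln K)/ln 2 with λ = 1.19, K = 0.46, the NCBI gapped parameters
for this scheme; they reproduce BLAST+ printed bit scores to within its
print rounding (≤ 0.5 bit), verified by the optional external-blastn
adapter, which runs the same scheme through a BLAST+ binary and parses
tabular output. N bases never match and never seed.

The screens need *all* confident local matches, not just the optimal
one — tandem copies are counted as separate hits (HSPs). A single
global Smith–Waterman matrix cannot deliver that: under a linear gap
cost a strong alignment (e.g. the exact main diagonal of a
self-comparison) reaches across neighbouring diagonals through cheap
gap chains and absorbs parallel repeat hits into one merged path. The
engine is therefore BLAST-like:

* exact k-mer seeds (word size 7 for the screen, 11 for read
  anchoring, 28 for dot plots) are grouped into clusters of nearby
  diagonals;
* each cluster is searched by banded dynamic programming (±24
  diagonals around the seed band), so hits on different repeat offsets
  can never shadow each other;
* candidate end cells are cells not improvable by any extension step;
  traceback truncates at internal score valleys deeper than 30 (an
  X-drop analogue: a tandem-offset jump costs twice the offset, while
  ≤ 20% divergence rarely dips a true alignment by more than ~20);
* hits overlapping an accepted higher-scoring hit by > 50% on both
  axes *within the same diagonal band* are dropped as redundant.

Small word-7 problems (exon vs intron) use a full matrix instead, where
shadowing cannot arise because any gap jump costs more than the hits
involved; gap runs are capped at 15 positions there for the same
reason. On 500 random short-query pairs the engine's optimal score
equals an independent dynamic-programming oracle exactly (the scheme's
optimum is unambiguous; band and cap do not bind on such inputs).

## Exon-stuttering screen

Each repeat-free exon is aligned against every intron of its own gene,
both strands; hits shorter than 20 aligned bases are dropped. The
confidence threshold is the *maximum* bit score observed in a shuffled
control — the same exons aligned against random permutations of the
same introns (composition-preserving). Confident hits must be strictly
greater. At genome scale a single shuffle per intron gives the control
the same breadth as the real screen; at desk scale that makes the
control maximum and the real noise maximum exchangeable draws, so
roughly half of clean genomes would show one spurious "confident" hit.
The estimator therefore shuffles each intron 10 times by default
(configurable), giving the control an order of magnitude more
comparisons than the real screen; when several replicate genomes form
one study, their controls are pooled into a single threshold, exactly
as a genome-wide screen derives one threshold for all loci.

Two discard rules apply: sub-threshold hits, and intronic target
regions matched by more than one source exon (clusters of overlapping
target ranges fed by ≥ 2 exons are removed wholesale). They are
independent conditions, but order matters for cluster formation: the
bit filter runs first so that a sub-threshold noise hit from a second
exon cannot drag a genuine single-source copy cluster into the
multi-source discard (observed on synthetic data: 3 of 10 true copies
lost under the opposite order).

Hits are labelled proximal when the target intron is one of the (at
most two) introns flanking the source exon. Border distance is
measured on the query exon relative to the edge shared with the target
intron; 0 means the alignment touches the border. Expansion span runs
from the leftmost to the rightmost base over all copies *plus the
source exon border* facing the target intron — the border, not the
whole source fragment, anchors the span, so a fragment ending exactly
at the border contributes its end coordinate. Only the trivial
identity self-alignment is excluded from copy counting (exon and
intron never overlap, so no other self-hit exists). The manual
curation step of a real study is represented by an exclusion-list
input; the pipeline reports pre- and post-exclusion gene tallies.

## Read typing

Anchors are the best-scoring hit of each flanking exon in the read
(bit > 50, |aligned length − exon length| ≤ 20% of exon length), ties
broken by leftmost read coordinate; both anchors must share
orientation. The intron length is the read-space distance between the
intron-facing alignment ends. Alignment ends, not projected reference
exon boundaries, define the measurement; any systematic ±few-bp offset
cancels in the 10% relative comparisons used downstream. Reads with
more than one consistent anchor pair for the same intron (chimeras,
tandem gene duplicates) are discarded for that intron. Read-to-gene
assignment is direct anchor search of every read against the exon
panel — adequate at desk scale; at biobank scale an external long-read
mapper would restrict the search per region first, which changes
nothing in the criteria above.

Allele calling cuts the per-intron length list at the split minimizing
the within-class sum of squared deviations over all split points of
the sorted list — the exact Jenks natural-breaks optimum for k = 2,
computed with prefix sums in O(n) after sorting. Classes whose means
differ by ≤ 10% of the larger mean merge into one allele (a homozygote
call); the same 10% rule defines population-level allele uniqueness,
keeping the two levels consistent.

Five staged filters, exactly as listed: (i) at least one allele longer
than 100 bp; (ii) more than 4 supporting reads ("> 4" read as ≥ 5);
(iii) two-allele read counts within 10× of each other; (iv) every
member length within 10% of its allele mean (scale-free by
construction); (v) intron absent from the simulated-reference
blacklist. The blacklist is built by resequencing the haploid
reference in silico — error-free reads, uniform positions, lengths
uniform on [5,000, 50,000], read count = coverage × genome length ÷
mean read length (default 100×) — and typing them: the reference has
one haplotype, so any intron called with two alleles is a method
artifact (in practice, cross-anchoring between near-identical
paralogs).

## Population aggregation

Each passing sample contributes exactly two allele draws (a homozygote
contributes its single allele twice), matching the rarefaction unit
"n = 6 = three diploid samples". Pairwise "> 10% different" is not an
equivalence relation, so unique alleles are formed by greedy centroid
clustering in ascending order: a draw joins the current cluster when
its mean is within 10% (relative to the larger of draw and running
centroid) of the cluster's draw-weighted mean, else it opens a new
cluster. The procedure is deterministic and order-independent given
the sort.

Allele richness is Hurlbert rarefaction — the expected number of
distinct alleles in a uniform subsample of n = 6 draws without
replacement, computed by the closed-form binomial expression (a
Monte-Carlo subsampler is provided as an independent cross-check and
agrees within 0.01 at 10⁵ resamples). Introns with fewer than 6 draws
are reported at n = N with a flag and excluded from Ar-based headline
tallies. Ar = 1 classifies an intron as stable, Ar > 1 as variable;
heterozygosity is the fraction of passing samples with two post-merge
alleles. Category effects are univariate OLS fits of log(response) on
an intercept plus a category indicator, the category compared against
all other variable introns; β is the log-fold change and p comes from
the two-sided t-statistic.

## Repeat coverage and dot plots

The combined simple-repeat track is the interval union of RepeatMasker
Simple_repeat-class ranges (class matched by prefix, so subfamilies
count) and the full Tandem Repeats Finder annotation supplied as BED;
per-intron coverage is covered bases over intron length, with overlaps
collapsed by the union. RepeatMasker .out parsing accepts the classic
15-column layout and header-less variants.

Dot plots use the word-28 scheme of the printed command line; the
E-value cutoff of the original command is approximated by the
word-28-seed requirement plus a raw-score floor of 28 (≈ 48 bits),
which on random kilobase sequences leaves exactly the main diagonal.
Self-hit sets are symmetrized; the main diagonal is always present and
maximal. Output is a plain segment table; rendering is a thin optional
raster.

## Synthetic data: what it emulates, and what it does not

The generator builds chromosomes in the three avian size classes with
i.i.d. background sequence (GC 0.60 on dot chromosomes, 0.42
elsewhere — echoing the GC-rich dot context without modelling biased
gene conversion). Dot-chromosome introns receive tandem clusters at a
configurable fraction: units of 20–200 bp repeated 1–44 times (the
generator's defaults), each emitted copy kept within 20% edit distance
of its consensus by rejection sampling (checked with edlib). Half of
the clusters, by default, are seeded across the exon border: the unit
is the terminal 20–60 bp of the adjacent exon plus 0–40 bp of intron,
so the source spans the splice junction and the screen should measure
border distance 0. Population alleles differ by whole unit copies,
consecutive allele lengths at least 15% apart by default; individuals
draw two alleles uniformly (Hardy–Weinberg). Reads are sampled
uniformly by position from a random haplotype, half
reverse-complemented, with i.i.d. per-base substitutions, insertions
and deletions; a ledger records every unit consensus, copy count, true
allele length, per-read provenance and the net indel inside each fully
covered intron, so downstream recovery is checkable exactly.

Not emulated: homopolymer-aware error profiles, read-quality
stratification, breed structure or kinship, linkage between introns
(alleles are drawn independently per intron), and real repeat-family
sequence. Passing tests therefore demonstrate the correctness of the
screens' logic and their robustness to indel-dominated noise at the
stated rates — not performance against basecaller-specific artifacts
or population structure.

## Problem sizes and validation conditions

The validation experiments (shared by the test suite and
`scripts/acceptance.py`) use desk-scale conditions chosen to exercise
every stage: 500 random pairs for the alignment oracle; 1,000 random
lists for the Jenks oracle; 50 count vectors × 10⁵ resamples for
rarefaction; a 50-gene dot-chromosome genome with ~20 engineered
exon-border expansions (3–10 copies, ≤ 20% divergence) for screen
recovery; 50 stutter-free five-gene genomes under one pooled-control
threshold for specificity; six diploid samples at 30× coverage and 3%
indel error (alleles ≥ 15% apart) for classification; and 100
replicated heterozygous introns (30 reads each) for allele-mean
recovery. Classification truth is the *realized* allele diversity
among the sampled individuals, since a screen cannot see population
alleles that no sampled bird carries.

## Known limitations

* Bit-score constants replicate one BLAST+ build; thresholds like the
  published 42.1 are build-specific, which is why the screen re-derives
  its own shuffled-control threshold rather than assuming
  transferability.
* The banded search requires an exact seed word; alignments of ≥ 20 bp
  at the divergence limit can, rarely, lack a seed and be missed in the
  seeded (long-subject) path. The full-matrix path used for the screen
  itself has no such gap.
* Copy counts for heavily diverged units are lower bounds: a copy whose
  exon-borne fragment has drifted past the scoring threshold is
  indistinguishable from background.
* The length measurement inherits anchor-end wobble of a few bases
  under indel noise; all downstream rules are relative (10%) and absorb
  it.
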