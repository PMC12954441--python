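"""Local alignment with BLASTn-style scoring and bit scores.

The screens need *all* confident local matches of a short query inside a
longer subject (tandem copies produce many HSPs per pair), under the
scheme match +1 / mismatch −2 / gap open 0 / gap extend 2 — a linear gap
cost of 2 per gap position. The engine is a Smith–Waterman matrix fill
(numba) with candidate-cell declumping so that distinct copies yield
distinct hits, plus exact k-mer seeding to restrict the matrix to
windows when the subject is long (read anchoring, word-28 dot plots).

Raw scores are converted to Karlin–Altschul bit scores
``(λ·S − ln K) / ln 2``. The default λ=1.19, K=0.46 are the NCBI gapped
parameters for reward 1 / penalty −2 / gap 0,2 and reproduce BLAST+
printed bit scores to within rounding.

N bases never match and never seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numba import njit

from .annotation import revcomp

__all__ = [
    "ScoringScheme",
    "AlignmentHit",
    "local_align",
    "best_raw_score",
    "bit_score",
    "min_raw_for_bit",
    "shuffle_sequence",
    "SCREEN_SCHEME",
    "DOTPLOT_SCHEME",
    "ANCHOR_SCHEME",
]

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """BLASTn-style scoring plus Karlin–Altschul statistics.

    gap_open 0 / gap_extend 2 means every gap position costs 2 — the
    linear gap model of the printed command line. ``word_size`` controls
    seeding: full dynamic programming is used for small problems, exact
    ``word_size``-mer seeds restrict the search otherwise. ``min_raw_score``
    is the reporting floor on the raw score.
    """

    match_reward: int = 1
    mismatch_penalty: int = -2
    gap_open: int = 0
    gap_extend: int = 2
    lam: float = 1.19
    K: float = 0.46
    word_size: int = 7
    min_hit_len: int = 1
    min_raw_score: int = 11
    #: split composite paths at internal score dips larger than this
    #: (X-drop analogue; a tandem-offset gap jump costs 2×offset, while
    #: <=20% divergence rarely dips a true alignment by more than ~20)
    xdrop: int = 30

    @property
    def max_gap_run(self) -> int:
        """Longest allowed consecutive gap run (xdrop / per-position cost)."""
        return max(1, self.xdrop // max(1, self.gap_extend))

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        if not (self.match_reward > 0 > self.mismatch_penalty):
            raise ValueError("need match_reward > 0 > mismatch_penalty")


#: screen scheme: short-query search, 7-mer seeds
SCREEN_SCHEME = ScoringScheme()
#: dot-plot scheme: long exact seeds as in the printed word_size 28 command
DOTPLOT_SCHEME = ScoringScheme(word_size=28, min_raw_score=28)
#: read-anchoring scheme: 11-mer seeds keep long-read search tractable
ANCHOR_SCHEME = ScoringScheme(word_size=11, min_raw_score=20)


@dataclass
class AlignmentHit:
    """One local alignment (HSP) with query/subject coordinates.

    Coordinates are 0-based half-open on the forward strands of both
    sequences; ``strand`` '-' means the reverse complement of the query
    matches the subject forward strand.
    """

    query_id: str
    query_range: tuple[int, int]
    subject_id: str
    subject_range: tuple[int, int]
    strand: str
    raw_score: int
    bit_score: float
    aligned_length: int
    identity: float

    def flipped(self, query_len: int, subject_len: int) -> "AlignmentHit":
        """The equivalent hit against the reverse-complemented subject."""
        qs, qe = self.query_range
        ss, se = self.subject_range
        return replace(
            self,
            subject_range=(subject_len - se, subject_len - ss),
            strand="-" if self.strand == "+" else "+",
        )


def bit_score(raw: int | float, scheme: ScoringScheme = SCREEN_SCHEME) -> float:
    """Karlin–Altschul normalized score: (λS − ln K)/ln 2."""
    return (scheme.lam * raw - math.log(scheme.K)) / math.log(2.0)


def min_raw_for_bit(bit: float, scheme: ScoringScheme = SCREEN_SCHEME) -> int:
    """Smallest integer raw score whose bit score exceeds ``bit``."""
    raw = (bit * math.log(2.0) + math.log(scheme.K)) / scheme.lam
    r = math.floor(raw) + 1
    while bit_score(r - 1, scheme) > bit:
        r -= 1
    return r


def shuffle_sequence(seq: str, seed: int | random.Random) -> str:
    """Uniform random permutation of the sequence's characters."""
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    chars = list(seq)
    rng.shuffle(chars)
    return "".join(chars)


@njit(cache=False)
def _sw_fill(q, s, match, mismatch, gap, maxrun):  # pragma: no cover - numba
    """Smith–Waterman with linear gap cost and a cap on consecutive gap
    run length (X-drop analogue: arbitrarily long gap chains would let a
    high-scoring diagonal cast a 'shadow' over nearby parallel repeats)."""
    m, n = len(q), len(s)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    gv = np.full(n + 1, -(10**9), dtype=np.int64)  # vertical-gap scores
    gvl = np.zeros(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        qi = q[i - 1]
        gh = -(10**9)
        ghl = 0
        for j in range(1, n + 1):
            sj = s[j - 1]
            sc = match if (qi == sj and qi != 4) else mismatch
            # vertical gap (consuming query rows)
            cand = H[i - 1, j] - gap
            if gv[j] - gap > cand and gvl[j] < maxrun:
                gv[j] = gv[j] - gap
                gvl[j] += 1
            else:
                gv[j] = cand
                gvl[j] = 1
            # horizontal gap (consuming subject cols)
            cand = H[i, j - 1] - gap
            if gh - gap > cand and ghl < maxrun:
                gh = gh - gap
                ghl += 1
            else:
                gh = cand
                ghl = 1
            h = H[i - 1, j - 1] + sc
            if gv[j] > h:
                h = int(gv[j])
            if gh > h:
                h = int(gh)
            if h < 0:
                h = 0
            H[i, j] = h
    return H


@njit(cache=False)
def _traceback(H, q, s, i, j, match, mismatch, gap, xdrop, maxrun):  # pragma: no cover - numba
    """Walk back from end cell (i, j); returns
    (q_start, s_start, aligned_length, n_matches, raw_score).

    Gap steps are taken as whole runs (up to ``maxrun``). The walk
    truncates at the last internal score valley deeper than ``xdrop``: a
    path merging two alignments through a costly jump is split at the
    valley and only the suffix alignment is reported.
    """
    end_score = H[i, j]
    alen = 0
    nmatch = 0
    min_h = end_score
    min_i, min_j = i, j
    min_alen, min_nmatch = 0, 0
    while i > 0 and j > 0 and H[i, j] > 0:
        eq = q[i - 1] == s[j - 1] and q[i - 1] != 4
        sc = match if eq else mismatch
        moved = False
        if H[i, j] == H[i - 1, j - 1] + sc:
            alen += 1
            if eq:
                nmatch += 1
            i -= 1
            j -= 1
            moved = True
        else:
            for k in range(1, maxrun + 1):
                if i - k >= 0 and H[i, j] == H[i - k, j] - gap * k:
                    alen += k
                    i -= k
                    moved = True
                    break
                if j - k >= 0 and H[i, j] == H[i, j - k] - gap * k:
                    alen += k
                    j -= k
                    moved = True
                    break
        if not moved:  # cell is a fresh local start
            break
        h = H[i, j]
        if h < min_h:
            min_h = h
            min_i, min_j = i, j
            min_alen, min_nmatch = alen, nmatch
        elif h > min_h + xdrop:
            return min_i, min_j, min_alen, min_nmatch, end_score - min_h
    return min_i, min_j, min_alen, min_nmatch, end_score - min_h


_FULL_DP_CELLS = 4_000_000


def _word_hashes(arr: np.ndarray, word: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling polynomial hashes of all ``word``-windows (uint64 wraparound;
    equal words always hash equal, so seeds are never missed) and a mask of
    windows free of N."""
    x = arr.astype(np.uint64)
    n = len(x) - word + 1
    mult = np.uint64(1099511628211)
    h = np.zeros(n, dtype=np.uint64)
    clean = np.ones(n, dtype=bool)
    isn = arr == 4
    for k in range(word):
        h = h * mult + x[k : k + n]
        clean &= ~isn[k : k + n]
    return h, clean


_BAND_PAD = 24  # diagonal drift allowed around a seed cluster


def _seed_diag_clusters(q: np.ndarray, s: np.ndarray, word: int) -> list[tuple[int, int]]:
    """Diagonal ranges (dlo, dhi) of exact shared ``word``-mer seeds.

    Seeds are grouped into clusters of nearby diagonals; each cluster is
    later searched with banded dynamic programming. Restricting the
    search to seed bands is what keeps distinct parallel repeat copies
    distinct: a global matrix would let a strong alignment reach across
    diagonals through gap chains and absorb its neighbours.
    """
    m, n = len(q), len(s)
    if m < word or n < word:
        return []
    qh, qc = _word_hashes(q, word)
    sh, sc = _word_hashes(s, word)
    index: dict[int, list[int]] = {}
    for qi in np.nonzero(qc)[0]:
        index.setdefault(int(qh[qi]), []).append(int(qi))
    diags: set[int] = set()
    shared = np.nonzero(sc & np.isin(sh, qh[qc]))[0]
    for j in shared:
        for qi in index.get(int(sh[j]), ()):
            diags.add(int(j) - qi)
    if not diags:
        return []
    out = []
    run = sorted(diags)
    lo = prev = run[0]
    for d in run[1:]:
        if d - prev > _BAND_PAD:
            out.append((lo, prev))
            lo = d
        prev = d
    out.append((lo, prev))
    return out


@njit(cache=False)
def _banded_fill(q, s, dlo, W, match, mismatch, gap):  # pragma: no cover - numba
    """Smith–Waterman restricted to diagonals [dlo, dlo+W): H[i, w] with
    j = i + dlo + (w - 1); sentinel columns w=0 and w=W+1 are walls."""
    m, n = len(q), len(s)
    NEG = -(10**9)
    H = np.full((m + 2, W + 2), NEG, dtype=np.int64)
    for w in range(W + 2):
        H[0, w] = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for w in range(1, W + 1):
            j = i + dlo + (w - 1)
            if j < 1 or j > n:
                continue
            sc = match if (qi == s[j - 1] and qi != 4) else mismatch
            h = H[i - 1, w] + sc  # diagonal: same w in previous row
            v = H[i - 1, w + 1] - gap  # vertical gap (consumes query)
            if v > h:
                h = v
            u = H[i, w - 1] - gap  # horizontal gap (consumes subject)
            if u > h:
                h = u
            if h < 0:
                h = 0
            H[i, w] = h
    for w in range(W + 2):  # pad row for end-cell tests
        H[m + 1, w] = NEG
    return H


@njit(cache=False)
def _banded_traceback(H, q, s, i, w, dlo, match, mismatch, gap, xdrop):  # pragma: no cover - numba
    """Banded analogue of the matrix traceback; returns
    (q_start, s_start, aligned_length, n_matches, raw_score)."""
    end_score = H[i, w]
    alen = 0
    nmatch = 0
    min_h = end_score
    min_i, min_w = i, w
    min_alen, min_nmatch = 0, 0
    W = H.shape[1] - 2
    while i > 0:
        j = i + dlo + (w - 1)
        if j <= 0 or H[i, w] <= 0:
            break
        eq = q[i - 1] == s[j - 1] and q[i - 1] != 4
        sc = match if eq else mismatch
        if H[i, w] == H[i - 1, w] + sc:
            alen += 1
            if eq:
                nmatch += 1
            i -= 1
        elif w + 1 <= W + 1 and H[i, w] == H[i - 1, w + 1] - gap:
            alen += 1
            i -= 1
            w += 1
        elif w - 1 >= 0 and H[i, w] == H[i, w - 1] - gap:
            alen += 1
            w -= 1
        else:
            break
        h = H[i, w]
        if h < min_h:
            min_h = h
            min_i, min_w = i, w
            min_alen, min_nmatch = alen, nmatch
        elif h > min_h + xdrop:
            break
    if min_h < 0:
        min_h = 0
    sj = min_i + dlo + (min_w - 1)
    return min_i, sj, min_alen, min_nmatch, end_score - min_h


def _banded_extract(
    H: np.ndarray,
    q: np.ndarray,
    s: np.ndarray,
    dlo: int,
    scheme: ScoringScheme,
    max_hits: int,
) -> list[tuple[int, int, int, int, int, int, int]]:
    """End cells + traceback in banded coordinates."""
    m = len(q)
    W = H.shape[1] - 2
    E = H[1 : m + 1, 1 : W + 1]
    diag_ext = H[2 : m + 2, 1 : W + 1]  # (i+1, w)
    vert_ext = H[2 : m + 2, 0:W]  # (i+1, w-1)
    horz_ext = H[1 : m + 1, 2 : W + 2]  # (i, w+1)
    ends = (E >= scheme.min_raw_score) & (E >= diag_ext) & (E >= vert_ext) & (E >= horz_ext)
    cand = np.argwhere(ends)
    if cand.size == 0:
        return []
    ci = cand[:, 0] + 1
    cw = cand[:, 1] + 1
    scores = np.asarray(H[ci, cw])
    order = np.argsort(-scores, kind="stable")[:20000]
    ci, cw = ci[order], cw[order]
    cj = ci + dlo + (cw - 1)
    alive = np.ones(len(ci), dtype=bool)
    out: list[tuple[int, int, int, int, int, int, int]] = []
    for pos in range(len(ci)):
        if len(out) >= max_hits:
            break
        if not alive[pos]:
            continue
        i, w = int(ci[pos]), int(cw[pos])
        qi, sj, alen, nmatch, raw = _banded_traceback(
            H, q, s, i, w, dlo, scheme.match_reward, scheme.mismatch_penalty,
            scheme.gap_extend, scheme.xdrop,
        )
        qa, qb, sa, sb = qi, i, sj, i + dlo + (w - 1)
        # mask candidate ends merging into this path (same band segment)
        alive &= ~((ci > qa) & (ci <= qb) & (cj > sa) & (cj <= sb))
        if raw >= scheme.min_raw_score and qb > qa:
            out.append((qa, qb, sa, sb, int(raw), alen, nmatch))
    return out


def _declump(
    hits: list[tuple[int, int, int, int, int, int, int]],
    max_hits: int,
) -> list[tuple[int, int, int, int, int, int, int]]:
    """Drop hits overlapping an accepted higher-scoring hit by >50% on
    both axes within the same diagonal band."""
    slack = 16
    hits = sorted(hits, key=lambda t: (-t[4], t[2], t[0]))
    accepted: list[tuple[int, int, int, int, int, int, int]] = []
    for qa, qb, sa, sb, raw, alen, nmatch in hits:
        dmin, dmax = min(sa - qa, sb - qb), max(sa - qa, sb - qb)
        reject = False
        for xa, xb, ya, yb, *_ in accepted:
            qo = max(0, min(qb, xb) - max(qa, xa))
            so = max(0, min(sb, yb) - max(sa, ya))
            if qo > 0.5 * (qb - qa) and so > 0.5 * (sb - sa):
                da = min(ya - xa, yb - xb)
                db = max(ya - xa, yb - xb)
                if dmin <= db + slack and dmax >= da - slack:
                    reject = True
                    break
        if not reject:
            accepted.append((qa, qb, sa, sb, raw, alen, nmatch))
            if len(accepted) >= max_hits:
                break
    return accepted


def _extract_hits(
    H: np.ndarray,
    q: np.ndarray,
    s: np.ndarray,
    scheme: ScoringScheme,
    s_offset: int,
    max_hits: int,
) -> list[tuple[int, int, int, int, int, int, int]]:
    """Declumped HSPs from a filled matrix.

    Returns tuples (q_start, q_end, s_start, s_end, raw, alen, nmatch)
    with subject coordinates shifted by ``s_offset``.
    """
    # candidate end cells: above the floor AND not improvable by any
    # extension step — interior cells of a path or its gap shadow never
    # qualify, so candidates are (nearly) one per distinct alignment
    E = H[1:, 1:]
    P = np.zeros((E.shape[0] + 1, E.shape[1] + 1), dtype=E.dtype)
    P[:-1, :-1] = E
    ends = (E >= scheme.min_raw_score) & (E >= P[1:, 1:]) & (E >= P[1:, :-1]) & (E >= P[:-1, 1:])
    cand = np.argwhere(ends) + 1  # back to H coordinates
    if cand.size == 0:
        return []
    scores = H[cand[:, 0], cand[:, 1]]
    order = np.argsort(-scores, kind="stable")
    cand = cand[order][:20000]
    ci = cand[:, 0].astype(np.int64)
    cj = cand[:, 1].astype(np.int64)
    cdiag = cj - ci
    alive = np.ones(len(ci), dtype=bool)
    accepted: list[tuple[int, int, int, int, int, int, int]] = []
    boxes: list[tuple[int, int, int, int, int, int]] = []  # qa qb sa sb dmin dmax
    slack = 16  # diagonal drift tolerated within one alignment (gaps cost 2/pos)
    pos = 0
    while pos < len(ci) and len(accepted) < max_hits:
        if not alive[pos]:
            pos += 1
            continue
        i, j = int(ci[pos]), int(cj[pos])
        qi, sj, alen, nmatch, raw = _traceback(
            H, q, s, i, j, scheme.match_reward, scheme.mismatch_penalty,
            scheme.gap_extend, scheme.xdrop, scheme.max_gap_run,
        )
        qa, qb, sa, sb = qi, i, sj, j
        dmin, dmax = min(sa - qa, sb - qb), max(sa - qa, sb - qb)
        # redundant iff >50% overlap on BOTH axes AND on the same diagonal
        # band as an accepted hit (off-diagonal self-hits stay distinct)
        reject = False
        for xa, xb, ya, yb, da, db in boxes:
            qo = max(0, min(qb, xb) - max(qa, xa))
            so = max(0, min(sb, yb) - max(sa, ya))
            if (
                qo > 0.5 * (qb - qa)
                and so > 0.5 * (sb - sa)
                and dmin <= db + slack
                and dmax >= da - slack
            ):
                reject = True
                break
        # mask remaining candidate end-cells lying on this alignment's own
        # diagonal band: their tracebacks merge into the same path
        alive &= ~(
            (ci > qa) & (ci <= qb) & (cj > sa) & (cj <= sb)
            & (cdiag >= dmin - slack) & (cdiag <= dmax + slack)
        )
        if not reject and raw >= scheme.min_raw_score:
            boxes.append((qa, qb, sa, sb, dmin, dmax))
            accepted.append(
                (qa, qb, sa + s_offset, sb + s_offset, int(raw), alen, nmatch)
            )
        pos += 1
    return accepted


def _align_one_strand(
    qarr: np.ndarray,
    sarr: np.ndarray,
    scheme: ScoringScheme,
    max_hits: int,
) -> list[tuple[int, int, int, int, int, int, int]]:
    m, n = len(qarr), len(sarr)
    if m == 0 or n == 0:
        return []
    if m * n <= _FULL_DP_CELLS and scheme.word_size <= 7:
        H = _sw_fill(
            qarr, sarr, scheme.match_reward, scheme.mismatch_penalty,
            scheme.gap_extend, scheme.max_gap_run,
        )
        return _extract_hits(H, qarr, sarr, scheme, 0, max_hits)
    raw_hits = []
    for dlo0, dhi0 in _seed_diag_clusters(qarr, sarr, scheme.word_size):
        dlo = dlo0 - _BAND_PAD
        W = dhi0 - dlo0 + 1 + 2 * _BAND_PAD
        H = _banded_fill(
            qarr, sarr, dlo, W, scheme.match_reward, scheme.mismatch_penalty,
            scheme.gap_extend,
        )
        raw_hits.extend(_banded_extract(H, qarr, sarr, dlo, scheme, max_hits))
    return _declump(raw_hits, max_hits)


def local_align(
    query: str,
    subject: str,
    scheme: ScoringScheme = SCREEN_SCHEME,
    query_id: str = "query",
    subject_id: str = "subject",
    max_hits: int = 200,
    strands: Sequence[str] = ("+", "-"),
) -> list[AlignmentHit]:
    """All mutually non-redundant local alignments on both strands.

    Hits below ``scheme.min_raw_score`` or shorter than
    ``scheme.min_hit_len`` are not reported; tandem copies of a query
    region in the subject produce one hit per copy. Sorted by
    descending raw score.
    """
    if not query or not subject:
        return []
    sarr = encode(subject)
    qlen = len(query)
    hits: list[AlignmentHit] = []
    for strand in strands:
        qseq = query if strand == "+" else revcomp(query)
        qarr = encode(qseq)
        for qa, qb, sa, sb, raw, alen, nmatch in _align_one_strand(
            qarr, sarr, scheme, max_hits
        ):
            if alen < scheme.min_hit_len:
                continue
            if strand == "-":
                qa, qb = qlen - qb, qlen - qa
            hits.append(
                AlignmentHit(
                    query_id=query_id,
                    query_range=(qa, qb),
                    subject_id=subject_id,
                    subject_range=(sa, sb),
                    strand=strand,
                    raw_score=raw,
                    bit_score=bit_score(raw, scheme),
                    aligned_length=alen,
                    identity=nmatch / alen if alen else 0.0,
                )
            )
    hits.sort(key=lambda h: (-h.raw_score, h.subject_range, h.strand))
    return hits[:max_hits]


def best_raw_score(query: str, subject: str, scheme: ScoringScheme = SCREEN_SCHEME) -> int:
    """Optimal Smith–Waterman raw score (both strands), 0 if none."""
    if not query or not subject:
        return 0
    sarr = encode(subject)
    best = 0
    for qseq in (query, revcomp(query)):
        H = _sw_fill(
            encode(qseq), sarr, scheme.match_reward, scheme.mismatch_penalty,
            scheme.gap_extend, scheme.max_gap_run,
        )
        best = max(best, int(H.max()))
    return best


def blast_local_align(
    query: str,
    subject: str,
    scheme: ScoringScheme = SCREEN_SCHEME,
    task: str = "blastn-short",
    evalue: float = 1000.0,
) -> list[AlignmentHit]:
    """Optional adapter: run an external ``blastn`` binary with the same
    scheme and parse its 12-column tabular output into AlignmentHits.

    Used for cross-validating bit-score calibration; raises
    ``FileNotFoundError`` when BLAST+ is not installed.
    """
    import subprocess
    import tempfile
    from pathlib import Path as _P

    with tempfile.TemporaryDirectory() as tmp:
        qf, sf = _P(tmp, "q.fa"), _P(tmp, "s.fa")
        qf.write_text(f">q\n{query}\n")
        sf.write_text(f">s\n{subject}\n")
        cmd = [
            "blastn", "-query", str(qf), "-subject", str(sf), "-task", task,
            "-reward", str(scheme.match_reward),
            "-penalty", str(scheme.mismatch_penalty),
            "-gapopen", str(scheme.gap_open), "-gapextend", str(scheme.gap_extend),
            "-dust", "no", "-soft_masking", "false", "-evalue", str(evalue),
            "-outfmt", "6 qstart qend sstart send sstrand score bitscore length pident",
        ]
        res = subprocess.run(cmd, capture_output=True, text=True, check=True)
    hits = []
    for line in res.stdout.splitlines():
        qs, qe, ss, se, sstrand, raw, bits, length, pident = line.split("\t")
        strand = "+" if sstrand == "plus" else "-"
        s0, s1 = (int(ss) - 1, int(se)) if strand == "+" else (int(se) - 1, int(ss))
        hits.append(
            AlignmentHit(
                "q", (int(qs) - 1, int(qe)), "s", (s0, s1), strand,
                int(raw), float(bits), int(length), float(pident) / 100.0,
            )
        )
    hits.sort(key=lambda h: (-h.raw_score, h.subject_range, h.strand))
    return hits
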