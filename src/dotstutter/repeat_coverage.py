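"""Simple-repeat annotation handling and per-intron coverage.

The combined simple-repeat track is the union of the RepeatMasker
``Simple_repeat`` class and the full Tandem Repeats Finder annotation
(as BED). Per-intron coverage is covered bases divided by intron
length, with overlaps collapsed by the union so no base double-counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import read_bed
from .intervals import Interval, merge_intervals, total_overlap

SIMPLE_CLASSES = ("Simple_repeat",)
EXCLUDED_INTERSPERSED = ("Simple_repeat", "Low_complexity")


@dataclass
class RepeatTrack:
    """Class-labelled repeat intervals grouped by chromosome."""

    intervals: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    source: str = "combined"

    def by_class(self, classes: Sequence[str] | None = None, invert: bool = False) -> dict[str, list[Interval]]:
        """Chromosome -> merged intervals, filtered by class prefix."""
        out: dict[str, list[Interval]] = {}
        for chrom, ivs in self.intervals.items():
            sel = []
            for s, e, cls in ivs:
                hit = classes is None or any(cls.startswith(c) for c in classes)
                if hit != invert:
                    sel.append((s, e))
            if sel:
                out[chrom] = merge_intervals(sel)
        return out


def parse_repeatmasker_out(path: str | Path) -> RepeatTrack:
    """Parse RepeatMasker .out (classic 15-column or header-less).

    Coordinates are 1-based inclusive in the file; converted to 0-based
    half-open. The repeat class/family column is matched by prefix
    downstream, so "Simple_repeat" also covers "Simple_repeat/...".
    """
    track = RepeatTrack(source="repeatmasker")
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if len(fields) < 11:
                continue
            try:
                score = int(fields[0])  # noqa: F841 - validates data row
                start = int(fields[5]) - 1
                end = int(fields[6])
            except ValueError:
                continue  # header / banner lines
            chrom, cls = fields[4], fields[10]
            track.intervals.setdefault(chrom, []).append((start, end, cls))
    return track


def parse_trf_bed(path: str | Path) -> RepeatTrack:
    """Tandem Repeats Finder annotation as BED (0-based half-open)."""
    track = RepeatTrack(source="trf")
    for chrom, start, end, _name in read_bed(path):
        track.intervals.setdefault(chrom, []).append((start, end, "trf"))
    return track


def combine_simple_repeats(
    rm_track: RepeatTrack,
    trf_track: RepeatTrack,
    chrom_names: Iterable[str] | None = None,
) -> RepeatTrack:
    """Union of RepeatMasker Simple_repeat intervals and all TRF intervals."""
    if chrom_names is not None:
        known = set(chrom_names)
        offenders = sorted(
            (set(rm_track.intervals) | set(trf_track.intervals)) - known
        )
        if offenders:
            raise ValueError(
                "repeat annotations name chromosomes absent from the assembly: "
                + ", ".join(offenders)
            )
    combined = RepeatTrack(source="combined")
    rm_simple = rm_track.by_class(SIMPLE_CLASSES)
    trf_all = trf_track.by_class(None)
    for chrom in sorted(set(rm_simple) | set(trf_all)):
        merged = merge_intervals(rm_simple.get(chrom, []) + trf_all.get(chrom, []))
        combined.intervals[chrom] = [(s, e, "simple") for s, e in merged]
    return combined


def intron_repeat_fraction(
    intron: Interval,
    chrom: str,
    combined: RepeatTrack,
) -> float:
    """Fraction of intron bases covered by the combined simple repeats."""
    length = intron[1] - intron[0]
    if length <= 0:
        raise ValueError("intron length must be positive")
    merged = merge_intervals([(s, e) for s, e, _ in combined.intervals.get(chrom, [])])
    return total_overlap(intron, merged) / length


def intron_coverage_table(
    introns: Mapping[str, tuple[str, Interval]],
    combined: RepeatTrack,
) -> pd.DataFrame:
    """intron_id -> (chrom, interval) to a coverage DataFrame."""
    merged_by_chrom = {
        chrom: merge_intervals([(s, e) for s, e, _ in ivs])
        for chrom, ivs in combined.intervals.items()
    }
    rows = []
    for iid, (chrom, iv) in sorted(introns.items()):
        covered = total_overlap(iv, merged_by_chrom.get(chrom, []))
        rows.append(
            {
                "intron_id": iid,
                "chrom": chrom,
                "start": iv[0],
                "end": iv[1],
                "fraction": covered / (iv[1] - iv[0]),
            }
        )
    return pd.DataFrame(rows, columns=["intron_id", "chrom", "start", "end", "fraction"])


def write_coverage_bed(path: str | Path, table: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        for _, r in table.iterrows():
            score = int(round(r["fraction"] * 1000))
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['intron_id']}\t{score}\n"
            )
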