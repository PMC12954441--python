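"""Population-level intron length variability.

Per-sample allele calls are aggregated across individuals into unique
length alleles (greedy centroid clustering at the 10% relative
difference rule, which makes the pairwise uniqueness criterion
transitive-safe). Each passing diploid sample contributes two allele
draws — homozygotes contribute their single allele twice. Allele
richness is rarefied to n = 6 draws (three diploids) with the Hurlbert
formula

    Ar = Σ_i [1 − C(N − N_i, n) / C(N, n)]

Introns with Ar = 1 are *stable*, Ar > 1 *length-variable*.
Category effects (dot-chromosome introns, exon-stuttering introns) on
positive right-skewed responses are quantified with univariate OLS on
the log response; β is the log-fold change of the category mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .read_typing import SampleAlleleCall

RAREFY_N = 6
UNIQUE_THRESHOLD = 0.10


@dataclass
class UniqueAllele:
    mean_length: float
    draw_count: int


@dataclass
class PopulationAlleleTable:
    """Cross-sample summary for one intron."""

    intron_id: str
    unique_alleles: list[UniqueAllele]
    n_draws: int
    Ar: float
    heterozygosity: float
    variable: bool
    rarefied_at: int = RAREFY_N
    chrom_class: str = "unknown"
    exon_stuttering: bool = False

    @property
    def classification(self) -> str:
        return "variable" if self.variable else "stable"


@dataclass
class CategoryModelResult:
    category: str
    beta: float
    p_value: float
    n_category: int
    n_reference: int


def aggregate_unique_alleles(
    calls: Sequence[SampleAlleleCall],
    threshold: float = UNIQUE_THRESHOLD,
) -> list[UniqueAllele]:
    """Cluster per-sample allele means into population unique alleles.

    Draws sorted ascending; a draw joins the current cluster when its
    mean is within ``threshold`` (relative to the larger of draw and
    running centroid) of the cluster's draw-weighted running mean,
    otherwise it opens a new cluster. Each passing sample contributes
    exactly two draws.
    """
    draws: list[tuple[float, int]] = []
    for call in calls:
        if not call.passed_filters:
            continue
        if len(call.alleles) == 1:
            draws.append((call.alleles[0].mean_length, 2))
        else:
            for al in call.alleles:
                draws.append((al.mean_length, 1))
    if not draws:
        return []
    draws.sort()
    clusters: list[list[tuple[float, int]]] = []
    centroid = None
    for mean, w in draws:
        if centroid is not None and abs(mean - centroid) <= threshold * max(mean, centroid):
            clusters[-1].append((mean, w))
        else:
            clusters.append([(mean, w)])
        members = clusters[-1]
        total = sum(ww for _, ww in members)
        centroid = sum(m * ww for m, ww in members) / total
    return [
        UniqueAllele(
            sum(m * w for m, w in cl) / sum(w for _, w in cl),
            sum(w for _, w in cl),
        )
        for cl in clusters
    ]


def rarefy_richness(draw_counts: Sequence[int], n: int = RAREFY_N) -> tuple[float, int]:
    """Hurlbert rarefied allele richness.

    Expected number of distinct alleles among ``n`` draws taken without
    replacement from the pooled draws. When fewer than ``n`` draws
    exist, richness is computed at n = N and the effective n is
    returned alongside (flagging the shortfall).
    """
    counts = [int(c) for c in draw_counts if c > 0]
    if not counts:
        raise ValueError("no draws")
    N = sum(counts)
    n_eff = min(n, N)
    denom = math.comb(N, n_eff)
    ar = sum(1.0 - math.comb(N - c, n_eff) / denom for c in counts)
    return ar, n_eff


def heterozygosity(calls: Sequence[SampleAlleleCall]) -> float:
    """Fraction of passing samples carrying two distinct length alleles."""
    passing = [c for c in calls if c.passed_filters]
    if not passing:
        raise ValueError("no passing samples")
    return sum(1 for c in passing if len(c.alleles) == 2) / len(passing)


def build_population_table(
    calls_by_intron: Mapping[str, Sequence[SampleAlleleCall]],
    chrom_class_by_intron: Mapping[str, str] | None = None,
    stutter_flags: Iterable[str] = (),
    rarefy_n: int = RAREFY_N,
    threshold: float = UNIQUE_THRESHOLD,
) -> list[PopulationAlleleTable]:
    """One PopulationAlleleTable per intron with >=1 passing sample."""
    stutter = set(stutter_flags)
    tables = []
    for iid, calls in sorted(calls_by_intron.items()):
        uniques = aggregate_unique_alleles(calls, threshold)
        if not uniques:
            continue
        ar, n_eff = rarefy_richness([u.draw_count for u in uniques], rarefy_n)
        tables.append(
            PopulationAlleleTable(
                intron_id=iid,
                unique_alleles=uniques,
                n_draws=sum(u.draw_count for u in uniques),
                Ar=ar,
                heterozygosity=heterozygosity(calls),
                variable=ar > 1.0,
                rarefied_at=n_eff,
                chrom_class=(chrom_class_by_intron or {}).get(iid, "unknown"),
                exon_stuttering=iid in stutter,
            )
        )
    return tables


def classify_and_tabulate(
    tables: Sequence[PopulationAlleleTable],
    rarefy_n: int = RAREFY_N,
) -> dict:
    """Stable/variable tallies per chromosome class plus Venn counts.

    Introns with fewer than ``rarefy_n`` draws are reported separately
    and excluded from the Ar-based headline tallies.
    """
    full = [t for t in tables if t.rarefied_at >= rarefy_n]
    short = [t for t in tables if t.rarefied_at < rarefy_n]
    by_class: dict[str, dict[str, int]] = {}
    for t in full:
        d = by_class.setdefault(t.chrom_class, {"stable": 0, "variable": 0})
        d[t.classification] += 1
    variable = {t.intron_id for t in full if t.variable}
    dots = {t.intron_id for t in full if t.chrom_class == "dot"}
    stutter = {t.intron_id for t in full if t.exon_stuttering}
    return {
        "n_introns": len(full),
        "n_excluded_short": len(short),
        "n_variable": len(variable),
        "n_stable": len(full) - len(variable),
        "per_class": by_class,
        "venn": {
            "variable_only": len(variable - dots - stutter),
            "variable_and_dot": len((variable & dots) - stutter),
            "variable_and_stutter": len((variable & stutter) - dots),
            "variable_dot_stutter": len(variable & dots & stutter),
            "dot_total": len(dots),
            "stutter_total": len(stutter),
        },
    }


def fit_category_model(
    response: Sequence[float],
    is_category: Sequence[bool],
    category: str = "category",
) -> CategoryModelResult:
    """OLS of log(response) on an intercept and a category indicator.

    β is the indicator coefficient (log-fold change of the category
    mean response vs the reference group); p is the two-sided t-test
    on β.
    """
    y = np.asarray(response, dtype=float)
    g = np.asarray(is_category, dtype=bool)
    if np.any(y <= 0):
        raise ValueError("responses must be strictly positive for the log transform")
    if g.all() or not g.any():
        raise ValueError("both category and reference groups must be non-empty")
    X = sm.add_constant(g.astype(float))
    fit = sm.OLS(np.log(y), X).fit()
    return CategoryModelResult(
        category=category,
        beta=float(fit.params[1]),
        p_value=float(fit.pvalues[1]),
        n_category=int(g.sum()),
        n_reference=int((~g).sum()),
    )


def rarefy_monte_carlo(
    draw_counts: Sequence[int],
    n: int = RAREFY_N,
    n_resamples: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo rarefaction cross-check: mean distinct alleles over
    random subsamples of ``n`` draws without replacement."""
    counts = [int(c) for c in draw_counts if c > 0]
    labels = np.repeat(np.arange(len(counts)), counts)
    N = len(labels)
    n_eff = min(n, N)
    rng = np.random.default_rng(seed)
    u = rng.random((n_resamples, N)).argsort(axis=1)[:, :n_eff]
    picked = np.sort(labels[u], axis=1)
    distinct = 1 + (np.diff(picked, axis=1) != 0).sum(axis=1)
    return float(distinct.mean())


def tables_to_frame(tables: Sequence[PopulationAlleleTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        rows.append(
            {
                "intron_id": t.intron_id,
                "n_unique_alleles": len(t.unique_alleles),
                "allele_lengths": ",".join(f"{u.mean_length:.1f}" for u in t.unique_alleles),
                "n_draws": t.n_draws,
                "Ar": t.Ar,
                "heterozygosity": t.heterozygosity,
                "class": t.classification,
                "chrom_class": t.chrom_class,
                "exon_stuttering": t.exon_stuttering,
                "rarefied_at": t.rarefied_at,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "intron_id", "n_unique_alleles", "allele_lengths", "n_draws",
            "Ar", "heterozygosity", "class", "chrom_class",
            "exon_stuttering", "rarefied_at",
        ],
    )
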