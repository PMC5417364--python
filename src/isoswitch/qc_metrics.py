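"""Read-distribution QC and the per-kb exon/intron ratio.

Reads arrive as intervals (no BAM parsing); each read is assigned a single
region category by its midpoint under a fixed precedence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment_stats import rank_sum_test
from .models import GeneCatalogue, GenomicInterval

log = logging.getLogger(__name__)

CATEGORIES = ("exon_cds", "utr", "promoter", "intron", "intergenic")

#: default TSS-upstream promoter window (bp)
DEFAULT_PROMOTER_SPAN = 1000


@dataclass
class RegionBreakdown:
    sample: str
    counts: dict[str, int]

    @property
    def fractions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        if total == 0:
            return {c: 0.0 for c in CATEGORIES}
        return {c: self.counts[c] / total for c in CATEGORIES}


@dataclass
class ExonIntronRatio:
    sample: str
    exon_density: float  # reads per kb of exon
    intron_density: float

    @property
    def ratio(self) -> float:
        if self.intron_density == 0:
            return float("inf")
        return self.exon_density / self.intron_density

    @property
    def infinite(self) -> bool:
        return self.intron_density == 0


def _region_index(cat: GeneCatalogue, promoter_span: int):
    """Per-chrom sorted interval lists for each category."""
    cds: dict[str, list[tuple[int, int]]] = {}
    exon: dict[str, list[tuple[int, int]]] = {}
    promoter: dict[str, list[tuple[int, int]]] = {}
    gene_span: dict[str, list[tuple[int, int]]] = {}
    for t in cat.transcripts():
        for iv in t.cds:
            cds.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for iv in t.exons:
            exon.setdefault(iv.chrom, []).append((iv.start, iv.end))
        if t.strand == "+":
            promoter.setdefault(t.chrom, []).append(
                (max(0, t.start - promoter_span), t.start)
            )
        else:
            promoter.setdefault(t.chrom, []).append((t.end, t.end + promoter_span))
        gene_span.setdefault(t.chrom, []).append((t.start, t.end))
    # merge to disjoint sorted intervals so membership is a single bisect
    def merge(d):
        for chrom, ivs in d.items():
            ivs.sort()
            merged = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            d[chrom] = merged

    for d in (cds, exon, promoter, gene_span):
        merge(d)
    return cds, exon, promoter, gene_span


def _hits(intervals: dict[str, list[tuple[int, int]]], chrom: str, pos: int) -> bool:
    ivs = intervals.get(chrom)
    if not ivs:
        return False
    import bisect

    i = bisect.bisect_right(ivs, (pos, float("inf")))
    return i > 0 and ivs[i - 1][0] <= pos < ivs[i - 1][1]


def assign_regions(
    reads: pd.DataFrame,
    cat: GeneCatalogue,
    sample: str | None = None,
    promoter_span: int = DEFAULT_PROMOTER_SPAN,
) -> RegionBreakdown:
    """Assign each read interval to one region category by midpoint.

    ``reads`` needs columns chrom, start, end (and optionally sample).
    Precedence: exon_cds > utr > promoter > intron > intergenic; utr is
    exonic-but-not-CDS sequence.  Reads on unknown chromosomes count as
    intergenic (logged).
    """
    cds, exon, promoter, gene_span = _region_index(cat, promoter_span)
    known_chroms = set(exon) | set(gene_span)
    if sample is not None and "sample" in reads.columns:
        reads = reads[reads["sample"] == sample]
    counts = {c: 0 for c in CATEGORIES}
    for r in reads.itertuples():
        mid = (int(r.start) + int(r.end)) // 2
        chrom = r.chrom
        if chrom not in known_chroms:
            log.warning("read on unknown chrom %s counted as intergenic", chrom)
            counts["intergenic"] += 1
            continue
        if _hits(cds, chrom, mid):
            counts["exon_cds"] += 1
        elif _hits(exon, chrom, mid):
            counts["utr"] += 1
        elif _hits(promoter, chrom, mid):
            counts["promoter"] += 1
        elif _hits(gene_span, chrom, mid):
            counts["intron"] += 1
        else:
            counts["intergenic"] += 1
    return RegionBreakdown(sample or "all", counts)


def exonic_kb(cat: GeneCatalogue) -> float:
    """Total merged (non-redundant) exonic length in kb."""
    _cds, exon, _prom, _span = _region_index(cat, 0)
    return sum(e - s for ivs in exon.values() for s, e in ivs) / 1000.0


def intronic_kb(cat: GeneCatalogue) -> float:
    """Gene-body length outside merged exons (the QC 'intron' region), kb."""
    _cds, _exon, _prom, span = _region_index(cat, 0)
    span_kb = sum(e - s for ivs in span.values() for s, e in ivs) / 1000.0
    return span_kb - exonic_kb(cat)


def exon_intron_ratio(
    sample: str,
    exon_reads: float,
    intron_reads: float,
    exon_kb: float,
    intron_kb: float,
) -> ExonIntronRatio:
    """Per-kb exon/intron read-density ratio for one sample."""
    if exon_kb <= 0 or intron_kb <= 0:
        raise ValueError("exon and intron total lengths must be positive")
    return ExonIntronRatio(sample, exon_reads / exon_kb, intron_reads / intron_kb)


def platform_consistency(
    ratios: Sequence[ExonIntronRatio], platforms: Sequence[str]
) -> tuple[dict[str, float], float | None]:
    """Per-platform median ratios and a rank-sum p across two platforms.

    With a single platform only medians are returned (p is None).
    """
    if len(ratios) != len(platforms):
        raise ValueError("ratios and platform labels must align")
    by_platform: dict[str, list[float]] = {}
    for r, plat in zip(ratios, platforms):
        by_platform.setdefault(plat, []).append(r.ratio)
    medians = {p: float(np.median(v)) for p, v in sorted(by_platform.items())}
    if len(by_platform) < 2:
        return medians, None
    if len(by_platform) != 2:
        raise ValueError("platform comparison defined for exactly 2 platforms")
    (a, b) = (by_platform[p] for p in sorted(by_platform))
    if min(len(a), len(b)) < 2:
        return medians, None
    _w, p = rank_sum_test(a, b, alternative="two-sided")
    return medians, p


def breakdown_table(breakdowns: Sequence[RegionBreakdown]) -> pd.DataFrame:
    rows = []
    for b in breakdowns:
        row = {"sample": b.sample}
        row.update({f"n_{c}": b.counts[c] for c in CATEGORIES})
        row.update({f"frac_{c}": b.fractions[c] for c in CATEGORIES})
        rows.append(row)
    return pd.DataFrame(rows)
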