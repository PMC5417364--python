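"""Per-intron expression and global retained-intron shift statistics.

Intron intervals are the complement of a gene's merged protein-coding exons
within the gene span; densities are reads per kilobase.  Fold-change profiles
are ordered 5'->3' in transcript orientation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enrichment_stats import rank_sum_test, signed_rank_test
from .models import GeneCatalogue, GenomicInterval

log = logging.getLogger(__name__)

#: pseudocount (reads/kb) keeping log fold-changes finite on empty introns
DEFAULT_EPSILON = 0.1


@dataclass
class IntronCoverage:
    gene_id: str
    index: int  # 5'->3' in transcript orientation
    interval: GenomicInterval
    density: dict[str, float]  # sample -> reads per kb


@dataclass
class IntronFoldChange:
    gene_id: str
    index: int
    log2fc: float


def gene_introns(cat: GeneCatalogue, gene_id: str) -> list[GenomicInterval]:
    """Intron intervals of a gene: merged-coding-exon complement, 5'->3'.

    Defined from reference protein-coding transcripts only (retained introns
    are relative to the coding structure); falls back to all transcripts for
    genes without a coding model.
    """
    txs = cat.genes[gene_id]
    coding = [t for t in txs if t.biotype == "protein_coding"]
    use = coding if coding else txs
    exons = sorted((e.start, e.end) for t in use for e in t.exons)
    merged: list[list[int]] = []
    for s, e in exons:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    chrom, strand = use[0].chrom, use[0].strand
    introns = [
        GenomicInterval(chrom, a[1], b[0], strand)
        for a, b in zip(merged, merged[1:])
        if a[1] < b[0]
    ]
    if strand == "-":
        introns = introns[::-1]
    return introns


def intron_density(
    cat: GeneCatalogue,
    gene_id: str,
    coverage: pd.DataFrame,
    sample: str,
) -> list[IntronCoverage]:
    """Per-intron read densities (reads/kb) for one gene and sample.

    ``coverage`` rows are keyed by (gene_id, chrom, start, end) and carry raw
    read counts per sample; a missing row yields density 0 with a warning.
    """
    rows = coverage[coverage["gene_id"] == gene_id]
    by_coord = {
        (r["chrom"], int(r["start"]), int(r["end"])): r[sample]
        for r in rows.to_dict("records")
    }
    out = []
    for idx, iv in enumerate(gene_introns(cat, gene_id)):
        key = (iv.chrom, iv.start, iv.end)
        if key in by_coord:
            reads = float(by_coord[key])
        else:
            log.warning("gene %s intron %s missing from coverage; density 0", gene_id, key)
            reads = 0.0
        out.append(
            IntronCoverage(gene_id, idx, iv, {sample: reads / (len(iv) / 1000.0)})
        )
    return out


def _density_matrix(
    cat: GeneCatalogue, gene_id: str, coverage: pd.DataFrame, samples: Sequence[str]
) -> np.ndarray:
    """introns × samples density array, 5'->3' order."""
    introns = gene_introns(cat, gene_id)
    rows = coverage[coverage["gene_id"] == gene_id]
    by_coord = {
        (r["chrom"], int(r["start"]), int(r["end"])): r for r in rows.to_dict("records")
    }
    mat = np.zeros((len(introns), len(samples)))
    for i, iv in enumerate(introns):
        row = by_coord.get((iv.chrom, iv.start, iv.end))
        if row is None:
            continue
        kb = len(iv) / 1000.0
        for j, s in enumerate(samples):
            mat[i, j] = float(row[s]) / kb
    return mat


def intron_log2fc(
    cat: GeneCatalogue,
    gene_id: str,
    coverage: pd.DataFrame,
    baseline_samples: Sequence[str],
    test_samples: Sequence[str],
    epsilon: float = DEFAULT_EPSILON,
) -> list[IntronFoldChange]:
    """Per-intron log2 fold-change of mean density, test over baseline."""
    if not baseline_samples or not test_samples:
        raise ValueError("both conditions need >= 1 sample")
    base = _density_matrix(cat, gene_id, coverage, baseline_samples).mean(axis=1)
    test = _density_matrix(cat, gene_id, coverage, test_samples).mean(axis=1)
    return [
        IntronFoldChange(gene_id, i, math.log2((t + epsilon) / (b + epsilon)))
        for i, (b, t) in enumerate(zip(base, test))
    ]


def intron_log2fc_matrix(
    cat: GeneCatalogue,
    gene_id: str,
    coverage: pd.DataFrame,
    baseline_samples: Sequence[str],
    conditions: dict[str, Sequence[str]],
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """introns × conditions log2 fold-change table relative to baseline."""
    data = {}
    for name, samples in conditions.items():
        fcs = intron_log2fc(cat, gene_id, coverage, baseline_samples, samples, epsilon)
        data[name] = [fc.log2fc for fc in fcs]
    df = pd.DataFrame(data)
    df.index.name = "intron_index"
    return df


def global_ri_shift(
    q: pd.DataFrame,
    cat: GeneCatalogue,
    group_a: Sequence[str],
    group_b: Sequence[str],
    paired: bool = True,
    epsilon: float = 1e-3,
) -> tuple[float, float]:
    """Gene-level shift in retained-intron transcript expression between groups.

    Sums retained_intron FPKM per gene, compares group means per gene, and
    tests across genes: Wilcoxon signed-rank on per-gene log2 differences for
    the paired/time-course design, rank-sum on the two per-gene mean vectors
    otherwise.  Returns (median per-gene log2 shift, p).
    """
    ri_by_gene: dict[str, list[str]] = {}
    for gid, txs in cat.genes.items():
        ri = [t.transcript_id for t in txs if t.biotype == "retained_intron"]
        if ri:
            ri_by_gene[gid] = ri
    if not ri_by_gene:
        raise ValueError("no retained_intron transcripts in catalogue")
    a_vals, b_vals = [], []
    for gid, tids in sorted(ri_by_gene.items()):
        sub = q.loc[[t for t in tids if t in q.index]]
        if sub.empty:
            continue
        a_vals.append(float(sub[list(group_a)].sum(axis=0).mean()))
        b_vals.append(float(sub[list(group_b)].sum(axis=0).mean()))
    deltas = [math.log2((b + epsilon) / (a + epsilon)) for a, b in zip(a_vals, b_vals)]
    shift = float(np.median(deltas))
    if paired:
        p = signed_rank_test(deltas)
    else:
        _w, p = rank_sum_test(a_vals, b_vals, alternative="two-sided")
    return shift, p


def switch_gene_expression_contrast(
    conco_genes: Iterable[str],
    q: pd.DataFrame,
    cat: GeneCatalogue,
    group_a: Sequence[str],
    group_b: Sequence[str],
    epsilon: float = 1e-3,
) -> tuple[pd.Series, float]:
    """Total-expression contrast at coding→noncoding switch (CoNCo) loci.

    Gene totals are summed isoform FPKM; returns per-gene log2 differences of
    group means (b over a) and a signed-rank p across genes.  Designed as a
    null-confirmation report: isoform-composition switches that conserve gene
    totals should test non-significant.
    """
    conco_genes = sorted(set(conco_genes))
    if not conco_genes:
        raise ValueError("empty CoNCo gene set")
    deltas = {}
    for gid in conco_genes:
        tids = [t.transcript_id for t in cat.genes[gid] if t.transcript_id in q.index]
        totals = q.loc[tids]
        a = float(totals[list(group_a)].sum(axis=0).mean())
        b = float(totals[list(group_b)].sum(axis=0).mean())
        deltas[gid] = math.log2((b + epsilon) / (a + epsilon))
    series = pd.Series(deltas, name="log2_delta")
    p = signed_rank_test(list(series))
    return series, p
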