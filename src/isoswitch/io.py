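"""Readers and writers for the plain-text dialects the pipeline exchanges.

GTF coordinates are 1-based inclusive on disk and converted to 0-based
half-open internally at this single site.  All tabular formats are TSV.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, TextIO

import pandas as pd

from .models import GeneCatalogue, GenomicInterval, JunctionRecord, TranscriptModel

log = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """Raised on a malformed GTF line; message carries the line number."""


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(stream: TextIO, origin: str = "reference") -> GeneCatalogue:
    """Parse GTF ``exon`` (and optional ``CDS``) features into a catalogue.

    Biotype comes from the ``transcript_biotype`` attribute when present,
    else ``novel_unclassified``.  Records with end <= start are rejected and
    logged rather than aborting the parse.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}  # tx -> (gene_id, biotype)
    order: list[str] = []

    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
        if feature not in ("exon", "CDS"):
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
        if strand not in ("+", "-"):
            raise GtfParseError(f"line {lineno}: bad strand {strand!r}")
        attr = _parse_attributes(attrs)
        if "gene_id" not in attr or "transcript_id" not in attr:
            raise GtfParseError(f"line {lineno}: missing gene_id/transcript_id")
        if end1 < start1:
            log.warning("rejected %s record at line %d: end < start", feature, lineno)
            continue
        iv = GenomicInterval(chrom, start1 - 1, end1, strand)
        tid = attr["transcript_id"]
        if tid not in meta:
            meta[tid] = (attr["gene_id"], attr.get("transcript_biotype", "novel_unclassified"))
            order.append(tid)
        (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)

    transcripts = []
    for tid in order:
        gene_id, biotype = meta[tid]
        if tid not in exons:
            log.warning("transcript %s has CDS but no exon records; skipped", tid)
            continue
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                exons=exons[tid],
                biotype=biotype,
                origin=origin,
                cds=sorted(cds.get(tid, []), key=lambda e: e.start),
            )
        )
    return GeneCatalogue(transcripts)


def write_gtf(cat: GeneCatalogue, stream: TextIO) -> None:
    """Emit the catalogue as GTF; inverse of :func:`read_gtf` (round-trip safe)."""
    for t in cat.transcripts():
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'transcript_biotype "{t.biotype}";'
        )
        for feature, ivs in (("exon", t.exons), ("CDS", t.cds)):
            for iv in ivs:
                stream.write(
                    "\t".join(
                        [
                            iv.chrom,
                            "isoswitch",
                            feature,
                            str(iv.start + 1),
                            str(iv.end),
                            ".",
                            iv.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# --------------------------------------------------------------------------
# tabular matrices


def read_quant_tsv(path) -> pd.DataFrame:
    """FPKM matrix: transcript_id index, one column per sample."""
    q = pd.read_csv(path, sep="\t", index_col=0)
    if (q.values < 0).any():
        raise ValueError("FPKM matrix contains negative entries")
    return q


def write_quant_tsv(q: pd.DataFrame, path) -> None:
    q.to_csv(path, sep="\t", index_label="transcript_id")


def read_junction_support_tsv(path) -> pd.DataFrame:
    """Junction support: chrom, strand, donor, acceptor then sample columns.

    Returned frame is indexed by JunctionRecord.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "strand", "donor", "acceptor"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"junction support TSV must start with columns {required}")
    idx = [
        JunctionRecord(r.chrom, r.strand, int(r.donor), int(r.acceptor))
        for r in df.itertuples()
    ]
    counts = df.drop(columns=required)
    if (counts.values < 0).any():
        raise ValueError("junction support counts must be non-negative")
    counts.index = pd.Index(idx)
    return counts


def write_junction_support_tsv(sup: pd.DataFrame, path) -> None:
    out = sup.copy()
    out.insert(0, "acceptor", [j.acceptor for j in sup.index])
    out.insert(0, "donor", [j.donor for j in sup.index])
    out.insert(0, "strand", [j.strand for j in sup.index])
    out.insert(0, "chrom", [j.chrom for j in sup.index])
    out.to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path) -> pd.DataFrame:
    """Intron coverage: gene_id, chrom, start, end then per-sample read counts."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chrom", "start", "end"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"coverage TSV must start with columns {required}")
    return df


def write_coverage_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path) -> pd.DataFrame:
    """Sample metadata: 'sample' column plus condition/group/platform columns."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in meta.columns:
        raise ValueError("metadata TSV needs a 'sample' column")
    return meta.set_index("sample")


def write_metadata_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def write_junction_bed(
    junctions: Iterable[tuple[JunctionRecord, str]], stream: TextIO
) -> None:
    """BED6 export of classified junctions; name column carries the class."""
    for j, cls in junctions:
        stream.write(
            f"{j.chrom}\t{j.donor}\t{j.acceptor}\t{cls}\t0\t{j.strand}\n"
        )


def read_ontology_edges_tsv(path) -> list[tuple[str, str]]:
    """Edge list TSV with columns child_id, parent_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["child_id", "parent_id"]:
        raise ValueError("ontology TSV must have columns child_id, parent_id")
    return list(df.itertuples(index=False, name=None))


def read_annotation_tsv(path) -> dict[str, set[str]]:
    """Gene->terms annotation TSV with columns gene_id, term_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "term_id"]:
        raise ValueError("annotation TSV must have columns gene_id, term_id")
    out: dict[str, set[str]] = {}
    for gene, term in df.itertuples(index=False, name=None):
        out.setdefault(gene, set()).add(term)
    return out
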