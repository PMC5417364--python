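"""Core domain types: genomic intervals, junctions, transcript models and catalogues.

Coordinates are 0-based half-open throughout the package; conversion to/from
the 1-based inclusive GTF convention happens only in :mod:`isoswitch.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

BIOTYPES = (
    "protein_coding",
    "retained_intron",
    "processed_transcript",
    "nmd",
    "other_noncoding",
    "novel_unclassified",
)

#: biotypes whose major-isoform status counts as noncoding
NONCODING_BIOTYPES = frozenset(
    {"retained_intron", "processed_transcript", "nmd", "other_noncoding"}
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True, order=True)
class JunctionRecord:
    """A splice junction: the excised-intron interval between two exons.

    ``donor`` is the genomic start of the intron (exclusive end of the upstream
    exon in genomic orientation) and ``acceptor`` the genomic end (start of the
    downstream exon).  On the minus strand the biological donor/acceptor roles
    are reversed; callers needing strand semantics use
    :meth:`biological_donor` / :meth:`biological_acceptor`.
    """

    chrom: str
    strand: str
    donor: int
    acceptor: int

    def __post_init__(self) -> None:
        if self.donor >= self.acceptor:
            raise ValueError(
                f"junction donor must be < acceptor, got {self.donor}..{self.acceptor}"
            )

    def biological_donor(self) -> int:
        return self.donor if self.strand == "+" else self.acceptor

    def biological_acceptor(self) -> int:
        return self.acceptor if self.strand == "+" else self.donor


@dataclass
class TranscriptModel:
    """A strand-aware exon chain with biotype and gene assignment."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    biotype: str = "novel_unclassified"
    origin: str = "reference"
    cds: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"{self.transcript_id}: exons must share one chrom and strand"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.origin not in ("reference", "novel"):
            raise ValueError(f"unknown origin {self.origin!r}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def introns(self) -> list[GenomicInterval]:
        """Intron intervals in genomic order."""
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    def junctions(self) -> list[JunctionRecord]:
        return [
            JunctionRecord(self.chrom, self.strand, a.end, b.start)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    def intron_chain(self) -> tuple:
        """Hashable structural key used for deduplication across catalogues.

        Multi-exon transcripts are identified by their intron chain;
        single-exon transcripts by their exact span.
        """
        if len(self.exons) == 1:
            return (self.chrom, self.strand, "mono", self.start, self.end)
        return (
            self.chrom,
            self.strand,
            tuple((i.start, i.end) for i in self.introns()),
        )

    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def is_coding(self) -> bool:
        return self.biotype == "protein_coding"

    def copy(self, **changes) -> "TranscriptModel":
        base = dict(
            transcript_id=self.transcript_id,
            gene_id=self.gene_id,
            exons=list(self.exons),
            biotype=self.biotype,
            origin=self.origin,
            cds=list(self.cds),
        )
        base.update(changes)
        return TranscriptModel(**base)


class GeneCatalogue:
    """Transcript models grouped by gene with a provenance-flagged junction index."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self.genes: dict[str, list[TranscriptModel]] = {}
        self._by_tx: dict[str, TranscriptModel] = {}
        # junction -> set of origins ("reference"/"novel") that contribute it
        self.junction_index: dict[JunctionRecord, set[str]] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self._by_tx:
            raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
        self.genes.setdefault(t.gene_id, []).append(t)
        self._by_tx[t.transcript_id] = t
        for j in t.junctions():
            self.junction_index.setdefault(j, set()).add(t.origin)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_tx

    def __len__(self) -> int:
        return len(self._by_tx)

    def transcript(self, transcript_id: str) -> TranscriptModel:
        return self._by_tx[transcript_id]

    def transcripts(self) -> Iterator[TranscriptModel]:
        for gid in self.genes:
            yield from self.genes[gid]

    def transcript_ids(self) -> list[str]:
        return list(self._by_tx)

    def gene_ids(self) -> list[str]:
        return list(self.genes)

    def n_genes(self) -> int:
        return len(self.genes)

    def subset(self, keep_tx_ids: set[str]) -> "GeneCatalogue":
        """Re-indexed catalogue containing only the named transcripts.

        Genes left without transcripts disappear.
        """
        return GeneCatalogue(
            t for t in self.transcripts() if t.transcript_id in keep_tx_ids
        )

    def reference_junctions(self) -> set[JunctionRecord]:
        return {j for j, origins in self.junction_index.items() if "reference" in origins}


__all__ = [
    "BIOTYPES",
    "NONCODING_BIOTYPES",
    "GenomicInterval",
    "JunctionRecord",
    "TranscriptModel",
    "GeneCatalogue",
    "replace",
]
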