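"""Augmented transcript-catalogue construction.

Builds a merged reference + novel catalogue, classifies junctions against the
reference, applies the junction-support and expression filters, and assigns
transcript biotypes.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Sequence, TextIO

import pandas as pd

from .io import read_gtf
from .models import GeneCatalogue, GenomicInterval, JunctionRecord, TranscriptModel

log = logging.getLogger(__name__)

COMPLETE = "complete"
PARTIAL = "partial"
NOVEL = "novel"

#: minimum ORF length (codons, incl. start, excl. stop) for a coding call
MIN_ORF_CODONS = 100
#: premature stop must sit more than this many nt upstream of the last junction
NMD_RULE_NT = 50

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def parse_annotation(gtf_stream: TextIO, origin: str = "reference") -> GeneCatalogue:
    """Parse a GTF stream into a :class:`GeneCatalogue`.

    GTF 1-based inclusive coordinates are converted to 0-based half-open;
    biotype is taken from the ``transcript_biotype`` attribute when present.
    """
    return read_gtf(gtf_stream, origin=origin)


def classify_junction(j: JunctionRecord, ref: GeneCatalogue) -> str:
    """Classify a junction against reference annotation.

    ``complete`` when both donor and acceptor match a single reference
    junction; ``partial`` when exactly one end occurs anywhere among reference
    junctions on the same chrom/strand; ``novel`` otherwise.
    """
    ref_juncs = ref.reference_junctions()
    if j in ref_juncs:
        return COMPLETE
    donors = set()
    acceptors = set()
    for r in ref_juncs:
        if r.chrom == j.chrom and r.strand == j.strand:
            donors.add(r.donor)
            acceptors.add(r.acceptor)
    donor_known = j.donor in donors
    acceptor_known = j.acceptor in acceptors
    # exactly one end annotated -> partial; anything else (neither end, or
    # both ends known but never paired) -> novel
    if donor_known != acceptor_known:
        return PARTIAL
    return NOVEL


def classify_junctions(
    junctions: Iterable[JunctionRecord], ref: GeneCatalogue
) -> dict[JunctionRecord, str]:
    return {j: classify_junction(j, ref) for j in junctions}


def filter_junction_support(
    cat: GeneCatalogue,
    sup: pd.DataFrame,
    min_reads: int = 2,
    min_samples: int = 2,
) -> GeneCatalogue:
    """Drop novel transcripts lacking read support at any junction.

    A novel transcript is retained iff every one of its junctions has
    >= ``min_reads`` reads in >= ``min_samples`` samples.  Reference-origin
    transcripts always pass (they are externally validated; the filter
    targets assembly artefacts).  Missing support rows count as all-zero.
    """
    has_novel = any(t.origin == "novel" for t in cat.transcripts())
    if sup.shape[1] == 0 and has_novel:
        log.warning("empty junction-support matrix: dropping all novel transcripts")

    supported: dict[JunctionRecord, bool] = {}

    def junction_ok(j: JunctionRecord) -> bool:
        if j not in supported:
            if j in sup.index:
                counts = sup.loc[j]
                supported[j] = int((counts >= min_reads).sum()) >= min_samples
            else:
                log.warning("junction %s missing from support matrix; treated as zero", j)
                supported[j] = False
        return supported[j]

    keep = set()
    for t in cat.transcripts():
        if t.origin == "reference" or all(junction_ok(j) for j in t.junctions()):
            keep.add(t.transcript_id)
    return cat.subset(keep)


def filter_expression(
    cat: GeneCatalogue,
    q: pd.DataFrame,
    min_fpkm: float = 0.5,
    min_samples: int = 3,
) -> GeneCatalogue:
    """Keep transcripts with FPKM strictly above ``min_fpkm`` in >= ``min_samples`` samples.

    Applies to all transcripts regardless of origin; genes left empty are
    removed.  Missing quantification rows count as all-zero.
    """
    if q.shape[1] < min_samples:
        raise ValueError(
            f"quant matrix has {q.shape[1]} samples; filter needs >= {min_samples}"
        )
    keep = set()
    for t in cat.transcripts():
        tid = t.transcript_id
        if tid not in q.index:
            log.warning("transcript %s missing from quant matrix; treated as zero", tid)
            continue
        if int((q.loc[tid] > min_fpkm).sum()) >= min_samples:
            keep.add(tid)
    return cat.subset(keep)


def _exonic_overlap(t: TranscriptModel, peers: Sequence[TranscriptModel]) -> int:
    total = 0
    for e in t.exons:
        best_per_exon = 0
        for p in peers:
            for pe in p.exons:
                if pe.strand == e.strand:
                    best_per_exon = max(best_per_exon, e.overlap_len(pe))
        total += best_per_exon
    return total


def merge_catalogues(
    reference: GeneCatalogue, novel_sets: Sequence[GeneCatalogue]
) -> GeneCatalogue:
    """Amalgamate novel transcript sets with the reference catalogue.

    Transcripts are deduplicated by (chrom, strand, intron chain); a novel
    transcript inherits the gene_id of the reference gene with maximal
    same-strand exonic overlap (ties: lexicographically smallest gene_id),
    else receives a fresh gene id.  Reference records are untouched.
    """
    merged = GeneCatalogue()
    seen_chains: dict[tuple, str] = {}
    for t in reference.transcripts():
        merged.add(t.copy())
        seen_chains[t.intron_chain()] = t.transcript_id

    # collect novel candidates deterministically across input order
    ref_genes = sorted(reference.genes.items())
    fresh_counter = 0
    for novel in novel_sets:
        for t in sorted(novel.transcripts(), key=lambda x: x.transcript_id):
            chain = t.intron_chain()
            if chain in seen_chains:
                continue
            # assign gene by maximal exonic overlap on same strand
            overlaps: dict[str, int] = {}
            for gid, peers in ref_genes:
                same = [p for p in peers if p.chrom == t.chrom and p.strand == t.strand]
                if same:
                    ov = _exonic_overlap(t, same)
                    if ov > 0:
                        overlaps[gid] = ov
            if overlaps:
                best_ov = max(overlaps.values())
                candidates = sorted(g for g, ov in overlaps.items() if ov == best_ov)
                if len(candidates) > 1:
                    log.info(
                        "transcript %s overlaps genes %s equally; keeping %s",
                        t.transcript_id, candidates, candidates[0],
                    )
                best_gid = candidates[0]
            else:
                best_gid = None
            if best_gid is None:
                fresh_counter += 1
                best_gid = f"NOVELG{fresh_counter:06d}"
            tid = t.transcript_id
            if tid in merged:
                tid = f"{tid}.novel{fresh_counter}"
            merged.add(t.copy(transcript_id=tid, gene_id=best_gid, origin="novel"))
            seen_chains[chain] = tid
    return merged


# --------------------------------------------------------------------------
# biotype classification


def _spans_intron_of_coding_peer(
    t: TranscriptModel, peers: Sequence[TranscriptModel]
) -> bool:
    for p in peers:
        if p.biotype != "protein_coding":
            continue
        for intron in p.introns():
            for e in t.exons:
                if e.start < intron.start and intron.end < e.end:
                    return True
    return False


def spliced_sequence(t: TranscriptModel, fetch: Callable[[str, int, int], str]) -> str:
    """mRNA sequence of the transcript, 5'->3', from a genome fetch callback."""
    seq = "".join(fetch(t.chrom, e.start, e.end) for e in t.exons).upper()
    if t.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


def _longest_orf(seq: str) -> tuple[int, int] | None:
    """(start, stop_end) of the longest ATG..stop ORF, in transcript coords."""
    stops = {"TAA", "TAG", "TGA"}
    best: tuple[int, int] | None = None
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None and codon == "ATG":
                start = i
            elif start is not None and codon in stops:
                if best is None or (i + 3 - start) > (best[1] - best[0]):
                    best = (start, i + 3)
                start = None
    return best


def classify_biotype(
    t: TranscriptModel,
    gene_peers: Sequence[TranscriptModel],
    fetch_sequence: Callable[[str, int, int], str] | None = None,
) -> str:
    """Assign a biotype to a transcript.

    Reference transcripts keep their annotated biotype.  Novel transcripts are
    classified structurally: retained_intron when an exon completely spans an
    intron of a protein-coding peer; otherwise, when genome sequence is
    available, an ORF scan distinguishes nmd (stop > 50 nt upstream of the
    last junction), protein_coding (ORF of >= 100 codons) and
    processed_transcript; without sequence, non-RI novels become
    processed_transcript.
    """
    if t.origin == "reference":
        return t.biotype
    if _spans_intron_of_coding_peer(t, gene_peers):
        return "retained_intron"
    if fetch_sequence is None or len(t.exons) == 0:
        return "processed_transcript"
    seq = spliced_sequence(t, fetch_sequence)
    orf = _longest_orf(seq)
    if orf is None or (orf[1] - orf[0]) // 3 - 1 < MIN_ORF_CODONS:
        return "processed_transcript"
    if len(t.exons) > 1:
        # position of last junction in transcript coordinates
        exon_lens = [len(e) for e in t.exons]
        if t.strand == "-":
            exon_lens = exon_lens[::-1]
        last_junction = sum(exon_lens[:-1])
        stop_end = orf[1]
        if last_junction - stop_end > NMD_RULE_NT:
            return "nmd"
    return "protein_coding"


def classify_novel_biotypes(
    cat: GeneCatalogue,
    fetch_sequence: Callable[[str, int, int], str] | None = None,
) -> GeneCatalogue:
    """Re-classify every novel transcript in place against its gene peers."""
    out = GeneCatalogue()
    for gid, peers in cat.genes.items():
        for t in peers:
            if t.origin == "novel":
                t = t.copy(biotype=classify_biotype(t, peers, fetch_sequence))
            else:
                t = t.copy()
            out.add(t)
    return out
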