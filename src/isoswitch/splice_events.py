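"""Pairwise alternative-splicing event classification.

Events between two isoforms of a gene are classified into seven categories:

* SE   — cassette (skipped) exon
* MXE  — mutually exclusive exons
* RI   — retained intron
* A5SS — alternative 5' (donor-side) splice site
* A3SS — alternative 3' (acceptor-side) splice site
* AFE  — alternative first exon
* ALE  — alternative last exon

Rules are structural, defined on intron/exon coordinates, and strand-aware:
donor/acceptor roles follow transcript orientation, so reflecting all
coordinates and flipping strand maps A5SS <-> A3SS and AFE <-> ALE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .models import GenomicInterval, TranscriptModel

EVENT_TYPES = ("SE", "MXE", "RI", "A3SS", "A5SS", "AFE", "ALE")


@dataclass
class SpliceEvent:
    gene_id: str
    event_type: str
    coords: tuple  # event-defining coordinate tuple, see _key below
    inclusion_tx: set[str] = field(default_factory=set)
    exclusion_tx: set[str] = field(default_factory=set)

    def key(self) -> tuple:
        return (self.event_type, self.coords)

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")


@dataclass
class EventInclusion:
    event: SpliceEvent
    sample: str
    inclusion_level: float | None  # None when denominator is zero

    @property
    def undefined(self) -> bool:
        return self.inclusion_level is None


def _intron_pairs(t: TranscriptModel) -> list[tuple[int, int]]:
    return [(i.start, i.end) for i in t.introns()]


def _exon_pairs(t: TranscriptModel) -> list[tuple[int, int]]:
    return [(e.start, e.end) for e in t.exons]


def classify_pair(tx_a: TranscriptModel, tx_b: TranscriptModel) -> list[SpliceEvent]:
    """Classify all pairwise AS events between two isoforms of one gene.

    Symmetric up to inclusion/exclusion role swap; ``classify_pair(t, t)``
    is empty.
    """
    if tx_a.gene_id != tx_b.gene_id:
        raise ValueError("transcripts belong to different genes")
    if tx_a.chrom != tx_b.chrom or tx_a.strand != tx_b.strand:
        raise ValueError("transcripts on different chrom/strand")

    gene = tx_a.gene_id
    strand = tx_a.strand
    events: list[SpliceEvent] = []

    ex_a, ex_b = _exon_pairs(tx_a), _exon_pairs(tx_b)
    in_a, in_b = _intron_pairs(tx_a), _intron_pairs(tx_b)
    set_in_a, set_in_b = set(in_a), set(in_b)

    def add(ev_type: str, coords: tuple, incl: TranscriptModel, excl: TranscriptModel):
        events.append(
            SpliceEvent(
                gene,
                ev_type,
                coords,
                inclusion_tx={incl.transcript_id},
                exclusion_tx={excl.transcript_id},
            )
        )

    # --- SE: internal exon of one isoform spliced around by the other ------
    def find_se(t_in, ex_in, t_ex, set_in_ex):
        for i in range(1, len(ex_in) - 1):
            es, ee = ex_in[i]
            left = (ex_in[i - 1][1], es)  # upstream intron of inclusion form
            right = (ee, ex_in[i + 1][0])
            skip = (left[0], right[1])
            if skip in set_in_ex:
                add("SE", (es, ee, left[0], right[1]), t_in, t_ex)

    find_se(tx_a, ex_a, tx_b, set_in_b)
    find_se(tx_b, ex_b, tx_a, set_in_a)

    # --- RI: exon spanning an intron with matching outer splice sites ------
    def find_ri(t_ret, ex_ret, t_spl, ex_spl, in_spl):
        exon_set = set(ex_ret)
        for k, (istart, iend) in enumerate(in_spl):
            up = ex_spl[k]
            down = ex_spl[k + 1]
            if (up[0], down[1]) in exon_set:
                add("RI", (istart, iend, up[0], down[1]), t_ret, t_spl)

    find_ri(tx_a, ex_a, tx_b, ex_b, in_b)
    find_ri(tx_b, ex_b, tx_a, ex_a, in_a)

    # --- MXE: two non-overlapping internal exons with shared outer flanks --
    set_ex_a, set_ex_b = set(ex_a), set(ex_b)
    for i in range(1, len(ex_a) - 1):
        e1 = ex_a[i]
        if e1 in set_ex_b:
            continue
        flank_a = (ex_a[i - 1][1], ex_a[i + 1][0])  # (left donor, right acceptor)
        for jx in range(1, len(ex_b) - 1):
            e2 = ex_b[jx]
            if e2 in set_ex_a:
                continue
            if not (e1[1] <= e2[0] or e2[1] <= e1[0]):
                continue  # must be mutually non-overlapping
            flank_b = (ex_b[jx - 1][1], ex_b[jx + 1][0])
            if flank_a == flank_b:
                first, second = sorted([e1, e2])
                if e1 < e2:
                    add("MXE", (*first, *second), tx_a, tx_b)
                else:
                    add("MXE", (*first, *second), tx_b, tx_a)

    # --- A5SS / A3SS: introns sharing exactly one end ----------------------
    # Guard: the exon abutting the differing end must agree on its outer
    # boundary in both isoforms, otherwise the difference is better explained
    # by another event class (SE/MXE flank mismatch fails this).
    def abutting_left_exon(ex, intron_start):
        for es, ee in ex:
            if ee == intron_start:
                return (es, ee)
        return None

    def abutting_right_exon(ex, intron_end):
        for es, ee in ex:
            if es == intron_end:
                return (es, ee)
        return None

    for ia in in_a:
        for ib in in_b:
            if ia == ib:
                continue
            if ia[1] == ib[1] and ia[0] != ib[0]:
                # shared genomic end, differing genomic starts
                la = abutting_left_exon(ex_a, ia[0])
                lb = abutting_left_exon(ex_b, ib[0])
                if la and lb and la[0] == lb[0]:
                    ev = "A5SS" if strand == "+" else "A3SS"
                    # longer exon (shorter intron) is the inclusion form
                    coords = (min(ia[0], ib[0]), max(ia[0], ib[0]), ia[1])
                    if ia[0] > ib[0]:
                        add(ev, coords, tx_a, tx_b)
                    else:
                        add(ev, coords, tx_b, tx_a)
            elif ia[0] == ib[0] and ia[1] != ib[1]:
                ra = abutting_right_exon(ex_a, ia[1])
                rb = abutting_right_exon(ex_b, ib[1])
                if ra and rb and ra[1] == rb[1]:
                    ev = "A3SS" if strand == "+" else "A5SS"
                    coords = (ia[0], min(ia[1], ib[1]), max(ia[1], ib[1]))
                    if ia[1] < ib[1]:
                        add(ev, coords, tx_a, tx_b)
                    else:
                        add(ev, coords, tx_b, tx_a)

    # --- AFE / ALE: differing non-overlapping terminal exons ---------------
    if len(ex_a) >= 2 and len(ex_b) >= 2:
        fa, fb = ex_a[0], ex_b[0]
        if fa != fb and (fa[1] <= fb[0] or fb[1] <= fa[0]):
            if in_a[0][1] == in_b[0][1]:  # shared downstream acceptor (genomic)
                ev = "AFE" if strand == "+" else "ALE"
                first, second = sorted([fa, fb])
                coords = (*first, *second, in_a[0][1])
                if fa < fb:
                    add(ev, coords, tx_a, tx_b)
                else:
                    add(ev, coords, tx_b, tx_a)
        la_, lb_ = ex_a[-1], ex_b[-1]
        if la_ != lb_ and (la_[1] <= lb_[0] or lb_[1] <= la_[0]):
            if in_a[-1][0] == in_b[-1][0]:  # shared upstream donor (genomic)
                ev = "ALE" if strand == "+" else "AFE"
                first, second = sorted([la_, lb_])
                coords = (*first, *second, in_a[-1][0])
                if la_ < lb_:
                    add(ev, coords, tx_a, tx_b)
                else:
                    add(ev, coords, tx_b, tx_a)

    return events


def enumerate_gene_events(gene: Sequence[TranscriptModel]) -> list[SpliceEvent]:
    """Union of pairwise events across all isoform pairs, deduplicated.

    Events identical in (type, coords) are merged and their inclusion /
    exclusion transcript sets aggregated.
    """
    if len(gene) < 2:
        return []
    merged: dict[tuple, SpliceEvent] = {}
    for i in range(len(gene)):
        for j in range(i + 1, len(gene)):
            for ev in classify_pair(gene[i], gene[j]):
                k = ev.key()
                if k in merged:
                    merged[k].inclusion_tx |= ev.inclusion_tx
                    merged[k].exclusion_tx |= ev.exclusion_tx
                else:
                    merged[k] = ev
    out = []
    for ev in merged.values():
        # a transcript supporting both forms across different pairs is
        # ambiguous for this event; drop it from both sides
        both = ev.inclusion_tx & ev.exclusion_tx
        ev.inclusion_tx -= both
        ev.exclusion_tx -= both
        if ev.inclusion_tx and ev.exclusion_tx:
            out.append(ev)
    return sorted(out, key=lambda e: (e.event_type, e.coords))


def event_inclusion(ev: SpliceEvent, q: pd.DataFrame, sample: str) -> EventInclusion:
    """Abundance-based inclusion level (PSI analogue) of an event in a sample."""
    incl = sum(float(q.at[t, sample]) for t in ev.inclusion_tx if t in q.index)
    excl = sum(float(q.at[t, sample]) for t in ev.exclusion_tx if t in q.index)
    denom = incl + excl
    if denom == 0:
        return EventInclusion(ev, sample, None)
    return EventInclusion(ev, sample, incl / denom)


def event_shift_test(
    ev: SpliceEvent,
    q: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
) -> tuple[str, float]:
    """Test for an inclusion-level shift of ``ev`` between two sample groups.

    Returns (direction, p) where direction is 'inclusion_up' /
    'inclusion_down' (group_b relative to group_a) or 'none'.  Uses the
    rank-sum test (exact at small n); direction comes from group-mean
    difference.  'none' when any sample has an undefined inclusion level or
    p exceeds ``alpha``.
    """
    from .enrichment_stats import rank_sum_test

    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    lev_a = [event_inclusion(ev, q, s).inclusion_level for s in group_a]
    lev_b = [event_inclusion(ev, q, s).inclusion_level for s in group_b]
    if any(v is None for v in lev_a + lev_b):
        return ("none", 1.0)
    if min(len(lev_a), len(lev_b)) < 2:
        diff = sum(lev_b) / len(lev_b) - sum(lev_a) / len(lev_a)
        if diff > 0:
            return ("inclusion_up", float("nan"))
        if diff < 0:
            return ("inclusion_down", float("nan"))
        return ("none", float("nan"))
    _stat, p = rank_sum_test(lev_a, lev_b, alternative="two-sided")
    diff = sum(lev_b) / len(lev_b) - sum(lev_a) / len(lev_a)
    if p > alpha or diff == 0:
        return ("none", p)
    return ("inclusion_up" if diff > 0 else "inclusion_down", p)


def events_table(
    events: Sequence[SpliceEvent],
    q: pd.DataFrame | None = None,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Flat TSV-ready table of events with optional per-sample inclusion."""
    rows = []
    for ev in events:
        row = {
            "gene_id": ev.gene_id,
            "event_type": ev.event_type,
            "coords": ",".join(str(c) for c in ev.coords),
            "inclusion_tx": ";".join(sorted(ev.inclusion_tx)),
            "exclusion_tx": ";".join(sorted(ev.exclusion_tx)),
        }
        if q is not None:
            for s in samples if samples is not None else q.columns:
                lev = event_inclusion(ev, q, s).inclusion_level
                row[f"psi_{s}"] = float("nan") if lev is None else lev
        rows.append(row)
    return pd.DataFrame(rows)
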