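from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from isoswitch.models import (
    GeneCatalogue,
    GenomicInterval,
    JunctionRecord,
    TranscriptModel,
)


def make_tx(
    tid: str,
    exons: list[tuple[int, int]],
    gene: str = "G1",
    chrom: str = "chr1",
    strand: str = "+",
    biotype: str = "protein_coding",
    origin: str = "reference",
    cds: list[tuple[int, int]] | None = None,
) -> TranscriptModel:
    return TranscriptModel(
        tid,
        gene,
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
        biotype=biotype,
        origin=origin,
        cds=[GenomicInterval(chrom, s, e, strand) for s, e in (cds or [])],
    )


@pytest.fixture
def three_tx_gene() -> GeneCatalogue:
    """One gene, three isoforms: full, exon-skipped, intron-retaining."""
    return GeneCatalogue(
        [
            make_tx("t1", [(100, 200), (300, 400), (500, 600)]),
            make_tx("t2", [(100, 200), (500, 600)], biotype="processed_transcript"),
            make_tx("t3", [(100, 400), (500, 600)], biotype="retained_intron"),
        ]
    )


@pytest.fixture
def filter_fixture():
    """Hand-built 25-transcript catalogue with support and FPKM tables.

    15 reference transcripts (GR01..GR05, 3 isoforms each) and 10 novel
    single-junction transcripts (NV01..NV10) whose junction support is
    hand-assigned.  Expected survivor sets for both filters are derived by
    hand in the tests that use this fixture.
    """
    transcripts = []
    # reference genes: gene g occupies [g*10_000, ...), 3 isoforms each
    for g in range(5):
        base = 10_000 * (g + 1)
        gene = f"GR{g + 1:02d}"
        exons_full = [(base, base + 200), (base + 500, base + 700), (base + 1000, base + 1200)]
        transcripts.append(make_tx(f"{gene}.t1", exons_full, gene=gene))
        transcripts.append(
            make_tx(
                f"{gene}.t2",
                [(base, base + 200), (base + 1000, base + 1200)],
                gene=gene,
                biotype="processed_transcript",
            )
        )
        transcripts.append(
            make_tx(
                f"{gene}.t3",
                [(base, base + 700), (base + 1000, base + 1200)],
                gene=gene,
                biotype="retained_intron",
            )
        )
    # novel transcripts: one junction each, placed inside gene g's span
    support_counts = {
        "NV01": [2, 2, 0],  # retained: 2 samples reach 2 reads
        "NV02": [1, 1, 1],  # dropped: no sample reaches 2
        "NV03": [5, 0, 0],  # dropped: only 1 sample reaches 2
        "NV04": [3, 3, 3],  # retained
        "NV05": [0, 0, 0],  # dropped
        "NV06": [2, 2, 2],  # retained
        "NV07": [2, 1, 1],  # dropped
        "NV08": [9, 9, 0],  # retained
        "NV09": [0, 2, 2],  # retained
        "NV10": [1, 0, 2],  # dropped
    }
    junctions = {}
    for i, name in enumerate(sorted(support_counts)):
        base = 10_000 * (i % 5 + 1)
        # distinct junction per novel transcript (offset avoids collisions)
        donor = base + 150 + 7 * i
        acceptor = base + 900 + 11 * i
        transcripts.append(
            make_tx(
                name,
                [(base + 100, donor), (acceptor, base + 1150)],
                gene=f"GR{i % 5 + 1:02d}",
                origin="novel",
                biotype="novel_unclassified",
            )
        )
        junctions[name] = JunctionRecord("chr1", "+", donor, acceptor)

    cat = GeneCatalogue(transcripts)
    samples = ["s1", "s2", "s3"]
    sup = pd.DataFrame(
        [support_counts[n] for n in sorted(support_counts)],
        index=pd.Index([junctions[n] for n in sorted(support_counts)]),
        columns=samples,
    )
    # FPKM: hand-set rows over 4 samples; survivors need >0.5 in >=3
    fpkm_samples = ["s1", "s2", "s3", "s4"]
    fpkm_rows = {}
    for i, t in enumerate(sorted(tt.transcript_id for tt in cat.transcripts())):
        if i % 4 == 0:
            fpkm_rows[t] = [0.6, 0.7, 0.8, 0.0]  # retained
        elif i % 4 == 1:
            fpkm_rows[t] = [0.5, 0.5, 0.5, 0.5]  # dropped: never exceeds 0.5
        elif i % 4 == 2:
            fpkm_rows[t] = [2.0, 3.0, 0.1, 0.2]  # dropped: only 2 samples
        else:
            fpkm_rows[t] = [1.0, 1.0, 1.0, 1.0]  # retained
    fpkm = pd.DataFrame.from_dict(fpkm_rows, orient="index", columns=fpkm_samples)
    junction_survivors = {"NV01", "NV04", "NV06", "NV08", "NV09"}
    fpkm_survivors = {
        t for i, t in enumerate(sorted(tt.transcript_id for tt in cat.transcripts()))
        if i % 4 in (0, 3)
    }
    return cat, sup, fpkm, junction_survivors, fpkm_survivors


@pytest.fixture
def quant_two_isoforms():
    """Simple coding (A) vs retained-intron (B) quant matrix."""
    return pd.DataFrame(
        {"s1": [10.0, 2.0], "s2": [2.0, 10.0], "s3": [5.0, 5.0]},
        index=["A", "B"],
    )
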