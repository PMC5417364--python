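"""Major-isoform assignment and coding→noncoding switch detection.

Major isoforms are called independently per sample (batch-effect mitigation),
reduced to coding/noncoding status, then compared across time-course
conditions or tumour/normal cohorts.  Also provides the per-sample noncoding
proportion, group comparisons, switch-set overlap testing and sample
clustering on major-isoform class.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .enrichment_stats import hypergeom_upper_tail, rank_sum_test
from .models import NONCODING_BIOTYPES, GeneCatalogue, TranscriptModel

#: default gene-level total FPKM below which a gene is called not_expressed
EXPRESSION_FLOOR = 1.0

CODING = "coding"
NONCODING = "noncoding"
NOT_EXPRESSED = "not_expressed"


@dataclass
class MajorIsoformCall:
    gene_id: str
    sample: str
    transcript_id: str | None
    status: str  # coding | noncoding | not_expressed


@dataclass
class SwitchRecord:
    gene_id: str
    design: str  # timecourse | cohort
    direction: str  # coding_to_noncoding | noncoding_to_coding | within_class
    switch_fraction: float
    driver_biotype: str | None = None


@dataclass
class SampleNoncodingProfile:
    sample: str
    group: str | None
    n_expressed: int
    n_noncoding_major: int

    @property
    def proportion(self) -> float:
        return self.n_noncoding_major / self.n_expressed


def _status_of(t: TranscriptModel) -> str:
    return NONCODING if t.biotype in NONCODING_BIOTYPES else CODING


def _argmax_isoform(
    transcripts: Sequence[TranscriptModel], values: dict[str, float]
) -> TranscriptModel:
    """Highest-abundance isoform; ties broken coding-first then by id."""
    return min(
        transcripts,
        key=lambda t: (
            -values[t.transcript_id],
            0 if t.is_coding() else 1,
            t.transcript_id,
        ),
    )


def call_major_isoform(
    transcripts: Sequence[TranscriptModel],
    q: pd.DataFrame,
    sample: str,
    floor: float = EXPRESSION_FLOOR,
) -> MajorIsoformCall:
    """Per-sample major-isoform call for one gene."""
    gene_id = transcripts[0].gene_id
    missing = [t.transcript_id for t in transcripts if t.transcript_id not in q.index]
    if missing:
        raise KeyError(f"gene {gene_id}: transcripts {missing} absent from quant matrix")
    vals = {t.transcript_id: float(q.at[t.transcript_id, sample]) for t in transcripts}
    if sum(vals.values()) < floor:
        return MajorIsoformCall(gene_id, sample, None, NOT_EXPRESSED)
    top = _argmax_isoform(transcripts, vals)
    return MajorIsoformCall(gene_id, sample, top.transcript_id, _status_of(top))


def call_major_isoforms(
    cat: GeneCatalogue, q: pd.DataFrame, floor: float = EXPRESSION_FLOOR
) -> pd.DataFrame:
    """Vectorised major-isoform calls for every gene × sample.

    Returns a long-format frame with columns gene_id, sample, transcript_id,
    status.  Calls are per-sample-independent by construction.
    """
    frames = []
    samples = list(q.columns)
    for gene_id in cat.gene_ids():
        txs = cat.genes[gene_id]
        tids = [t.transcript_id for t in txs]
        sub = q.loc[tids, samples].to_numpy(dtype=float)
        totals = sub.sum(axis=0)
        # tie-break: subtract a tiny id/coding-rank epsilon is fragile; use
        # lexsort on (-fpkm, noncoding flag, id rank) per column instead
        id_rank = np.broadcast_to(
            np.argsort(np.argsort(tids))[:, None], sub.shape
        )
        noncoding_flag = np.broadcast_to(
            np.array([0 if t.is_coding() else 1 for t in txs])[:, None], sub.shape
        )
        order = np.lexsort((id_rank, noncoding_flag, -sub), axis=0)
        top_idx = order[0]
        for si, s in enumerate(samples):
            if totals[si] < floor:
                frames.append((gene_id, s, None, NOT_EXPRESSED))
            else:
                t = txs[int(top_idx[si])]
                frames.append((gene_id, s, t.transcript_id, _status_of(t)))
    return pd.DataFrame(frames, columns=["gene_id", "sample", "transcript_id", "status"])


def status_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-format calls to a genes × samples status matrix."""
    return calls.pivot(index="gene_id", columns="sample", values="status")


def _condition_major(
    txs: Sequence[TranscriptModel], q: pd.DataFrame, samples: Sequence[str],
    floor: float,
) -> tuple[str | None, str]:
    """Major isoform of the argmax on mean FPKM within a condition."""
    mean = {t.transcript_id: float(q.loc[t.transcript_id, list(samples)].mean()) for t in txs}
    if sum(mean.values()) < floor:
        return None, NOT_EXPRESSED
    top = _argmax_isoform(txs, mean)
    return top.transcript_id, _status_of(top)


def timecourse_switches(
    cat: GeneCatalogue,
    q: pd.DataFrame,
    baseline_samples: Sequence[str],
    test_samples: Sequence[str],
    floor: float = EXPRESSION_FLOOR,
) -> list[SwitchRecord]:
    """Detect major-isoform switches between two replicate conditions.

    Condition-level status uses the argmax isoform on mean FPKM within each
    condition; a record is emitted whenever the condition-level major
    transcript differs.  ``driver_biotype`` is the biotype of the isoform
    gained in the test condition (distinguishing retained-intron-driven
    switches).
    """
    if not baseline_samples or not test_samples:
        raise ValueError("both conditions need at least one sample")
    records = []
    for gene_id in cat.gene_ids():
        txs = cat.genes[gene_id]
        tid_base, st_base = _condition_major(txs, q, baseline_samples, floor)
        tid_test, st_test = _condition_major(txs, q, test_samples, floor)
        if tid_base is None or tid_test is None or tid_base == tid_test:
            continue
        if st_base == CODING and st_test == NONCODING:
            direction = "coding_to_noncoding"
        elif st_base == NONCODING and st_test == CODING:
            direction = "noncoding_to_coding"
        else:
            direction = "within_class"
        records.append(
            SwitchRecord(
                gene_id,
                "timecourse",
                direction,
                switch_fraction=1.0,
                driver_biotype=cat.transcript(tid_test).biotype,
            )
        )
    return records


def _modal_status(statuses: Iterable[str]) -> str | None:
    counts = Counter(s for s in statuses if s != NOT_EXPRESSED)
    if not counts:
        return None
    top = counts.most_common()
    best = top[0][1]
    # deterministic tie-break: coding before noncoding
    return sorted([s for s, c in top if c == best])[0]


def cohort_switch_genes(
    calls: pd.DataFrame,
    normal_samples: Sequence[str],
    tumour_samples: Sequence[str],
    min_fraction: float = 0.05,
    reference_baseline: dict[str, str] | None = None,
) -> list[SwitchRecord]:
    """Genes whose status deviates from baseline in >= ``min_fraction`` of tumours.

    Baseline class per gene is the modal status among normal samples, falling
    back to ``reference_baseline`` (gene -> coding/noncoding, e.g. from the
    annotation's principal isoform) when no normal call is available.
    not_expressed tumour samples are excluded from the denominator.
    """
    mat = status_matrix(calls)
    normal_samples = [s for s in normal_samples if s in mat.columns]
    tumour_samples = [s for s in tumour_samples if s in mat.columns]
    records = []
    for gene_id, row in mat.iterrows():
        baseline = _modal_status(row[normal_samples]) if normal_samples else None
        if baseline is None:
            if reference_baseline is None or gene_id not in reference_baseline:
                raise ValueError(
                    f"gene {gene_id}: no normal-sample calls and no reference baseline"
                )
            baseline = reference_baseline[gene_id]
        tumour = row[tumour_samples]
        expressed = tumour[tumour != NOT_EXPRESSED]
        if len(expressed) == 0:
            continue
        deviant = (expressed != baseline).sum()
        frac = deviant / len(expressed)
        if frac >= min_fraction:
            gained = expressed[expressed != baseline]
            direction = (
                "coding_to_noncoding"
                if baseline == CODING and (gained == NONCODING).any()
                else "noncoding_to_coding"
                if baseline == NONCODING
                else "within_class"
            )
            records.append(SwitchRecord(gene_id, "cohort", direction, float(frac)))
    return records


def group_class_switches(
    calls: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]
) -> list[str]:
    """Genes with modal status coding in group_a and noncoding in group_b."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    mat = status_matrix(calls)
    out = []
    for gene_id, row in mat.iterrows():
        if (
            _modal_status(row[list(group_a)]) == CODING
            and _modal_status(row[list(group_b)]) == NONCODING
        ):
            out.append(gene_id)
    return out


def noncoding_proportion(
    calls: pd.DataFrame, sample: str, group: str | None = None
) -> SampleNoncodingProfile:
    """Fraction of a sample's expressed genes whose major isoform is noncoding."""
    sub = calls[calls["sample"] == sample]
    expressed = sub[sub["status"] != NOT_EXPRESSED]
    if len(expressed) == 0:
        raise ValueError(f"sample {sample}: no expressed genes")
    n_nc = int((expressed["status"] == NONCODING).sum())
    return SampleNoncodingProfile(sample, group, len(expressed), n_nc)


def noncoding_proportion_test(
    calls: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> tuple[float, float, float]:
    """(mean proportion a, mean proportion b, rank-sum p) between sample groups."""
    pa = [noncoding_proportion(calls, s).proportion for s in group_a]
    pb = [noncoding_proportion(calls, s).proportion for s in group_b]
    _w, p = rank_sum_test(pa, pb, alternative="two-sided")
    return float(np.mean(pa)), float(np.mean(pb)), p


def switch_set_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> float:
    """Upper-tail hypergeometric p for the overlap of two gene sets."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be contained in the universe")
    return hypergeom_upper_tail(
        len(set_a & set_b), len(set_a), len(set_b), len(universe)
    )


def cluster_samples(
    status: pd.DataFrame, k: int = 3
) -> tuple[np.ndarray, pd.Series]:
    """Agglomerative clustering of samples on major-isoform class.

    Jaccard distance on the binarised (noncoding = 1) genes × samples matrix,
    average linkage; returns (linkage matrix, k-cluster labels indexed by
    sample).  A constant matrix yields a single cluster with a warning.
    """
    if status.shape[1] < 2:
        raise ValueError("clustering needs >= 2 samples")
    binary = (status == NONCODING).to_numpy(dtype=bool).T  # samples × genes
    if bool(np.all(binary == binary[0])):
        import warnings

        warnings.warn("constant status matrix: all samples in one cluster")
        labels = pd.Series(1, index=status.columns, name="cluster")
        z = linkage(np.zeros((binary.shape[0], 1)), method="average")
        return z, labels
    d = pdist(binary, metric="jaccard")
    z = linkage(d, method="average")
    labels = pd.Series(
        fcluster(z, t=k, criterion="maxclust"), index=status.columns, name="cluster"
    )
    return z, labels


def calls_to_tsv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def switches_to_tsv(records: Sequence[SwitchRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "design": r.design,
                "direction": r.direction,
                "switch_fraction": r.switch_fraction,
                "driver_biotype": r.driver_biotype or "",
            }
            for r in records
        ],
        columns=["gene_id", "design", "direction", "switch_fraction", "driver_biotype"],
    ).to_csv(path, sep="\t", index=False)
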