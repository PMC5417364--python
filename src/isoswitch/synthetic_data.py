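"""Ground-truth simulator for catalogues, quantifications and cohorts.

Generates multi-isoform gene models by applying structural edits (SE, RI,
A5SS, A3SS) to a base coding transcript, then simulates time-course and
tumour/normal cohort expression with negative-binomial noise, junction read
support and per-intron coverage.  Every injected effect is recorded in a
:class:`SimTruth` ledger so downstream operations can be tested for
parameter recovery.  All randomness flows through one seeded generator.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .models import GeneCatalogue, GenomicInterval, JunctionRecord, TranscriptModel

# structural bounds for generated genes
MIN_EXONS, MAX_EXONS = 2, 12
EXON_LEN = (80, 500)
INTRON_LEN = (200, 5000)
NONCODING_ALT_BIOTYPES = ("processed_transcript", "nmd", "other_noncoding")


@dataclass
class SimConfig:
    """Parameters of the simulation; ``seed`` is mandatory."""

    n_genes: int = 100
    seed: int = 0
    # isoform count ~ Geometric(p), support >= 1; default p gives median 5
    isoform_geom_p: float = 1.0 - 0.5 ** 0.25
    max_isoforms: int = 12
    noncoding_fraction: float = 0.44
    ri_share: float = 0.5  # share of noncoding alt isoforms built by RI edits
    novel_fraction: float = 0.0  # alt isoforms flagged origin="novel"
    # expression
    switch_gene_fraction: float = 0.1
    switch_fold: float = 4.0
    nb_dispersion: float = 0.1
    depth: float = 20.0  # expected counts per FPKM unit (noise granularity)
    library_size_spread: float = 0.0  # lognormal sigma of per-sample factors
    n_replicates: int = 3
    gene_total_log_mean: float = 3.0
    gene_total_log_sigma: float = 0.8
    conserve_totals: bool = True  # gene totals invariant under switching
    total_change_fold: float = 2.0  # used when conserve_totals is False
    # junction support / intron coverage
    support_depth: float = 2.0  # expected junction reads per FPKM unit
    intron_base_density: float = 1.0  # baseline intron reads per kb
    ri_fold: float = 4.0  # injected intron-coverage fold for RI switch genes
    # cohort design
    n_normal: int = 10
    n_tumour: int = 100
    cohort_switch_genes: int = 20
    cohort_prevalence: float = 0.2
    cohort_background_flip: float = 0.0
    cohort_group_shift: float = 0.0
    planted_clusters: int = 0
    planted_block_size: int = 20

    def __post_init__(self) -> None:
        for name in (
            "noncoding_fraction",
            "ri_share",
            "novel_fraction",
            "switch_gene_fraction",
            "cohort_prevalence",
            "cohort_background_flip",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.switch_fold <= 0 or self.ri_fold <= 0:
            raise ValueError("fold parameters must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class IsoformTruth:
    transcript_id: str
    biotype: str
    edit_type: str | None = None  # None for the base isoform
    retained_intron: tuple[int, int] | None = None
    novel: bool = False


@dataclass
class GeneTruth:
    gene_id: str
    base_tx: str
    isoforms: list[IsoformTruth] = field(default_factory=list)
    is_switch_gene: bool = False
    designated_tx: str | None = None  # noncoding isoform the switch promotes
    driver_biotype: str | None = None
    ri_fold: float | None = None
    is_cohort_switch: bool = False
    prevalence: float | None = None
    cluster_block: int | None = None

    def noncoding_tx(self) -> list[IsoformTruth]:
        return [i for i in self.isoforms if i.biotype != "protein_coding"]


@dataclass
class SimTruth:
    """Ground-truth ledger of everything the simulator injected."""

    genes: dict[str, GeneTruth] = field(default_factory=dict)
    sample_groups: dict[str, str] = field(default_factory=dict)
    sample_clusters: dict[str, int] = field(default_factory=dict)
    junction_classes: list[tuple[dict, str]] = field(default_factory=list)

    def switch_genes(self) -> set[str]:
        return {g for g, t in self.genes.items() if t.is_switch_gene}

    def cohort_switch_gene_set(self) -> set[str]:
        return {g for g, t in self.genes.items() if t.is_cohort_switch}

    def to_json(self, path) -> None:
        payload = {
            "genes": {g: dataclasses.asdict(t) for g, t in sorted(self.genes.items())},
            "sample_groups": self.sample_groups,
            "sample_clusters": self.sample_clusters,
            "junction_classes": self.junction_classes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# --------------------------------------------------------------------------
# structural edits


def _edit_se(exons, rng):
    i = int(rng.integers(1, len(exons) - 1))
    removed = exons[i]
    return exons[:i] + exons[i + 1 :], ("SE", removed, None)


def _edit_ri(exons, rng):
    k = int(rng.integers(0, len(exons) - 1))
    retained = (exons[k][1], exons[k + 1][0])
    merged = exons[:k] + [(exons[k][0], exons[k + 1][1])] + exons[k + 2 :]
    return merged, ("RI", retained, retained)


def _shift_boundary(exons, rng, k, side):
    """Move one exon boundary into the exon body or the adjacent intron."""
    s, e = exons[k]
    if side == "end":  # boundary shared with the downstream intron
        intron_len = exons[k + 1][0] - e
        room_in = max(0, (e - s) - 40)
        room_out = max(0, intron_len - 20)
    else:
        intron_len = s - exons[k - 1][1]
        room_in = max(0, (e - s) - 40)
        room_out = max(0, intron_len - 20)
    choices = []
    if room_in >= 15:
        choices.append(("in", min(60, room_in)))
    if room_out >= 15:
        choices.append(("out", min(60, room_out)))
    if not choices:
        return None
    direction, cap = choices[int(rng.integers(0, len(choices)))]
    d = int(rng.integers(15, cap + 1))
    if side == "end":
        new = (s, e - d) if direction == "in" else (s, e + d)
    else:
        new = (s + d, e) if direction == "in" else (s - d, e)
    out = list(exons)
    out[k] = new
    return out


def _edit_donor(exons, rng, strand):
    """Alternative 5' splice site: perturb a donor-side exon boundary."""
    if strand == "+":
        k = int(rng.integers(0, len(exons) - 1))
        new = _shift_boundary(exons, rng, k, "end")
    else:
        k = int(rng.integers(1, len(exons)))
        new = _shift_boundary(exons, rng, k, "start")
    if new is None:
        return None
    return new, ("A5SS", tuple(new[k]), None)


def _edit_acceptor(exons, rng, strand):
    """Alternative 3' splice site: perturb an acceptor-side exon boundary."""
    if strand == "+":
        k = int(rng.integers(1, len(exons)))
        new = _shift_boundary(exons, rng, k, "start")
    else:
        k = int(rng.integers(0, len(exons) - 1))
        new = _shift_boundary(exons, rng, k, "end")
    if new is None:
        return None
    return new, ("A3SS", tuple(new[k]), None)


def _apply_edit(exons, edit_type, rng, strand):
    if edit_type == "SE":
        if len(exons) < 3:
            return None
        return _edit_se(exons, rng)
    if edit_type == "RI":
        if len(exons) < 2:
            return None
        return _edit_ri(exons, rng)
    if edit_type == "A5SS":
        return _edit_donor(exons, rng, strand)
    if edit_type == "A3SS":
        return _edit_acceptor(exons, rng, strand)
    raise ValueError(edit_type)


def _chain(exons) -> tuple:
    if len(exons) == 1:
        return ("mono", exons[0])
    return tuple((a[1], b[0]) for a, b in zip(exons, exons[1:]))


# --------------------------------------------------------------------------
# catalogue generation


def simulate_catalogue(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Generate a multi-isoform catalogue plus its truth ledger.

    Each gene has a base protein-coding transcript (2-12 exons, exon lengths
    80-500 bp, introns 200-5,000 bp) and alternative isoforms built by a
    single SE/RI/A5SS/A3SS edit, so every generated event is classifiable.
    Biotypes are drawn to hit ``cfg.noncoding_fraction`` over all transcripts.
    """
    rng = cfg.rng() if rng is None else rng
    n_iso = np.minimum(
        rng.geometric(cfg.isoform_geom_p, size=cfg.n_genes), cfg.max_isoforms
    )
    total_tx = int(n_iso.sum())
    n_alt = total_tx - cfg.n_genes
    # probability that an alt isoform is noncoding, chosen to land the
    # overall noncoding fraction (base isoforms are always coding)
    q_nc = 0.0 if n_alt == 0 else min(1.0, cfg.noncoding_fraction * total_tx / n_alt)

    transcripts: list[TranscriptModel] = []
    truth = SimTruth()
    cursors = {f"chr{i}": 10_000 for i in range(1, 6)}

    for g in range(cfg.n_genes):
        gene_id = f"G{g + 1:05d}"
        chrom = f"chr{g % 5 + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(MIN_EXONS, MAX_EXONS + 1))
        pos = cursors[chrom]
        exons = []
        for i in range(n_ex):
            length = int(rng.integers(*EXON_LEN))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(*INTRON_LEN))
        cursors[chrom] = pos + 50_000  # spacer so genes never overlap

        base_id = f"{gene_id}.t1"
        cds = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
        transcripts.append(
            TranscriptModel(
                base_id,
                gene_id,
                [GenomicInterval(chrom, s, e, strand) for s, e in exons],
                biotype="protein_coding",
                origin="reference",
                cds=cds,
            )
        )
        gt = GeneTruth(gene_id, base_id)
        gt.isoforms.append(IsoformTruth(base_id, "protein_coding"))

        chains = {_chain(exons)}
        made = 1
        attempts = 0
        while made < int(n_iso[g]) and attempts < 50 * int(n_iso[g]):
            attempts += 1
            noncoding = rng.random() < q_nc
            if noncoding:
                edit_type = (
                    "RI"
                    if rng.random() < cfg.ri_share
                    else ["SE", "A5SS", "A3SS"][int(rng.integers(0, 3))]
                )
            else:
                edit_type = ["SE", "A5SS", "A3SS"][int(rng.integers(0, 3))]
            res = _apply_edit(exons, edit_type, rng, strand)
            if res is None:
                continue
            new_exons, (etype, _coords, retained) = res
            ch = _chain(new_exons)
            if ch in chains:
                continue
            chains.add(ch)
            made += 1
            tid = f"{gene_id}.t{made}"
            if noncoding:
                biotype = (
                    "retained_intron"
                    if etype == "RI"
                    else NONCODING_ALT_BIOTYPES[int(rng.integers(0, 3))]
                )
            else:
                biotype = "protein_coding"
            novel = rng.random() < cfg.novel_fraction
            transcripts.append(
                TranscriptModel(
                    tid,
                    gene_id,
                    [GenomicInterval(chrom, s, e, strand) for s, e in new_exons],
                    biotype=biotype,
                    origin="novel" if novel else "reference",
                )
            )
            gt.isoforms.append(
                IsoformTruth(tid, biotype, etype, retained, novel)
            )
        truth.genes[gene_id] = gt

    return GeneCatalogue(transcripts), truth


def perturb_junctions(
    cat: GeneCatalogue,
    one_end_rate: float = 0.10,
    both_end_rate: float = 0.02,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> list[tuple[JunctionRecord, str]]:
    """Emit query junctions with injected perturbation classes.

    Each catalogue junction is returned unchanged (``complete``), with one
    end shifted to an unannotated coordinate (``partial``) or with both ends
    shifted (``novel``) at the given rates.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    ref = sorted(cat.junction_index)
    used = {(j.chrom, j.strand, j.donor) for j in ref} | {
        (j.chrom, j.strand, j.acceptor) for j in ref
    }

    def fresh(chrom, strand, near):
        while True:
            cand = near + int(rng.integers(5, 50))
            if (chrom, strand, cand) not in used:
                used.add((chrom, strand, cand))
                return cand

    out = []
    for j in ref:
        u = rng.random()
        if u < both_end_rate:
            out.append(
                (
                    JunctionRecord(
                        j.chrom, j.strand,
                        fresh(j.chrom, j.strand, j.donor),
                        fresh(j.chrom, j.strand, j.acceptor),
                    ),
                    "novel",
                )
            )
        elif u < both_end_rate + one_end_rate:
            if rng.random() < 0.5:
                out.append(
                    (
                        JunctionRecord(
                            j.chrom, j.strand, fresh(j.chrom, j.strand, j.donor), j.acceptor
                        ),
                        "partial",
                    )
                )
            else:
                out.append(
                    (
                        JunctionRecord(
                            j.chrom, j.strand, j.donor, fresh(j.chrom, j.strand, j.acceptor)
                        ),
                        "partial",
                    )
                )
        else:
            out.append((j, "complete"))
    return out


# --------------------------------------------------------------------------
# expression simulation


def _nb_noise(
    rng: np.random.Generator, expected: np.ndarray, dispersion: float, depth: float
) -> np.ndarray:
    """NB-count noise around expected FPKM, returned on the FPKM scale."""
    if dispersion <= 0:
        return expected.copy()
    mu = expected * depth
    n = 1.0 / dispersion
    p = n / (n + mu)
    counts = rng.negative_binomial(n, p)
    return counts / depth


def _gene_noise(
    rng: np.random.Generator,
    expected: np.ndarray,
    dispersion: float,
    depth: float,
) -> np.ndarray:
    """Gene-level NB total + multinomial isoform split, on the FPKM scale.

    ``expected`` is the isoforms x samples expected-FPKM block of one gene.
    Drawing the total once per sample keeps the gene-total distribution
    identical between conditions whose isoform composition differs — the
    property the conserved-totals null check relies on.
    """
    if dispersion <= 0:
        return expected.copy()
    totals = expected.sum(axis=0)
    mu = totals * depth
    n = 1.0 / dispersion
    p = n / (n + mu)
    tot_counts = rng.negative_binomial(n, p)
    out = np.empty_like(expected, dtype=float)
    for j in range(expected.shape[1]):
        if totals[j] <= 0:
            out[:, j] = 0.0
            continue
        out[:, j] = rng.multinomial(int(tot_counts[j]), expected[:, j] / totals[j])
    return out / depth


def _gene_shares(
    gt: GeneTruth, rng: np.random.Generator, switch: bool
) -> tuple[dict[str, float], str | None]:
    """Baseline isoform shares; base coding isoform is the expected major.

    For switch genes a designated noncoding isoform receives a substantial
    baseline share so that the configured fold robustly promotes it.
    """
    tids = [i.transcript_id for i in gt.isoforms]
    designated = None
    shares = {}
    if switch:
        nc = gt.noncoding_tx()
        designated = nc[int(rng.integers(0, len(nc)))].transcript_id
        s0 = rng.uniform(0.52, 0.60)
        sd = rng.uniform(0.18, 0.25)
        rest = [t for t in tids if t not in (gt.base_tx, designated)]
        shares[gt.base_tx] = s0
        shares[designated] = sd
        remainder = 1.0 - s0 - sd
        if rest:
            w = rng.dirichlet(np.ones(len(rest)))
            for t, wi in zip(rest, w):
                shares[t] = remainder * float(wi)
    else:
        s0 = rng.uniform(0.5, 0.6)
        rest = [t for t in tids if t != gt.base_tx]
        shares[gt.base_tx] = s0
        if rest:
            w = rng.dirichlet(np.ones(len(rest)))
            for t, wi in zip(rest, w):
                shares[t] = (1.0 - s0) * float(wi)
        else:
            shares[gt.base_tx] = 1.0
    return shares, designated


def simulate_timecourse(
    cat: GeneCatalogue,
    truth: SimTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    baseline_label: str = "0h",
    test_label: str = "24h",
):
    """Simulate a two-condition replicate design with isoform switches.

    For switch genes the designated noncoding isoform's expected share is
    multiplied by ``cfg.switch_fold`` in the test condition; shares are then
    renormalised so gene totals are conserved (unless
    ``cfg.conserve_totals=False``, in which case the test-condition total is
    additionally multiplied by ``cfg.total_change_fold`` — the positive
    control for the expression-contrast null check).

    Returns (quant DataFrame, metadata DataFrame, junction-support DataFrame,
    intron-coverage DataFrame, truth).
    """
    rng = cfg.rng() if rng is None else rng
    gene_ids = sorted(truth.genes)
    eligible = [g for g in gene_ids if truth.genes[g].noncoding_tx()]
    n_switch = int(round(cfg.switch_gene_fraction * len(gene_ids)))
    switch_set = set(
        rng.choice(eligible, size=min(n_switch, len(eligible)), replace=False).tolist()
    ) if n_switch and cfg.switch_fold != 1.0 else set()

    samples = [f"{baseline_label}_r{i + 1}" for i in range(cfg.n_replicates)] + [
        f"{test_label}_r{i + 1}" for i in range(cfg.n_replicates)
    ]
    conditions = [baseline_label] * cfg.n_replicates + [test_label] * cfg.n_replicates

    tx_order: list[str] = []
    blocks = []
    for g in gene_ids:
        gt = truth.genes[g]
        total = float(
            np.exp(rng.normal(cfg.gene_total_log_mean, cfg.gene_total_log_sigma))
        )
        is_switch = g in switch_set
        shares, designated = _gene_shares(gt, rng, is_switch)
        gt.is_switch_gene = is_switch
        gt.designated_tx = designated
        if is_switch and designated is not None:
            by_tx = {i.transcript_id: i for i in gt.isoforms}
            gt.driver_biotype = by_tx[designated].biotype
            if gt.driver_biotype == "retained_intron":
                gt.ri_fold = cfg.ri_fold
        test_shares = dict(shares)
        if is_switch and designated is not None:
            test_shares[designated] = shares[designated] * cfg.switch_fold
            z = sum(test_shares.values())
            test_shares = {t: v / z for t, v in test_shares.items()}
        test_total = total if cfg.conserve_totals else total * cfg.total_change_fold
        E = np.array(
            [
                [
                    (total * shares[i.transcript_id])
                    if c == baseline_label
                    else (test_total * test_shares[i.transcript_id])
                    for c in conditions
                ]
                for i in gt.isoforms
            ]
        )
        tx_order.extend(i.transcript_id for i in gt.isoforms)
        blocks.append(_gene_noise(rng, E, cfg.nb_dispersion, cfg.depth))

    Q = np.vstack(blocks)
    if cfg.library_size_spread > 0:
        Q = Q * np.exp(rng.normal(0, cfg.library_size_spread, size=len(samples)))
    q = pd.DataFrame(Q, index=tx_order, columns=samples)
    meta = pd.DataFrame({"condition": conditions}, index=pd.Index(samples, name="sample"))

    support = _junction_support(cat, q, cfg, rng)
    coverage = _intron_coverage(cat, truth, cfg, rng, samples, conditions, test_label)
    return q, meta, support, coverage, truth


def _junction_support(cat, q, cfg, rng) -> pd.DataFrame:
    """Junction read counts drawn consistent with isoform abundance."""
    junc_expr: dict[JunctionRecord, np.ndarray] = {}
    for t in cat.transcripts():
        if t.transcript_id not in q.index:
            continue
        vals = q.loc[t.transcript_id].to_numpy(dtype=float)
        for j in t.junctions():
            junc_expr[j] = junc_expr.get(j, 0) + vals
    rows = sorted(junc_expr)
    lam = np.array([junc_expr[j] * cfg.support_depth for j in rows])
    counts = rng.poisson(lam) if cfg.nb_dispersion > 0 else np.round(lam).astype(int)
    return pd.DataFrame(counts, index=pd.Index(rows), columns=q.columns)


def _intron_coverage(cat, truth, cfg, rng, samples, conditions, test_label):
    """Per-intron read counts; retained introns of RI switch genes are
    elevated by ``cfg.ri_fold`` in the test condition."""
    from .intron_retention import gene_introns

    records = []
    for g in sorted(truth.genes):
        gt = truth.genes[g]
        ri_intervals = []
        if gt.is_switch_gene and gt.ri_fold:
            by_tx = {i.transcript_id: i for i in gt.isoforms}
            iso = by_tx.get(gt.designated_tx)
            if iso and iso.retained_intron:
                ri_intervals.append(iso.retained_intron)
        for iv in gene_introns(cat, g):
            kb = len(iv) / 1000.0
            lam_base = kb * cfg.intron_base_density
            boosted = any(
                iv.start < r[1] and r[0] < iv.end for r in ri_intervals
            )
            row = {"gene_id": g, "chrom": iv.chrom, "start": iv.start, "end": iv.end}
            for s, c in zip(samples, conditions):
                lam = lam_base * (cfg.ri_fold if boosted and c == test_label else 1.0)
                row[s] = (
                    int(rng.poisson(lam)) if cfg.nb_dispersion > 0 else int(round(lam))
                )
            records.append(row)
    return pd.DataFrame(records)


def simulate_ontology(
    truth: SimTruth,
    rng: np.random.Generator,
    n_random_terms: int = 8,
    spike_recall: float = 0.9,
):
    """Toy GO-like DAG whose 'switch pathway' term marks injected switch genes.

    Returns (edges, annotation, names).  The spiked term annotates
    ``spike_recall`` of the switch genes plus a sprinkling of background
    genes, nested under a broader parent, so enrichment and the
    redundancy filter both have something to find.
    """
    genes = sorted(truth.genes)
    switch = sorted(truth.switch_genes() | truth.cohort_switch_gene_set())
    edges = [("T:SWITCH", "T:PROCESS"), ("T:PROCESS", "T:ROOT")]
    names = {
        "T:ROOT": "biological process",
        "T:PROCESS": "transcriptome remodelling",
        "T:SWITCH": "isoform switch pathway",
    }
    annotation: dict[str, set[str]] = {g: set() for g in genes}
    for g in switch:
        if rng.random() < spike_recall:
            annotation[g].add("T:SWITCH")
        else:
            annotation[g].add("T:PROCESS")
    background = [g for g in genes if g not in switch]
    for g in background:
        if rng.random() < 0.05:
            annotation[g].add("T:SWITCH")
        elif rng.random() < 0.2:
            annotation[g].add("T:PROCESS")
    for i in range(n_random_terms):
        term = f"T:RAND{i + 1:02d}"
        edges.append((term, "T:ROOT"))
        names[term] = f"random module {i + 1}"
        for g in genes:
            if rng.random() < 0.1:
                annotation[g].add(term)
    annotation = {g: t for g, t in annotation.items() if t}
    return edges, annotation, names


def simulate_reads(
    cat: GeneCatalogue,
    rng: np.random.Generator,
    samples: Sequence[str],
    n_reads: int = 2000,
    exon_intron_density_ratio: float = 500.0,
    intergenic_fraction: float = 0.02,
    read_len: int = 100,
    platforms: Sequence[str] = ("HiSeq", "GAII"),
) -> pd.DataFrame:
    """Read intervals over the catalogue with a set exon:intron density ratio.

    Reads are placed uniformly within a randomly chosen exonic or intronic
    region, with exon/intron totals weighted by length x density so the
    per-kb ratio is the injected parameter.  Exonic regions are the merged
    exons over all isoforms; intronic regions their complement within each
    gene span (matching the QC assignment precedence).  Platforms alternate
    across samples.
    """

    def merged(intervals):
        out = []
        for s, e in sorted(intervals):
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out

    exons: list[tuple[str, int, int]] = []
    introns: list[tuple[str, int, int]] = []
    for g in sorted(cat.genes):
        txs = cat.genes[g]
        chrom = txs[0].chrom
        merged_ex = merged([(e.start, e.end) for t in txs for e in t.exons])
        exons.extend((chrom, s, e) for s, e in merged_ex)
        for (s1, e1), (s2, e2) in zip(merged_ex, merged_ex[1:]):
            if e1 < s2:
                introns.append((chrom, e1, s2))
    exon_kb = sum((e - s) for _, s, e in exons) / 1000.0
    intron_kb = sum((e - s) for _, s, e in introns) / 1000.0
    w_exon = exon_intron_density_ratio * exon_kb
    w_intron = 1.0 * intron_kb
    p_exon = w_exon / (w_exon + w_intron)

    exon_lens = np.array([e - s for _, s, e in exons], dtype=float)
    intron_lens = np.array([e - s for _, s, e in introns], dtype=float)
    rows = []
    for si, sample in enumerate(samples):
        platform = platforms[si % len(platforms)]
        for _ in range(n_reads):
            u = rng.random()
            if u < intergenic_fraction:
                chrom = f"chr{int(rng.integers(1, 6))}"
                mid = int(rng.integers(1_000_000, 2_000_000))
            elif rng.random() < p_exon:
                i = int(rng.choice(len(exons), p=exon_lens / exon_lens.sum()))
                chrom, s, e = exons[i]
                mid = int(rng.integers(s, e))
            else:
                i = int(rng.choice(len(introns), p=intron_lens / intron_lens.sum()))
                chrom, s, e = introns[i]
                mid = int(rng.integers(s, e))
            # centre the read on the sampled midpoint so midpoint-based
            # assignment recovers the sampled feature exactly
            start = max(0, mid - read_len // 2)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + read_len,
                    "strand": "+",
                    "sample": sample,
                    "platform": platform,
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(
    cat: GeneCatalogue,
    truth: SimTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
):
    """Simulate a tumour/normal cohort with per-gene switch prevalence.

    Normal samples follow baseline composition.  In tumour samples a gene's
    base and designated-noncoding shares are swapped (flipping the major
    isoform to noncoding) when any of these fire: per-gene prevalence for
    designated cohort-switch genes, a background flip probability (raised by
    ``cfg.cohort_group_shift`` in the 'with_tumour' half), or membership of a
    planted cluster block.

    Returns (quant DataFrame, metadata DataFrame, truth).
    """
    rng = cfg.rng() if rng is None else rng
    gene_ids = sorted(truth.genes)
    eligible = [g for g in gene_ids if truth.genes[g].noncoding_tx()]
    n_sw = min(cfg.cohort_switch_genes, len(eligible))
    switch_set = (
        set(rng.choice(eligible, size=n_sw, replace=False).tolist()) if n_sw else set()
    )
    if cfg.cohort_prevalence * cfg.n_tumour < 1 and switch_set:
        import warnings

        warnings.warn("prevalence x n_tumour < 1: injected switches unobservable")

    normals = [f"N{i + 1:03d}" for i in range(cfg.n_normal)]
    tumours = [f"T{i + 1:03d}" for i in range(cfg.n_tumour)]
    samples = normals + tumours
    half = cfg.n_tumour // 2
    groups = {s: "normal" for s in normals}
    for i, s in enumerate(tumours):
        groups[s] = "tumour_free" if i < half else "with_tumour"
    truth.sample_groups = dict(groups)

    # planted cluster structure over tumour samples and disjoint gene blocks
    blocks: list[list[str]] = []
    if cfg.planted_clusters > 0:
        pool = [g for g in eligible if g not in switch_set]
        need = cfg.planted_clusters * cfg.planted_block_size
        if len(pool) < need:
            raise ValueError("not enough eligible genes for planted blocks")
        chosen = rng.choice(pool, size=need, replace=False).tolist()
        blocks = [
            chosen[i * cfg.planted_block_size : (i + 1) * cfg.planted_block_size]
            for i in range(cfg.planted_clusters)
        ]
        for ci, block in enumerate(blocks):
            for g in block:
                truth.genes[g].cluster_block = ci
        for i, s in enumerate(tumours):
            truth.sample_clusters[s] = i % cfg.planted_clusters

    tx_order: list[str] = []
    expect_rows: list[np.ndarray] = []
    n_samples = len(samples)
    for g in gene_ids:
        gt = truth.genes[g]
        total = float(
            np.exp(rng.normal(cfg.gene_total_log_mean, cfg.gene_total_log_sigma))
        )
        in_switch = g in switch_set
        shares, designated = _gene_shares(gt, rng, switch=bool(gt.noncoding_tx()))
        if not gt.noncoding_tx():
            designated = None
        gt.is_cohort_switch = in_switch
        gt.prevalence = cfg.cohort_prevalence if in_switch else None
        if designated is not None and gt.designated_tx is None:
            gt.designated_tx = designated
        designated = gt.designated_tx

        flip = np.zeros(n_samples, dtype=bool)
        if designated is not None:
            for si, s in enumerate(samples):
                if s in normals:
                    continue
                p_flip = 0.0
                if in_switch:
                    p_flip = max(p_flip, cfg.cohort_prevalence)
                bg = cfg.cohort_background_flip
                if groups[s] == "with_tumour":
                    bg += cfg.cohort_group_shift
                p_flip = max(p_flip, 0.0) if bg == 0 else 1 - (1 - p_flip) * (1 - bg)
                if gt.cluster_block is not None and truth.sample_clusters.get(s) == gt.cluster_block:
                    p_flip = 1.0
                flip[si] = rng.random() < p_flip

        tids = [i.transcript_id for i in gt.isoforms]
        base_vec = np.array([total * shares[t] for t in tids])
        if designated is not None:
            swapped = base_vec.copy()
            bi, di = tids.index(gt.base_tx), tids.index(designated)
            swapped[bi], swapped[di] = base_vec[di], base_vec[bi]
        else:
            swapped = base_vec
        gene_E = np.where(flip[None, :], swapped[:, None], base_vec[:, None])
        tx_order.extend(tids)
        expect_rows.append(_gene_noise(rng, gene_E, cfg.nb_dispersion, cfg.depth))

    Q = np.vstack(expect_rows)
    q = pd.DataFrame(Q, index=tx_order, columns=samples)
    meta = pd.DataFrame(
        {"group": [groups[s] for s in samples]}, index=pd.Index(samples, name="sample")
    )
    return q, meta, truth
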