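"""End-to-end orchestration: simulate → catalogue → events → switches →
introns → enrichment → QC → report, with a deterministic manifest.

Every stage output is a pure function of (inputs, config, seed); re-running
with the same config reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import catalogue as cat_mod
from . import io as io_mod
from . import isoform_switch as sw
from . import qc_metrics as qc
from .enrichment_stats import OntologyDag, bh_adjust, go_enrichment, rank_sum_test, reduce_redundant
from .intron_retention import global_ri_shift, intron_log2fc_matrix
from .splice_events import enumerate_gene_events, event_shift_test, events_table
from .synthetic_data import (
    SimConfig,
    simulate_catalogue,
    simulate_cohort,
    simulate_ontology,
    simulate_reads,
    simulate_timecourse,
)

log = logging.getLogger(__name__)

STAGES = ("simulate", "catalogue", "events", "switches", "introns", "enrichment", "qc", "report")


@dataclass
class RunConfig:
    out_dir: str = "run"
    design: str = "timecourse"  # timecourse | cohort
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # filter and test thresholds
    min_junc_reads: int = 2
    min_junc_samples: int = 2
    min_fpkm: float = 0.5
    min_fpkm_samples: int = 3
    min_fraction: float = 0.05
    event_fdr: float = 0.01
    enrichment_q: float = 0.01
    de_fold: float = 2.0
    de_q: float = 0.01
    expression_floor: float = 1.0
    k_clusters: int = 3
    epsilon: float = 0.1
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.design not in ("timecourse", "cohort"):
            raise ValueError(f"unknown design {self.design!r}")
        for name in ("min_junc_reads", "min_junc_samples", "min_fpkm", "min_fraction",
                     "event_fdr", "enrichment_q", "de_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        full = {s: True for s in STAGES}
        full.update(self.stages)
        self.stages = full

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def de_fold_filter(
    gene_totals: pd.DataFrame,
    baseline_samples: Sequence[str],
    test_samples: Sequence[str],
    fold: float = 2.0,
    q_threshold: float = 0.01,
    epsilon: float = 0.1,
) -> pd.DataFrame:
    """Differential-expression plumbing: fold filter plus rank-test BH q.

    A gene is flagged when |log2((mean test + eps)/(mean baseline + eps))|
    exceeds log2(fold) and the BH-adjusted rank-sum q falls below
    ``q_threshold``.  Note the exact rank-sum floor at small n (p = 0.1
    two-sided at 3 vs 3) makes very strict q thresholds unattainable there.
    """
    base = gene_totals[list(baseline_samples)]
    test = gene_totals[list(test_samples)]
    lfc = np.log2((test.mean(axis=1) + epsilon) / (base.mean(axis=1) + epsilon))
    pvals = []
    for g in gene_totals.index:
        _w, p = rank_sum_test(
            base.loc[g].tolist(), test.loc[g].tolist(), alternative="two-sided"
        )
        pvals.append(p)
    qvals = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "p": pvals,
            "q": qvals,
        },
        index=gene_totals.index,
    )
    out["flagged"] = (out["log2fc"].abs() > math.log2(fold)) & (out["q"] < q_threshold)
    return out


class PipelineRun:
    def __init__(self, config: RunConfig) -> None:
        self.config = config
        self.out = Path(config.out_dir)
        self.manifest: dict = {"config": asdict(config), "stages": {}, "outputs": {}}

    # ---------------- helpers

    def _write(self, name: str, writer) -> Path:
        path = self.out / name
        path.parent.mkdir(parents=True, exist_ok=True)
        writer(path)
        self.manifest["outputs"][name] = _sha256(path)
        return path

    def _groups(self, meta: pd.DataFrame) -> tuple[list[str], list[str]]:
        if self.config.design == "timecourse":
            col = meta["condition"]
            labels = sorted(col.unique())
            return (
                list(meta.index[col == labels[0]]),
                list(meta.index[col == labels[-1]]),
            )
        col = meta["group"]
        return list(meta.index[col == "normal"]), list(meta.index[col != "normal"])

    # ---------------- stages

    def run(self) -> dict:
        cfg = self.config
        self.out.mkdir(parents=True, exist_ok=True)
        try:
            state: dict = {}
            for stage in STAGES:
                if not cfg.stages.get(stage, True):
                    self.manifest["stages"][stage] = "skipped"
                    continue
                getattr(self, f"stage_{stage}")(state)
                self.manifest["stages"][stage] = "ok"
                log.info("stage %s done", stage)
        except Exception:
            (self.out / "FAILED").write_text("pipeline failed; partial outputs retained\n")
            raise
        self._write(
            "manifest.json",
            lambda p: p.write_text(json.dumps(self.manifest, indent=1, sort_keys=True) + "\n"),
        )
        return self.manifest

    def stage_simulate(self, state: dict) -> None:
        cfg = self.config
        sim = cfg.sim_config()
        rng = sim.rng()
        cat, truth = simulate_catalogue(sim, rng)
        if cfg.design == "timecourse":
            q, meta, support, coverage, truth = simulate_timecourse(cat, truth, sim, rng)
            state["coverage"] = coverage
            self._write("coverage.tsv", lambda p: io_mod.write_coverage_tsv(coverage, p))
            self._write("support.tsv", lambda p: io_mod.write_junction_support_tsv(support, p))
            state["support"] = support
        else:
            q, meta, truth = simulate_cohort(cat, truth, sim, rng)
        edges, annotation, names = simulate_ontology(truth, rng)
        reads = simulate_reads(cat, rng, samples=list(q.columns)[: min(6, q.shape[1])])
        state.update(cat=cat, truth=truth, q=q, meta=meta,
                     ontology=(edges, annotation, names), reads=reads)
        self._write("catalogue.gtf", lambda p: io_mod.write_gtf(cat, open(p, "w")))
        self._write("quant.tsv", lambda p: io_mod.write_quant_tsv(q, p))
        self._write("meta.tsv", lambda p: io_mod.write_metadata_tsv(meta, p))
        self._write("truth.json", lambda p: truth.to_json(p))
        self._write(
            "ontology.tsv",
            lambda p: pd.DataFrame(edges, columns=["child_id", "parent_id"]).to_csv(
                p, sep="\t", index=False
            ),
        )
        self._write(
            "annotation.tsv",
            lambda p: pd.DataFrame(
                [(g, t) for g in sorted(annotation) for t in sorted(annotation[g])],
                columns=["gene_id", "term_id"],
            ).to_csv(p, sep="\t", index=False),
        )
        self._write("reads.tsv", lambda p: reads.to_csv(p, sep="\t", index=False))

    def stage_catalogue(self, state: dict) -> None:
        cfg = self.config
        if "cat" in state:  # keeps novel/reference origin flags
            cat = state["cat"]
        else:
            with open(self.out / "catalogue.gtf") as fh:
                cat = cat_mod.parse_annotation(fh)
            state["cat"] = cat
        q = io_mod.read_quant_tsv(self.out / "quant.tsv")
        n0 = len(cat)
        if "support" in state:
            cat = cat_mod.filter_junction_support(
                cat, state["support"], cfg.min_junc_reads, cfg.min_junc_samples
            )
        n1 = len(cat)
        cat = cat_mod.filter_expression(cat, q, cfg.min_fpkm, cfg.min_fpkm_samples)
        state["filtered_cat"] = cat
        classes = cat_mod.classify_junctions(sorted(cat.junction_index), cat)
        self._write(
            "junctions.bed",
            lambda p: io_mod.write_junction_bed(sorted(classes.items()), open(p, "w")),
        )
        self._write("filtered.gtf", lambda p: io_mod.write_gtf(cat, open(p, "w")))
        self.manifest["stages"]["catalogue_counts"] = {
            "input_tx": n0, "after_junction_filter": n1, "after_expression_filter": len(cat),
        }

    def stage_events(self, state: dict) -> None:
        cfg = self.config
        cat = state["filtered_cat"]
        q = state["q"]
        group_a, group_b = self._groups(state["meta"])
        events = []
        for gid in cat.gene_ids():
            events.extend(enumerate_gene_events(cat.genes[gid]))
        table = events_table(events, q)
        if events and len(group_a) >= 2 and len(group_b) >= 2:
            dirs, ps = [], []
            for ev in events:
                d, p = event_shift_test(ev, q, group_a, group_b)
                dirs.append(d)
                ps.append(p)
            table["direction"] = dirs
            table["p"] = ps
            table["q"] = bh_adjust(ps)
            table["significant"] = table["q"] < cfg.event_fdr
        state["events"] = events
        self._write("events.tsv", lambda p: table.to_csv(p, sep="\t", index=False))

    def stage_switches(self, state: dict) -> None:
        cfg = self.config
        cat = state["filtered_cat"]
        q = state["q"]
        meta = state["meta"]
        calls = sw.call_major_isoforms(cat, q, floor=cfg.expression_floor)
        self._write("calls.tsv", lambda p: sw.calls_to_tsv(calls, p))
        group_a, group_b = self._groups(meta)
        if cfg.design == "timecourse":
            records = sw.timecourse_switches(cat, q, group_a, group_b, cfg.expression_floor)
        else:
            records = sw.cohort_switch_genes(calls, group_a, group_b, cfg.min_fraction)
        self._write("switches.tsv", lambda p: sw.switches_to_tsv(records, p))
        state["switch_genes"] = sorted(
            {r.gene_id for r in records if r.direction == "coding_to_noncoding"}
        )
        profiles = []
        for s in meta.index:
            try:
                prof = sw.noncoding_proportion(calls, s)
            except ValueError:
                continue
            profiles.append(
                {
                    "sample": s,
                    "group": meta.iloc[:, 0][s],
                    "n_expressed": prof.n_expressed,
                    "n_noncoding_major": prof.n_noncoding_major,
                    "proportion": prof.proportion,
                }
            )
        self._write(
            "noncoding_proportion.tsv",
            lambda p: pd.DataFrame(profiles).to_csv(p, sep="\t", index=False),
        )
        if cfg.design == "cohort" and len(meta) >= 2:
            _z, labels = sw.cluster_samples(sw.status_matrix(calls), k=cfg.k_clusters)
            self._write(
                "clusters.tsv",
                lambda p: labels.to_frame().to_csv(p, sep="\t", index_label="sample"),
            )

    def stage_introns(self, state: dict) -> None:
        cfg = self.config
        if "coverage" not in state:
            self.manifest["stages"]["introns"] = "skipped (no coverage input)"
            return
        cat = state["cat"]
        truth = state["truth"]
        meta = state["meta"]
        q = state["q"]
        group_a, group_b = self._groups(meta)
        try:
            shift, p = global_ri_shift(q, cat, group_a, group_b, paired=True)
            summary = {"median_log2_shift": shift, "p": p}
        except ValueError as exc:
            summary = {"error": str(exc)}
        self._write(
            "ri_summary.json",
            lambda path: path.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n"),
        )
        # per-intron fold-change profile for RI-driven switch genes
        ri_genes = [
            g for g, t in sorted(truth.genes.items())
            if t.is_switch_gene and t.driver_biotype == "retained_intron"
        ][:5]
        mats = []
        for g in ri_genes:
            m = intron_log2fc_matrix(
                cat, g, state["coverage"], group_a, {"test": group_b}, cfg.epsilon
            )
            m.insert(0, "gene_id", g)
            mats.append(m.reset_index())
        if mats:
            out = pd.concat(mats, ignore_index=True)
            self._write("intron_log2fc.tsv", lambda p: out.to_csv(p, sep="\t", index=False))

    def stage_enrichment(self, state: dict) -> None:
        cfg = self.config
        edges, annotation, names = state["ontology"]
        dag = OntologyDag(edges, annotation, names)
        universe = sorted(state["truth"].genes)
        gene_set = [g for g in state.get("switch_genes", []) if g in set(universe)]
        if not gene_set:
            self.manifest["stages"]["enrichment"] = "skipped (empty switch set)"
            return
        results = go_enrichment(gene_set, universe, dag, cfg.enrichment_q)
        results = reduce_redundant(results, dag)
        df = pd.DataFrame(
            [
                {
                    "term_id": r.term_id, "term_name": r.term_name,
                    "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                    "p": r.p, "q": r.q, "enriched": r.enriched,
                }
                for r in results
            ]
        )
        self._write("enrichment.tsv", lambda p: df.to_csv(p, sep="\t", index=False))

    def stage_qc(self, state: dict) -> None:
        cat = state["cat"]
        reads = state["reads"]
        rows = []
        ratios, platforms = [], []
        exon_kb = qc.exonic_kb(cat)
        intron_kb = qc.intronic_kb(cat)
        for sample, sub in reads.groupby("sample", sort=True):
            b = qc.assign_regions(sub, cat, sample=sample)
            rows.append(b)
            exonic = b.counts["exon_cds"] + b.counts["utr"]
            r = qc.exon_intron_ratio(sample, exonic, b.counts["intron"], exon_kb, intron_kb)
            ratios.append(r)
            platforms.append(str(sub["platform"].iloc[0]))
        table = qc.breakdown_table(rows)
        table["exon_intron_ratio"] = [r.ratio for r in ratios]
        table["platform"] = platforms
        medians, p = qc.platform_consistency(ratios, platforms)
        self._write("qc.tsv", lambda path: table.to_csv(path, sep="\t", index=False))
        self._write(
            "qc_platforms.json",
            lambda path: path.write_text(
                json.dumps({"medians": medians, "p": p}, indent=1, sort_keys=True) + "\n"
            ),
        )

    def stage_report(self, state: dict) -> None:
        cfg = self.config
        lines = ["# isoswitch run summary", ""]
        counts = self.manifest["stages"].get("catalogue_counts")
        if counts:
            lines += [
                "## Catalogue",
                f"- transcripts in: {counts['input_tx']}",
                f"- after junction-support filter: {counts['after_junction_filter']}",
                f"- after expression filter: {counts['after_expression_filter']}",
                "",
            ]
        if "events" in state:
            lines.append("## Splicing events")
            by_type: dict[str, int] = {}
            for ev in state["events"]:
                by_type[ev.event_type] = by_type.get(ev.event_type, 0) + 1
            for t in sorted(by_type):
                lines.append(f"- {t}: {by_type[t]}")
            lines.append("")
        if "switch_genes" in state:
            lines += [
                "## Coding→noncoding switches",
                f"- design: {cfg.design}",
                f"- switch genes: {len(state['switch_genes'])}",
                "",
            ]
        lines.append(
            "_DE calling uses a fold-change + rank-test surrogate, not a "
            "negative-binomial model._"
        )
        self._write("report.md", lambda p: p.write_text("\n".join(lines) + "\n"))


def run(config: RunConfig) -> dict:
    """Execute all enabled stages; returns the manifest."""
    return PipelineRun(config).run()
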