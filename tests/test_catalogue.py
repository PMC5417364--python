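import io

import pandas as pd
import pytest

from isoswitch import catalogue as cat_mod
from isoswitch.io import read_gtf, write_gtf, GtfParseError
from isoswitch.models import GeneCatalogue, JunctionRecord
from isoswitch.synthetic_data import SimConfig, perturb_junctions, simulate_catalogue

from conftest import make_tx

GTF_MINIMAL = (
    'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
    'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
)


class TestParseAnnotation:
    def test_coordinate_convention(self):
        cat = cat_mod.parse_annotation(io.StringIO(GTF_MINIMAL))
        t = cat.transcript("t1")
        assert (t.exons[0].start, t.exons[0].end) == (100, 200)

    def test_two_exons_one_junction(self):
        cat = cat_mod.parse_annotation(io.StringIO(GTF_MINIMAL))
        assert len(cat) == 1
        assert len(cat.transcript("t1").exons) == 2
        assert set(cat.junction_index) == {JunctionRecord("chr1", "+", 200, 300)}

    def test_three_transcript_gene_junction_union(self, three_tx_gene, tmp_path):
        # oracle: hand count of distinct introns in the fixture
        # t1: (200,300),(400,500); t2: (200,500); t3: (400,500)
        buf = io.StringIO()
        write_gtf(three_tx_gene, buf)
        buf.seek(0)
        cat = cat_mod.parse_annotation(buf)
        assert cat.n_genes() == 1 and len(cat) == 3
        expected = {
            JunctionRecord("chr1", "+", 200, 300),
            JunctionRecord("chr1", "+", 400, 500),
            JunctionRecord("chr1", "+", 200, 500),
        }
        assert set(cat.junction_index) == expected

    def test_malformed_line_reports_lineno(self):
        bad = GTF_MINIMAL + "chr1\tonly\tthree\n"
        with pytest.raises(GtfParseError, match="line 3"):
            cat_mod.parse_annotation(io.StringIO(bad))

    def test_bad_record_rejected_not_fatal(self, caplog):
        bad = GTF_MINIMAL + (
            'chr1\tsrc\texon\t500\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t2";\n'
        )
        with caplog.at_level("WARNING"):
            cat = cat_mod.parse_annotation(io.StringIO(bad))
        assert "t2" not in cat

    def test_roundtrip_identity(self, three_tx_gene):
        buf = io.StringIO()
        write_gtf(three_tx_gene, buf)
        buf.seek(0)
        back = read_gtf(buf)
        for t in three_tx_gene.transcripts():
            r = back.transcript(t.transcript_id)
            assert [(e.start, e.end) for e in r.exons] == [
                (e.start, e.end) for e in t.exons
            ]
            assert r.biotype == t.biotype and r.gene_id == t.gene_id


class TestClassifyJunction:
    @pytest.fixture
    def ref(self):
        return GeneCatalogue([make_tx("r1", [(100, 200), (500, 600), (800, 900)])])

    def test_complete(self, ref):
        assert cat_mod.classify_junction(JunctionRecord("chr1", "+", 200, 500), ref) == "complete"

    def test_partial_donor_known(self, ref):
        assert cat_mod.classify_junction(JunctionRecord("chr1", "+", 200, 550), ref) == "partial"

    def test_partial_acceptor_known(self, ref):
        assert cat_mod.classify_junction(JunctionRecord("chr1", "+", 250, 500), ref) == "partial"

    def test_novel(self, ref):
        assert cat_mod.classify_junction(JunctionRecord("chr1", "+", 250, 550), ref) == "novel"

    def test_both_ends_known_unpaired_is_novel(self, ref):
        # donor of junction 1, acceptor of junction 2, never annotated together
        assert cat_mod.classify_junction(JunctionRecord("chr1", "+", 200, 800), ref) == "novel"

    def test_partition_property(self, ref):
        queries = [
            JunctionRecord("chr1", "+", d, a)
            for d, a in [(200, 500), (200, 550), (250, 500), (250, 550), (600, 800)]
        ]
        classes = cat_mod.classify_junctions(queries, ref)
        counts = pd.Series(list(classes.values())).value_counts()
        assert counts.sum() == len(queries)

    def test_simulated_perturbation_rates(self):
        cfg = SimConfig(n_genes=150, seed=3)
        cat, _truth = simulate_catalogue(cfg)
        queries = perturb_junctions(cat, one_end_rate=0.10, both_end_rate=0.02, seed=9)
        n = len(queries)
        assert n > 300
        correct = sum(
            1 for j, want in queries if cat_mod.classify_junction(j, cat) == want
        )
        assert correct == n  # injected class is always recovered
        frac_partial = sum(1 for _, w in queries if w == "partial") / n
        frac_novel = sum(1 for _, w in queries if w == "novel") / n
        # realised rates within ~4 binomial sigma of injected rates
        assert abs(frac_partial - 0.10) < 4 * (0.10 * 0.90 / n) ** 0.5
        assert abs(frac_novel - 0.02) < 4 * (0.02 * 0.98 / n) ** 0.5


class TestFilterJunctionSupport:
    def _one_junction_cat(self):
        return GeneCatalogue(
            [
                make_tx("ref1", [(100, 200), (500, 600)]),
                make_tx("nov1", [(100, 250), (500, 600)], origin="novel"),
            ]
        )

    def _sup(self, counts):
        return pd.DataFrame(
            [counts],
            index=pd.Index([JunctionRecord("chr1", "+", 250, 500)]),
            columns=[f"s{i}" for i in range(len(counts))],
        )

    def test_threshold_met_exactly(self):
        out = cat_mod.filter_junction_support(self._one_junction_cat(), self._sup([2, 2, 0]))
        assert "nov1" in out

    def test_no_sample_reaches_two_reads(self):
        out = cat_mod.filter_junction_support(self._one_junction_cat(), self._sup([1, 1, 1]))
        assert "nov1" not in out

    def test_reference_always_retained(self):
        out = cat_mod.filter_junction_support(self._one_junction_cat(), self._sup([0, 0, 0]))
        assert "ref1" in out

    def test_fixture_survivors(self, filter_fixture):
        cat, sup, _fpkm, junction_survivors, _ = filter_fixture
        out = cat_mod.filter_junction_support(cat, sup)
        novel_kept = {t.transcript_id for t in out.transcripts() if t.origin == "novel"}
        assert novel_kept == junction_survivors

    def test_idempotent(self, filter_fixture):
        cat, sup, _fpkm, _js, _ = filter_fixture
        once = cat_mod.filter_junction_support(cat, sup)
        twice = cat_mod.filter_junction_support(once, sup)
        assert set(once.transcript_ids()) == set(twice.transcript_ids())

    def test_only_removes(self, filter_fixture):
        cat, sup, _fpkm, _js, _ = filter_fixture
        out = cat_mod.filter_junction_support(cat, sup)
        assert set(out.transcript_ids()) <= set(cat.transcript_ids())

    def test_empty_support_drops_all_novel(self, caplog):
        cat = self._one_junction_cat()
        empty = pd.DataFrame(index=pd.Index([]), columns=[])
        with caplog.at_level("WARNING"):
            out = cat_mod.filter_junction_support(cat, empty)
        assert "nov1" not in out and "ref1" in out


class TestFilterExpression:
    def _cat(self):
        return GeneCatalogue([make_tx("t1", [(100, 200), (500, 600)])])

    def _q(self, vals):
        return pd.DataFrame([vals], index=["t1"], columns=[f"s{i}" for i in range(len(vals))])

    def test_retained_three_above(self):
        assert "t1" in cat_mod.filter_expression(self._cat(), self._q([0.6, 0.6, 0.6, 0.0]))

    def test_strict_inequality_at_boundary(self):
        assert "t1" not in cat_mod.filter_expression(self._cat(), self._q([0.5, 0.5, 0.5, 0.5]))

    def test_fixture_survivors(self, filter_fixture):
        cat, _sup, fpkm, _js, fpkm_survivors = filter_fixture
        out = cat_mod.filter_expression(cat, fpkm)
        assert set(out.transcript_ids()) == fpkm_survivors

    def test_empty_genes_removed(self, filter_fixture):
        cat, _sup, fpkm, _js, _fs = filter_fixture
        out = cat_mod.filter_expression(cat, fpkm)
        assert all(out.genes[g] for g in out.gene_ids())

    def test_idempotent(self, filter_fixture):
        cat, _sup, fpkm, _js, _fs = filter_fixture
        once = cat_mod.filter_expression(cat, fpkm)
        twice = cat_mod.filter_expression(once, fpkm)
        assert set(once.transcript_ids()) == set(twice.transcript_ids())

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="filter needs"):
            cat_mod.filter_expression(self._cat(), self._q([1.0, 1.0]))


class TestMergeCatalogues:
    def test_duplicate_chain_not_added(self):
        ref = GeneCatalogue([make_tx("r1", [(100, 200), (500, 600)])])
        nov = GeneCatalogue(
            [make_tx("n1", [(90, 200), (500, 610)], gene="X", origin="novel")]
        )  # same intron chain, different ends -> duplicate
        merged = cat_mod.merge_catalogues(ref, [nov])
        assert len(merged) == 1

    def test_single_exon_containment_inherits_gene(self):
        ref = GeneCatalogue([make_tx("r1", [(100, 200), (500, 600)], gene="GENE_A")])
        nov = GeneCatalogue([make_tx("n1", [(120, 180)], gene="X", origin="novel")])
        merged = cat_mod.merge_catalogues(ref, [nov])
        assert merged.transcript("n1").gene_id == "GENE_A"

    def test_no_overlap_gets_fresh_gene(self):
        ref = GeneCatalogue([make_tx("r1", [(100, 200), (500, 600)], gene="GENE_A")])
        nov = GeneCatalogue([make_tx("n1", [(90_000, 90_500)], gene="X", origin="novel")])
        merged = cat_mod.merge_catalogues(ref, [nov])
        assert merged.transcript("n1").gene_id.startswith("NOVELG")

    def test_equal_overlap_tie_lexicographic(self):
        ref = GeneCatalogue(
            [
                make_tx("r1", [(100, 200)], gene="GB"),
                make_tx("r2", [(100, 200)], gene="GA", strand="+"),
            ]
        )
        nov = GeneCatalogue([make_tx("n1", [(100, 200), (300, 400)], gene="X", origin="novel")])
        merged = cat_mod.merge_catalogues(ref, [nov])
        assert merged.transcript("n1").gene_id == "GA"

    def test_order_insensitive(self):
        ref = GeneCatalogue([make_tx("r1", [(100, 200), (500, 600)], gene="GENE_A")])
        n1 = GeneCatalogue([make_tx("n1", [(100, 250), (500, 600)], gene="X", origin="novel")])
        n2 = GeneCatalogue([make_tx("n2", [(100, 200), (550, 600)], gene="Y", origin="novel")])
        a = cat_mod.merge_catalogues(ref, [n1, n2])
        b = cat_mod.merge_catalogues(ref, [n2, n1])
        chains_a = sorted(str(t.intron_chain()) for t in a.transcripts())
        chains_b = sorted(str(t.intron_chain()) for t in b.transcripts())
        assert chains_a == chains_b

    def test_simulated_merge_bookkeeping(self):
        cfg = SimConfig(n_genes=100, seed=21)
        ref, _ = simulate_catalogue(cfg)
        # novel models: one unique A5SS-like variant per of 50 genes
        novels = []
        chains = {t.intron_chain() for t in ref.transcripts()}
        n_new = 0
        for gid in sorted(ref.genes)[:50]:
            base = ref.genes[gid][0]
            exons = [(e.start, e.end) for e in base.exons]
            if len(exons) < 2:
                continue
            exons[0] = (exons[0][0], exons[0][1] - 17)
            t = make_tx(
                f"NOV_{gid}", exons, gene="X",
                chrom=base.chrom, strand=base.strand, origin="novel",
            )
            novels.append(t)
            if t.intron_chain() not in chains:
                n_new += 1
                chains.add(t.intron_chain())
        merged = cat_mod.merge_catalogues(ref, [GeneCatalogue(novels)])
        assert len(merged) == len(ref) + n_new


class TestClassifyBiotype:
    def test_exon_spanning_intron_is_retained(self):
        peer = make_tx("p", [(100, 200), (500, 600)])
        t = make_tx("n", [(100, 600)], origin="novel", biotype="novel_unclassified")
        assert cat_mod.classify_biotype(t, [peer, t]) == "retained_intron"

    def test_sequence_free_default_processed(self):
        peer = make_tx("p", [(100, 200), (500, 600)])
        t = make_tx("n", [(100, 200), (550, 600)], origin="novel")
        assert cat_mod.classify_biotype(t, [peer, t]) == "processed_transcript"

    def test_reference_keeps_annotation(self):
        t = make_tx("r", [(100, 200)], biotype="nmd")
        assert cat_mod.classify_biotype(t, [t]) == "nmd"

    def _fetch_factory(self, seq_by_pos: str):
        def fetch(chrom, start, end):
            return seq_by_pos[start:end]

        return fetch

    def test_long_orf_gives_protein_coding(self):
        # 2 exons; ORF of 120 codons spliced across the junction
        orf = "ATG" + "GCT" * 119 + "TAA"
        genome = ["A"] * 2000
        spliced_positions = list(range(100, 300)) + list(range(500, 800))
        for pos, base in zip(spliced_positions, orf):
            genome[pos] = base
        fetch = self._fetch_factory("".join(genome))
        t = make_tx("n", [(100, 300), (500, 800)], origin="novel")
        peer = make_tx("p", [(100, 300), (500, 800)])
        assert cat_mod.classify_biotype(t, [peer, t], fetch) == "protein_coding"

    def test_premature_stop_gives_nmd(self):
        # ORF ends >50 nt before the last junction (at transcript pos 200)
        orf = "ATG" + "GCT" * 110 + "TAA"  # 336 nt, ends at 436
        genome = ["A"] * 3000
        # exon1 long enough to hold the ORF entirely, junction far downstream
        spliced_positions = list(range(100, 700)) + list(range(1500, 1700))
        for pos, base in zip(spliced_positions, orf):
            genome[pos] = base
        fetch = self._fetch_factory("".join(genome))
        t = make_tx("n", [(100, 700), (1500, 1700)], origin="novel")
        peer = make_tx("p", [(100, 700), (1500, 1700)])
        assert cat_mod.classify_biotype(t, [peer, t], fetch) == "nmd"

    def test_simulated_ri_isoforms_all_recovered(self):
        cfg = SimConfig(n_genes=120, seed=5, noncoding_fraction=0.5, ri_share=0.8)
        cat, truth = simulate_catalogue(cfg)
        n_ri = 0
        for gid, gt in truth.genes.items():
            peers = cat.genes[gid]
            for iso in gt.isoforms:
                if iso.edit_type == "RI":
                    n_ri += 1
                    t = cat.transcript(iso.transcript_id).copy(origin="novel")
                    assert cat_mod.classify_biotype(t, peers) == "retained_intron"
        assert n_ri >= 100  # the check exercised a substantial sample
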