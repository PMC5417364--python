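import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from isoswitch import isoform_switch as sw
from isoswitch.models import GeneCatalogue

from conftest import make_tx


def two_isoform_gene():
    return [
        make_tx("A", [(100, 200), (500, 600)]),
        make_tx("B", [(100, 600)], biotype="retained_intron"),
    ]


class TestCallMajorIsoform:
    def test_coding_argmax(self):
        q = pd.DataFrame({"s1": [10.0, 2.0]}, index=["A", "B"])
        call = sw.call_major_isoform(two_isoform_gene(), q, "s1")
        assert call.transcript_id == "A" and call.status == "coding"

    def test_noncoding_argmax(self):
        q = pd.DataFrame({"s1": [2.0, 10.0]}, index=["A", "B"])
        call = sw.call_major_isoform(two_isoform_gene(), q, "s1")
        assert call.transcript_id == "B" and call.status == "noncoding"

    def test_tie_prefers_coding(self):
        q = pd.DataFrame({"s1": [5.0, 5.0]}, index=["A", "B"])
        call = sw.call_major_isoform(two_isoform_gene(), q, "s1")
        assert call.transcript_id == "A" and call.status == "coding"

    def test_below_floor_not_expressed(self):
        q = pd.DataFrame({"s1": [0.3, 0.2]}, index=["A", "B"])
        call = sw.call_major_isoform(two_isoform_gene(), q, "s1")
        assert call.status == "not_expressed" and call.transcript_id is None

    def test_missing_gene_errors(self):
        q = pd.DataFrame({"s1": [1.0]}, index=["A"])
        with pytest.raises(KeyError):
            sw.call_major_isoform(two_isoform_gene(), q, "s1")

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(0)
        cat = GeneCatalogue(two_isoform_gene())
        q = pd.DataFrame(
            rng.gamma(2.0, 2.0, size=(2, 8)), index=["A", "B"],
            columns=[f"s{i}" for i in range(8)],
        )
        calls = sw.call_major_isoforms(cat, q)
        for s in q.columns:
            one = sw.call_major_isoform(two_isoform_gene(), q, s)
            row = calls[(calls["sample"] == s) & (calls["gene_id"] == "G1")].iloc[0]
            assert row["status"] == one.status
            assert (row["transcript_id"] == one.transcript_id) or (
                one.transcript_id is None and pd.isna(row["transcript_id"])
            )

    def test_sample_scaling_invariance(self):
        cat = GeneCatalogue(two_isoform_gene())
        q = pd.DataFrame({"s1": [4.0, 3.0], "s2": [3.0, 4.0]}, index=["A", "B"])
        before = sw.call_major_isoforms(cat, q)
        q2 = q.copy()
        q2["s1"] = q2["s1"] * 7.0
        after = sw.call_major_isoforms(cat, q2)
        b = before[before["sample"] == "s1"].iloc[0]
        a = after[after["sample"] == "s1"].iloc[0]
        assert a["transcript_id"] == b["transcript_id"]

    def test_column_permutation_permutes_calls(self):
        cat = GeneCatalogue(two_isoform_gene())
        q = pd.DataFrame({"s1": [4.0, 3.0], "s2": [3.0, 4.0]}, index=["A", "B"])
        calls = sw.call_major_isoforms(cat, q).set_index("sample")
        perm = sw.call_major_isoforms(cat, q[["s2", "s1"]]).set_index("sample")
        for s in ("s1", "s2"):
            assert calls.loc[s, "transcript_id"] == perm.loc[s, "transcript_id"]


class TestTimecourseSwitches:
    def _cat_q(self, base_vals, test_vals):
        cat = GeneCatalogue(two_isoform_gene())
        cols = {}
        for i, v in enumerate(base_vals):
            cols[f"b{i}"] = v
        for i, v in enumerate(test_vals):
            cols[f"t{i}"] = v
        q = pd.DataFrame(cols, index=["A", "B"])
        return cat, q, [f"b{i}" for i in range(len(base_vals))], [
            f"t{i}" for i in range(len(test_vals))
        ]

    def test_coding_to_noncoding_with_driver(self):
        cat, q, b, t = self._cat_q([[10, 2]] * 3, [[2, 10]] * 3)
        recs = sw.timecourse_switches(cat, q, b, t)
        assert len(recs) == 1
        assert recs[0].direction == "coding_to_noncoding"
        assert recs[0].driver_biotype == "retained_intron"

    def test_same_major_no_record(self):
        cat, q, b, t = self._cat_q([[10, 2]] * 3, [[8, 3]] * 3)
        assert sw.timecourse_switches(cat, q, b, t) == []

    def test_empty_condition_errors(self):
        cat, q, b, _t = self._cat_q([[10, 2]] * 3, [[2, 10]] * 3)
        with pytest.raises(ValueError):
            sw.timecourse_switches(cat, q, b, [])


class TestCohortSwitchGenes:
    def _calls(self, baseline, tumour_statuses):
        rows = []
        for i, st in enumerate(baseline):
            rows.append({"gene_id": "G1", "sample": f"n{i}", "transcript_id": "A", "status": st})
        for i, st in enumerate(tumour_statuses):
            rows.append({"gene_id": "G1", "sample": f"t{i}", "transcript_id": "A", "status": st})
        calls = pd.DataFrame(rows)
        return calls, [f"n{i}" for i in range(len(baseline))], [
            f"t{i}" for i in range(len(tumour_statuses))
        ]

    def test_six_percent_reported(self):
        calls, n, t = self._calls(["coding"] * 3, ["noncoding"] * 6 + ["coding"] * 94)
        recs = sw.cohort_switch_genes(calls, n, t, 0.05)
        assert len(recs) == 1
        assert recs[0].switch_fraction == pytest.approx(0.06)
        assert recs[0].direction == "coding_to_noncoding"

    def test_four_percent_not_reported(self):
        calls, n, t = self._calls(["coding"] * 3, ["noncoding"] * 4 + ["coding"] * 96)
        assert sw.cohort_switch_genes(calls, n, t, 0.05) == []

    def test_not_expressed_excluded_from_denominator(self):
        calls, n, t = self._calls(
            ["coding"] * 3, ["noncoding"] * 5 + ["coding"] * 45 + ["not_expressed"] * 50
        )
        recs = sw.cohort_switch_genes(calls, n, t, 0.05)
        assert recs[0].switch_fraction == pytest.approx(0.1)

    def test_no_baseline_no_fallback_errors(self):
        calls, _n, t = self._calls(["not_expressed"] * 2, ["coding"] * 5)
        with pytest.raises(ValueError):
            sw.cohort_switch_genes(calls, [f"n{i}" for i in range(2)], t, 0.05)

    def test_reference_fallback_used(self):
        calls, n, t = self._calls(["not_expressed"] * 2, ["noncoding"] * 2 + ["coding"] * 2)
        recs = sw.cohort_switch_genes(
            calls, n, t, 0.05, reference_baseline={"G1": "coding"}
        )
        assert recs[0].switch_fraction == pytest.approx(0.5)

    def test_min_fraction_zero_and_above_one(self):
        calls, n, t = self._calls(["coding"] * 3, ["noncoding"] + ["coding"] * 99)
        assert len(sw.cohort_switch_genes(calls, n, t, 0.0)) == 1
        assert sw.cohort_switch_genes(calls, n, t, 1.01) == []


class TestGroupClassSwitches:
    def _calls(self, a_status, b_status):
        rows = []
        for i, st in enumerate(a_status):
            rows.append({"gene_id": "G1", "sample": f"a{i}", "transcript_id": "x", "status": st})
        for i, st in enumerate(b_status):
            rows.append({"gene_id": "G1", "sample": f"b{i}", "transcript_id": "x", "status": st})
        return (
            pd.DataFrame(rows),
            [f"a{i}" for i in range(len(a_status))],
            [f"b{i}" for i in range(len(b_status))],
        )

    def test_modal_flip_reported(self):
        calls, a, b = self._calls(["coding"] * 3, ["noncoding", "noncoding", "coding"])
        assert sw.group_class_switches(calls, a, b) == ["G1"]

    def test_modal_same_not_reported(self):
        calls, a, b = self._calls(["coding"] * 3, ["coding"] * 3)
        assert sw.group_class_switches(calls, a, b) == []

    def test_direction_specific(self):
        calls, a, b = self._calls(["noncoding"] * 3, ["coding"] * 3)
        assert sw.group_class_switches(calls, a, b) == []


class TestNoncodingProportion:
    def _calls(self):
        rows = []
        statuses = ["noncoding"] * 3 + ["coding"] * 7
        for i, st in enumerate(statuses):
            rows.append({"gene_id": f"G{i}", "sample": "s1", "transcript_id": "x", "status": st})
        rows.append({"gene_id": "G10", "sample": "s1", "transcript_id": None,
                     "status": "not_expressed"})
        return pd.DataFrame(rows)

    def test_arithmetic(self):
        prof = sw.noncoding_proportion(self._calls(), "s1")
        assert prof.n_expressed == 10
        assert prof.proportion == pytest.approx(0.3)

    def test_all_coding_zero(self):
        calls = pd.DataFrame(
            [{"gene_id": f"G{i}", "sample": "s", "transcript_id": "x", "status": "coding"}
             for i in range(4)]
        )
        assert sw.noncoding_proportion(calls, "s").proportion == 0.0

    def test_counts_partition(self):
        prof = sw.noncoding_proportion(self._calls(), "s1")
        calls = self._calls()
        n_coding = ((calls["sample"] == "s1") & (calls["status"] == "coding")).sum()
        assert prof.n_noncoding_major + n_coding == prof.n_expressed

    def test_zero_expressed_errors(self):
        calls = pd.DataFrame(
            [{"gene_id": "G", "sample": "s", "transcript_id": None, "status": "not_expressed"}]
        )
        with pytest.raises(ValueError):
            sw.noncoding_proportion(calls, "s")

    def test_gene_order_invariant(self):
        calls = self._calls()
        shuffled = calls.sample(frac=1.0, random_state=1)
        assert (
            sw.noncoding_proportion(calls, "s1").proportion
            == sw.noncoding_proportion(shuffled, "s1").proportion
        )


class TestSwitchSetOverlap:
    def test_disjoint_near_one(self):
        universe = [f"g{i}" for i in range(1000)]
        p = sw.switch_set_overlap(universe[:5], universe[5:10], universe)
        assert p > 0.9

    def test_identical_sets_exact(self):
        universe = [f"g{i}" for i in range(10)]
        p = sw.switch_set_overlap(universe[:5], universe[:5], universe)
        assert p == pytest.approx(1 / 252)

    def test_overlap_three_exact_half(self):
        universe = [f"g{i}" for i in range(10)]
        set_a = universe[:5]
        set_b = universe[2:7]  # overlap 3
        assert sw.switch_set_overlap(set_a, set_b, universe) == pytest.approx(0.5)

    def test_not_in_universe_errors(self):
        with pytest.raises(ValueError):
            sw.switch_set_overlap(["zz"], ["g1"], ["g1"])

    def test_matches_bruteforce_small_universes(self):
        from oracles import hypergeom_tail_bruteforce

        for n_universe in (6, 10, 15):
            universe = [f"g{i}" for i in range(n_universe)]
            for na in (2, 4):
                for nb in (3, 5):
                    for k in range(0, min(na, nb) + 1):
                        set_a = universe[:na]
                        set_b = universe[na - k : na - k + nb]
                        p = sw.switch_set_overlap(set_a, set_b, universe)
                        want = hypergeom_tail_bruteforce(
                            len(set(set_a) & set(set_b)), na, nb, n_universe
                        )
                        assert p == pytest.approx(want)


class TestClusterSamples:
    def _status(self, cols):
        return pd.DataFrame(cols, index=[f"G{i}" for i in range(len(next(iter(cols.values()))))])

    def test_identical_samples_merge_first(self):
        status = self._status(
            {
                "s1": ["noncoding", "coding", "coding"],
                "s2": ["noncoding", "coding", "coding"],
                "s3": ["coding", "noncoding", "noncoding"],
            }
        )
        z, labels = sw.cluster_samples(status, k=2)
        assert z[0, 2] == 0.0  # first merge at distance zero
        assert labels["s1"] == labels["s2"] != labels["s3"]

    def test_complementary_samples_distance_one(self):
        status = self._status(
            {"s1": ["noncoding", "coding"], "s2": ["coding", "noncoding"]}
        )
        z, _labels = sw.cluster_samples(status, k=2)
        assert z[0, 2] == pytest.approx(1.0)

    def test_constant_matrix_single_cluster(self):
        status = self._status({"s1": ["coding"] * 3, "s2": ["coding"] * 3})
        with pytest.warns(UserWarning):
            _z, labels = sw.cluster_samples(status, k=3)
        assert labels.nunique() == 1
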