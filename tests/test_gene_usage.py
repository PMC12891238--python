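"""Usage frequencies, tumor deltas, enrichment tests, and CDR3 features."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bcrtme import clonal_structure as cl
from bcrtme import gene_usage as gu
from bcrtme import synthetic_cohort as sc


def usage_table(calls, productive=None, patient="P1", tissue="tumor", isotype="IGHM"):
    tbl, _ = sc.simulate_repertoire(len(calls),
                                    sc.CloneSizeDistribution(1, kind="uniform"),
                                    seed=0, patient_id=patient, tissue=tissue,
                                    isotype=isotype)
    tbl = tbl.copy()
    tbl["sequence_id"] = [f"{patient}_{tissue}_{i}" for i in range(len(calls))]
    tbl["v_call"] = calls
    if productive is not None:
        tbl["productive"] = productive
    return tbl


class TestUsageFrequencies:
    def test_single_gene_is_one(self):
        freqs = gu.usage_frequencies(usage_table(["IGHV3-7*01"] * 10))
        assert freqs.iloc[0]["IGHV3-7"] == 1.0

    def test_six_four_split(self):
        calls = ["IGHV3-7*01"] * 6 + ["IGHV1-24*01"] * 4
        freqs = gu.usage_frequencies(usage_table(calls))
        assert freqs.iloc[0]["IGHV3-7"] == pytest.approx(0.6)
        assert freqs.iloc[0]["IGHV1-24"] == pytest.approx(0.4)

    def test_non_productive_excluded_by_default(self):
        calls = ["IGHV3-7*01"] * 6 + ["IGHV1-24*01"] * 4
        productive = [True] * 6 + [False] * 4
        freqs = gu.usage_frequencies(usage_table(calls, productive))
        assert freqs.iloc[0]["IGHV3-7"] == 1.0
        assert "IGHV1-24" not in freqs.columns or freqs.iloc[0]["IGHV1-24"] == 0.0

    def test_rows_sum_to_one(self, mini_cohort):
        table, _, _ = mini_cohort
        freqs = gu.usage_frequencies(table, segment="v")
        assert np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9)


class TestDeltaVsBaseline:
    def _usage(self, data, patients):
        return pd.DataFrame(data, index=pd.Index(patients, name="patient_id"))

    def test_identical_usage_all_zero(self):
        u = self._usage({"a": [0.5, 0.6], "b": [0.5, 0.4]}, ["P1", "P2"])
        delta = gu.delta_vs_baseline(u, u.copy())
        assert (delta.values == 0).all()

    def test_subtraction(self):
        t = self._usage({"a": [0.2], "b": [0.8]}, ["P1"])
        b = self._usage({"a": [0.6], "b": [0.4]}, ["P1"])
        delta = gu.delta_vs_baseline(t, b)
        assert delta.loc["P1", "a"] == pytest.approx(-0.4)
        assert delta.loc["P1", "b"] == pytest.approx(0.4)

    def test_absent_gene_zero_filled(self):
        t = self._usage({"a": [0.9], "c": [0.1]}, ["P1"])
        b = self._usage({"a": [1.0]}, ["P1"])
        delta = gu.delta_vs_baseline(t, b)
        assert delta.loc["P1", "c"] == pytest.approx(0.1)

    def test_rows_sum_to_zero(self, mini_cohort):
        table, _, _ = mini_cohort
        freqs = gu.usage_frequencies(table)
        tumor = freqs.xs(("tumor", "IGHM"), level=("tissue", "isotype"))
        pbmc = freqs.xs(("PBMC", "IGHM"), level=("tissue", "isotype"))
        delta = gu.delta_vs_baseline(tumor, pbmc)
        assert np.allclose(delta.sum(axis=1), 0.0, atol=1e-9)

    def test_unpaired_patient_skipped_with_warning(self, caplog):
        t = self._usage({"a": [1.0, 1.0]}, ["P1", "P2"])
        b = self._usage({"a": [1.0]}, ["P1"])
        with caplog.at_level("WARNING"):
            delta = gu.delta_vs_baseline(t, b)
        assert list(delta.index) == ["P1"]
        assert any("P2" in r.message for r in caplog.records)


class TestCohortEnrichment:
    def test_all_zero_deltas_give_t0_p1(self):
        deltas = pd.DataFrame(0.0, index=[f"P{i}" for i in range(6)],
                              columns=["a", "b"])
        res = gu.cohort_enrichment_test(deltas, min_patients=0)
        row = res[res["gene"] == "a"].iloc[0]
        assert row["t"] == 0.0 and row["p"] == 1.0

    def test_zero_variance_reported_degenerate(self):
        deltas = pd.DataFrame({"a": [0.1] * 4, "b": [-0.1, 0.1, 0.05, -0.05]},
                              index=list("wxyz"))
        res = gu.cohort_enrichment_test(deltas, min_patients=0)
        row = res[res["gene"] == "a"].iloc[0]
        assert row["degenerate"]
        assert row["q"] == 0.0 and row["direction"] == "enriched"

    def test_spiked_genes_detected_without_false_positives(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(12)]
        spiked = {"g0", "g1", "g2"}
        deltas = pd.DataFrame(
            rng.normal(0, 0.02, size=(20, 12)), columns=genes,
            index=[f"P{i}" for i in range(20)])
        for g in spiked:
            deltas[g] += 0.05
        res = gu.cohort_enrichment_test(deltas, min_patients=0)
        hits = set(res.loc[res["significant"] & (res["direction"] == "enriched"), "gene"])
        assert hits == spiked

    def test_too_few_patients_rejected(self):
        deltas = pd.DataFrame({"a": [0.1]}, index=["P1"])
        with pytest.raises(ValueError, match="patients"):
            gu.cohort_enrichment_test(deltas)


class TestRecurrentTopGenes:
    def _deltas(self, rows, genes):
        return pd.DataFrame(rows, columns=genes,
                            index=[f"P{i}" for i in range(len(rows))])

    def test_shared_top_gene_counted(self):
        genes = ["a", "b", "c", "d", "e", "f"]
        rows = [[0.5, 0.1, 0.05, 0.02, 0.01, -0.68]] * 6
        res = gu.recurrent_top_genes(self._deltas(rows, genes), k=5, min_recurrence=5)
        assert res.loc[res["gene"] == "a", "n_patients_top_k"].iloc[0] == 6

    def test_below_min_recurrence_excluded(self):
        genes = [f"g{i}" for i in range(8)]
        rng = np.random.default_rng(1)
        rows = []
        for i in range(10):
            r = rng.normal(0, 0.01, 8)
            r[0] = 1.0 if i < 4 else -1.0  # g0 tops exactly 4 patients
            rows.append(r)
        res = gu.recurrent_top_genes(self._deltas(rows, genes), k=1, min_recurrence=5)
        assert "g0" not in set(res["gene"])

    def test_invariant_to_patient_and_column_order(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(10)]
        deltas = self._deltas(rng.normal(0, 0.05, size=(12, 10)), genes)
        a = gu.recurrent_top_genes(deltas, k=3, min_recurrence=2)
        shuffled = deltas.sample(frac=1, random_state=3)[list(reversed(genes))]
        b = gu.recurrent_top_genes(shuffled, k=3, min_recurrence=2)
        pd.testing.assert_frame_equal(a, b)


class TestCdr3Features:
    @pytest.mark.parametrize("seq,length,charge,basic,acidic", [
        ("CAW", 3, 0, 0.0, 0.0),
        ("CARKDEW", 7, 0, 2 / 7, 2 / 7),
        ("CRRRW", 5, 3, 3 / 5, 0.0),
    ])
    def test_hand_examples(self, seq, length, charge, basic, acidic):
        f = gu.cdr3_features(seq)
        assert (f.length, f.net_charge) == (length, charge)
        assert f.basic_fraction == pytest.approx(basic)
        assert f.acidic_fraction == pytest.approx(acidic)

    def test_histidine_basic_but_uncharged(self):
        f = gu.cdr3_features("CHHW")
        assert f.net_charge == 0
        assert f.basic_fraction == pytest.approx(0.5)

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            gu.cdr3_features("CAXZ")

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40))
    def test_matches_letter_histogram_oracle(self, seq):
        f = gu.cdr3_features(seq)
        hist = {aa: seq.count(aa) for aa in set(seq)}
        charge = hist.get("R", 0) + hist.get("K", 0) - hist.get("D", 0) - hist.get("E", 0)
        basic = (hist.get("R", 0) + hist.get("K", 0) + hist.get("H", 0)) / len(seq)
        assert f.net_charge == charge
        assert f.basic_fraction == pytest.approx(basic)
        assert 0 <= f.basic_fraction + f.acidic_fraction <= 1


class TestEnrichedDepletedContrast:
    def test_same_sets_give_zero_differences(self, small_repertoire):
        tbl, _ = small_repertoire
        part = cl.assign_clones(tbl)
        genes = set(tbl["v_call"].str.split("*").str[0])
        per_patient, _ = gu.enriched_depleted_contrast(tbl, part, genes, genes)
        assert np.allclose(per_patient["difference"], 0.0)

    def test_normalized_clone_size_arithmetic(self):
        # one patient, 100 productive sequences, enriched clones of 30 and 10
        calls = (["IGHV3-7*01"] * 40 + ["IGHV1-24*01"] * 60)
        tbl = usage_table(calls)
        tbl["junction"] = ["TGT" + "AAA" * 5 + "TGG"] * 100
        juncs = []
        for i in range(100):
            if i < 30:
                juncs.append("TGT" + "AAA" * 5 + "TGG")
            elif i < 40:
                juncs.append("TGT" + "CCC" * 5 + "TGG")
            else:
                juncs.append("TGT" + "GGG" * 5 + "TGG")
        tbl["junction"] = juncs
        part = cl.assign_clones(tbl, threshold=0.0)
        per_patient, _ = gu.enriched_depleted_contrast(
            tbl, part, enriched={"IGHV3-7"}, depleted={"IGHV1-24"})
        sizes = per_patient[per_patient["feature"] == "normalized_clone_size"]
        # enriched sequences: 30 in a 0.30 clone, 10 in a 0.10 clone
        assert sizes["enriched"].iloc[0] == pytest.approx((30 * 0.3 + 10 * 0.1) / 40)

    def test_empty_gene_set_rejected(self, small_repertoire):
        tbl, _ = small_repertoire
        part = cl.assign_clones(tbl)
        with pytest.raises(ValueError, match="non-empty"):
            gu.enriched_depleted_contrast(tbl, part, set(), {"IGHV3-7"})


class TestEnrichedFraction:
    def test_all_and_none(self):
        tbl = usage_table(["IGHV3-7*01"] * 10)
        assert gu.enriched_fraction(tbl, {"IGHV3-7"}) == 1.0
        assert gu.enriched_fraction(tbl, {"IGHV1-24"}) == 0.0

    def test_counting(self):
        calls = ["IGHV3-7*01"] * 75 + ["IGHV1-24*01"] * 25
        assert gu.enriched_fraction(usage_table(calls), {"IGHV3-7"}) == pytest.approx(0.75)

    def test_empty_scope_flagged(self):
        tbl = usage_table(["IGHV3-7*01"] * 4)
        with pytest.raises(ValueError, match="empty"):
            gu.enriched_fraction(tbl, {"IGHV3-7"},
                                 mask=pd.Series(False, index=tbl.index))
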