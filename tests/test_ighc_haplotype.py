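"""Constant-region filtering, SNV calling, MEC phasing, alleles, class switch."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bcrtme import _germline as gl
from bcrtme import ighc_haplotype as ih
from bcrtme import synthetic_cohort as sc


def reads_frame(constant_segments, prefix="VDJ", **extra):
    rows = []
    for i, seg in enumerate(constant_segments):
        row = {"read_id": f"r{i:03d}", "sequence": prefix + seg,
               "c_start": len(prefix), "c_gene": "IGHG1",
               "subisotype": "IGHG1", "clone_id": "c0"}
        for k, v in extra.items():
            row[k] = v[i] if isinstance(v, (list, tuple)) else v
        rows.append(row)
    return pd.DataFrame(rows)


def brute_force_mec(A):
    """Exhaustive bipartition oracle: per-site minority counts, all 2^(n-1) splits."""
    n, s = A.shape
    best = None
    ones = (A == 1).astype(int)
    zeros = (A == 0).astype(int)
    for bits in range(2 ** (n - 1)):
        side = np.array([(bits >> i) & 1 for i in range(n)])
        cost = 0
        for lab in (0, 1):
            sub = side == lab
            o = ones[sub].sum(axis=0)
            z = zeros[sub].sum(axis=0)
            cost += np.minimum(o, z).sum()
        best = cost if best is None else min(best, cost)
    return int(best)


def random_instance(rng, n_reads, n_sites, miss=0.1, noise=0.2):
    A = rng.integers(0, 2, size=(n_reads, n_sites)).astype(np.int8)
    A[rng.random(A.shape) < miss] = -1
    return A


def frame_from_matrix(A, reference):
    """Build a read frame whose het-site alleles reproduce matrix A."""
    sites = [ih.SnvSite(position=3 * s, ref=reference[3 * s], alt="G"
                        if reference[3 * s] != "G" else "C", depth=len(A),
                        alt_fraction=0.5)
             for s in range(A.shape[1])]
    segs = []
    for r in range(A.shape[0]):
        seg = list(reference)
        for s, site in enumerate(sites):
            if A[r, s] == 1:
                seg[site.position] = site.alt
            elif A[r, s] == -1:
                seg[site.position] = "N"
        segs.append("".join(seg))
    return reads_frame(segs), sites


class TestFilterConstantReads:
    def test_boundary_lengths_inclusive(self):
        segs = ["A" * n for n in (850, 900, 1000, 1100, 1101)]
        kept = ih.filter_constant_reads(reads_frame(segs))
        lengths = sorted(kept["sequence"].str.len() - kept["c_start"])
        assert lengths == [900, 1000, 1100]

    def test_empty_input(self):
        empty = pd.DataFrame(columns=["read_id", "sequence", "c_start"])
        assert ih.filter_constant_reads(empty).empty

    def test_all_in_range_identity(self):
        segs = ["A" * 1000] * 4
        assert len(ih.filter_constant_reads(reads_frame(segs))) == 4


class TestCallHetSites:
    def test_identical_reads_no_sites(self):
        ref = "ACGT" * 10
        sites = ih.call_het_sites(reads_frame([ref] * 20), ref, min_depth=10)
        assert sites == []

    def test_fifty_fifty_site_called(self):
        ref = "A" * 40
        segs = [ref] * 10 + ["A" * 20 + "G" + "A" * 19] * 10
        sites = ih.call_het_sites(reads_frame(segs), ref, min_depth=10)
        assert len(sites) == 1
        assert (sites[0].position, sites[0].ref, sites[0].alt) == (20, "A", "G")
        assert sites[0].alt_fraction == pytest.approx(0.5)

    def test_low_fraction_not_called(self):
        ref = "A" * 40
        segs = [ref] * 18 + ["A" * 20 + "G" + "A" * 19] * 2
        assert ih.call_het_sites(reads_frame(segs), ref) == []

    def test_low_depth_not_called(self):
        ref = "A" * 40
        segs = [ref] * 4 + ["A" * 20 + "G" + "A" * 19] * 4
        assert ih.call_het_sites(reads_frame(segs), ref, min_depth=10) == []


class TestPhaseReads:
    def test_perfect_separation_two_sites(self):
        ref = "A" * 12
        A = np.array([[0, 0], [0, 0], [1, 1], [1, 1], [1, 1]], dtype=np.int8)
        frame, sites = frame_from_matrix(A, ref)
        part = ih.phase_reads(frame, sites)
        assert part.mec == 0
        # majority side (three reads) is haplotype 1
        assert list(part.assignment[["r002", "r003", "r004"]]) == [1, 1, 1]
        assert list(part.assignment[["r000", "r001"]]) == [2, 2]

    def test_single_discordant_read_costs_one(self):
        ref = "A" * 12
        A = np.array([[0, 0], [0, 0], [1, 1], [1, 1], [1, 0]], dtype=np.int8)
        frame, sites = frame_from_matrix(A, ref)
        part = ih.phase_reads(frame, sites)
        assert part.mec == 1 == brute_force_mec(A)

    def test_label_swap_leaves_mec_invariant(self):
        rng = np.random.default_rng(3)
        A = random_instance(rng, 10, 4)
        frame, sites = frame_from_matrix(A, "A" * 12)
        part = ih.phase_reads(frame, sites)
        swapped = part.assignment.map({1: 2, 2: 1})
        assert ih.mec_score(frame, sites, swapped) == part.mec

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bipartition_oracle_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n, s = int(rng.integers(2, 13)), int(rng.integers(2, 6))
        A = random_instance(rng, n, s)
        if not (A >= 0).any():
            return
        frame, sites = frame_from_matrix(A, "A" * (3 * s + 3))
        part = ih.phase_reads(frame, sites)
        assert part.mec == brute_force_mec(A)

    @pytest.mark.parametrize("seed", range(10))
    def test_refinement_heuristic_matches_exact_on_separable_instances(self, seed):
        rng = np.random.default_rng(100 + seed)
        h1 = rng.integers(0, 2, size=8).astype(np.int8)
        h2 = (1 - h1).astype(np.int8)
        A = np.array([h1 if rng.random() < 0.6 else h2 for _ in range(10)])
        flip = rng.random(A.shape) < 0.05
        A = np.where(flip, 1 - A, A).astype(np.int8)
        exact = brute_force_mec(A)
        side = ih._phase_refine(A)
        cost, _, _ = ih._mec_of_sides(A, side)
        assert cost == exact

    def test_no_sites_rejected(self):
        frame = reads_frame(["AAAA"] * 3)
        with pytest.raises(ValueError, match="het site"):
            ih.phase_reads(frame, [])


class TestCallAlleles:
    def test_homozygous_single_cluster(self):
        ref = gl.c_allele("IGHG1")[:100]
        calls = ih.call_alleles(reads_frame([ref] * 20), {"IGHG1*01": ref})
        assert len(calls) == 1
        assert calls[0].allele == "IGHG1*01" and not calls[0].novel

    def test_five_percent_boundary_inclusive(self):
        ref = "A" * 50
        alt = "G" + "A" * 49
        # 95 ref + 5 alt: alt cluster sits exactly at 5%
        calls = ih.call_alleles(reads_frame([ref] * 95 + [alt] * 5),
                                {"x*01": ref}, min_cluster_fraction=0.05)
        assert len(calls) == 2
        # 96 ref + 4 alt: 4% cluster dropped
        calls = ih.call_alleles(reads_frame([ref] * 96 + [alt] * 4),
                                {"x*01": ref}, min_cluster_fraction=0.05)
        assert len(calls) == 1

    def test_heterozygote_recovers_both_alleles(self):
        a1 = gl.c_allele("IGHG1")[:200]
        a2 = gl.c_allele("IGHG1", "02", (10, 50))[:200]
        calls = ih.call_alleles(reads_frame([a1] * 30 + [a2] * 30),
                                {"IGHG1*01": a1, "IGHG1*02": a2})
        assert {c.allele for c in calls} == {"IGHG1*01", "IGHG1*02"}
        assert all(c.distance == 0 for c in calls)


class TestClassSwitchTable:
    def _phased(self, subisotypes, haplotypes):
        frame = reads_frame(["A" * 10] * len(subisotypes),
                            subisotype=list(subisotypes))
        part = ih.HaplotypePartition(
            assignment=pd.Series(haplotypes, index=frame["read_id"].values),
            consensus={1: "0", 2: "1"}, mec=0)
        return frame, part

    def test_equal_counts_unit_ratios(self):
        frame, part = self._phased(["IGHG1", "IGHG4"] * 4, [1, 1, 1, 1, 2, 2, 2, 2])
        table = ih.class_switch_table(frame, part)
        assert table.fold_ratio(1, "IGHG4", "IGHG1") == pytest.approx(1.0)

    def test_ratio_4_6(self):
        subs = ["IGHG4"] * 92 + ["IGHG1"] * 20
        frame, part = self._phased(subs, [1] * 112)
        table = ih.class_switch_table(frame, part)
        assert table.fold_ratio(1, "IGHG4", "IGHG1") == pytest.approx(4.6)

    def test_zero_denominator_undefined(self):
        frame, part = self._phased(["IGHG4"] * 5, [1] * 5)
        table = ih.class_switch_table(frame, part)
        assert table.fold_ratio(1, "IGHG4", "IGHG1") is None

    def test_marginals_conserved(self):
        frame, part = self._phased(["IGHG1", "IGHG2", "IGHG4"] * 5, [1, 2, 1] * 5)
        table = ih.class_switch_table(frame, part)
        assert table.counts.to_numpy().sum() == 15


class TestCloneAlleleMutationContrast:
    def test_unmutated_clone_all_zero(self):
        from bcrtme import clonal_structure as cl
        tbl, _ = sc.simulate_repertoire(
            30, sc.CloneSizeDistribution(3, ratio=0.8), shm_rate=0.0, seed=6)
        t = cl.assign_clones(tbl).table
        clone = t["clone_id"].iloc[0]
        allele_of = pd.Series("IGHG1*01", index=t["sequence_id"].values)
        res = ih.clone_allele_mutation_contrast(t, allele_of, [clone])
        row = res[res["clone_id"] == clone].iloc[0]
        assert row["r_frequency"] == 0.0
        assert row["cdr_r"] == 0 and row["fwr_r"] == 0

    def test_allele_permutation_swaps_rows(self, small_repertoire):
        tbl, _ = small_repertoire
        from bcrtme import clonal_structure as cl
        part = cl.assign_clones(tbl)
        t = part.table
        clone = t["clone_id"].value_counts().index[0]
        ids = t.loc[t["clone_id"] == clone, "sequence_id"].values
        alleles = pd.Series(["a1" if i % 2 else "a2" for i in range(len(ids))],
                            index=ids)
        res1 = ih.clone_allele_mutation_contrast(t, alleles, [clone])
        res2 = ih.clone_allele_mutation_contrast(
            t, alleles.map({"a1": "a2", "a2": "a1"}), [clone])
        m1 = res1.set_index("allele").sort_index()
        m2 = res2.set_index("allele").rename(index={"a1": "a2", "a2": "a1"}).sort_index()
        pd.testing.assert_frame_equal(m1, m2, check_like=True)


class TestSubisotypeStats:
    def _records(self, counts, patient="P1"):
        rows = []
        for sub, n in counts.items():
            rows += [{"patient_id": patient, "subisotype": sub}] * n
        return pd.DataFrame(rows)

    def test_ratio_arithmetic(self):
        res = ih.subisotype_stats(self._records(
            {"IGHG1": 4, "IGHG2": 2, "IGHG3": 2, "IGHG4": 2}))
        assert res["g1g4_over_g2g3"].iloc[0] == pytest.approx(1.5)

    def test_equal_frequencies_unit_ratio(self):
        res = ih.subisotype_stats(self._records(
            {"IGHG1": 5, "IGHG2": 5, "IGHG3": 5, "IGHG4": 5}))
        assert res["g1g4_over_g2g3"].iloc[0] == pytest.approx(1.0)

    def test_zero_denominator_marked_undefined(self):
        res = ih.subisotype_stats(self._records({"IGHG1": 5, "IGHG4": 5}))
        assert res["ratio_undefined"].iloc[0]
        assert np.isnan(res["g1g4_over_g2g3"].iloc[0])

    def test_frequencies_sum_to_one(self):
        res = ih.subisotype_stats(self._records(
            {"IGHG1": 3, "IGHG2": 1, "IGHG3": 1, "IGHG4": 5}))
        assert res[["IGHG1", "IGHG2", "IGHG3", "IGHG4"]].sum(axis=1).iloc[0] == \
            pytest.approx(1.0)
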