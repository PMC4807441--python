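"""Disequilibrium statistics: HWE, F_IS, theta, composite LD, cytonuclear
disequilibrium and FDR."""

import numpy as np
import pandas as pd
import pytest

from hybridzone.io import GenotypeTable
from hybridzone.stats import (ChainSettings, composite_ld_test,
                              cytonuclear_disequilibrium, fdr_adjust,
                              fst_theta, genotype_counts, hwe_exact_test,
                              inbreeding_coefficient)
from oracles import hwe_exact_oracle, theta_oracle

FAST_CHAIN = ChainSettings(dememorization=500, batches=40,
                           iterations_per_batch=500)


class TestHweExact:
    @pytest.mark.parametrize("counts", [
        {(1, 1): 3, (2, 2): 3},          # extreme deficit, n=6
        {(1, 2): 5},                      # all heterozygotes, n=5
        {(1, 1): 1, (1, 2): 2, (2, 2): 2},
        {(1, 2): 2, (1, 3): 1, (2, 3): 1, (3, 3): 1},  # three alleles
    ])
    def test_chain_matches_enumeration(self, counts):
        exact_g, exact_d, exact_e = hwe_exact_oracle(counts)
        res = hwe_exact_test(counts, chain=ChainSettings(), seed=42)
        assert res.p_global == pytest.approx(exact_g, abs=3 * res.se_global + 1e-9)
        assert res.p_deficit == pytest.approx(exact_d, abs=3 * res.se_deficit + 1e-9)
        assert res.p_excess == pytest.approx(exact_e, abs=3 * res.se_excess + 1e-9)

    def test_all_heterozygotes_sidedness(self):
        counts = {(1, 2): 10}
        res = hwe_exact_test(counts, chain=FAST_CHAIN, seed=7)
        assert res.p_deficit == pytest.approx(1.0, abs=1e-12)
        assert res.p_excess < 0.05

    def test_monomorphic_is_degenerate(self):
        res = hwe_exact_test({(1, 1): 20}, seed=0)
        assert res.degenerate and res.p_global == 1.0

    def test_oracle_levene_vs_matching_enumeration(self):
        # meta-check: the Levene-formula oracle agrees with brute-force
        # enumeration of pairings of labelled allele copies
        from itertools import permutations
        counts = {(1, 1): 1, (1, 2): 1, (2, 2): 1}
        copies = [1, 1, 1, 2, 2, 2]
        tables = {}
        total = 0
        for perm in set(permutations(copies)):
            key = tuple(sorted(tuple(sorted(perm[2 * i:2 * i + 2]))
                               for i in range(3)))
            tables[key] = tables.get(key, 0) + 1
            total += 1
        obs_key = tuple(sorted([(1, 1), (1, 2), (2, 2)]))
        p_obs = tables[obs_key] / total
        het_obs = 1
        pg = sum(c for k, c in tables.items()
                 if c / total <= p_obs * (1 + 1e-12)) / total
        exact_g, _, _ = hwe_exact_oracle(counts)
        assert exact_g == pytest.approx(pg, abs=1e-12)


class TestFis:
    def test_all_heterozygotes_negative(self):
        res = inbreeding_coefficient({(1, 2): 50})
        h_exp = (100 / 99) * 0.5  # 2n = 100 allele copies
        assert res.fis == pytest.approx(1 - 1.0 / h_exp)
        assert res.fis < 0

    def test_single_homozygote_degenerate(self):
        res = inbreeding_coefficient({(1, 1): 1})
        assert res.degenerate and res.fis is None

    def test_hw_proportions_near_zero(self):
        rng = np.random.default_rng(5)
        g = rng.choice(3, size=5000, p=[0.25, 0.5, 0.25])
        counts = {(1, 1): int((g == 0).sum()), (1, 2): int((g == 1).sum()),
                  (2, 2): int((g == 2).sum())}
        assert abs(inbreeding_coefficient(counts).fis) < 0.05

    def test_zero_individuals_error(self):
        with pytest.raises(ValueError):
            inbreeding_coefficient({})


def _table_from_pop_calls(calls_by_pop: dict, loci) -> GenotypeTable:
    rows = []
    for site, by_locus in calls_by_pop.items():
        n = len(next(iter(by_locus.values())))
        for i in range(n):
            row = {"individual_id": f"{site}_{i}", "site_id": site}
            for locus in loci:
                a1, a2 = by_locus[locus][i]
                row[f"{locus}.a1"], row[f"{locus}.a2"] = a1, a2
            rows.append(row)
    return GenotypeTable(pd.DataFrame(rows), list(loci))


class TestFstTheta:
    def test_fixed_difference_theta_one(self):
        table = _table_from_pop_calls(
            {1: {"L1": [(1, 1)] * 10, "L2": [(3, 3)] * 10},
             2: {"L1": [(2, 2)] * 10, "L2": [(4, 4)] * 10}}, ["L1", "L2"])
        res = fst_theta(table, [1], [2], n_perm=99, seed=0)
        assert res.theta == pytest.approx(1.0)
        # only the two perfectly separating label arrangements reach theta*=1
        assert res.p_value <= 3 / 100

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(8)
        pops = {}
        for site, p in ((1, 0.3), (2, 0.6)):
            calls = [tuple(1 + rng.binomial(1, p, 2)) for _ in range(25)]
            calls2 = [tuple(3 + rng.binomial(1, 0.5, 2)) for _ in range(25)]
            pops[site] = {"L1": calls, "L2": calls2}
        table = _table_from_pop_calls(pops, ["L1", "L2"])
        res = fst_theta(table, [1], [2], n_perm=19, seed=0)
        expected = theta_oracle([pops[1], pops[2]])
        assert res.theta == pytest.approx(expected, abs=1e-9)

    def test_self_comparison_near_zero(self):
        rng = np.random.default_rng(3)
        calls = [tuple(sorted(1 + rng.binomial(1, 0.5, 2))) for _ in range(200)]
        pops = {1: {"L": calls[:100]}, 2: {"L": calls[100:]}}
        table = _table_from_pop_calls(pops, ["L"])
        res = fst_theta(table, [1], [2], n_perm=199, seed=1)
        assert abs(res.theta) < 0.02
        assert res.p_value > 0.05

    def test_invariance_allele_and_locus_relabeling(self):
        rng = np.random.default_rng(9)
        pops = {}
        for site, p in ((1, 0.2), (2, 0.7)):
            pops[site] = {
                "L1": [tuple(sorted(1 + rng.binomial(1, p, 2))) for _ in range(30)],
                "L2": [tuple(sorted(5 + rng.binomial(1, 0.4, 2))) for _ in range(30)],
            }
        t1 = _table_from_pop_calls(pops, ["L1", "L2"])
        relabeled = {s: {"L2": [(a + 10, b + 10) for a, b in d["L2"]],
                         "L1": d["L1"]} for s, d in pops.items()}
        t2 = _table_from_pop_calls(relabeled, ["L2", "L1"])
        r1 = fst_theta(t1, [1], [2], n_perm=9, seed=0)
        r2 = fst_theta(t2, [1], [2], n_perm=9, seed=0)
        assert r1.theta == pytest.approx(r2.theta, abs=1e-12)

    def test_permutation_p_respects_plus_one(self):
        table = _table_from_pop_calls(
            {1: {"L": [(1, 1)] * 10}, 2: {"L": [(2, 2)] * 10}}, ["L"])
        res = fst_theta(table, [1], [2], n_perm=49, seed=0)
        assert res.p_value >= 1 / 50


class TestCompositeLd:
    def _toy_2x2(self):
        # 20 individuals, doses chosen for a hand-checkable composite delta
        calls1 = [(1, 1)] * 6 + [(1, 2)] * 8 + [(2, 2)] * 6
        calls2 = [(3, 3)] * 6 + [(3, 4)] * 8 + [(4, 4)] * 6
        return _table_from_pop_calls({1: {"A": calls1, "B": calls2}}, ["A", "B"])

    def test_hand_computed_delta(self):
        table = self._toy_2x2()
        res = composite_ld_test(table, 1, "A", "B", n_perm=99, seed=0)
        # perfectly matched doses: X = Y per individual
        X = np.array([2] * 6 + [1] * 8 + [0] * 6)
        n = 20
        pA = X.mean() / 2
        delta_hand = (X * X).sum() / (2 * n) - 2 * pA * pA
        assert res.deltas.loc[1, 3] == pytest.approx(delta_hand, abs=1e-9)

    def test_perfect_covariation_minimal_p(self):
        rng = np.random.default_rng(2)
        doses = rng.integers(0, 3, 50)
        calls1 = [((1, 1), (1, 2), (2, 2))[d] for d in doses]
        calls2 = [((3, 3), (3, 4), (4, 4))[d] for d in doses]
        table = _table_from_pop_calls({1: {"A": calls1, "B": calls2}}, ["A", "B"])
        res = composite_ld_test(table, 1, "A", "B", n_perm=999, seed=0)
        assert res.p_permutation == pytest.approx(1 / 1000)

    def test_symmetric_in_locus_order(self):
        table = self._toy_2x2()
        r1 = composite_ld_test(table, 1, "A", "B", n_perm=49, seed=3)
        r2 = composite_ld_test(table, 1, "B", "A", n_perm=49, seed=3)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-9)

    def test_monomorphic_locus_degenerate(self):
        table = _table_from_pop_calls(
            {1: {"A": [(1, 1)] * 10, "B": [(3, 4)] * 10}}, ["A", "B"])
        res = composite_ld_test(table, 1, "A", "B", n_perm=9, seed=0)
        assert res.degenerate and res.statistic == 0.0 and res.p_permutation == 1.0

    def test_too_few_individuals_error(self):
        table = _table_from_pop_calls(
            {1: {"A": [(1, 2)] * 4, "B": [(3, 4)] * 4}}, ["A", "B"])
        with pytest.raises(ValueError):
            composite_ld_test(table, 1, "A", "B")


class TestCytonuclear:
    def test_maximal_association(self):
        # all northern-mito homozygous composite-A, southern homozygous B
        dose = np.array([2.0] * 12 + [0.0] * 8)
        mito = np.array(["N"] * 12 + ["S"] * 8, dtype=object)
        res = cytonuclear_disequilibrium(dose, mito, n_perm=199, seed=0)
        p_m = 12 / 20
        assert res.d_allelic == pytest.approx(p_m * (1 - p_m), abs=1e-12)
        assert res.p_allelic == pytest.approx(1 / 200)

    def test_genotypic_components_sum_to_zero(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            dose = rng.integers(0, 3, 30).astype(float)
            mito = np.array(rng.choice(["N", "S"], 30), dtype=object)
            if len(set(dose)) < 2 or len(set(mito)) < 2:
                continue
            res = cytonuclear_disequilibrium(dose, mito, n_perm=9, seed=0)
            assert res.d1 + res.d2 + res.d3 == pytest.approx(0.0, abs=1e-9)

    def test_independent_construction_small_d(self):
        rng = np.random.default_rng(6)
        n = 400
        dose = rng.binomial(2, 0.5, n).astype(float)
        mito = np.array(rng.choice(["N", "S"], n), dtype=object)
        res = cytonuclear_disequilibrium(dose, mito, n_perm=199, seed=0)
        se = np.sqrt(0.25 * 0.5 / n)  # rough scale of D under independence
        assert abs(res.d_allelic) < 3 * se + 0.02

    def test_monomorphic_mito_degenerate(self):
        dose = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        mito = np.array(["N"] * 6, dtype=object)
        res = cytonuclear_disequilibrium(dose, mito, n_perm=9, seed=0)
        assert res.degenerate and res.d_allelic == 0.0 and res.p_allelic == 1.0


class TestFdr:
    def test_spec_examples(self):
        flags, _ = fdr_adjust([0.001, 0.2, 0.9], q=0.05)
        assert flags.sum() == 1 and flags[0]
        flags, _ = fdr_adjust([0.01, 0.012, 0.013, 0.8], q=0.05)
        assert flags.tolist() == [True, True, True, False]

    def test_all_ones_none_flagged(self):
        flags, thr = fdr_adjust([1.0] * 5, q=0.05)
        assert not flags.any() and thr == 0.0

    def test_empty_input(self):
        flags, _ = fdr_adjust([])
        assert flags.size == 0

    def test_superset_of_bonferroni(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            p = rng.random(20) ** 3
            flags, _ = fdr_adjust(p, q=0.05)
            bonf = p <= 0.05 / len(p)
            assert (flags | ~bonf).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestGenotypeCounts:
    def test_counts_exclude_missing(self, toy_table):
        counts = genotype_counts(toy_table, 2, "LocB")
        assert sum(counts.values()) == 1  # b2 is missing at LocB
        assert counts == {(107, 107): 1}
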