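"""Ranking metrics, enrichment score, permutation null and NES/p/FDR."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ptasig.errors import ConfigurationError, InputError, UnstableEstimateWarning
from ptasig.gsea import (
    RankedList,
    enrichment_score,
    exhaustive_null,
    gsea_batch,
    normalize_and_test,
    permutation_null,
    rank_genes,
    results_table,
)
from ptasig.setstats import GeneSet
from ptasig.simulate import SimConfig, generate_condition_experiment
from ptasig.stromal import ExpressionMatrix


def running_sum_oracle(scores, hit_flags, weight):
    """Step-by-step reference computation of the running sum and ES."""
    n = len(scores)
    k = sum(hit_flags)
    denom = sum(abs(s) ** weight for s, h in zip(scores, hit_flags) if h)
    run, values = 0.0, []
    for s, h in zip(scores, hit_flags):
        if h:
            run += abs(s) ** weight / denom
        else:
            run -= 1.0 / (n - k)
        values.append(run)
    es = max(values, key=abs)
    return es, values


class TestRankGenes:
    @staticmethod
    def _matrix(log2_a, log2_b, n_a=3, n_b=3):
        """Build a matrix whose log2(x+1) group values are exactly as given."""
        rows = []
        for va, vb in zip(log2_a, log2_b):
            rows.append([2.0 ** v - 1 for v in va[:n_a]] + [2.0 ** v - 1 for v in vb[:n_b]])
        samples = [f"A_{i}" for i in range(n_a)] + [f"B_{i}" for i in range(n_b)]
        df = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))], columns=samples)
        labels = pd.Series(["A"] * n_a + ["B"] * n_b, index=samples)
        return ExpressionMatrix(values=df, sample_labels=labels)

    def test_equal_groups_score_zero(self):
        m = self._matrix([[5, 6, 7]], [[5, 6, 7]])
        ranked = rank_genes(m, ("A", "B"), metric="signal-to-noise")
        assert ranked.scores[0] == pytest.approx(0.0)

    def test_signal_to_noise_formula(self):
        # muA=2, muB=1, sd floors kick in: sd_a = max(1, .4, .2), sd_b = max(1, .2, .2)
        m = self._matrix([[1, 2, 3]], [[0, 1, 2]])
        ranked = rank_genes(m, ("A", "B"), metric="signal-to-noise")
        assert ranked.scores[0] == pytest.approx((2 - 1) / (1 + 1))

    def test_sigma_floor_applies_to_tight_groups(self):
        # tiny within-group sd: floor = 0.2*|mu| dominates
        m = self._matrix([[5.0, 5.0, 5.0]], [[3.0, 3.0, 3.0]])
        ranked = rank_genes(m, ("A", "B"), metric="signal-to-noise")
        assert ranked.scores[0] == pytest.approx((5 - 3) / (0.2 * 5 + 0.2 * 3))

    def test_too_few_samples_error_names_fallback(self):
        m = self._matrix([[5, 6]], [[3, 4]], n_a=2, n_b=2)
        with pytest.raises(InputError, match="log2-fold-change"):
            rank_genes(m, ("A", "B"), metric="signal-to-noise")
        ranked = rank_genes(m, ("A", "B"), metric="log2-fold-change")
        assert len(ranked) == 1

    def test_ordering_matches_independent_sort_oracle(self):
        rng = np.random.default_rng(5)
        n = 100
        values = rng.lognormal(3, 1, (n, 6))
        samples = [f"s{i}" for i in range(6)]
        df = pd.DataFrame(values, index=[f"g{i:03d}" for i in range(n)], columns=samples)
        m = ExpressionMatrix(values=df, sample_labels=pd.Series(["A"] * 3 + ["B"] * 3, index=samples))
        ranked = rank_genes(m, ("A", "B"), metric="signal-to-noise")
        log = np.log2(values + 1)
        mu_a, mu_b = log[:, :3].mean(1), log[:, 3:].mean(1)
        sd = lambda x, mu: np.maximum(x.std(1, ddof=1), np.maximum(0.2 * np.abs(mu), 0.2))
        scores = (mu_a - mu_b) / (sd(log[:, :3], mu_a) + sd(log[:, 3:], mu_b))
        oracle = sorted(zip(df.index, scores), key=lambda t: (-t[1], t[0]))
        assert list(ranked.genes) == [g for g, _ in oracle]

    def test_ties_broken_by_gene_id(self):
        ranked = RankedList.from_scores(pd.Series({"z": 1.0, "a": 1.0, "m": 2.0}))
        assert ranked.genes == ("m", "a", "z")


class TestEnrichmentScore:
    def test_single_top_hit_gives_unit_score(self, small_ranked):
        res = enrichment_score(small_ranked, GeneSet.from_iterable("top", ["gA"]))
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ("gA",)

    def test_all_two_gene_sets_match_brute_force_oracle(self, small_ranked):
        for pair in itertools.combinations(small_ranked.genes, 2):
            gs = GeneSet.from_iterable("pair", pair)
            res = enrichment_score(small_ranked, gs, weight=1.0)
            hits = [g in pair for g in small_ranked.genes]
            es_oracle, run_oracle = running_sum_oracle(small_ranked.scores, hits, 1.0)
            assert res.es == pytest.approx(es_oracle, abs=1e-12)
            assert np.allclose(res.running_sum, run_oracle)

    def test_weight_zero_equals_two_sample_ks_statistic(self, small_ranked):
        for pair in itertools.combinations(range(len(small_ranked)), 2):
            gs = GeneSet.from_iterable("pair", [small_ranked.genes[i] for i in pair])
            res = enrichment_score(small_ranked, gs, weight=0.0)
            hit_pos = np.array(pair)
            miss_pos = np.array([i for i in range(len(small_ranked)) if i not in pair])
            ks = stats.ks_2samp(hit_pos, miss_pos).statistic
            assert abs(res.es) == pytest.approx(ks, abs=1e-12)

    def test_es_bounded_and_reversal_negates_for_weight_zero(self):
        rng = np.random.default_rng(8)
        scores = np.sort(rng.normal(0, 1, 30))[::-1]
        genes = tuple(f"g{i:02d}" for i in range(30))
        ranked = RankedList(genes=genes, scores=scores)
        reversed_ranked = RankedList(genes=genes[::-1], scores=-scores[::-1])
        for seed in range(5):
            members = tuple(rng.choice(genes, 7, replace=False))
            gs = GeneSet.from_iterable("s", members)
            es_fwd = enrichment_score(ranked, gs, weight=0.0).es
            es_rev = enrichment_score(reversed_ranked, gs, weight=0.0).es
            assert -1 <= es_fwd <= 1
            assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    def test_planted_downregulated_set_scores_negative_without_noise(self):
        cfg = SimConfig(n_genes=500, downregulated_set_size=40, effect_size_log2=2.0,
                        noise_sd_log2=0.0, seed=10)
        matrix, truth = generate_condition_experiment(cfg)
        ranked = rank_genes(matrix, ("GVHDpos", "GVHDneg"), metric="log2-fold-change")
        # planted genes occupy the bottom tail of the ranking
        bottom = set(ranked.genes[-len(truth.downregulated_genes):])
        assert bottom == set(truth.downregulated_genes)
        gs = GeneSet.from_iterable("planted", truth.downregulated_genes)
        assert enrichment_score(ranked, gs).es < 0

    def test_empty_and_full_intersections_rejected(self, small_ranked):
        with pytest.raises(InputError):
            enrichment_score(small_ranked, GeneSet.from_iterable("none", ["nope"]))
        with pytest.raises(InputError):
            enrichment_score(small_ranked, GeneSet.from_iterable("all", small_ranked.genes))

    def test_matches_external_reference_implementation(self):
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(7)
        genes = [f"G{i:03d}" for i in range(50)]
        ranked = RankedList.from_scores(pd.Series(np.round(rng.normal(0, 2, 50), 4), index=genes))
        members = list(rng.choice(genes, 10, replace=False))
        es_mine = enrichment_score(ranked, GeneSet.from_iterable("S1", members)).es
        rnk = pd.DataFrame({"gene": ranked.genes, "score": ranked.scores})
        res = gseapy.prerank(rnk=rnk, gene_sets={"S1": members}, permutation_num=10,
                             min_size=1, max_size=100, weight=1.0, seed=0, outdir=None,
                             threads=1, no_plot=True, verbose=False)
        assert es_mine == pytest.approx(float(res.res2d["ES"].iloc[0]), abs=1e-9)


class TestPermutationNull:
    def test_same_seed_same_null(self, small_ranked):
        n1 = permutation_null(small_ranked, 2, n_perm=100, seed=42)
        n2 = permutation_null(small_ranked, 2, n_perm=100, seed=42)
        assert np.array_equal(n1, n2)

    def test_small_n_perm_rejected(self, small_ranked):
        with pytest.raises(ConfigurationError):
            permutation_null(small_ranked, 2, n_perm=10, seed=0)

    def test_exhaustive_null_equals_per_set_enumeration(self):
        rng = np.random.default_rng(2)
        genes = tuple(f"g{i}" for i in range(8))
        scores = np.sort(rng.normal(0, 1, 8))[::-1]
        ranked = RankedList(genes=genes, scores=scores)
        null = exhaustive_null(ranked, 2)
        oracle = []
        for pair in itertools.combinations(genes, 2):
            oracle.append(enrichment_score(ranked, GeneSet.from_iterable("p", pair)).es)
        assert sorted(null) == pytest.approx(sorted(oracle))

    def test_sampled_null_mean_consistent_with_symmetric_scores(self):
        # mirrored scores: the ES distribution is symmetric, mean ~ 0
        scores = np.array([4.0, 3.0, 2.0, 1.0, -1.0, -2.0, -3.0, -4.0])
        ranked = RankedList(genes=tuple(f"g{i}" for i in range(8)), scores=scores)
        null = permutation_null(ranked, 3, n_perm=2000, seed=1)
        se = null.std(ddof=1) / np.sqrt(len(null))
        assert abs(null.mean()) < 3 * se + 1e-3


class TestNormalizeAndTest:
    def test_es_at_null_maximum_gets_two_over_n_plus_one(self):
        null = np.array([0.1, 0.2, 0.5, -0.3, -0.4])
        nes, p = normalize_and_test(0.5, null)
        assert p == pytest.approx(2 / (1 + 3))  # 3 same-sign values, add-one rule

    def test_mirrored_null_normalizes_to_unit_nes(self):
        null = np.array([0.4, -0.4, 0.4, -0.4])
        nes, p = normalize_and_test(0.4, null)
        assert abs(nes) == pytest.approx(1.0)

    def test_exact_tail_mass_on_enumerated_null(self):
        rng = np.random.default_rng(3)
        genes = tuple(f"g{i}" for i in range(8))
        ranked = RankedList(genes=genes, scores=np.sort(rng.normal(0, 1, 8))[::-1])
        null = exhaustive_null(ranked, 2)
        gs = GeneSet.from_iterable("obs", genes[:2])
        es = enrichment_score(ranked, gs).es
        nes, p = normalize_and_test(es, null)
        same = null[null * np.sign(es) > 0]
        assert p == pytest.approx((1 + np.sum(np.abs(same) >= abs(es))) / (1 + len(same)))

    def test_p_never_zero(self):
        null = np.array([0.01, 0.02, -0.05])
        _, p = normalize_and_test(0.99, null)
        assert p > 0

    def test_no_same_sign_null_warns(self):
        with pytest.warns(UnstableEstimateWarning):
            nes, p = normalize_and_test(0.5, np.array([-0.1, -0.2]))
        assert p == 1.0


class TestBatch:
    def test_single_pair_equals_atomic_composition(self, small_ranked):
        gs = GeneSet.from_iterable("pair", ["gA", "gF"])
        results = gsea_batch({"c": small_ranked}, [gs], n_perm=200, seed=9)
        assert len(results) == 1
        r = results[0]
        atomic_es = enrichment_score(small_ranked, gs).es
        null = permutation_null(small_ranked, 2, n_perm=200, seed=r.seed)
        nes, p = normalize_and_test(atomic_es, null)
        assert r.es == pytest.approx(atomic_es)
        assert r.nes == pytest.approx(nes)
        assert r.p_nominal == pytest.approx(p)

    def test_batch_is_deterministic(self, small_ranked):
        sets = [GeneSet.from_iterable(f"s{i}", [small_ranked.genes[i], small_ranked.genes[i + 1]])
                for i in range(4)]
        t1 = results_table(gsea_batch({"c": small_ranked}, sets, n_perm=150, seed=3))
        t2 = results_table(gsea_batch({"c": small_ranked}, sets, n_perm=150, seed=3))
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_pair_reported_batch_continues(self, small_ranked):
        good = GeneSet.from_iterable("good", ["gA", "gB"])
        bad = GeneSet.from_iterable("bad", ["absent1", "absent2"])
        results = gsea_batch({"c": small_ranked}, [good, bad], n_perm=150, seed=1)
        by_name = {r.set_name: r for r in results}
        assert by_name["bad"].error != ""
        assert np.isnan(by_name["bad"].es)
        assert by_name["good"].error == ""
        assert np.isfinite(by_name["good"].es)

    def test_nes_sign_matches_es_sign_and_q_in_range(self):
        cfg = SimConfig(n_genes=300, downregulated_set_size=30, effect_size_log2=1.0,
                        noise_sd_log2=0.5, seed=4)
        matrix, truth = generate_condition_experiment(cfg)
        ranked = rank_genes(matrix, ("GVHDpos", "GVHDneg"))
        rng = np.random.default_rng(0)
        decoys = [GeneSet.from_iterable(f"decoy{i}", rng.choice(list(matrix.genes), 30, replace=False))
                  for i in range(5)]
        planted = GeneSet.from_iterable("planted", truth.downregulated_genes)
        results = gsea_batch({"gvhd": ranked}, [planted] + decoys, n_perm=200, seed=11)
        for r in results:
            if r.es != 0 and np.isfinite(r.nes):
                assert np.sign(r.nes) == np.sign(r.es)
            assert 0 <= r.fdr_q <= 1
            assert 0 < r.p_nominal <= 1
        by_name = {r.set_name: r for r in results}
        assert by_name["planted"].nes < 0
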