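from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methscore.enrichment import (gsea_es, gsea_run, kgroup_test,
                                  ora_hypergeometric, signature_score)


class TestGseaEs:
    def test_hand_walked_top_gene_unweighted(self):
        # N=4, set={g1}, p=0: running sum = [1, 2/3, 1/3, 0] -> ES = 1
        es, running, leading = gsea_es(["g1", "g2", "g3", "g4"],
                                       [3.0, 2.0, 1.0, 0.5], ["g1"],
                                       weight_p=0)
        assert es == pytest.approx(1.0)
        np.testing.assert_allclose(running, [1.0, 2 / 3, 1 / 3, 0.0],
                                   atol=1e-12)
        assert leading == ["g1"]

    def test_hand_walked_weighted_two_hits(self):
        # hits g1 (stat 3) and g3 (stat 1): steps +3/4, -1/2, +1/4, -1/2
        es, running, _ = gsea_es(["g1", "g2", "g3", "g4"],
                                 [3.0, 2.0, 1.0, 0.5], ["g1", "g3"],
                                 weight_p=1)
        np.testing.assert_allclose(running, [0.75, 0.25, 0.5, 0.0],
                                   atol=1e-12)
        assert es == pytest.approx(0.75)

    def test_set_equal_to_list_gives_es_one(self):
        genes = [f"g{i}" for i in range(6)]
        es, _, _ = gsea_es(genes, list(range(6, 0, -1)), genes)
        assert es == pytest.approx(1.0)

    def test_disjoint_set_is_an_error(self):
        with pytest.raises(ValueError, match="no genes"):
            gsea_es(["a", "b"], [2.0, 1.0], ["zzz"])

    def test_equal_stats_make_weighting_irrelevant(self):
        genes = [f"g{i}" for i in range(10)]
        stat = [1.0] * 10
        members = ["g1", "g4", "g7"]
        es0, r0, _ = gsea_es(genes, stat, members, weight_p=0)
        es1, r1, _ = gsea_es(genes, stat, members, weight_p=1)
        assert es0 == pytest.approx(es1, abs=1e-12)
        np.testing.assert_allclose(r0, r1, atol=1e-12)


class TestGseaRun:
    def test_planted_top_block_strongly_enriched(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(200)]
        stat = np.sort(rng.normal(size=200))[::-1]
        sets = {"planted": genes[:50], "random": list(rng.choice(genes, 30,
                                                                 replace=False))}
        res = gsea_run(genes, stat, sets, n_perm=200, seed=1)
        assert res.table.loc["planted", "nes"] > 0
        assert res.table.loc["planted", "p"] <= 2 / 201

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(300)]
        stat = rng.normal(size=300)
        sets = {f"s{i}": list(rng.choice(genes, 15, replace=False))
                for i in range(50)}
        res = gsea_run(genes, stat, sets, n_perm=200, seed=3)
        ks = stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(100)]
        stat = rng.normal(size=100)
        sets = {"s": list(rng.choice(genes, 10, replace=False))}
        r1 = gsea_run(genes, stat, sets, n_perm=100, seed=5)
        r2 = gsea_run(genes, stat, sets, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)


def _ora_oracle(N, K, n, k):
    """Exact upper-tail hypergeometric by direct combinatorial sum."""
    return sum(comb(K, j) * comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / comb(N, n)


class TestOra:
    def test_matches_exact_tail_sum_on_small_grid(self):
        for N in (5, 12, 20, 30):
            universe = [f"g{i}" for i in range(N)]
            for K in (1, N // 2, N):
                for n in (1, N // 3 + 1, N):
                    for k in range(0, min(K, n) + 1):
                        members = universe[:K]
                        hits = universe[:k] + universe[K:K + (n - k)]
                        if len(hits) != n:
                            continue
                        out = ora_hypergeometric(hits, {"s": members},
                                                 universe)
                        assert out.loc["s", "p"] == pytest.approx(
                            _ora_oracle(N, K, n, k), rel=1e-12)

    def test_spec_worked_example(self):
        # N=100, K=5, n=10, k=5 -> exact tail reduces to the single term
        universe = [f"g{i}" for i in range(100)]
        members = universe[:5]
        hits = universe[:5] + universe[50:55]
        out = ora_hypergeometric(hits, {"s": members}, universe)
        expected = comb(95, 5) / comb(100, 10)
        assert out.loc["s", "p"] == pytest.approx(expected, rel=1e-12)

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        out = ora_hypergeometric(universe[10:12], {"s": universe[:5]},
                                 universe)
        assert out.loc["s", "overlap"] == 0
        assert out.loc["s", "p"] == pytest.approx(1.0)

    def test_list_equal_to_universe_saturates(self):
        universe = [f"g{i}" for i in range(15)]
        out = ora_hypergeometric(universe, {"s": universe[:6]}, universe)
        assert out.loc["s", "overlap"] == 6
        assert out.loc["s", "p"] == pytest.approx(1.0)


class TestSignatureScore:
    def test_single_gene_mean_z_equals_that_genes_z(self, tiny_expression):
        from methscore.preprocess import zscore_genes
        scores = signature_score(tiny_expression,
                                 {"solo": [tiny_expression.index[0]]})
        z = zscore_genes(tiny_expression).loc[tiny_expression.index[0]]
        np.testing.assert_allclose(scores["solo"], z, atol=1e-12)

    def test_duplicated_sample_scores_identically(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(8, 5))
        expr = pd.DataFrame(np.hstack([base, base[:, :1]]),
                            index=[f"G{i}" for i in range(8)],
                            columns=[f"S{i}" for i in range(6)])
        for method in ("mean_z", "ssgsea"):
            scores = signature_score(expr, {"s": ["G0", "G3", "G5"]},
                                     method=method)
            assert scores.loc["S0", "s"] == pytest.approx(
                scores.loc["S5", "s"], abs=1e-12)

    @pytest.mark.parametrize("method", ["mean_z", "ssgsea"])
    def test_planted_upshift_detected_with_high_auc(self, method):
        rng = np.random.default_rng(6)
        n, g = 100, 60
        expr = rng.normal(8, 1, size=(g, n))
        members = [f"G{i}" for i in range(10)]
        hot = np.zeros(n, dtype=bool)
        hot[:50] = True
        expr[:10, hot] += 1.0
        frame = pd.DataFrame(expr, index=[f"G{i}" for i in range(g)],
                             columns=[f"S{i}" for i in range(n)])
        scores = signature_score(frame, {"sig": members}, method=method)
        s = scores["sig"].to_numpy()
        # AUC via rank-sum
        ranks = stats.rankdata(s)
        auc = (ranks[hot].sum() - 50 * 51 / 2) / (50 * 50)
        assert auc >= 0.95


class TestKgroupTest:
    def test_null_three_group_calibration(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.normal(size=(1500, 60)),
                            index=[f"G{i}" for i in range(1500)],
                            columns=[f"S{i}" for i in range(60)])
        labels = pd.Series(np.repeat(["a", "b", "c"], 20), index=expr.columns)
        for method in ("kruskal", "anova"):
            out = kgroup_test(expr, labels, method=method)
            assert 0.03 <= (out["p"] < 0.05).mean() <= 0.07

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.normal(size=(5, 30)),
                            index=[f"G{i}" for i in range(5)],
                            columns=[f"S{i}" for i in range(30)])
        labels = pd.Series(np.repeat(["a", "b", "c"], 10), index=expr.columns)
        expr.loc["G0", labels == "c"] += 3.0
        out = kgroup_test(expr, labels)
        assert out.loc["G0", "p"] < 1e-4
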