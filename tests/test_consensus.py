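import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import methscore as ms
from methscore.consensus import (consensus_cluster, correlation_distance,
                                 kmedoids, pam_cost, select_k)


def _euclid(X):
    return np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))


class TestKmedoids:
    def test_separable_clouds_recovered(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (10, 2)),
                       rng.normal(100, 0.1, (10, 2))])
        labels, _ = kmedoids(_euclid(X), 2)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_k_equals_n_zero_cost(self):
        rng = np.random.default_rng(1)
        D = _euclid(rng.normal(size=(6, 2)))
        labels, med = kmedoids(D, 6)
        assert sorted(med) == list(range(6))
        assert pam_cost(D, med) == 0.0

    def test_matches_exhaustive_search_on_small_instances(self):
        rng = np.random.default_rng(2)
        for n, k in [(8, 2), (8, 3), (9, 3), (7, 2)]:
            for _ in range(10):
                D = _euclid(rng.normal(size=(n, 2)))
                _, med = kmedoids(D, k)
                best = min(pam_cost(D, s)
                           for s in itertools.combinations(range(n), k))
                assert pam_cost(D, med) == pytest.approx(best, abs=1e-9)

    def test_invalid_inputs_rejected(self):
        D = _euclid(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError, match="out of range"):
            kmedoids(D, 6)
        with pytest.raises(ValueError, match="symmetric"):
            kmedoids(np.arange(9.0).reshape(3, 3), 2)


class TestConsensus:
    def test_planted_three_clusters_recovered(self, planted_cohort):
        res = consensus_cluster(planted_cohort.expression,
                                list(ms.DEFAULT_PANEL), k_range=(2, 3, 4),
                                n_resamples=100, seed=0)
        ari = adjusted_rand_score(planted_cohort.sample_truth["true_cluster"],
                                  res.assignments[3])
        assert ari >= 0.95
        M = res.consensus[3].to_numpy()
        truth = planted_cohort.sample_truth["true_cluster"].to_numpy()
        within = M[truth[:, None] == truth[None, :]]
        assert np.median(within) >= 0.9

    def test_matrix_invariants_on_random_data(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(30, 40)),
                            index=[f"G{i}" for i in range(30)],
                            columns=[f"S{i}" for i in range(40)])
        res = consensus_cluster(expr, None, k_range=(2, 3), n_resamples=60,
                                seed=1)
        for k, M in res.consensus.items():
            A = M.to_numpy()
            assert np.allclose(A, A.T)
            assert np.allclose(np.diag(A), 1.0)
            assert (A >= 0).all() and (A <= 1).all()
            labels = res.assignments[k]
            assert labels.nunique() == k

    def test_seed_determinism(self, planted_cohort):
        kwargs = dict(features=list(ms.DEFAULT_PANEL), k_range=(2, 3),
                      n_resamples=40, seed=9)
        r1 = consensus_cluster(planted_cohort.expression, **kwargs)
        r2 = consensus_cluster(planted_cohort.expression, **kwargs)
        for k in (2, 3):
            pd.testing.assert_frame_equal(r1.consensus[k], r2.consensus[k])
            pd.testing.assert_series_equal(r1.assignments[k],
                                           r2.assignments[k])
        assert r1.chosen_k == r2.chosen_k

    def test_single_run_full_sample_reduces_to_co_membership(self,
                                                             planted_cohort):
        res = consensus_cluster(planted_cohort.expression,
                                list(ms.DEFAULT_PANEL), k_range=(3,),
                                n_resamples=1, p_item=1.0, seed=0)
        M = res.consensus[3].to_numpy()
        D = correlation_distance(planted_cohort.expression,
                                 list(ms.DEFAULT_PANEL))
        labels, _ = kmedoids(D.to_numpy(), 3)
        np.testing.assert_array_equal(
            M, (labels[:, None] == labels[None, :]).astype(float))

    def test_too_few_resamples_raise_on_uncovered_pairs(self, planted_cohort):
        with pytest.raises(ValueError, match="co-sampled"):
            consensus_cluster(planted_cohort.expression,
                              list(ms.DEFAULT_PANEL), k_range=(2,),
                              n_resamples=1, p_item=0.3, seed=0)


class TestSelectK:
    def test_planted_k3_recommended(self, planted_cohort):
        res = consensus_cluster(planted_cohort.expression,
                                list(ms.DEFAULT_PANEL), k_range=(2, 3, 4, 5),
                                n_resamples=100, seed=2)
        k, report = select_k(res)
        assert k == 3
        assert not report.attrs["low_confidence"]

    def test_single_k_range_returned(self, planted_cohort):
        res = consensus_cluster(planted_cohort.expression,
                                list(ms.DEFAULT_PANEL), k_range=(2,),
                                n_resamples=40, seed=0)
        k, _ = select_k(res)
        assert k == 2

    def test_structureless_data_flagged_low_confidence(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.normal(size=(25, 50)),
                            index=[f"G{i}" for i in range(25)],
                            columns=[f"S{i}" for i in range(50)])
        res = consensus_cluster(expr, None, k_range=(2, 3, 4),
                                n_resamples=80, seed=3)
        _, report = select_k(res)
        assert report.attrs["low_confidence"]

    def test_null_pac_exceeds_planted_pac(self, planted_cohort):
        """PAC at k=2 on structureless data is worse (higher) than on a
        planted cohort, over a handful of replicates."""
        null_pacs, planted_pacs = [], []
        for seed in range(5):
            cfg = ms.SimulationConfig(n_samples=60, cluster_shift=0.0,
                                      n_background_genes=30, n_deg_true=0,
                                      surv_beta=0.0, seed=100 + seed)
            null = ms.simulate_cohort(cfg)
            res = consensus_cluster(null.expression, list(ms.DEFAULT_PANEL),
                                    k_range=(2,), n_resamples=60, seed=seed)
            null_pacs.append(res.pac[2])
            cfg2 = ms.SimulationConfig(n_samples=60, cluster_shift=2.0,
                                       k_true=2, n_background_genes=30,
                                       n_deg_true=10, seed=200 + seed)
            planted = ms.simulate_cohort(cfg2)
            res2 = consensus_cluster(planted.expression,
                                     list(ms.DEFAULT_PANEL), k_range=(2,),
                                     n_resamples=60, seed=seed)
            planted_pacs.append(res2.pac[2])
        assert np.mean(null_pacs) > np.mean(planted_pacs)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_consensus_invariants_property(seed):
    rng = np.random.default_rng(seed)
    expr = pd.DataFrame(rng.normal(size=(10, 18)),
                        index=[f"G{i}" for i in range(10)],
                        columns=[f"S{i}" for i in range(18)])
    res = consensus_cluster(expr, None, k_range=(2,), n_resamples=40,
                            seed=seed % 1000)
    A = res.consensus[2].to_numpy()
    assert np.allclose(A, A.T) and np.allclose(np.diag(A), 1.0)
    assert (A >= 0).all() and (A <= 1).all()
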