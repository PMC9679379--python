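import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import methscore as ms
from methscore.dms import apply_dms, cox_screen, fit_dms
from tests.conftest import grid_maximize, naive_breslow_loglik


def _cohort_frames(n=20, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-0.8 * x) * 10)
    e = rng.random(n) < 0.8
    expr = pd.DataFrame([x], index=["G1"],
                        columns=[f"S{i}" for i in range(n)])
    clin = pd.DataFrame({"os_time": t, "os_status": e.astype(int)},
                        index=pd.Index(expr.columns, name="sample_id"))
    return expr, clin


class TestCoxScreen:
    def test_constant_covariate_flagged_not_kept(self):
        expr, clin = _cohort_frames()
        expr.loc["flat"] = 1.0
        out = cox_screen(expr, clin, ["G1", "flat"], min_events=1)
        assert not bool(out.loc["flat", "converged"])
        assert not bool(out.loc["flat", "kept"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_continuous_covariate_matches_grid_oracle(self, seed):
        expr, clin = _cohort_frames(seed=seed)
        out = cox_screen(expr, clin, ["G1"], min_events=1)
        x = expr.loc["G1"].to_numpy()
        t = clin["os_time"].to_numpy()
        e = clin["os_status"].to_numpy()
        oracle = grid_maximize(lambda b: naive_breslow_loglik(b, x, t, e))
        assert out.loc["G1", "coef"] == pytest.approx(oracle, abs=1e-4)

    def test_binary_covariate_matches_grid_oracle(self):
        rng = np.random.default_rng(5)
        x = np.repeat([0.0, 1.0], 10)
        t = rng.exponential(np.where(x > 0, 4.0, 12.0))
        e = np.ones(20, dtype=int)
        expr = pd.DataFrame([x], index=["B"],
                            columns=[f"S{i}" for i in range(20)])
        clin = pd.DataFrame({"os_time": t, "os_status": e},
                            index=pd.Index(expr.columns, name="sample_id"))
        out = cox_screen(expr, clin, ["B"], min_events=1)
        oracle = grid_maximize(lambda b: naive_breslow_loglik(b, x, t, e))
        assert out.loc["B", "coef"] == pytest.approx(oracle, abs=1e-4)

    def test_matches_lifelines_without_ties(self):
        expr, clin = _cohort_frames(n=40, seed=3)
        out = cox_screen(expr, clin, ["G1"])
        df = clin.assign(x=expr.loc["G1"])
        cph = CoxPHFitter().fit(df, duration_col="os_time",
                                event_col="os_status")
        # lifelines' Newton stops at a looser step tolerance than ours
        assert out.loc["G1", "coef"] == pytest.approx(
            cph.params_["x"], abs=1e-4)

    def test_no_events_rejected(self):
        expr, clin = _cohort_frames()
        clin["os_status"] = 0
        with pytest.raises(ValueError, match="no events"):
            cox_screen(expr, clin, ["G1"])

    def test_planted_cohort_screen_enriches_true_degs(self):
        """True DEGs are kept far above the null-gene rate; the null-gene
        rate averages near the nominal alpha (per-cohort rates are
        over-dispersed because all genes share one survival realization,
        so the calibration check averages over cohorts)."""
        deg_rates, null_rates = [], []
        for seed in (23, 24, 25):
            cfg = ms.SimulationConfig(n_samples=200, surv_beta=1.0,
                                      n_background_genes=400, n_deg_true=60,
                                      seed=seed)
            cohort = ms.simulate_cohort(cfg)
            truth = cohort.gene_truth
            degs = list(truth.index[truth["role"] == "deg"])
            nulls = list(truth.index[truth["role"] == "null"])[:200]
            out = cox_screen(cohort.expression, cohort.clinical, degs + nulls)
            deg_rates.append(out.loc[degs, "kept"].mean())
            null_rates.append(out.loc[nulls, "kept"].mean())
        assert np.mean(deg_rates) > 0.5
        assert np.mean(null_rates) <= 0.09  # ~ nominal alpha on average
        assert np.mean(deg_rates) > 5 * np.mean(null_rates)


class TestFitDms:
    @pytest.fixture()
    def planted_fit(self, planted_cohort):
        truth = planted_cohort.gene_truth
        degs = list(truth.index[truth["role"] == "deg"])
        screen = cox_screen(planted_cohort.expression,
                            planted_cohort.clinical, degs)
        model, scores = fit_dms(planted_cohort.expression, screen)
        return planted_cohort, model, scores

    def test_duplicated_samples_get_identical_dms(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(5, 6))
        expr = pd.DataFrame(np.hstack([base, base[:, :1]]),
                            index=[f"G{i}" for i in range(5)],
                            columns=[f"S{i}" for i in range(7)])
        _, scores = fit_dms(expr, list(expr.index))
        assert scores.loc["S0", "dms"] == pytest.approx(
            scores.loc["S6", "dms"], abs=1e-10)

    def test_gene_order_invariance(self, tiny_expression):
        genes = list(tiny_expression.index)
        _, s1 = fit_dms(tiny_expression, genes)
        _, s2 = fit_dms(tiny_expression.loc[genes[::-1]], genes[::-1])
        np.testing.assert_allclose(s1["dms"], s2["dms"], atol=1e-10)

    def test_loadings_unit_norm_orthogonal_scores_centered(self, planted_fit):
        _, model, scores = planted_fit
        L = model.loadings.to_numpy()
        np.testing.assert_allclose(np.linalg.norm(L, axis=0), [1.0, 1.0],
                                   atol=1e-10)
        assert abs(L[:, 0] @ L[:, 1]) < 1e-10
        assert abs(scores["pc1"].mean()) < 1e-9
        assert abs(scores["pc2"].mean()) < 1e-9
        evr = model.explained_variance_ratio
        assert 0 < evr[0] <= 1 and evr[0] + evr[1] <= 1

    def test_recovers_latent_score_with_positive_orientation(self,
                                                             planted_fit):
        cohort, _, scores = planted_fit
        r = np.corrcoef(scores["dms"],
                        cohort.sample_truth["latent_score"])[0, 1]
        assert r >= 0.8  # oriented positively by the HR<1 anchor

    def test_single_gene_falls_back_to_one_component(self, tiny_expression):
        with pytest.warns(UserWarning, match="single-component"):
            model, scores = fit_dms(tiny_expression, [tiny_expression.index[0]])
        assert (scores["pc2"] == 0).all()

    def test_empty_screen_rejected(self, tiny_expression):
        with pytest.raises(ValueError, match="no screened genes"):
            fit_dms(tiny_expression, [])


class TestApplyDms:
    def test_training_cohort_reproduced_exactly(self, tiny_expression):
        model, train = fit_dms(tiny_expression, list(tiny_expression.index))
        again = apply_dms(model, tiny_expression)
        np.testing.assert_allclose(train["dms"], again["dms"], atol=1e-10)

    def test_missing_genes_imputed_and_logged(self, tiny_expression):
        model, _ = fit_dms(tiny_expression, list(tiny_expression.index))
        reduced = tiny_expression.drop(index=tiny_expression.index[0])
        out = apply_dms(model, reduced)
        assert np.isfinite(out["dms"]).all()
        assert out.attrs["n_missing_genes"] == 1

    def test_coverage_floor_enforced(self, tiny_expression):
        model, _ = fit_dms(tiny_expression, list(tiny_expression.index))
        tiny = tiny_expression.iloc[:2]
        with pytest.raises(ValueError, match="covers only"):
            apply_dms(model, tiny)

    def test_validation_cohort_stratifies_survival(self):
        """A DMS trained on one planted cohort separates survival in an
        independent cohort from the same generator."""
        train = ms.simulate_cohort(ms.SimulationConfig(
            n_samples=200, surv_beta=1.0, n_background_genes=300,
            n_deg_true=60, seed=31))
        valid = ms.simulate_cohort(ms.SimulationConfig(
            n_samples=200, surv_beta=1.0, n_background_genes=300,
            n_deg_true=60, seed=32))
        truth = train.gene_truth
        degs = list(truth.index[truth["role"] == "deg"])
        screen = cox_screen(train.expression, train.clinical, degs)
        model, _ = fit_dms(train.expression, screen)
        scores = apply_dms(model, valid.expression)
        cut = ms.find_cutpoint(scores["dms"].to_numpy(),
                               valid.clinical["os_time"].to_numpy(),
                               valid.clinical["os_status"].to_numpy())
        groups = cut.groups(scores["dms"])
        _, _, p = ms.logrank_test(valid.clinical["os_time"],
                                  valid.clinical["os_status"],
                                  groups.to_numpy())
        assert p < 0.01
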