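import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from mealcontext import association as assoc
from mealcontext import data_model as dm
from mealcontext import diet_quality as dq
from mealcontext import synthetic_data as sd
from mealcontext.errors import DegenerateDataError, SpecError


def _clustered_data(rng, n_clusters=80, cluster_size=4, icc=0.1, beta=2.0):
    cid = np.repeat(np.arange(n_clusters), cluster_size)
    x = rng.normal(0, 1, cid.size)
    b = rng.normal(0, np.sqrt(icc), n_clusters)
    y = 1.0 + beta * x + b[cid] + rng.normal(0, np.sqrt(1 - icc), cid.size)
    return pd.DataFrame({"participant_id": cid, "x": x, "y": y})


class TestFitGee:
    def test_single_obs_per_cluster_equals_ols(self):
        rng = np.random.default_rng(0)
        d = _clustered_data(rng, n_clusters=120, cluster_size=1)
        fit = assoc.fit_gee(d, assoc.ModelSpec(outcome="y", terms=("x",)))
        X = sm.add_constant(d["x"])
        ols = sm.OLS(d["y"], X).fit()
        assert fit.params["intercept"] == pytest.approx(ols.params["const"],
                                                        abs=1e-8)
        assert fit.params["x"] == pytest.approx(ols.params["x"], abs=1e-8)

    def test_single_obs_logit_equals_glm(self):
        rng = np.random.default_rng(1)
        n = 300
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(float)
        d = pd.DataFrame({"participant_id": np.arange(n), "x": x, "y": y})
        fit = assoc.fit_gee(d, assoc.ModelSpec(outcome="y", terms=("x",),
                                               link="logit"))
        glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        assert fit.params["x"] == pytest.approx(glm.params[1], abs=1e-8)

    def test_constant_outcome_degenerate(self):
        d = pd.DataFrame({"participant_id": [1, 1, 2, 2],
                          "x": [0.0, 1.0, 0.0, 1.0], "y": 3.0})
        fit = assoc.fit_gee(d, assoc.ModelSpec(outcome="y", terms=("x",)))
        assert fit.degenerate
        assert fit.params["x"] == 0.0 and fit.se["x"] == 0.0
        assert fit.params["intercept"] == 3.0

    def test_singular_design_names_alias(self):
        rng = np.random.default_rng(2)
        d = _clustered_data(rng)
        d["x2"] = 2 * d["x"]
        with pytest.raises(SpecError, match="x2"):
            assoc.fit_gee(d, assoc.ModelSpec(outcome="y", terms=("x", "x2")))

    def test_logit_requires_binary(self):
        rng = np.random.default_rng(3)
        d = _clustered_data(rng)
        with pytest.raises(SpecError, match="binary"):
            assoc.fit_gee(d, assoc.ModelSpec(outcome="y", terms=("x",),
                                             link="logit"))

    def test_needs_two_clusters(self):
        d = pd.DataFrame({"participant_id": 1, "x": [0.0, 1.0], "y": [0.0, 1.0]})
        with pytest.raises(SpecError, match="clusters"):
            assoc.fit_gee(d, assoc.ModelSpec(outcome="y", terms=("x",)))

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        d = _clustered_data(rng)
        fit1 = assoc.fit_gee(d, assoc.ModelSpec(outcome="y", terms=("x",)))
        shuffled = d.sample(frac=1, random_state=9)
        fit2 = assoc.fit_gee(shuffled,
                             assoc.ModelSpec(outcome="y", terms=("x",)))
        assert fit1.params["x"] == pytest.approx(fit2.params["x"], abs=1e-10)
        assert fit1.se["x"] == pytest.approx(fit2.se["x"], abs=1e-10)

    def test_sandwich_ci_coverage(self):
        # nominal 95% CIs under working-independence misspecification
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 250
        for _ in range(n_rep):
            d = _clustered_data(rng, n_clusters=150, cluster_size=6, icc=0.1)
            fit = assoc.fit_gee(d, assoc.ModelSpec(outcome="y", terms=("x",)))
            hits += fit.ci_lo["x"] <= 2.0 <= fit.ci_hi["x"]
        assert 0.92 * n_rep <= hits <= 0.98 * n_rep

    def test_working_correlation_sensitivity(self):
        rng = np.random.default_rng(6)
        d = _clustered_data(rng, n_clusters=150, cluster_size=6)
        fits = {wc: assoc.fit_gee(d, assoc.ModelSpec(
            outcome="y", terms=("x",), working_correlation=wc))
            for wc in ("independent", "exchangeable", "ar1")}
        se = fits["independent"].se["x"]
        for wc in ("exchangeable", "ar1"):
            assert abs(fits[wc].params["x"]
                       - fits["independent"].params["x"]) < 0.1 * se


class TestWaldCompare:
    def test_empty_terms_rejected(self):
        d = _clustered_data(np.random.default_rng(0))
        with pytest.raises(SpecError):
            assoc.wald_compare(d, "y", [])

    def test_added_term_duplicating_null_column(self):
        d = _clustered_data(np.random.default_rng(0))
        with pytest.raises(SpecError):
            assoc.wald_compare(d, "y", ["x"], null_terms=["x"])

    def test_reparameterization_invariance(self):
        rng = np.random.default_rng(7)
        d = _clustered_data(rng, n_clusters=100, cluster_size=5)
        d["z"] = rng.normal(0, 1, len(d))
        d["c1"] = rng.normal(0, 1, len(d))
        d["c2"] = rng.normal(0, 1, len(d))
        # reparameterize the null covariates by a nonsingular map
        d["c1r"] = 2.0 * d["c1"] + 0.5 * d["c2"]
        d["c2r"] = -d["c1"] + 3.0 * d["c2"]
        w1 = assoc.wald_compare(d, "y", ["z"], null_terms=["c1", "c2"])
        w2 = assoc.wald_compare(d, "y", ["z"], null_terms=["c1r", "c2r"])
        assert w1.statistic == pytest.approx(w2.statistic, abs=1e-6)
        assert w1.df == w2.df == 1

    def test_null_pvalues_uniform(self):
        # added term truly null: p-values ~ Uniform(0,1) across replicates
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(400):
            d = _clustered_data(rng, n_clusters=150, cluster_size=3,
                                beta=0.0)
            d["z"] = rng.normal(0, 1, len(d))
            ps.append(assoc.wald_compare(d, "y", ["z"]).p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_strong_dependence_detected(self):
        # location-conditional companion rates (study defaults) produce
        # overwhelming evidence against the null model
        bundle, _ = sd.simulate_cohort(
            sd.SimulationConfig(n_participants=250, seed=13),
            include_cgm=False)
        meals, _ = dm.filter_meals(bundle.meals)
        tab = assoc.build_analysis_table(bundle.participants, meals)
        ctx = tab.loc[~tab["location_excluded"]]
        loc_terms = [t for t in assoc.LOCATION_TERMS if ctx[t].sum() > 0]
        w = assoc.wald_compare(ctx, "comp_colleagues", loc_terms, link="logit")
        assert w.p < 0.001


class TestBootstrapCorrelation:
    def test_perfect_correlation(self):
        x = np.arange(30.0)
        res = assoc.bootstrap_correlation(x, x, np.arange(30) // 3,
                                          n_boot=500, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.ci_lo == pytest.approx(1.0) and res.ci_hi == pytest.approx(1.0)
        assert res.p < 0.01

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(0, 1, (2, 200))
        cid = np.arange(200) // 5
        a = assoc.bootstrap_correlation(x, y, cid, n_boot=1000, seed=3)
        b = assoc.bootstrap_correlation(x, y, cid, n_boot=1000, seed=3)
        assert (a.ci_lo, a.ci_hi, a.p) == (b.ci_lo, b.ci_hi, b.p)

    def test_cluster_size_one_equals_plain_bootstrap(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0, 1, (2, 150))
        cid = np.arange(150)  # every row its own cluster
        a = assoc.bootstrap_correlation(x, y, cid, n_boot=800, seed=5,
                                        unit="cluster")
        b = assoc.bootstrap_correlation(x, y, cid, n_boot=800, seed=5,
                                        unit="meal")
        assert a.ci_lo == b.ci_lo and a.ci_hi == b.ci_hi and a.p == b.p

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            assoc.bootstrap_correlation(np.ones(20), np.arange(20.0),
                                        np.arange(20) // 2, n_boot=100, seed=0)

    def test_missing_pairs_dropped(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([1.0, np.nan, 3.0, 4.0, 5.0, 7.0])
        res = assoc.bootstrap_correlation(x, y, np.arange(6) // 2,
                                          n_boot=200, seed=0)
        assert res.n_obs == 4


class TestMarginalEstimates:
    def test_intercept_only_returns_grand_mean(self):
        rng = np.random.default_rng(12)
        d = _clustered_data(rng)
        fit = assoc.fit_gee(d, assoc.ModelSpec(outcome="y", terms=()))
        out = assoc.marginal_estimates(fit, d, {"a": {}, "b": {}})
        for m in out:
            assert m.estimate == pytest.approx(d["y"].mean(), abs=1e-6)

    def test_focal_only_identity_equals_raw_group_means(self):
        rng = np.random.default_rng(13)
        g = rng.integers(0, 3, 300)
        y = np.array([0.0, 1.5, -0.7])[g] + rng.normal(0, 0.3, 300)
        d = pd.DataFrame({"participant_id": np.arange(300) // 4, "y": y,
                          "g1": (g == 1).astype(float),
                          "g2": (g == 2).astype(float)})
        fit = assoc.fit_gee(d, assoc.ModelSpec(outcome="y",
                                               terms=("g1", "g2")))
        out = assoc.marginal_estimates(
            fit, d, {"g0": {"g1": 0.0, "g2": 0.0},
                     "g1": {"g1": 1.0, "g2": 0.0},
                     "g2": {"g1": 0.0, "g2": 1.0}})
        raw = {f"g{k}": d.loc[g == k, "y"].mean() for k in range(3)}
        for m in out:
            assert m.estimate == pytest.approx(raw[m.level], abs=1e-8)

    def test_unknown_focal_column_rejected(self):
        rng = np.random.default_rng(14)
        d = _clustered_data(rng)
        fit = assoc.fit_gee(d, assoc.ModelSpec(outcome="y", terms=("x",)))
        with pytest.raises(SpecError):
            assoc.marginal_estimates(fit, d, {"lvl": {"nope": 1.0}})


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        rng = np.random.default_rng(15)
        n = 400
        d = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=["a", "b", "c"])
        out = assoc.vif(d, ["a", "b", "c"])
        assert (out < 1.1).all()

    def test_duplicated_predictor_infinite(self):
        rng = np.random.default_rng(16)
        d = pd.DataFrame({"a": rng.normal(0, 1, 100)})
        d["b"] = d["a"]
        out = assoc.vif(d, ["a", "b"])
        assert np.isinf(out).all()

    def test_multivariable_design_band(self):
        # the full adjustment design on generated data shows only the mild
        # collinearity expected of overlapping context indicators
        bundle, truth = sd.simulate_cohort(
            sd.SimulationConfig(n_participants=250, seed=21),
            include_cgm=False)
        meals, _ = dm.filter_meals(bundle.meals)
        tab = assoc.build_analysis_table(bundle.participants, meals)
        terms = [t for t in assoc.BASELINE_ADJUSTMENT_TERMS
                 + assoc.CONTEXT_TERMS if tab[t].sum() > 0]
        out = assoc.vif(tab, terms)
        assert np.isfinite(out).all()
        assert out.max() < 5.0


class TestRecovery:
    def test_injected_hawker_effect_within_ci(self):
        cfg = sd.SimulationConfig(n_participants=300, seed=31,
                                  excursion_effects={"location:hawker": 30.0})
        bundle, truth = sd.simulate_cohort(cfg, include_cgm=False)
        meals, _ = dm.filter_meals(bundle.meals)
        scores = dq.score_dataset(meals)
        tab = assoc.build_analysis_table(bundle.participants, meals, scores)
        tab = tab.merge(truth.meal_truth[["meal_id", "iauc_target"]],
                        on="meal_id")
        tab = tab.loc[~tab["location_excluded"]]
        loc = tuple(t for t in assoc.LOCATION_TERMS if tab[t].sum() > 0)
        terms = (assoc.BASELINE_ADJUSTMENT_TERMS + assoc.COMPANION_TERMS
                 + assoc.ACTIVITY_TERMS + loc)
        fit = assoc.fit_gee(tab, assoc.ModelSpec(outcome="iauc_target",
                                                 terms=terms))
        # single-cohort sanity check at 3.5 robust SEs; the nominal 95%
        # coverage rate is asserted over repeated cohorts elsewhere
        z = abs(fit.params["loc_hawker"] - 30.0) / fit.se["loc_hawker"]
        assert z < 3.5


class TestRunTable3:
    def test_three_outcomes_and_sensitivity(self, default_cohort):
        bundle, truth = default_cohort
        meals, _ = dm.filter_meals(bundle.meals)
        scores = dq.score_dataset(meals)
        from mealcontext import cgm_linkage as cl
        pp = cl.link_all(meals, bundle.cgm)
        pm = dm.extract_premeal_states(meals, bundle.surveys)
        tab = assoc.build_analysis_table(bundle.participants, meals, scores,
                                         pp, pm)
        res = assoc.run_table3(tab, working_correlations=("independent",
                                                          "exchangeable"))
        assert set(res["outcome"]) == {"diet_quality", "fullness", "iauc"}
        assert set(res["working_correlation"]) == {"independent",
                                                   "exchangeable"}
        assert set(res["model_id"]) == {"primary", "premeal_states"}
        # premeal-state models are restricted to meals with states
        prim = res.query("model_id=='primary' and outcome=='diet_quality' "
                         "and working_correlation=='independent'")
        state = res.query("model_id=='premeal_states' and "
                          "outcome=='diet_quality' and "
                          "working_correlation=='independent'")
        assert state["n_obs"].iloc[0] < prim["n_obs"].iloc[0]
        assert {f"premeal_{s}" for s in dm.PSYCH_STATES} <= \
            set(state["term"])
        # estimates stable across working correlations
        for term in ("loc_hawker", "comp_friends"):
            a = prim.set_index("term").loc[term, "beta"]
            b = res.query("model_id=='primary' and outcome=='diet_quality' "
                          "and working_correlation=='exchangeable'"
                          ).set_index("term").loc[term, "beta"]
            se = prim.set_index("term").loc[term, "se"]
            assert abs(a - b) < 0.1 * se + 1e-12
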