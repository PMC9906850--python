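"""AICc enumeration, Akaike weights, and full model averaging."""

import numpy as np
import pandas as pd
import pytest

from owlmove import modelsel as ms


def _lmm_data(n_ind=64, nper=2, beta=None, noise=0.4, u_sd=0.3, seed=0):
    rng = np.random.default_rng(seed)
    beta = beta or {}
    n = n_ind * nper
    ind = np.repeat(np.arange(n_ind), nper)
    df = pd.DataFrame({
        "individual": ind,
        "x1": rng.normal(0, 1, n),
        "x2": rng.normal(0, 1, n),
        "x3": rng.normal(0, 1, n),
    })
    u = rng.normal(0, u_sd, n_ind)
    df["y"] = (
        sum(b * df[c] for c, b in beta.items())
        + u[ind]
        + rng.normal(0, noise, n)
    )
    return df


class TestStandardize:
    def test_three_point_example_uses_sample_sd(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out, params = ms.standardize(df, ["a"])
        assert np.allclose(out["a"], [-1.0, 0.0, 1.0])
        assert params["sd"].iloc[0] == 1.0

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(size=100)})
        once, _ = ms.standardize(df, ["a"])
        twice, _ = ms.standardize(once, ["a"])
        assert np.allclose(once["a"], twice["a"], atol=1e-12)

    def test_backmapping_recovers_raw_scale_slope(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 4, 200)
        y = 2.5 * x + rng.normal(0, 0.1, 200)
        df = pd.DataFrame({"x": x, "y": y})
        z, params = ms.standardize(df, ["x"])
        slope_std = np.polyfit(z["x"], y, 1)[0]
        assert ms.backmap_slope(slope_std, params, "x") == pytest.approx(2.5, abs=0.01)

    def test_zero_variance_column_named(self):
        with pytest.raises(ValueError, match="a"):
            ms.standardize(pd.DataFrame({"a": [1.0, 1.0]}), ["a"])


class TestCollinearity:
    def test_proportional_pair_flagged(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8]})
        rep = ms.collinearity_screen(df, ["x", "y"])
        assert rep["flagged"].all()

    def test_independent_covariates_clean(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.normal(size=10_000), "y": rng.normal(size=10_000)})
        rep = ms.collinearity_screen(df, ["x", "y"])
        assert not rep["flagged"].any()

    def test_flagged_pair_never_cooccurs_in_models(self):
        rng = np.random.default_rng(3)
        df = _lmm_data(seed=3)
        df["x2"] = 0.9 * df["x1"] + np.sqrt(1 - 0.81) * rng.normal(0, 1, len(df))
        rep = ms.collinearity_screen(df, ["x1", "x2"])
        assert rep["flagged"].iloc[0]
        excluded = {frozenset(("x1", "x2"))}
        models = ms.enumerate_and_rank(
            df, "y", ["x1", "x2", "x3"], excluded_pairs=excluded
        )
        for m in models:
            assert not {"x1", "x2"} <= set(m.predictors)


class TestAICc:
    def test_closed_form_toy(self):
        assert ms.aicc(-10.0, 3, 20) == 27.5

    def test_approaches_aic_at_large_n(self):
        aic = -2 * (-10.0) + 2 * 3
        assert ms.aicc(-10.0, 3, 10**9) == pytest.approx(aic, abs=1e-6)

    def test_always_above_aic(self):
        for n in (10, 50, 500):
            assert ms.aicc(-10.0, 3, n) > -2 * (-10.0) + 2 * 3

    def test_undefined_below_minimum_n(self):
        with pytest.raises(ValueError):
            ms.aicc(-10.0, 3, 4)


class TestLMMML:
    def test_no_group_variance_reduces_to_ols(self):
        # singleton groups: V is proportional to I, so GLS collapses to OLS
        rng = np.random.default_rng(4)
        n = 200
        df = pd.DataFrame({
            "individual": np.arange(n),
            "x1": rng.normal(size=n),
        })
        df["y"] = 2.0 + 1.5 * df["x1"] + rng.normal(0, 0.5, n)
        m = ms.fit_lmm_ml(df, "y", ("x1",))
        ols = np.linalg.lstsq(
            np.column_stack([np.ones(n), df["x1"]]), df["y"], rcond=None
        )[0]
        assert np.allclose(m.coef.to_numpy(), ols, atol=1e-6)

    def test_balanced_design_matches_gls_closed_form(self):
        # known variance ratio theta: GLS with per-group shrinkage weights
        rng = np.random.default_rng(5)
        k, m_per = 40, 5
        u = rng.normal(0, 1.0, k)
        ind = np.repeat(np.arange(k), m_per)
        x = rng.normal(0, 1, k * m_per)
        y = 1.0 + 0.8 * x + u[ind] + rng.normal(0, 1.0, k * m_per)
        df = pd.DataFrame({"individual": ind, "x1": x, "y": y})
        fit = ms.fit_lmm_ml(df, "y", ("x1",))
        from owlmove.repeatability import fit_lmm

        vc = fit_lmm(df, value_col="y", group_col="individual", fixed=["x1"], reml=False)
        theta = vc.var_among / vc.var_within
        c = theta / (1 + m_per * theta)
        Xf = np.column_stack([np.ones(k * m_per), x])
        V_inv_blocks = np.eye(m_per) - c * np.ones((m_per, m_per))
        XtX = sum(
            Xf[ind == g].T @ V_inv_blocks @ Xf[ind == g] for g in range(k)
        )
        Xty = sum(Xf[ind == g].T @ V_inv_blocks @ y[ind == g] for g in range(k))
        beta_gls = np.linalg.solve(XtX, Xty)
        assert np.allclose(fit.coef.to_numpy(), beta_gls, atol=1e-6)

    def test_preset_coefficients_recovered(self):
        df = _lmm_data(beta={"x1": 0.54, "x2": 0.34}, seed=6)
        m = ms.fit_lmm_ml(df, "y", ("x1", "x2"))
        assert m.coef["x1"] == pytest.approx(0.54, abs=0.1)
        assert m.coef["x2"] == pytest.approx(0.34, abs=0.1)


class TestEnumeration:
    def test_three_free_predictors_give_eight_models(self):
        df = _lmm_data(seed=7)
        models = ms.enumerate_and_rank(df, "y", ["x1", "x2", "x3"])
        assert len(models) == 8

    def test_forced_predictor_halves_the_space(self):
        df = _lmm_data(seed=8)
        models = ms.enumerate_and_rank(df, "y", ["x1", "x2", "x3"], forced=("x1",))
        assert len(models) == 4
        assert all("x1" in m.predictors for m in models)

    def test_refuses_oversized_enumeration(self):
        df = _lmm_data(seed=9)
        many = [f"p{i}" for i in range(13)]
        for c in many:
            df[c] = np.random.default_rng(1).normal(size=len(df))
        with pytest.raises(ValueError, match="exceed"):
            ms.enumerate_and_rank(df, "y", many, max_models=4096)

    def test_weights_sum_to_one_and_deltas_start_at_zero(self):
        df = _lmm_data(beta={"x1": 0.5}, seed=10)
        models = ms.enumerate_and_rank(df, "y", ["x1", "x2"])
        assert sum(m.weight for m in models) == pytest.approx(1.0)
        assert models[0].delta == 0.0

    def test_null_simulation_keeps_intercept_model_near_top(self):
        hits = 0
        n_rep = 60
        for s in range(n_rep):
            df = _lmm_data(n_ind=40, seed=200 + s)
            models = ms.enumerate_and_rank(df, "y", ["x1", "x2", "x3"])
            null = next(m for m in models if m.predictors == ())
            hits += null.delta <= 2.0
        assert hits / n_rep >= 0.8


class TestModelAverage:
    def test_single_model_scope_returns_its_estimates(self):
        df = _lmm_data(beta={"x1": 2.0}, noise=0.1, seed=11)
        models = ms.enumerate_and_rank(df, "y", ["x1"])
        scope = [m for m in models if m.delta < 1e-9]
        avg = ms.model_average(models, delta_max=1e-6)
        top = scope[0]
        row = avg.set_index("term")
        assert row.loc["x1", "estimate"] == pytest.approx(top.coef["x1"])
        assert row.loc["x1", "unconditional_se"] == pytest.approx(top.se["x1"])

    def test_absent_predictor_absent_from_output(self):
        df = _lmm_data(seed=12)
        models = ms.enumerate_and_rank(df, "y", ["x1", "x2"])
        in_scope = [m for m in models if m.delta < 4]
        avg = ms.model_average(models)
        for term in avg["term"]:
            assert any(term in m.coef.index for m in in_scope)

    def test_average_lies_between_zero_and_largest_estimate(self):
        df = _lmm_data(beta={"x1": 0.5}, seed=13)
        models = ms.enumerate_and_rank(df, "y", ["x1", "x2"])
        avg = ms.model_average(models).set_index("term")
        ests = [m.coef.get("x1", 0.0) for m in models if m.delta < 4]
        assert 0 <= avg.loc["x1", "estimate"] <= max(ests) + 1e-12

    def test_weight_invariance_to_aicc_shift(self):
        df = _lmm_data(beta={"x1": 0.5}, seed=14)
        models = ms.enumerate_and_rank(df, "y", ["x1", "x2"])
        w = np.array([m.weight for m in models])
        deltas = np.array([m.aicc for m in models]) + 100.0
        w2 = np.exp(-0.5 * (deltas - deltas.min()))
        w2 /= w2.sum()
        order = np.argsort([m.aicc for m in models])
        assert np.allclose(np.sort(w)[::-1], np.sort(w2)[::-1])

    def test_dominant_age_effect_recovered_across_replicates(self):
        # a single strong predictor (preset 0.856) should survive averaging
        hits_ci = 0
        ests = []
        n_rep = 20
        for s in range(n_rep):
            rng = np.random.default_rng(300 + s)
            n_ind = 64
            ind = np.repeat(np.arange(n_ind), 2)
            age = np.repeat(rng.integers(0, 2, n_ind), 2).astype(float)
            u = rng.normal(0, 0.3, n_ind)
            df = pd.DataFrame({
                "individual": ind,
                "age": age,
                "elev": rng.normal(0, 1, n_ind * 2),
                "year": rng.normal(0, 1, n_ind * 2),
                "y": 1.047 + 0.856 * age + u[ind] + rng.normal(0, 0.5, n_ind * 2),
            })
            models = ms.enumerate_and_rank(df, "y", ["age", "elev", "year"])
            avg = ms.model_average(models).set_index("term")
            ests.append(avg.loc["age", "estimate"])
            hits_ci += avg.loc["age", "ci_low"] > 0
        assert np.mean(ests) == pytest.approx(0.856, abs=0.2)
        assert hits_ci / n_rep >= 0.9


class TestTwoStagePlan:
    def test_stage2_terms_only_augment_top_models(self):
        df = _lmm_data(beta={"x1": 1.0}, seed=15)
        df["geo"] = np.random.default_rng(2).normal(size=len(df))
        models = ms.enumerate_and_rank(
            df, "y", ["x1", "x2"], stage2=["geo"], stage2_delta=4.3
        )
        with_geo = [m for m in models if "geo" in m.predictors]
        assert with_geo  # augmentation happened
        assert sum(m.weight for m in models) == pytest.approx(1.0)
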