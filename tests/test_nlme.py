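"""Two-level NLME: oracle equivalences, degeneracies, EBLUPs, LRT."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from pinecrown.growth import ModelSpec, evaluate
from pinecrown import nlme, nls
from pinecrown.nlme import (NLMEResult, RandomEffectsSpec, TwoLevelNLME,
                            VarianceSpec, fit_nlme, loglik, lrt,
                            search_random_effects, predict)


def _make_result(spec, re_spec, beta, D1, D2, sigma2, n=0):
    """Minimal NLMEResult carrying parameters for standalone loglik."""
    q1, q2 = re_spec.q1, re_spec.q2
    return NLMEResult(
        spec=spec, re_spec=re_spec, var_spec=VarianceSpec(), beta=beta,
        se={}, pvalues={},
        D1=pd.DataFrame(np.atleast_2d(D1) if q1 else np.zeros((0, 0)),
                        index=re_spec.level1_params,
                        columns=re_spec.level1_params),
        D2=pd.DataFrame(np.atleast_2d(D2) if q2 else np.zeros((0, 0)),
                        index=re_spec.level2_params,
                        columns=re_spec.level2_params),
        sigma2=sigma2, var_params={}, loglik=np.nan, aic=np.nan, n=n,
        n_params=0, eblups_level1=pd.DataFrame(),
        eblups_level2=pd.DataFrame(), mae=np.nan, rmse=np.nan, ra2=np.nan,
        converged=True, iterations=0)


@pytest.fixture(scope="module")
def tiny_linear_instance():
    """5 groups, one scalar random effect on the amplitude a: the model
    is linear in the effect, so Laplace integration is exact."""
    rng = np.random.default_rng(21)
    a, b, c = 2.0, 0.8, 0.004
    d, s2 = 0.25, 1.0
    rows = []
    for i in range(5):
        u = np.sqrt(d) * rng.standard_normal()
        for j in (1, 2):
            for k in range(4):
                x = rng.uniform(20, 300)
                g = x**b * np.exp(-c * x)
                y = (a + u) * g + np.sqrt(s2) * rng.standard_normal()
                rows.append((0, i, j, k, j, x, y))
    df = pd.DataFrame(rows, columns=["tree_id", "branch_id", "whorl_id",
                                     "obs_id", "SAGE", "SDINC", "SBL"])
    return df, dict(a=a, b=b, c=c, d=d, s2=s2)


def _gh_oracle_loglik(df, a, b, c, d, s2, n_nodes=80):
    """Brute-force adaptive Gauss-Hermite marginal loglik, one random
    amplitude per group: independent of the package's linear algebra."""
    zs, ws = np.polynomial.hermite.hermgauss(n_nodes)
    total = 0.0
    for _, sub in df.groupby("branch_id"):
        x = sub["SDINC"].to_numpy()
        y = sub["SBL"].to_numpy()
        g = x**b * np.exp(-c * x)
        # posterior mode/curvature of u for adaptive centering
        prec = g @ g / s2 + 1 / d
        mode = (g @ (y - a * g) / s2) / prec
        sd = 1 / np.sqrt(prec)
        u = mode + np.sqrt(2.0) * sd * zs
        resid = y[None, :] - (a + u[:, None]) * g[None, :]
        logf = (-0.5 * np.sum(resid**2, axis=1) / s2
                - 0.5 * len(y) * np.log(2 * np.pi * s2)
                - 0.5 * u**2 / d - 0.5 * np.log(2 * np.pi * d))
        vals = np.log(ws) + zs**2 + logf
        m = vals.max()
        total += m + np.log(np.sum(np.exp(vals - m))) \
            + 0.5 * np.log(2.0) + np.log(sd)
    return total


def test_laplace_loglik_matches_quadrature_oracle(tiny_linear_instance):
    df, p = tiny_linear_instance
    spec = ModelSpec("M7")
    re_spec = RandomEffectsSpec(("a",), ())
    res = _make_result(spec, re_spec, {"a": p["a"], "b": p["b"], "c": p["c"]},
                       [[p["d"]]], None, p["s2"])
    got = loglik(res, df, response="SBL")
    want = _gh_oracle_loglik(df, p["a"], p["b"], p["c"], p["d"], p["s2"])
    assert got == pytest.approx(want, abs=1e-4)


def test_loglik_zero_variance_reduces_to_nls(tiny_linear_instance):
    df, p = tiny_linear_instance
    spec = ModelSpec("M7")
    fit = nls.fit(spec, df, "SBL")
    s2_ml = fit.rss / fit.n
    res = _make_result(spec, RandomEffectsSpec(("a",), ()), fit.estimates,
                       [[1e-16]], None, s2_ml)
    assert loglik(res, df, response="SBL") == pytest.approx(fit.loglik,
                                                            abs=1e-5)


def test_doubling_sigma2_decreases_loglik(tiny_linear_instance):
    df, p = tiny_linear_instance
    spec = ModelSpec("M7")
    re_spec = RandomEffectsSpec(("a",), ())
    beta = {"a": p["a"], "b": p["b"], "c": p["c"]}
    base = _make_result(spec, re_spec, beta, [[p["d"]]], None, p["s2"])
    worse = _make_result(spec, re_spec, beta, [[p["d"]]], None, 2 * p["s2"])
    assert loglik(base, df, response="SBL") > loglik(worse, df, response="SBL")


@pytest.fixture(scope="module")
def fitted_sbl(sbl_small_df, sbl_spec):
    est = TwoLevelNLME(spec=sbl_spec, level1=("b", "c"), level2=("b",))
    est.fit(sbl_small_df)
    assert est.converged_
    return est


class TestFittedModel:
    def test_estimates_near_generating_values(self, fitted_sbl):
        r = fitted_sbl.result_
        # single replicate at reduced scale: generous sanity bands only
        # (the amplitude/exponent ridge makes individual draws wander)
        assert r.beta["b"] == pytest.approx(0.989, abs=0.15)
        assert r.beta["c"] == pytest.approx(0.003, abs=0.0012)
        assert r.sigma2 == pytest.approx(251.6, rel=0.10)

    def test_aic_consistent_with_loglik(self, fitted_sbl):
        r = fitted_sbl.result_
        assert r.aic == pytest.approx(-2 * r.loglik + 2 * r.n_params,
                                      rel=1e-12)
        # p(4) + D1(3) + D2(1) + sigma2(1)
        assert r.n_params == 9

    def test_variance_report_keys(self, fitted_sbl):
        rep = fitted_sbl.result_.variance_report()
        assert set(rep) == {"sigma2", "var_b_level1", "var_c_level1",
                            "corr_bc_level1", "var_b_level2"}
        assert -1 <= rep["corr_bc_level1"] <= 1
        assert all(v >= 0 for k, v in rep.items() if k.startswith("var"))

    def test_d_matrices_positive_semidefinite(self, fitted_sbl):
        r = fitted_sbl.result_
        assert np.min(np.linalg.eigvalsh(r.D1.to_numpy())) >= -1e-12
        assert np.min(np.linalg.eigvalsh(r.D2.to_numpy())) >= -1e-12

    def test_population_prediction_is_curve_at_beta(self, fitted_sbl,
                                                    sbl_small_df, sbl_spec):
        pred = fitted_sbl.predict(sbl_small_df, mode="population")
        want = evaluate(sbl_spec, fitted_sbl.beta_, sbl_small_df["SDINC"],
                        sbl_small_df, check=False)
        np.testing.assert_allclose(pred, want, rtol=1e-12)

    def test_subject_mode_shrinks_training_error(self, fitted_sbl,
                                                 sbl_small_df):
        y = sbl_small_df["SBL"].to_numpy()
        rp = np.sqrt(np.mean((fitted_sbl.predict(
            sbl_small_df, mode="population") - y) ** 2))
        rs = np.sqrt(np.mean((fitted_sbl.predict(
            sbl_small_df, mode="subject") - y) ** 2))
        assert rs < rp

    def test_unseen_group_falls_back_to_population(self, fitted_sbl,
                                                   sbl_small_df):
        new = sbl_small_df.head(5).copy()
        new["branch_id"] = 10_000
        np.testing.assert_allclose(
            fitted_sbl.predict(new, mode="subject"),
            fitted_sbl.predict(new, mode="population"), rtol=1e-12)

    def test_eblup_centering_and_shrinkage(self, fitted_sbl):
        r = fitted_sbl.result_
        eb = r.eblups_level1[["b", "c"]].to_numpy()
        sd_gen = np.sqrt(np.diag(r.D1.to_numpy()))
        assert np.all(np.abs(eb.mean(axis=0)) < 0.5 * sd_gen)
        # shrinkage: empirical spread does not exceed the estimated D1
        emp = eb.var(axis=0, ddof=1)
        assert np.all(emp <= np.diag(r.D1.to_numpy()) * 1.05)

    def test_standalone_loglik_matches_reported(self, fitted_sbl,
                                                sbl_small_df):
        r = fitted_sbl.result_
        assert loglik(r, sbl_small_df, response="SBL") == pytest.approx(
            r.loglik, abs=0.1)


def test_zero_variance_data_degenerates_to_nls(sbl_fixed_df, sbl_spec):
    sub = sbl_fixed_df[sbl_fixed_df["tree_id"] < 6]
    fe = nls.fit(sbl_spec, sub, "SBL")
    res = fit_nlme(sbl_spec, RandomEffectsSpec(("b",), ("b",)), None, sub,
                   refine=False)
    for k in ("a", "b", "c"):
        assert abs(res.beta[k] - fe.estimates[k]) <= 2.5 * fe.se[k] + 1e-9
    assert res.D1.iloc[0, 0] < 1e-4      # shrinks toward zero
    assert res.D2.iloc[0, 0] < 1e-4
    assert res.sigma2 == pytest.approx(fe.rss / fe.n, rel=0.02)


def test_full_model_loglik_not_below_nested(fitted_sbl, sbl_small_df,
                                            sbl_spec):
    nested = fit_nlme(sbl_spec, RandomEffectsSpec(("b",), ()), None,
                      sbl_small_df, refine=False)
    full = fitted_sbl.result_
    assert full.loglik >= nested.loglik - 1e-3
    stat, df, p = lrt(nested, full)
    assert stat >= 0 and df == full.n_params - nested.n_params
    assert 0 <= p <= 1


def test_lrt_identical_models(fitted_sbl):
    r = fitted_sbl.result_
    stat, df, p = lrt(r, r)
    assert stat == 0 and df == 0 and p == 1.0


def test_lrt_rejects_non_nested_order(fitted_sbl, sbl_small_df, sbl_spec):
    nested = fit_nlme(sbl_spec, RandomEffectsSpec(("b",), ()), None,
                      sbl_small_df, refine=False)
    with pytest.raises(ValueError):
        lrt(fitted_sbl.result_, nested)


def test_search_zero_random_effects_is_single_nls_row(sbl_small_df, sbl_spec):
    tab = search_random_effects(sbl_spec, sbl_small_df, max_random=0)
    assert len(tab) == 1
    assert tab.iloc[0]["level1"] == () and tab.iloc[0]["level2"] == ()


def test_search_ranks_by_aic(sbl_small_df, sbl_spec):
    combos = [(("b",), ()), (("b",), ("b",))]
    tab = search_random_effects(sbl_spec, sbl_small_df, combos=combos,
                                refine=False, theta_maxiter=150)
    conv = tab[tab["converged"]]
    assert conv["aic"].is_monotonic_increasing
    assert len(tab) == 2


def test_power_variance_function_recovery():
    """Heteroscedastic machinery: sd proportional to |mu|^delta."""
    rng = np.random.default_rng(31)
    rows = []
    a, b, c, delta = 0.5, 0.9, 0.003, 0.5
    for i in range(60):
        u = 0.05 * rng.standard_normal()
        for j in (1, 2, 3):
            for k in range(3):
                x = rng.uniform(20, 400)
                mu = a * x ** (b + u) * np.exp(-c * x)
                y = mu + 0.4 * np.abs(mu) ** delta * rng.standard_normal()
                rows.append((0, i, j, k, j, x, y))
    df = pd.DataFrame(rows, columns=["tree_id", "branch_id", "whorl_id",
                                     "obs_id", "SAGE", "SDINC", "SBL"])
    res = fit_nlme(ModelSpec("M7"), RandomEffectsSpec(("b",), ()),
                   VarianceSpec(within_group="power"), df, refine=False)
    assert res.converged
    assert res.var_params["delta"] == pytest.approx(delta, abs=0.15)


def test_ar1_correlation_structure_runs(sbl_small_df, sbl_spec):
    sub = sbl_small_df[sbl_small_df["tree_id"] < 4]
    res = fit_nlme(sbl_spec, RandomEffectsSpec(("b",), ()),
                   VarianceSpec(correlation="AR1"), sub, refine=False,
                   max_outer=30)
    assert np.isfinite(res.loglik)
    assert "cor1" in res.var_params


def test_too_many_random_parameters_warns():
    with pytest.warns(UserWarning, match="four"):
        RandomEffectsSpec(("a", "b", "c"), ("a", "b"))


def test_random_effect_on_unknown_parameter_errors(sbl_small_df):
    with pytest.raises(ValueError, match="free parameter"):
        fit_nlme(ModelSpec("M7"), RandomEffectsSpec(("b1",), ()), None,
                 sbl_small_df)
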