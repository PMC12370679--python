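"""Fixed-effects NLS fitting, screening and covariate search."""

import numpy as np
import pandas as pd
import pytest

from pinecrown.growth import ModelSpec, evaluate
from pinecrown import nls
from pinecrown.nls import GrowthCurveRegressor, initial_values


def _m7_frame(rng, n, a=0.364, b=0.928, c=0.002, sd=0.0):
    x = rng.uniform(5, 500, n)
    y = a * x**b * np.exp(-c * x) + sd * rng.standard_normal(n)
    return pd.DataFrame({"SDINC": x, "SBL": y})


class TestInitialValues:
    def test_exact_on_noisefree_m7(self):
        rng = np.random.default_rng(0)
        df = _m7_frame(rng, 200)
        init = initial_values(ModelSpec("M7"), df, df["SBL"])
        assert init["a"] == pytest.approx(0.364, abs=1e-8)
        assert init["b"] == pytest.approx(0.928, abs=1e-8)
        assert init["c"] == pytest.approx(0.002, abs=1e-8)

    def test_three_point_exact_solve(self):
        # exactly identified 3x3 log-linear system
        x = np.array([10.0, 100.0, 300.0])
        a, b, c = 0.5, 0.9, 0.004
        y = a * x**b * np.exp(-c * x)
        A = np.column_stack([np.ones(3), np.log(x), -x])
        expect = np.linalg.solve(A, np.log(y))
        init = initial_values(ModelSpec("M7"),
                              pd.DataFrame({"SDINC": x}), y)
        assert init["a"] == pytest.approx(np.exp(expect[0]), rel=1e-10)
        assert init["b"] == pytest.approx(expect[1], rel=1e-10)
        assert init["c"] == pytest.approx(expect[2], rel=1e-10)

    def test_constant_design_errors(self):
        df = pd.DataFrame({"SDINC": np.full(10, 50.0)})
        with pytest.raises(ValueError, match="constant"):
            initial_values(ModelSpec("M7"), df, np.ones(10))


class TestFit:
    def test_noisefree_recovery(self):
        rng = np.random.default_rng(1)
        df = _m7_frame(rng, 300)
        res = nls.fit(ModelSpec("M7"), df, "SBL")
        assert res.converged
        assert res.estimates["a"] == pytest.approx(0.364, abs=1e-6)
        assert res.estimates["b"] == pytest.approx(0.928, abs=1e-6)
        assert res.estimates["c"] == pytest.approx(0.002, abs=1e-6)
        assert res.rss == pytest.approx(0.0, abs=1e-12)

    def test_underidentified_flagged_not_raised(self):
        df = pd.DataFrame({"SDINC": [10.0, 20.0], "SBL": [5.0, 8.0]})
        res = nls.fit(ModelSpec("M7"), df, "SBL")
        assert not res.converged
        assert "under-identified" in res.message

    def test_indices_and_loglik_identity(self, sbl_fixed_df):
        res = nls.fit(ModelSpec("M7", {"a": "PDINC"}), sbl_fixed_df, "SBL")
        assert res.converged
        assert res.rmse == pytest.approx(np.sqrt(res.rss / res.n), rel=1e-12)
        # Gaussian ML identity: -2 logLik = n log(2 pi RSS / n) + n
        assert -2 * res.loglik == pytest.approx(
            res.n * np.log(2 * np.pi * res.rss / res.n) + res.n, rel=1e-12)
        assert res.aic == pytest.approx(
            -2 * res.loglik + 2 * (len(res.estimates) + 1), rel=1e-12)
        assert res.ra2 <= 1

    def test_row_order_invariance(self, sbl_fixed_df):
        res1 = nls.fit(ModelSpec("M7"), sbl_fixed_df, "SBL")
        shuffled = sbl_fixed_df.sample(frac=1.0, random_state=3)
        res2 = nls.fit(ModelSpec("M7"), shuffled, "SBL")
        assert res1.rmse == pytest.approx(res2.rmse, rel=1e-9)
        assert res1.mae == pytest.approx(res2.mae, rel=1e-9)

    def test_parameter_recovery_with_noise(self, sbl_fixed_df):
        """Optimal-model values recovered within 2 Monte-Carlo SEs."""
        truth = {"a": 0.188, "a1": 3.0e-4, "b": 0.974, "c": 0.002}
        ests = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            df = sbl_fixed_df.copy()
            mu = evaluate(ModelSpec("M7", {"a": "PDINC"}), truth,
                          df["SDINC"], df)
            df["SBL"] = mu + 18.96 * rng.standard_normal(len(df))
            res = nls.fit(ModelSpec("M7", {"a": "PDINC"}), df, "SBL")
            assert res.converged
            ests.append([res.estimates[k] for k in ("a", "a1", "b", "c")])
        arr = np.asarray(ests)
        mean = arr.mean(axis=0)
        mcse = arr.std(axis=0, ddof=1) / np.sqrt(len(arr))
        for i, k in enumerate(("a", "a1", "b", "c")):
            assert abs(mean[i] - truth[k]) <= 2 * mcse[i] + 1e-12, k


class TestScreening:
    def test_single_candidate(self, sbl_fixed_df):
        tab = nls.screen_candidates(sbl_fixed_df, ["M7"])
        assert len(tab) == 1

    def test_empty_candidate_list(self, sbl_fixed_df):
        with pytest.raises(ValueError):
            nls.screen_candidates(sbl_fixed_df, [])

    def test_m3_truth_ranks_first(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(5, 500, 4000)
        y = 30.0 / (1 + 5.0 * np.exp(-0.02 * x)) + rng.standard_normal(4000)
        df = pd.DataFrame({"SDINC": x, "SBL": y})
        tab = nls.screen_candidates(df)
        assert tab.iloc[0]["function_id"] == "M3"

    def test_sorted_by_aic_with_nonconverged_last(self, sbl_fixed_df):
        tab = nls.screen_candidates(sbl_fixed_df)
        conv = tab[tab["converged"]]
        assert conv["aic"].is_monotonic_increasing


class TestCovariateSearch:
    def test_recovers_pdinc_on_a(self, sbl_fixed_df):
        tab = nls.covariate_search(ModelSpec("M7"), sbl_fixed_df,
                                   ["PDINC", "HT", "CW"], response="SBL")
        assert tab.iloc[0]["covariate_map"] == {"a": "PDINC"}

    def test_null_case_keeps_base_model(self):
        rng = np.random.default_rng(3)
        df = _m7_frame(rng, 1500, sd=1.0)
        df["NOISE1"] = rng.standard_normal(len(df))
        df["NOISE2"] = rng.standard_normal(len(df))
        tab = nls.covariate_search(ModelSpec("M7"), df, ["NOISE1", "NOISE2"],
                                   response="SBL")
        # pure-noise expansions are rarely significant; base model never
        # disappears from the survivor table
        assert any(m == {} for m in tab["covariate_map"])

    def test_missing_covariate_errors(self, sbl_fixed_df):
        with pytest.raises(ValueError):
            nls.covariate_search(ModelSpec("M7"), sbl_fixed_df, ["NOPE"])

    def test_ra2_increases_with_generating_covariate(self, sbl_fixed_df):
        base = nls.fit(ModelSpec("M7"), sbl_fixed_df, "SBL")
        ext = nls.fit(ModelSpec("M7", {"a": "PDINC"}), sbl_fixed_df, "SBL")
        assert ext.ra2 > base.ra2


def test_overfit_penalty_in_expectation():
    """Richer model on nested-truth data has larger AIC on average."""
    rng = np.random.default_rng(4)
    diffs = []
    for _ in range(10):
        x = rng.uniform(5, 500, 400)
        y = 0.4 * x**0.9 * np.exp(-0.002 * x) + rng.standard_normal(400)
        df = pd.DataFrame({"SDINC": x, "SBL": y,
                           "Z": rng.standard_normal(400)})
        small = nls.fit(ModelSpec("M7"), df, "SBL")
        big = nls.fit(ModelSpec("M7", {"b": "Z"}), df, "SBL")
        diffs.append(big.aic - small.aic)
    assert np.mean(diffs) > 0


def test_sklearn_estimator_interface(sbl_fixed_df):
    est = GrowthCurveRegressor(spec=ModelSpec("M7"))
    est.fit(sbl_fixed_df, sbl_fixed_df["SBL"])
    assert est.converged_
    pred = est.predict(sbl_fixed_df)
    assert pred.shape == (len(sbl_fixed_df),)
    params = est.get_params()
    assert "spec" in params and "max_iter" in params
    r2 = est.score(sbl_fixed_df, sbl_fixed_df["SBL"])
    assert 0 < r2 <= 1
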