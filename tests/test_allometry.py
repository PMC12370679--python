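"""Log-log power-law fits and percentile-bootstrap intervals."""

import numpy as np
import pandas as pd
import pytest

from pinecrown import allometry
from pinecrown.allometry import (PowerLawAllometry, bootstrap_ci, fit_loglog,
                                 scaling_profile)
from pinecrown.synth import GeneratorConfig, generate_dataset


class TestFitLogLog:
    def test_identity(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        gamma, b = fit_loglog(x, x)
        assert gamma == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(1.0, abs=1e-12)

    def test_exact_power_law(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        gamma, b = fit_loglog(x, 4.0 * x**2)
        assert b == pytest.approx(2.0, abs=1e-12)
        assert gamma == pytest.approx(np.log(4.0), abs=1e-12)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(1, 50, 20)
        y = 2.0 * x**0.8 * np.exp(rng.normal(0, 0.3, 20))
        gamma, b = fit_loglog(x, y)
        # textbook normal-equation oracle
        lx, ly = np.log(x), np.log(y)
        b0 = (np.sum((lx - lx.mean()) * (ly - ly.mean()))
              / np.sum((lx - lx.mean()) ** 2))
        g0 = ly.mean() - b0 * lx.mean()
        assert b == pytest.approx(b0, abs=1e-12)
        assert gamma == pytest.approx(g0, abs=1e-12)

    def test_unit_rescaling_moves_only_gamma(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(1, 50, 30)
        y = 3.0 * x**0.7 * np.exp(rng.normal(0, 0.2, 30))
        _, b1 = fit_loglog(x, y)
        g1, _ = fit_loglog(x, y)
        g2, b2 = fit_loglog(x * 10.0, y / 100.0)
        assert b2 == pytest.approx(b1, abs=1e-12)
        assert g2 != pytest.approx(g1, abs=1e-6)

    def test_errors(self):
        with pytest.raises(ValueError, match="nonpositive"):
            fit_loglog([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="3 pairs"):
            fit_loglog([1.0, 2.0], [1.0, 2.0])


class TestBootstrap:
    def test_degenerate_noisefree_interval(self):
        x = np.linspace(1, 20, 25)
        y = 1.7 * x**1.3
        (g_lo, g_hi), (e_lo, e_hi) = bootstrap_ci(x, y, B=200, seed=1)
        assert e_hi - e_lo < 1e-10
        assert g_hi - g_lo < 1e-10

    def test_matches_bruteforce_resampling_loop(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(1, 30, 15)
        y = 2.0 * x**0.9 * np.exp(rng.normal(0, 0.4, 15))
        B, seed = 50, 123
        got_g, got_e = bootstrap_ci(x, y, B=B, seed=seed)
        # independent loop drawing the identical index stream
        idx = np.random.default_rng(seed).integers(0, len(x), size=(B, len(x)))
        slopes, gammas = [], []
        for r in range(B):
            lx, ly = np.log(x[idx[r]]), np.log(y[idx[r]])
            bb = np.polyfit(lx, ly, 1)
            slopes.append(bb[0])
            gammas.append(bb[1])
        np.testing.assert_allclose(
            got_e, np.quantile(slopes, [0.025, 0.975]), rtol=1e-10)
        np.testing.assert_allclose(
            got_g, np.quantile(gammas, [0.025, 0.975]), rtol=1e-10)

    def test_single_replicate_collapses(self):
        x = np.array([1.0, 3.0, 7.0, 12.0])
        y = 2.0 * x**1.1 * np.array([1.1, 0.9, 1.05, 0.97])
        (_, _), (lo, hi) = bootstrap_ci(x, y, B=1, seed=4)
        assert lo == hi

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(1, 30, 20)
        y = x ** 1.2 * np.exp(rng.normal(0, 0.3, 20))
        assert bootstrap_ci(x, y, B=100, seed=5) == bootstrap_ci(
            x, y, B=100, seed=5)
        assert bootstrap_ci(x, y, B=100, seed=5) != bootstrap_ci(
            x, y, B=100, seed=6)


def test_estimator_interface():
    rng = np.random.default_rng(11)
    x = rng.uniform(1, 40, 50)
    y = 3.0 * x**0.75 * np.exp(rng.normal(0, 0.2, 50))
    est = PowerLawAllometry(B=200, seed=2).fit(x, y)
    assert est.exponent_ci_[0] <= est.exponent_ * 1.0001
    assert est.exponent_ * 0.9999 <= est.exponent_ci_[1]
    pred = est.predict([10.0])
    assert pred[0] == pytest.approx(est.amplitude_ * 10 ** est.exponent_)
    assert est.get_params()["B"] == 200


class TestScalingProfile:
    @pytest.fixture(scope="class")
    def dataset(self):
        return generate_dataset(GeneratorConfig(seed=17, n_trees=18))

    def test_homogeneous_exponent_recovered(self):
        """All groups share one generating exponent: estimates cluster at
        the truth and group CIs overlap it."""
        rng = np.random.default_rng(12)
        ds = generate_dataset(GeneratorConfig(
            seed=18, n_trees=12, branches_per_tree=6, whorls_per_branch=4,
            obs_per_whorl=1))
        # overwrite sizes with a clean power law of the parent size
        prim = ds.primaries.set_index(["tree_id", "branch_id"])
        pbl = prim.loc[pd.MultiIndex.from_frame(
            ds.secondaries[["tree_id", "branch_id"]]), "PBL"].to_numpy()
        ds.secondaries["SBL"] = (pbl / 8.0) ** (1 / 0.8) \
            * np.exp(rng.normal(0, 0.05, len(ds.secondaries)))
        fits = scaling_profile(ds, grouping="primary_age", measure="length",
                               B=400, seed=3)
        good = [f for f in fits if f.reliable]
        assert len(good) >= 3
        exps = np.array([f.exponent for f in good])
        assert np.abs(np.median(exps) - 0.8) < 0.1
        cover = [f.exponent_ci[0] <= 0.8 <= f.exponent_ci[1] for f in good]
        assert np.mean(cover) > 0.5

    def test_groupings_produce_fits(self, dataset):
        for grouping in ("primary_age", "secondary_age", "tree_age"):
            fits = scaling_profile(dataset, grouping=grouping,
                                   measure="diameter", B=50, seed=4)
            assert len(fits) >= 1
            for f in fits:
                assert f.n >= 3 and np.isfinite(f.exponent)

    def test_single_group_equals_direct_composition(self, dataset):
        fits = scaling_profile(dataset, grouping="tree_age",
                               measure="length", B=100, seed=9)
        one = [f for f in fits if f.group == "age=28"][0]
        from pinecrown.allometry import _basal_pairs

        pairs = _basal_pairs(dataset)
        sub = pairs[(pairs["age"] == 28) & (pairs["SBL"] > 0)
                    & (pairs["PBL"] > 0)]
        g, e = fit_loglog(sub["SBL"], sub["PBL"])
        assert one.exponent == pytest.approx(e, rel=1e-12)
        assert one.gamma == pytest.approx(g, rel=1e-12)

    def test_bad_inputs(self, dataset):
        with pytest.raises(ValueError):
            scaling_profile(dataset, grouping="nope")
        with pytest.raises(ValueError):
            scaling_profile(dataset, measure="girth")
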