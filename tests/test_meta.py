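"""Pooling, meta-regression and bootstrap: hand oracles, cross-implementation
checks, and estimator-identity properties."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from harvestmeta.effects import percent_difference
from harvestmeta.meta import (
    bootstrap_ci,
    estimate_stratum_effects,
    fit_meta_regression,
    pool_random_effects,
)


class TestPooling:
    def test_identical_effects_no_heterogeneity(self):
        fit = pool_random_effects([0.2, 0.2, 0.2], [0.1, 0.1, 0.1])
        assert fit.estimate == pytest.approx(0.2, abs=1e-12)
        assert fit.tau2 == pytest.approx(0.0, abs=1e-12)

    def test_dersimonian_laird_two_study_hand_formula(self):
        # w = 100 each: Q = 2, C = 200 - 20000/200 = 100, tau2 = (2-1)/100
        fit = pool_random_effects([0.2, 0.4], [0.1, 0.1], method="DL")
        assert fit.tau2 == pytest.approx(0.01, abs=1e-12)
        assert fit.estimate == pytest.approx(0.3, abs=1e-12)

    def test_dl_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            k = rng.integers(3, 25)
            y = rng.normal(0, 0.5, k)
            se = rng.uniform(0.05, 0.4, k)
            w = 1 / se**2
            ybar = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
            q = sum(wi * (yi - ybar) ** 2 for wi, yi in zip(w, y))
            c = sum(w) - sum(wi**2 for wi in w) / sum(w)
            tau2 = max(0.0, (q - (k - 1)) / c)
            fit = pool_random_effects(y, se, method="DL")
            assert fit.tau2 == pytest.approx(tau2, abs=1e-10)
            wstar = 1 / (se**2 + tau2)
            assert fit.estimate == pytest.approx(
                float(np.sum(wstar * y) / np.sum(wstar)), abs=1e-10
            )

    # fixture values computed independently with a reference REML/DL
    # meta-analysis implementation on the same inputs
    @pytest.mark.parametrize(
        "method,mu,se_mu,tau2",
        [
            ("DL", -0.471396, 0.121388, 0.061205),
            ("REML", -0.466600, 0.136945, 0.084719),
        ],
    )
    def test_matches_reference_implementation(self, method, mu, se_mu, tau2):
        y = [-0.8, -0.2, -0.5, 0.1, -0.9, -0.35]
        se = [0.15, 0.2, 0.1, 0.25, 0.18, 0.12]
        fit = pool_random_effects(y, se, method=method)
        assert fit.estimate == pytest.approx(mu, abs=2e-5)
        assert float(fit.se_coefficients.iloc[0]) == pytest.approx(se_mu, abs=2e-5)
        assert fit.tau2 == pytest.approx(tau2, abs=2e-5)

    def test_equal_se_zero_tau2_reduces_to_arithmetic_mean(self):
        y = [0.12, -0.05, 0.31, 0.02]
        fit = pool_random_effects(y, [0.2] * 4, method="DL")
        if fit.tau2 == 0.0:
            assert fit.estimate == pytest.approx(np.mean(y), abs=1e-12)
        # equal weights make the pooled mean the arithmetic mean regardless
        assert fit.estimate == pytest.approx(np.mean(y), abs=1e-12)

    def test_all_zero_se_is_degenerate_weights_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            pool_random_effects([0.1, 0.2], [0.0, 0.0])

    def test_parameter_recovery_simulation(self):
        theta, tau, k = -0.3, 0.2, 200
        rng = np.random.default_rng(12)
        est, tau2s = [], []
        for _ in range(100):
            se = rng.uniform(0.1, 0.3, k)
            y = theta + rng.normal(0, tau, k) + rng.normal(0, se)
            fit = pool_random_effects(y, se, method="DL")
            est.append(fit.estimate)
            tau2s.append(fit.tau2)
        mc_se = np.std(est) / math.sqrt(len(est))
        assert abs(np.mean(est) - theta) < 3 * mc_se
        assert abs(np.mean(tau2s) - tau**2) / tau**2 < 0.25


class TestMetaRegression:
    @staticmethod
    def sim_frame(seed=42, n_study=25, theta=(-1.0, -0.4), tau=0.25, sd=0.3):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_study):
            b = rng.normal(0, tau)
            tr = "clearcut" if rng.random() < 0.5 else "partial"
            th = theta[0] if tr == "clearcut" else theta[1]
            for _ in range(int(rng.integers(3, 7))):
                se = rng.uniform(0.1, 0.3)
                rows.append(
                    {
                        "study_id": f"S{s}",
                        "treatment": tr,
                        "biome": "boreal" if rng.random() < 0.5 else "temperate",
                        "rr": th + b + rng.normal(0, se),
                        "se_rr": se,
                    }
                )
        return pd.DataFrame(rows)

    def test_intercept_only_weighted_equals_pooling(self):
        df = self.sim_frame()
        reg = fit_meta_regression(df, fixed=(), mode="weighted", include_study=False)
        pool = pool_random_effects(df["rr"], df["se_rr"], method="REML")
        assert reg.estimate == pytest.approx(pool.estimate, abs=1e-6)
        assert reg.tau2 == pytest.approx(pool.tau2, abs=1e-6)

    def test_unweighted_matches_independent_mixed_model(self):
        import statsmodels.formula.api as smf

        df = self.sim_frame(seed=7)
        fit = fit_meta_regression(df, fixed=["treatment"], mode="unweighted")
        mlm = smf.mixedlm("rr ~ treatment", df, groups="study_id").fit(reml=True)
        assert fit.coefficients["intercept"] == pytest.approx(
            mlm.params["Intercept"], abs=1e-4
        )
        assert fit.coefficients["treatment[partial]"] == pytest.approx(
            mlm.params["treatment[T.partial]"], abs=1e-4
        )
        assert fit.se_coefficients["treatment[partial]"] == pytest.approx(
            mlm.bse["treatment[T.partial]"], rel=1e-2
        )
        assert fit.sigma2 == pytest.approx(mlm.scale, rel=1e-3)

    def test_treatment_contrast_recovery_cell_means(self):
        # truth: clearcut exp(-1.5)-1 = -78%, partial exp(-0.6)-1 = -45%
        df = self.sim_frame(seed=101, n_study=60, theta=(-1.5, -0.6), tau=0.15)
        fit = fit_meta_regression(
            df, fixed=["treatment"], mode="weighted", cell_means=True,
            include_study=False,
        )
        cc = percent_difference(fit.coefficients["treatment[clearcut]"])
        pc = percent_difference(fit.coefficients["treatment[partial]"])
        assert cc == pytest.approx(-77.7, abs=6.0)
        assert pc == pytest.approx(-45.1, abs=8.0)

    def test_rank_deficiency_names_aliased_columns(self):
        df = self.sim_frame()
        df["dup"] = df["treatment"]  # perfectly aliased moderator
        with pytest.raises(ValueError, match="rank deficient"):
            fit_meta_regression(df, fixed=["treatment", "dup"], mode="unweighted")

    def test_single_level_random_factor_dropped_with_warning(self):
        df = self.sim_frame()
        df["region"] = "east"
        with pytest.warns(UserWarning, match="single level"):
            fit = fit_meta_regression(
                df, fixed=(), random=["region"], mode="unweighted",
                include_study=False,
            )
        assert "region" not in fit.random_terms

    def test_weighted_mode_requires_se_everywhere(self):
        df = self.sim_frame()
        df.loc[0, "se_rr"] = np.nan
        with pytest.raises(ValueError, match="se_rr"):
            fit_meta_regression(df, fixed=(), mode="weighted")


class TestBootstrap:
    @staticmethod
    def frame(seed=0, n_study=30):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_study):
            b = rng.normal(0, 0.2)
            for _ in range(3):
                rows.append({"study_id": f"S{s}", "rr": -0.3 + b + rng.normal(0, 0.2)})
        return pd.DataFrame(rows)

    def test_same_seed_identical_result(self):
        df = self.frame()
        stat = lambda d: d["rr"].mean()
        b1 = bootstrap_ci(stat, df, n_boot=300, seed=5)
        b2 = bootstrap_ci(stat, df, n_boot=300, seed=5)
        assert b1 == b2
        b3 = bootstrap_ci(stat, df, n_boot=300, seed=6)
        assert (b3.lower, b3.upper) != (b1.lower, b1.upper)

    def test_degenerate_data_zero_width(self):
        df = pd.DataFrame({"study_id": ["a", "b", "c"], "rr": [0.4, 0.4, 0.4]})
        b = bootstrap_ci(lambda d: d["rr"].mean(), df, n_boot=200, seed=1)
        assert b.lower == b.upper == b.point == pytest.approx(0.4)

    def test_observation_unit_resamples_rows(self):
        df = self.frame(n_study=5)
        b = bootstrap_ci(
            lambda d: d["rr"].mean(), df, n_boot=300, seed=2, unit="observation"
        )
        assert b.lower < b.point < b.upper

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_ci(lambda d: 0.0, self.frame(), n_boot=50)

    def test_failing_replicates_counted_and_warned(self):
        df = self.frame(n_study=8)
        calls = {"n": 0}

        def flaky(d):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("no fit")
            return d["rr"].mean()

        with pytest.warns(UserWarning, match="replicates failed"):
            b = bootstrap_ci(flaky, df, n_boot=300, seed=3)
        assert b.n_failed > 0

    def test_all_failures_is_error(self):
        df = self.frame()

        def fails_on_resamples(d):
            # full data passes (point estimate), every resample raises
            if d.index.has_duplicates or len(d) != len(df):
                raise RuntimeError("no fit")
            return d["rr"].mean()

        with pytest.raises(RuntimeError, match="all bootstrap"):
            bootstrap_ci(fails_on_resamples, df, n_boot=200, seed=4)


class TestStratumEffects:
    def test_back_transform_after_pooling_not_before(self):
        # skewed effects: pooling percent differences first is a different,
        # larger estimator (Jensen); the table must back-transform the pooled
        # log-scale mean
        rng = np.random.default_rng(9)
        rr = rng.normal(0.0, 0.8, 120)
        df = pd.DataFrame(
            {
                "study_id": [f"S{i % 20}" for i in range(120)],
                "pool": "understory",
                "treatment": "clearcut",
                "biome": "boreal",
                "rr": rr,
                "se_rr": 0.2,
            }
        )
        table = estimate_stratum_effects(df, mode="unweighted", n_boot=300, seed=0)
        correct = percent_difference(rr.mean())
        wrong = np.mean([(math.exp(v) - 1) * 100 for v in rr])
        est = table["percent_diff"].iloc[0]
        assert est == pytest.approx(correct, abs=1e-6)
        assert abs(est - wrong) > 5.0

    def test_insufficient_strata_flagged_not_fitted(self):
        df = pd.DataFrame(
            {
                "study_id": ["a", "b"],
                "pool": ["snags", "snags"],
                "treatment": ["clearcut", "clearcut"],
                "biome": ["boreal", "boreal"],
                "rr": [0.1, 0.2],
                "se_rr": [0.1, 0.1],
            }
        )
        table = estimate_stratum_effects(df, min_k=3, n_boot=300)
        assert bool(table["insufficient"].iloc[0])
        assert np.isnan(table["percent_diff"].iloc[0])

    def test_weighted_and_unweighted_agree_on_clean_data(self):
        df = TestMetaRegression.sim_frame(seed=33, n_study=40, theta=(-0.7, -0.7), tau=0.05)
        df["pool"] = "live_trees"
        df["biome"] = "boreal"
        w = estimate_stratum_effects(df, mode="weighted")
        u = estimate_stratum_effects(df, mode="unweighted", n_boot=400, seed=1)
        for tr in ("clearcut", "partial"):
            a = w.loc[w.treatment == tr, "percent_diff"].iloc[0]
            b = u.loc[u.treatment == tr, "percent_diff"].iloc[0]
            assert a == pytest.approx(b, abs=5.0)

    def test_null_stratum_ci_includes_zero(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame(
            {
                "study_id": [f"S{i % 25}" for i in range(100)],
                "pool": "mineral_soil",
                "treatment": "clearcut",
                "biome": "boreal",
                "rr": rng.normal(0, 0.25, 100),
                "se_rr": 0.2,
            }
        )
        table = estimate_stratum_effects(df, mode="unweighted", n_boot=500, seed=2)
        assert not bool(table["significant"].iloc[0])
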