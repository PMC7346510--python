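from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import hypergeom

from stopover import synthetic
from stopover.inference import (
    StudyConfig,
    attach_weather,
    fisher_exact_2x2,
    fit_beta_regression,
    fit_linear_model,
    mann_whitney,
    run_study,
)


class TestBetaRegression:
    def _simulate(self, n, beta, phi, seed):
        rng = np.random.default_rng(seed)
        robin = rng.integers(0, 2, n).astype(float)
        z = rng.normal(0, 1, n)
        x = pd.DataFrame({"intercept": 1.0, "robin": robin, "z": z})
        mu = 1 / (1 + np.exp(-(x.to_numpy() @ beta)))
        y = np.clip(rng.beta(mu * phi, (1 - mu) * phi), 1e-9, 1 - 1e-9)
        return y, x

    def test_parameter_recovery_within_2se(self):
        beta = np.array([-1.20, 1.15, -0.45])
        y, x = self._simulate(500, beta, 15.0, seed=3)
        fit = fit_beta_regression(y, x)
        for est, se, truth in zip(fit.params, fit.se, beta):
            assert abs(est - truth) <= 2 * se
        assert fit.phi > 0 and 0 <= fit.pseudo_r2 <= 1

    def test_matches_statsmodels(self):
        from statsmodels.othermod.betareg import BetaModel

        y, x = self._simulate(200, np.array([-0.5, 0.8, -0.3]), 10.0, seed=7)
        fit = fit_beta_regression(y, x)
        sm_fit = BetaModel(y, x).fit(disp=0)
        sm_params = np.asarray(sm_fit.params)
        np.testing.assert_allclose(fit.params, sm_params[:3], atol=1e-4)
        np.testing.assert_allclose(fit.se, np.asarray(sm_fit.bse)[:3], rtol=1e-2)
        assert fit.phi == pytest.approx(np.exp(sm_params[3]), rel=1e-3)

    def test_intercept_only_symmetric(self):
        rng = np.random.default_rng(0)
        y = np.concatenate([rng.uniform(0.3, 0.5, 50), 1 - rng.uniform(0.3, 0.5, 50)])
        fit = fit_beta_regression(y, pd.DataFrame({"intercept": np.ones(100)}))
        assert fit.params[0] == pytest.approx(0.0, abs=0.1)

    def test_boundary_values_rejected(self):
        with pytest.raises(ValueError, match="strictly inside"):
            fit_beta_regression(
                np.array([0.0, 0.5, 0.7]), pd.DataFrame({"intercept": np.ones(3)})
            )

    def test_optimum_beats_generating_parameters(self):
        """The ML optimum's log-likelihood should not fall below the
        generating parameters' on the vast majority of datasets."""
        from stopover.inference import _beta_negloglik_grad

        beta = np.array([-1.0, 0.9, -0.4])
        wins = 0
        for seed in range(20):
            y, x = self._simulate(120, beta, 12.0, seed=seed)
            fit = fit_beta_regression(y, x)
            nll_true, _ = _beta_negloglik_grad(
                np.concatenate([beta, [np.log(12.0)]]), x.to_numpy(), y
            )
            wins += fit.loglik >= -nll_true - 1e-6
        assert wins >= 19


class TestLinearModel:
    def test_exact_fit(self):
        x = pd.DataFrame({"intercept": 1.0, "x": np.arange(10.0)})
        y = 2.0 + 3.0 * np.arange(10.0)
        fit = fit_linear_model(y, x)
        assert fit.r2 == pytest.approx(1.0)
        np.testing.assert_allclose(fit.params, [2.0, 3.0], atol=1e-10)

    def test_log10_transform(self):
        x = pd.DataFrame({"intercept": np.ones(5), "x": np.arange(5.0)})
        y = 10 ** (1.0 + 0.5 * np.arange(5.0))
        fit = fit_linear_model(y, x, transform="log10")
        np.testing.assert_allclose(fit.params, [1.0, 0.5], atol=1e-10)
        with pytest.raises(ValueError):
            fit_linear_model(-y, x, transform="log10")

    def test_singular_design_rejected(self):
        x = pd.DataFrame({"a": np.ones(6), "b": np.ones(6)})
        with pytest.raises(ValueError, match="singular"):
            fit_linear_model(np.arange(6.0), x)

    def test_null_f_rejection_rate(self):
        """Under a zero slope the F test rejects at ~5% (1,000 repeats)."""
        rng = np.random.default_rng(21)
        rej = 0
        reps = 1000
        for _ in range(reps):
            xv = rng.normal(0, 1, 25)
            y = rng.normal(0, 1, 25)
            fit = fit_linear_model(y, pd.DataFrame({"intercept": np.ones(25), "x": xv}))
            rej += fit.f_p < 0.05
        assert 0.03 <= rej / reps <= 0.07


class TestMannWhitney:
    def test_complete_separation(self):
        assert mann_whitney([1, 2, 3], [4, 5, 6])["W"] == 0.0
        assert mann_whitney([4, 5, 6], [1, 2, 3])["W"] == 9.0

    @given(
        a=st.lists(st.integers(0, 30), min_size=1, max_size=8),
        b=st.lists(st.integers(0, 30), min_size=1, max_size=8),
    )
    def test_w_matches_bruteforce_pair_count(self, a, b):
        w = mann_whitney(a, b)["W"]
        brute = sum(
            1.0 if ai > bj else (0.5 if ai == bj else 0.0) for ai in a for bj in b
        )
        assert w == pytest.approx(brute)

    def test_exact_p_matches_enumeration(self):
        """Exact two-sided p equals brute-force enumeration over all
        rank assignments for small untied samples."""
        a, b = [1.2, 3.4, 5.1], [2.2, 4.0, 6.3, 7.7]
        res = mann_whitney(a, b)
        pooled = sorted(a + b)
        n_a = len(a)
        w_obs = res["W"]
        ws = []
        for idx in combinations(range(len(pooled)), n_a):
            aa = [pooled[i] for i in idx]
            bb = [pooled[i] for i in range(len(pooled)) if i not in idx]
            ws.append(sum(1.0 for x in aa for yv in bb if x > yv))
        ws = np.array(ws)
        mean_w = n_a * (len(b)) / 2
        p_brute = np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-9)
        assert res["p"] == pytest.approx(p_brute, abs=1e-9)


class TestFisher:
    def test_paper_style_table(self):
        # 6/14 vs 7/21 departures -> non-significant
        assert fisher_exact_2x2([[6, 8], [7, 14]]) == pytest.approx(0.72, abs=0.01)

    @given(
        a=st.integers(0, 8), b=st.integers(0, 8),
        c=st.integers(0, 8), d=st.integers(0, 8),
    )
    def test_matches_hypergeometric_enumeration(self, a, b, c, d):
        p = fisher_exact_2x2([[a, b], [c, d]])
        row1, col1, n = a + b, a + c, a + b + c + d
        if n == 0:
            assert p == pytest.approx(1.0)
            return
        lo, hi = max(0, row1 + col1 - n), min(row1, col1)
        probs = {k: hypergeom.pmf(k, n, row1, col1) for k in range(lo, hi + 1)}
        p_obs = probs[a]
        brute = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-7))
        assert p == pytest.approx(brute, abs=1e-9)


class TestWeather:
    def _weather(self):
        ts = pd.date_range("2018-09-02", "2018-09-04", freq="h", tz="UTC")
        return pd.DataFrame(
            {
                "ts": ts,
                "wind_speed": 7.5,
                "wind_dir": 70.0,
                "precip": 0.0,
                "temp": 19.0,
            }
        )

    def test_sunset_hour_matched(self):
        from datetime import date

        out = attach_weather([date(2018, 9, 2)], self._weather(), 54.183, 7.883)
        row = out.iloc[0]
        assert not row["missing"]
        assert row["wind_speed"] == 7.5 and row["wind_dir"] == 70.0
        assert row["wind_toward"] == 250.0
        # nearest full hour to the 18:17 UTC sunset
        assert row["sunset"].hour == 18

    def test_missing_day_flagged(self):
        from datetime import date

        out = attach_weather([date(2018, 12, 25)], self._weather(), 54.183, 7.883)
        assert bool(out.iloc[0]["missing"])


class TestRunStudy:
    def test_synthetic_cohort_report(self, cohort):
        birds, truth = cohort
        rep = run_study(birds, StudyConfig(randomization_reps=500))
        assert rep["n"] == {"CR": 14, "ER": 21}
        # restriction rule: stores models use first-night birds only
        n_first = int((truth["days_on_island"] == 1).sum())
        if "beta_first_night" in rep:
            assert rep["beta_first_night"]["n"] == n_first
        assert rep["departure_fraction"]["table"][0][0] + rep["departure_fraction"][
            "table"
        ][0][1] == 14
        assert 0 <= rep["departure_fraction"]["fisher_p"] <= 1
        for entry in rep["directions"].values():
            if isinstance(entry, dict) and "rayleigh_p" in entry:
                assert 0 <= entry["rho"] <= 1

    def test_parameter_recovery_through_pipeline(self):
        """Beta-regression coefficients recovered from full synthetic
        cohorts (n = 500 each): the mean estimate over five replicate
        cohorts lies within 3 pooled SEs of the generating values."""
        beh = synthetic.SimConfig().behaviour
        targets = {
            "intercept": beh.beta_intercept,
            "species_robin": beh.beta_species,
            "stores_scaled": beh.beta_stores,
        }
        ests = {k: [] for k in targets}
        ses = {k: [] for k in targets}
        seeds = range(5)
        for seed in seeds:
            cfg = synthetic.SimConfig(
                n_birds_per_species={"CR": 250, "ER": 250}, seed=seed
            )
            birds, _ = synthetic.simulate_cohort(cfg)
            rep = run_study(birds, StudyConfig(randomization_reps=200))
            coefs = rep["beta_first_night"]["coefficients"]
            for name in targets:
                ests[name].append(coefs[name]["estimate"])
                ses[name].append(coefs[name]["se"])
        for name, truth_val in targets.items():
            mean_est = np.mean(ests[name])
            pooled_se = np.mean(ses[name]) / np.sqrt(len(list(seeds)))
            assert abs(mean_est - truth_val) <= 3 * pooled_se, name

    def test_all_birds_undetected_yields_exclusions(self):
        birds = pd.DataFrame(
            {
                "Time": ["09:00"] * 6,
                "Species": ["CR"] * 3 + ["ER"] * 3,
                "Muscle": [2] * 6,
                "Wing": [78.0, 79.0, 80.0, 72.0, 73.0, 74.0],
                "Bodymass": [14.0, 14.5, 15.0, 15.0, 15.5, 16.0],
                "take.off": [None] * 6,
                "dep.dir": [np.nan] * 6,
                "days.on.island": [np.nan] * 6,
                "dep.min.sunset": [np.nan] * 6,
                "dep.realtive.night": [np.nan] * 6,
                "wind.speed": [np.nan] * 6,
                "wind.dir": [np.nan] * 6,
            }
        )
        rep = run_study(birds)
        assert rep["exclusions"]  # everything model-like skipped
        assert "beta_first_night" not in rep
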