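"""Weighted Cox fitting: likelihood optimum, variance, baseline, risks."""

import numpy as np
import pandas as pd
import pytest

import ccsurv as cc
from ccsurv.coxfit import (CoxFit, SeparationError, delta_aic, hazard_ratios,
                           model_aic, predict_risk, z_transform)
from conftest import single_marker_config, toy_cohort


class TestZTransform:
    def test_closed_forms(self):
        assert z_transform([10.0], 10.0, 5.0)[0] == 0.0
        assert z_transform([15.0], 10.0, 5.0)[0] == 1.0
        np.testing.assert_allclose(
            z_transform([5.0, 10.0, 15.0], 10.0, 5.0), [-1.0, 0.0, 1.0])

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            z_transform([1.0], 0.0, 0.0)


def brute_force_partial_likelihood(beta, times, statuses, x):
    """Breslow log partial likelihood by direct enumeration of risk sets."""
    ll = 0.0
    for i in range(len(times)):
        if statuses[i] == 1:
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestFit:
    def test_four_subject_toy_matches_grid_search(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        statuses = np.array([1, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        grid = np.linspace(-5, 5, 10_001)
        for _ in range(4):  # refine to ~1e-12 around the grid optimum
            ll = [brute_force_partial_likelihood(b, times, statuses, x) for b in grid]
            b0 = grid[int(np.argmax(ll))]
            width = grid[1] - grid[0]
            grid = np.linspace(b0 - width, b0 + width, 2001)
        cen = cc.as_census(toy_cohort(times, statuses, x), "e")
        fit = cc.fit_weighted_cox(cen, cc.ModelSpec("m", "e", (cc.Term("x"),)))
        assert fit.beta[0] == pytest.approx(b0, abs=1e-6)

    def test_monotone_likelihood_guard(self):
        # an overwhelming risk-set weight on the never-event group keeps
        # the score from vanishing, so the coefficient marches off to +inf
        # and must trip the monotone-likelihood guard
        cen = cc.as_census(toy_cohort([1.0, 2.0, 3.0], [1, 1, 0],
                                      [1.0, 1.0, 0.0]), "e")
        cen.rows.loc[cen.rows["uid"] == 3, "weight"] = 1e30
        with pytest.raises(SeparationError, match="monotone"):
            cc.fit_weighted_cox(cen, cc.ModelSpec("m", "e", (cc.Term("x"),)))

    def test_constant_covariate_rejected(self):
        cen = cc.as_census(toy_cohort([1, 2, 3, 4], [1, 1, 0, 1], [1, 1, 1, 1]), "e")
        with pytest.raises(ValueError, match="constant"):
            cc.fit_weighted_cox(cen, cc.ModelSpec("m", "e", (cc.Term("x"),)))

    def test_scale_equivariance(self, small_cohort):
        cen = cc.as_census(small_cohort, "diabetes")
        spec_raw = cc.ModelSpec("m", "diabetes", (cc.Term("crp"),))
        fit_raw = cc.fit_weighted_cox(cen, spec_raw)
        scaled = small_cohort.copy()
        scaled["crp"] = scaled["crp"] * 10.0
        fit_scaled = cc.fit_weighted_cox(cc.as_census(scaled, "diabetes"), spec_raw)
        assert fit_scaled.beta[0] == pytest.approx(fit_raw.beta[0] / 10.0, rel=1e-6)
        # z-transformed coefficient is scale-free
        spec_z = cc.ModelSpec("m", "diabetes", (cc.Term("crp", zscore=True),))
        fit_z = cc.fit_weighted_cox(cen, spec_z)
        fit_z2 = cc.fit_weighted_cox(cc.as_census(scaled, "diabetes"), spec_z)
        assert fit_z2.beta[0] == pytest.approx(fit_z.beta[0], rel=1e-6)

    def test_null_covariate_ci_coverage(self):
        hits, reps = 0, 100
        for seed in range(reps):
            coh = cc.simulate_cohort(single_marker_config(1_500, seed=1000 + seed))
            cen = cc.as_census(coh, "e")
            fit = cc.fit_weighted_cox(
                cen, cc.ModelSpec("m", "e",
                                  (cc.Term("age"), cc.Term("bm", zscore=True))))
            hr = hazard_ratios(fit)
            row = hr[hr["term"] == "bm"].iloc[0]
            hits += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert hits / reps >= 0.93


class TestHazardRatios:
    def test_closed_form_ci(self):
        fit = CoxFit(spec=None, beta=np.array([np.log(2)]),
                     robust_cov=np.array([[0.01]]), loglik_w=-1.0, k=1,
                     names=["x"], scaling={}, baseline_times=np.array([1.0]),
                     baseline_cumhaz=np.array([0.1]), n_events=1, n_at_risk=2)
        hr = hazard_ratios(fit)
        zc = 1.959963984540054
        assert hr["hr"].iloc[0] == pytest.approx(2.0)
        assert hr["ci_low"].iloc[0] == pytest.approx(np.exp(np.log(2) - zc * 0.1))
        assert hr["ci_high"].iloc[0] == pytest.approx(np.exp(np.log(2) + zc * 0.1))

    def test_protective_marker_recovery(self):
        from ccsurv.simulate import BiomarkerSpec, EndpointSpec, SimulationConfig
        beta = np.log(0.33)
        # moderately skewed marker (log-SD 0.5): the subcohort sample SD
        # used for standardization is then stable enough for a single draw
        cfg = SimulationConfig(
            n_subjects=20_000,
            biomarkers=(BiomarkerSpec("bm", 0.0, 0.5),),
            biomarker_corr=np.eye(1),
            endpoints=(EndpointSpec("e", 1.3, 40.0, log_hr={"bm": beta},
                                    target_incidence=0.10),),
            frailty_sd=0.0, seed=21)
        coh = cc.simulate_cohort(cfg)
        s = cc.draw_subcohort(coh, cc.SamplingDesign(fractions=0.1, seed=22), "e")
        fit = cc.fit_weighted_cox(
            s, cc.ModelSpec("m", "e", (cc.Term("bm", zscore=True),)))
        hr = np.exp(fit.beta[0])
        assert 0.28 < hr < 0.39


class TestBaselineAndRisk:
    def test_null_model_equals_nelson_aalen(self):
        # beta = 0, weights 1, no censoring: jumps d_k / Y_k exactly
        from ccsurv.coxfit import _design_weighted_breslow
        times = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        cen = cc.as_census(toy_cohort(times, np.ones(5, dtype=int),
                                      np.zeros(5)), "e")
        data = cen.data.set_index("uid")
        _, cumhaz = _design_weighted_breslow(cen, np.zeros((5, 1)), data.index,
                                             np.zeros(1))
        na = np.cumsum(1.0 / np.arange(5, 0, -1))
        np.testing.assert_allclose(cumhaz, na, rtol=1e-12)

    def test_single_event_jump(self):
        # one event at t=1 among 4 at risk, beta = 0: jump 1/4
        from ccsurv.coxfit import _design_weighted_breslow
        cen = cc.as_census(toy_cohort([1.0, 2.0, 3.0, 4.0], [1, 0, 0, 0],
                                      [1.0, 0.0, 1.0, 0.0]), "e")
        data = cen.data.set_index("uid")
        _, cumhaz = _design_weighted_breslow(cen, np.zeros((4, 1)), data.index,
                                             np.zeros(1))
        assert cumhaz[0] == pytest.approx(0.25, abs=1e-12)

    def test_breslow_recovers_weibull_truth(self):
        cfg = single_marker_config(40_000, seed=23, log_hr=np.log(1.4))
        coh = cc.simulate_cohort(cfg)
        cen = cc.as_census(coh, "e")
        fit = cc.fit_weighted_cox(
            cen, cc.ModelSpec("m", "e", (cc.Term("bm", zscore=True),)))
        # truth: cumulative hazard of the calibrated Weibull at the mean
        # covariate profile; recover the calibrated scale from incidence
        from ccsurv.simulate import _calibrate_scale, _linear_predictor
        ep = cfg.endpoints[0]
        lp = _linear_predictor(coh, cfg, ep)
        scale = _calibrate_scale(ep, lp)
        h0_true = (10.0 / scale) ** ep.shape
        assert fit.baseline_at(10.0) == pytest.approx(h0_true, rel=0.05)

    def test_predict_risk_closed_form(self):
        spec = cc.ModelSpec("m", "e", (cc.Term("x"),))
        fit = CoxFit(spec=spec, beta=np.array([np.log(2)]),
                     robust_cov=np.eye(1), loglik_w=-1.0, k=1, names=["x"],
                     scaling={"x": ("continuous", 0.0, 1.0)},
                     baseline_times=np.array([5.0]),
                     baseline_cumhaz=np.array([0.1]), n_events=1, n_at_risk=2)
        # baseline subject: 1 - exp(-H0)
        p0 = predict_risk(fit, pd.DataFrame({"x": [0.0]}), 10.0)
        assert p0[0] == pytest.approx(1 - np.exp(-0.1))
        # x'beta = log 2: 1 - exp(-0.2)
        p1 = predict_risk(fit, pd.DataFrame({"x": [1.0]}), 10.0)
        assert p1[0] == pytest.approx(1 - np.exp(-0.2))

    def test_missing_covariate_errors(self):
        spec = cc.ModelSpec("m", "e", (cc.Term("x"),))
        fit = CoxFit(spec=spec, beta=np.array([0.0]), robust_cov=np.eye(1),
                     loglik_w=0.0, k=1, names=["x"],
                     scaling={"x": ("continuous", 0.0, 1.0)},
                     baseline_times=np.array([1.0]),
                     baseline_cumhaz=np.array([0.1]), n_events=1, n_at_risk=2)
        with pytest.raises(KeyError, match="x"):
            predict_risk(fit, pd.DataFrame({"y": [1.0]}), 10.0)

    def test_mean_risk_matches_weighted_km_incidence(self, small_cohort):
        # calibration-in-the-large on the case-cohort sample
        s = cc.draw_subcohort(small_cohort, cc.SamplingDesign(0.2, seed=31),
                              "diabetes")
        models = cc.build_models("diabetes", ["crp", "adiponectin"])
        fit = cc.fit_weighted_cox(s, models["model_c"])
        pr = predict_risk(fit, s.data, 10.0)
        sub = s.data["in_subcohort"] == 1
        w = s.data["weight_design"].to_numpy()
        jumps, surv = cc.weighted_km(s.data.loc[sub, "time"],
                                     s.data.loc[sub, "status"], w[sub])
        km_inc = 1 - surv[np.searchsorted(jumps, 10.0, side="right") - 1]
        assert np.average(pr[sub], weights=w[sub]) == pytest.approx(km_inc, abs=0.015)


class TestAic:
    def test_identity_and_bookkeeping(self, diabetes_sample):
        spec = cc.ModelSpec("m", "diabetes",
                            (cc.Term("age"), cc.Term("crp", zscore=True)))
        fit = cc.fit_weighted_cox(diabetes_sample, spec)
        assert fit.k == 2
        assert model_aic(fit) == pytest.approx(-2 * fit.loglik_w + 2 * fit.k)
        d = delta_aic(fit, fit)
        assert d.value == 0.0 and not d.essential

    def test_mismatched_samples_rejected(self, small_cohort, diabetes_sample):
        spec = cc.ModelSpec("m", "diabetes", (cc.Term("age"),))
        fit1 = cc.fit_weighted_cox(diabetes_sample, spec)
        other = cc.draw_subcohort(small_cohort, cc.SamplingDesign(0.3, seed=4),
                                  "diabetes")
        fit2 = cc.fit_weighted_cox(other, spec)
        with pytest.raises(ValueError, match="same sample"):
            delta_aic(fit1, fit2)

    def test_strong_covariate_gives_essential_delta(self):
        coh = cc.simulate_cohort(single_marker_config(8_000, seed=41,
                                                      log_hr=0.5))
        cen = cc.as_census(coh, "e")
        base = cc.ModelSpec("base", "e", (cc.Term("age"),))
        full = cc.ModelSpec("full", "e",
                            (cc.Term("age"), cc.Term("bm", zscore=True)))
        d = delta_aic(cc.fit_weighted_cox(cen, full), cc.fit_weighted_cox(cen, base))
        assert d.value > 10 and d.essential

    def test_noise_covariate_delta_distribution(self):
        # delta AIC for one pure-noise covariate: -2 + chi2_1 draw
        deltas = []
        for seed in range(100):
            coh = cc.simulate_cohort(single_marker_config(1_000, seed=500 + seed))
            cen = cc.as_census(coh, "e")
            base = cc.ModelSpec("base", "e", (cc.Term("age"),))
            full = cc.ModelSpec("full", "e",
                                (cc.Term("age"), cc.Term("bm", zscore=True)))
            deltas.append(delta_aic(cc.fit_weighted_cox(cen, full),
                                    cc.fit_weighted_cox(cen, base)).value)
        deltas = np.asarray(deltas)
        assert deltas.min() > -2.001
        # median of -2 + chi2_1 is about -1.545
        assert np.median(deltas) == pytest.approx(-1.545, abs=0.45)
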