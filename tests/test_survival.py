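"""Survival models: product-limit and log-rank oracles, Cox grid-search
equivalence, log-logistic survivor/hazard identities, parametric MLE
recovery and model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize

import erlurbi as e
from erlurbi.params import FINAL_OS_PARAMS, LogLogisticOSParams

from conftest import toy_surv_df


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def product_limit_oracle(times, events):
    """Hand-rolled Kaplan-Meier product-limit estimate."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    uniq = np.unique(times[events])
    s, out = 1.0, {}
    for t in uniq:
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & events)
        s *= 1 - d / at_risk
        out[t] = s
    return out


def two_group_logrank_oracle(t1, e1, t2, e2):
    """O-E log-rank chi-square from the 2x2 table at each event time."""
    t = np.concatenate([t1, t2])
    ev = np.concatenate([e1, e2]).astype(bool)
    grp = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    O_minus_E, V = 0.0, 0.0
    for tt in np.unique(t[ev]):
        at_risk = t >= tt
        n = at_risk.sum()
        n1 = (at_risk & (grp == 0)).sum()
        d = (ev & (t == tt)).sum()
        d1 = (ev & (t == tt) & (grp == 0)).sum()
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O_minus_E**2 / V


def cox_partial_loglik(beta, times, events, x):
    """Breslow partial log-likelihood for one binary covariate, no ties."""
    ll = 0.0
    for i in np.where(events)[0]:
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_all_events_product_limit_by_hand(self):
        km = e.km_estimate([1.0, 2.0, 3.0], [True, True, True])
        np.testing.assert_allclose(km.at([1.0, 2.0, 3.0]), [2 / 3, 1 / 3, 0.0])
        assert km.median == 2.0

    def test_single_censored_record_median_not_reached(self):
        km = e.km_estimate([5.0], [False])
        assert km.at(5.0) == 1.0
        assert np.isinf(km.median)

    def test_matches_oracle_on_random_small_datasets(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(3, 12)
            t = rng.integers(1, 8, n).astype(float)
            ev = rng.uniform(size=n) < 0.7
            if not ev.any():
                continue
            km = e.km_estimate(t, ev)
            for tt, s in product_limit_oracle(t, ev).items():
                assert km.at(tt) == pytest.approx(s, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            e.km_estimate([], [])
        with pytest.raises(ValueError):
            e.km_estimate([-1.0], [True])


class TestLogrank:
    def test_identical_groups_null_identity(self):
        t = np.arange(1.0, 21.0)
        ev = np.ones(20, bool)
        chi2, df, p = e.logrank_test([(t, ev), (t, ev)])
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_matches_hand_contingency_on_toy(self):
        t1, e1 = np.array([1.0, 4.0, 6.0]), np.array([1, 1, 0])
        t2, e2 = np.array([2.0, 3.0, 5.0]), np.array([1, 0, 1])
        chi2, df, _ = e.logrank_test([(t1, e1), (t2, e2)])
        assert chi2 == pytest.approx(two_group_logrank_oracle(t1, e1, t2, e2), rel=1e-6)

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 5000
        for _ in range(n_rep):
            t1 = rng.exponential(10.0, 25)
            t2 = rng.exponential(10.0, 25)
            ev = np.ones(25, bool)
            _, _, p = e.logrank_test([(t1, ev), (t2, ev)])
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.01)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            e.logrank_test([(np.array([1.0]), np.array([1])), (np.array([]), np.array([]))])


class TestCox:
    def test_five_subject_grid_search_oracle(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ev = np.array([1, 1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 0.0])
        df = toy_surv_df(t, ev, x=x)
        fit = e.cox_fit(df, ["x"])
        grid = np.linspace(-3, 3, 60001)
        lls = [cox_partial_loglik(b, t, ev, x) for b in grid]
        assert fit.estimates["x"] == pytest.approx(grid[np.argmax(lls)], abs=1e-4)

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(1)
        n = 2000
        df = toy_surv_df(rng.exponential(10, n), np.ones(n), x=rng.standard_normal(n))
        fit = e.cox_fit(df, ["x"])
        assert 0.9 < np.exp(fit.estimates["x"]) < 1.1

    def test_determinism_and_errors(self):
        rng = np.random.default_rng(2)
        df = toy_surv_df(rng.exponential(5, 100), np.ones(100), x=rng.standard_normal(100))
        a = e.cox_fit(df, ["x"]).estimates["x"]
        b = e.cox_fit(df, ["x"]).estimates["x"]
        assert a == b
        with pytest.raises(ValueError):
            e.cox_fit(toy_surv_df([1, 2], [0, 0], x=[0.0, 1.0]), ["x"])
        with pytest.raises(ValueError):
            e.cox_fit(toy_surv_df([1, 2], [1, 1], x=[1.0, 1.0]), ["x"])


# ---------------------------------------------------------------------------
# log-logistic model functions
# ---------------------------------------------------------------------------


class TestLogLogisticFunctions:
    def test_scale_is_the_median_and_boundaries(self):
        p = LogLogisticOSParams(p=2.4, lam=294.2)
        assert e.loglogistic_survival(294.2, p) == pytest.approx(0.5)
        assert e.loglogistic_survival(0.0, p) == 1.0
        assert e.loglogistic_survival(1e9, p) < 1e-6

    def test_survivor_equals_integrated_hazard(self):
        """S(t|x) == exp(-int_0^t h) for random times and covariates."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = {
                "ctfi_ge90": float(rng.integers(0, 2)),
                "log_ldh": rng.normal(0, 0.5),
                "nl_ratio": rng.normal(0, 2),
                "brain_mets": float(rng.integers(0, 2)),
                "auc_u": rng.uniform(0, 2),
                "auc_dox": rng.uniform(0, 2),
            }
            x["auc_u_x_auc_dox"] = x["auc_u"] * x["auc_dox"]
            t = rng.uniform(10, 1500)
            H, _ = integrate.quad(
                lambda u: e.loglogistic_hazard(u, FINAL_OS_PARAMS, x), 1e-12, t, limit=200
            )
            assert e.loglogistic_survival(t, FINAL_OS_PARAMS, x) == pytest.approx(
                np.exp(-H), abs=1e-6
            )

    def test_hazard_unimodal_at_shape_2p4(self):
        t = np.geomspace(1, 5000, 2000)
        h = e.loglogistic_hazard(t, LogLogisticOSParams(p=2.4, lam=294.2))
        peak = np.argmax(h)
        assert 0 < peak < len(t) - 1
        assert np.all(np.diff(h[: peak + 1]) >= 0) and np.all(np.diff(h[peak:]) <= 0)

    def test_hazard_monotone_decreasing_at_shape_1(self):
        t = np.geomspace(0.5, 5000, 500)
        h = e.loglogistic_hazard(t, LogLogisticOSParams(p=1.0, lam=294.2))
        assert np.all(np.diff(h) < 0)
        assert h[0] == pytest.approx(1 / 294.2 / (1 + 0.5 / 294.2), rel=1e-6)

    def test_hazard_matches_numeric_log_survivor_slope(self):
        prm = LogLogisticOSParams(p=2.4, lam=294.2)
        for t in (30.0, 150.0, 600.0):
            dt = 1e-4
            num = -(
                np.log(e.loglogistic_survival(t + dt, prm))
                - np.log(e.loglogistic_survival(t - dt, prm))
            ) / (2 * dt)
            assert e.loglogistic_hazard(t, prm) == pytest.approx(num, abs=1e-4)

    def test_density_equals_hazard_times_survivor(self):
        prm = FINAL_OS_PARAMS
        rng = np.random.default_rng(4)
        t = rng.uniform(1, 2000, 100)
        h = e.loglogistic_hazard(t, prm)
        s = e.loglogistic_survival(t, prm)
        dt = 1e-3
        f_num = -(e.loglogistic_survival(t + dt, prm) - e.loglogistic_survival(t - dt, prm)) / (2 * dt)
        np.testing.assert_allclose(f_num, h * s, atol=1e-6)

    def test_domain_errors(self):
        prm = LogLogisticOSParams(p=2.0, lam=100.0)
        with pytest.raises(ValueError):
            e.loglogistic_survival(-1.0, prm)
        with pytest.raises(ValueError):
            e.loglogistic_hazard(0.0, prm)


# ---------------------------------------------------------------------------
# parametric maximum likelihood
# ---------------------------------------------------------------------------


class TestParametricFit:
    def test_exponential_closed_form_mle(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(100.0, 400)
        cens = np.minimum(t, 250.0)
        ev = (t <= 250.0).astype(int)
        fit = e.fit_parametric_os(toy_surv_df(cens, ev), "exponential")
        # rate MLE = events / total time at risk; lam = 1/rate
        assert fit.estimates["lam"] == pytest.approx(cens.sum() / ev.sum(), rel=1e-5)

    def test_single_cohort_recovery_within_two_se(self, os_fit_2000):
        truth = FINAL_OS_PARAMS
        assert os_fit_2000.converged
        for c in e.OS_COVARIATES:
            est, se = os_fit_2000.estimates[c], os_fit_2000.se[c]
            assert abs(est - truth.alphas[c]) < 2.5 * se, c
        assert os_fit_2000.estimates["p"] == pytest.approx(truth.p, rel=0.1)

    def test_matches_lifelines_aft_cross_check(self, os_design_2000):
        """Independent fitter agrees on coefficients and likelihood."""
        from lifelines import LogLogisticAFTFitter

        fit = e.fit_parametric_os(os_design_2000, "log-logistic", e.OS_COVARIATES)
        llf = LogLogisticAFTFitter()
        llf.fit(
            os_design_2000[[*e.OS_COVARIATES, "time", "event"]],
            duration_col="time",
            event_col="event",
        )
        for c in e.OS_COVARIATES:
            assert fit.estimates[c] == pytest.approx(llf.params_[("alpha_", c)], abs=0.01)
        assert fit.estimates["p"] == pytest.approx(np.exp(llf.params_[("beta_", "Intercept")]), rel=1e-2)
        # same likelihood surface; our optimum must be at least as good
        assert fit.minus2ll == pytest.approx(-2 * llf.log_likelihood_, abs=0.01)
        assert fit.minus2ll <= -2 * llf.log_likelihood_ + 1e-6

    def test_nested_model_likelihood_dominance(self, os_design_2000):
        full = e.fit_parametric_os(os_design_2000, "log-logistic", e.OS_COVARIATES)
        reduced = e.fit_parametric_os(
            os_design_2000, "log-logistic", [c for c in e.OS_COVARIATES if c != "auc_u"]
        )
        assert full.minus2ll <= reduced.minus2ll + 1e-6

    def test_aic_definition_and_comparison_table(self, os_design_2000):
        fits = [
            e.fit_parametric_os(os_design_2000, fam, ("ctfi_ge90",))
            for fam in ("log-logistic", "weibull", "lognormal", "exponential")
        ]
        for f in fits:
            assert f.aic == pytest.approx(f.minus2ll + 2 * f.n_free_params)
        tab = e.compare_models(fits)
        assert tab["aic"].is_monotonic_increasing
        assert tab["delta_aic"].iloc[0] == 0.0
        assert tab.loc[0, "family"] == "log-logistic"

    def test_compare_models_rejects_mismatched_data(self, os_design_2000):
        f1 = e.fit_parametric_os(os_design_2000, "exponential")
        f2 = e.fit_parametric_os(os_design_2000.iloc[:500], "exponential")
        with pytest.raises(ValueError):
            e.compare_models([f1, f2])
        assert e.compare_models([f1])["delta_aic"].iloc[0] == 0.0

    def test_gompertz_and_gaussian_fit_their_own_data(self):
        rng = np.random.default_rng(6)
        n = 1500
        # gompertz inverse-cdf sampling: H = a/b (e^{bt}-1) = -log U
        a, b = 0.002, 0.004
        u = rng.uniform(size=n)
        t = np.log(1 - b / a * np.log(u)) / b
        fit_g = e.fit_parametric_os(toy_surv_df(t, np.ones(n)), "gompertz")
        assert fit_g.estimates["a"] == pytest.approx(a, rel=0.2)
        assert fit_g.estimates["b"] == pytest.approx(b, rel=0.2)
        tn = np.clip(rng.normal(300, 50, n), 1, None)
        fit_n = e.fit_parametric_os(toy_surv_df(tn, np.ones(n)), "gaussian")
        assert fit_n.estimates["mu"] == pytest.approx(300, rel=0.02)

    def test_error_paths(self, os_design_2000):
        with pytest.raises(ValueError):
            e.fit_parametric_os(os_design_2000, "pareto")
        no_events = os_design_2000.copy()
        no_events["event"] = 0
        with pytest.raises(ValueError):
            e.fit_parametric_os(no_events, "log-logistic")
        const = os_design_2000.copy()
        const["brain_mets"] = 1.0
        with pytest.raises(ValueError):
            e.fit_parametric_os(const, "log-logistic", ("brain_mets",))


class TestAccelerationFactors:
    def test_table_and_zero_coefficient(self, os_fit_2000):
        af = e.acceleration_factors(os_fit_2000)
        assert set(af.index) == set(e.OS_COVARIATES)
        assert ((af["lo"] <= af["af"]) & (af["af"] <= af["hi"])).all()

    def test_ci_width_shrinks_with_sample_size(self):
        widths = []
        for n in (250, 1000, 4000):
            df = e.simulate_os_dataset(n, seed=31)
            d = e.os_design_matrix(df)
            d["time"], d["event"] = df["time"].to_numpy(), df["event"].to_numpy()
            fit = e.fit_parametric_os(d, "log-logistic", ("ctfi_ge90",))
            af = e.acceleration_factors(fit)
            widths.append(float(np.log(af["hi"] / af["lo"]).iloc[0]))
        assert widths[0] > widths[1] > widths[2]
        # ~ n^(-1/2) scaling across a 16x range
        assert widths[0] / widths[2] == pytest.approx(4.0, rel=0.4)

    def test_non_aft_family_unsupported(self, os_design_2000):
        fit = e.fit_parametric_os(os_design_2000, "gaussian", ("ctfi_ge90",))
        with pytest.raises(ValueError):
            e.acceleration_factors(fit)


class TestModelSelectionAndPH:
    def test_loglogistic_beats_exponential_on_loglogistic_data(self):
        """AIC prefers the true family in >=90% of replicate datasets."""
        wins = 0
        n_rep = 100
        from erlurbi._rng import child_seeds

        for s in child_seeds(77, n_rep):
            df = e.simulate_os_dataset(500, s)
            d = e.os_design_matrix(df)
            d["time"], d["event"] = df["time"].to_numpy(), df["event"].to_numpy()
            ll = e.fit_parametric_os(d, "log-logistic", ("ctfi_ge90",))
            ex = e.fit_parametric_os(d, "exponential", ("ctfi_ge90",))
            wins += ll.aic < ex.aic
        assert wins >= 90

    def test_ph_diagnostic_flags_crossing_hazards(self):
        """Schoenfeld-type test detects non-proportionality generated by a
        strong time-accelerating effect under shape > 1."""
        n = 3000
        rng = np.random.default_rng(8)
        grp = (rng.uniform(size=n) < 0.5).astype(float)
        truth = LogLogisticOSParams(p=2.4, lam=294.2, alphas={"ctfi_ge90": np.log(1.9)})
        u = rng.uniform(size=n)
        t = truth.lam * np.exp(np.log(1.9) * grp) * (u / (1 - u)) ** (1 / truth.p)
        df = toy_surv_df(t, np.ones(n), ctfi_ge90=grp)
        tab = e.ph_diagnostic(df, ["ctfi_ge90"])
        assert float(tab["p"].iloc[0]) < 0.05
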