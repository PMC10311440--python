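"""Screening, splitting, VPC, calibration and bootstrap machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import erlurbi as e
from erlurbi._rng import child_seeds
from erlurbi.params import FINAL_OS_PARAMS

from conftest import toy_surv_df


class TestUnivariateScreens:
    def test_strong_os_effect_detected(self):
        rng = np.random.default_rng(20)
        n = 1000
        grp = (rng.uniform(size=n) < 0.5).astype(float)
        u = rng.uniform(size=n)
        t = 294.2 * np.exp(np.log(2.0) * grp) * (u / (1 - u)) ** (1 / 2.4)
        df = toy_surv_df(t, np.ones(n), grp=grp, noise=rng.standard_normal(n))
        res = e.univariate_screen_os(df, ["grp", "noise"])
        assert res.table.loc["grp", "p"] < 1e-3
        assert res.table.index[0] == "grp"  # sorted by p

    def test_null_pvalues_uniform(self):
        """Screening p-values are calibrated under the null."""
        rng = np.random.default_rng(21)
        pvals = []
        for _ in range(300):
            n = 60
            df = toy_surv_df(
                rng.exponential(10, n), np.ones(n), x=rng.standard_normal(n)
            )
            pvals.append(float(e.univariate_screen_os(df, ["x"]).table["p"].iloc[0]))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_covariate_skipped_with_warning(self, os_design_2000):
        df = os_design_2000.assign(const=1.0)
        with pytest.warns(UserWarning, match="constant"):
            res = e.univariate_screen_os(df, ["ctfi_ge90", "const"])
        assert res.skipped == ["const"]

    def test_orr_screen_null_and_recovery(self):
        rng = np.random.default_rng(22)
        n = 2000
        x = rng.standard_normal(n)
        from scipy.special import expit

        y = (rng.uniform(size=n) < expit(-1 + 1.0 * x)).astype(int)
        df = pd.DataFrame({"x": x, "null": rng.standard_normal(n), "responder": y})
        res = e.univariate_screen_orr(df, ["x", "null"])
        assert 0.8 < res.table.loc["null", "effect"] < 1.25
        lo, hi = res.table.loc["x", ["lo", "hi"]]
        assert lo < np.exp(1.0) < hi * 1.5  # true OR e^1 within/near the CI
        assert res.effect_name == "OR"


class TestTrainTestSplit:
    def test_sizes_partition_and_determinism(self, os_sim_2000):
        train, test = e.train_test_split(os_sim_2000.head(100), 0.3, seed=5)
        assert len(train) == 70 and len(test) == 30
        combined = pd.concat([train, test]).sort_index()
        pd.testing.assert_frame_equal(combined, os_sim_2000.head(100))
        train2, test2 = e.train_test_split(os_sim_2000.head(100), 0.3, seed=5)
        pd.testing.assert_frame_equal(train, train2)

    def test_stratification_preserves_proportions(self, os_sim_2000):
        train, test = e.train_test_split(
            os_sim_2000, 0.3, seed=6, stratify_by=["event", "ctfi_group"]
        )
        assert train["event"].mean() == pytest.approx(test["event"].mean(), abs=0.01)
        p_tr = (train["ctfi_group"] == "sensitive").mean()
        p_te = (test["ctfi_group"] == "sensitive").mean()
        assert p_tr == pytest.approx(p_te, abs=0.01)

    def test_fraction_out_of_range(self, os_sim_2000):
        with pytest.raises(ValueError):
            e.train_test_split(os_sim_2000, 1.5, seed=1)


class TestVPC:
    def test_self_consistency_os(self, os_fit_2000, os_design_2000):
        """Data simulated from the fitted model lie inside their own bands."""
        res = e.vpc_os(os_fit_2000, os_design_2000, n_replicates=50, seed=9)
        assert res.n_replicates == 50
        inside = (res.observed >= res.lo) & (res.observed <= res.hi)
        assert inside.mean() >= 0.9
        # bands are ordered and non-increasing over time
        assert np.all(res.lo <= res.mid + 1e-12) and np.all(res.mid <= res.hi + 1e-12)
        assert np.all(np.diff(res.mid) <= 1e-12)

    def test_band_width_grows_with_percentile_extremity(self, os_fit_2000, os_design_2000):
        res = e.vpc_os(os_fit_2000, os_design_2000.head(300), n_replicates=40, seed=10)
        # 2.5/97.5 bands must be at least as wide as the inner 10/90 bands
        # recompute inner percentiles from the same replicates is not exposed;
        # proxy: the 95% band has positive width wherever survival is mixed
        mid_range = (res.mid > 0.05) & (res.mid < 0.95)
        assert np.all((res.hi - res.lo)[mid_range] > 0)

    def test_replicate_default_and_validation(self, os_fit_2000, os_design_2000):
        import inspect

        assert inspect.signature(e.vpc_os).parameters["n_replicates"].default == 50
        assert inspect.signature(e.bootstrap_fits).parameters["n_boot"].default == 250
        with pytest.raises(ValueError):
            e.vpc_os(os_fit_2000, os_design_2000, n_replicates=1, seed=1)

    def test_seed_reproducibility(self, os_fit_2000, os_design_2000):
        a = e.vpc_os(os_fit_2000, os_design_2000.head(200), n_replicates=10, seed=3)
        b = e.vpc_os(os_fit_2000, os_design_2000.head(200), n_replicates=10, seed=3)
        np.testing.assert_array_equal(a.lo, b.lo)
        np.testing.assert_array_equal(a.hi, b.hi)

    def test_orr_vpc_self_consistency(self, orr_fit_2000, orr_sim_2000):
        res = e.vpc_orr(orr_fit_2000, orr_sim_2000, n_replicates=50, seed=4)
        inside = (res.observed >= res.lo) & (res.observed <= res.hi)
        assert inside.mean() >= 0.75
        assert res.as_frame().shape[0] == 4  # exposure quartiles


class TestCalibration:
    def test_self_calibration_error_small(self, os_fit_2000, os_design_2000):
        tps = np.quantile(os_design_2000["time"], np.linspace(0.1, 0.9, 9))
        tab = e.calibration_and_prediction_error(os_fit_2000, os_design_2000, tps)
        assert np.all(np.abs(tab["error"]) < 0.03)

    def test_timepoint_beyond_followup_dropped(self, os_fit_2000, os_design_2000):
        tmax = os_design_2000["time"].max()
        with pytest.warns(UserWarning, match="beyond max follow-up"):
            tab = e.calibration_and_prediction_error(
                os_fit_2000, os_design_2000, [100.0, tmax * 2]
            )
        assert len(tab) == 1

    def test_deterministic(self, os_fit_2000, os_design_2000):
        t1 = e.calibration_and_prediction_error(os_fit_2000, os_design_2000, [200.0])
        t2 = e.calibration_and_prediction_error(os_fit_2000, os_design_2000, [200.0])
        pd.testing.assert_frame_equal(t1, t2)


class TestBootstrap:
    def test_coverage_of_mean_ci(self):
        """Percentile bootstrap CI of a mean covers the truth ~95% of the time."""
        rng = np.random.default_rng(30)
        covered = 0
        n_outer = 100
        for s in child_seeds(101, n_outer):
            data = pd.DataFrame({"v": np.random.default_rng(s).normal(5.0, 2.0, 80)})
            res = e.bootstrap_fits(data, lambda d: {"mean": d["v"].mean()}, n_boot=100, seed=s)
            lo, hi = res["ci"].loc["mean", "lo"], res["ci"].loc["mean", "hi"]
            covered += lo <= 5.0 <= hi
        assert covered >= 88  # ~95% nominal with MC and small-n error

    def test_failure_threshold(self):
        data = pd.DataFrame({"v": np.arange(10.0)})

        def flaky(d):
            if (d["v"] == 0).any():
                raise RuntimeError("boom")
            return {"mean": d["v"].mean()}

        with pytest.raises(RuntimeError, match="failed"):
            e.bootstrap_fits(data, flaky, n_boot=50, seed=1)

    def test_seed_reproducibility_and_metadata(self):
        data = pd.DataFrame({"v": np.random.default_rng(1).normal(size=50)})
        f = lambda d: {"mean": d["v"].mean()}
        a = e.bootstrap_fits(data, f, n_boot=25, seed=2)
        b = e.bootstrap_fits(data, f, n_boot=25, seed=2)
        pd.testing.assert_frame_equal(a["replicates"], b["replicates"])
        assert a["n_boot"] == 25 and a["n_failed"] == 0

    def test_bootstrap_ci_close_to_wald_on_smooth_problem(self, os_design_2000):
        """Percentile CI width tracks the Wald width on a well-behaved fit."""
        sub = os_design_2000.head(800)
        fit = e.fit_parametric_os(sub, "log-logistic", ("ctfi_ge90",))
        res = e.bootstrap_fits(
            sub,
            lambda d: {"coef": e.fit_parametric_os(d, "log-logistic", ("ctfi_ge90",)).estimates["ctfi_ge90"]},
            n_boot=120,
            seed=3,
        )
        wald_width = 2 * 1.96 * fit.se["ctfi_ge90"]
        boot_width = res["ci"].loc["coef", "hi"] - res["ci"].loc["coef", "lo"]
        assert boot_width == pytest.approx(wald_width, rel=0.25)
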