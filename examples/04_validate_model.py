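"""Validate a fitted survival model: VPC, calibration and bootstrap.

Mirrors the published validation procedure: a visual predictive check with
50 replicates and monthly 95% prediction bands, calibration/prediction
error at follow-up quantiles, and 250 bootstrap subsamples for parameter
uncertainty (reduced here to keep the example quick).
"""

import numpy as np

import erlurbi as e

df = e.simulate_os_dataset(n=800, seed=31)
design = e.os_design_matrix(df)
design["time"] = df["time"].to_numpy()
design["event"] = df["event"].to_numpy()
design["censor_time"] = df["censor_time"].to_numpy()

fit = e.fit_parametric_os(design, "log-logistic", e.OS_COVARIATES)

vpc = e.vpc_os(fit, design, n_replicates=50, seed=31)
inside = ((vpc.observed >= vpc.lo) & (vpc.observed <= vpc.hi)).mean()
print(f"VPC: {vpc.n_replicates} replicates, monthly bands; observed KM inside 95% band in {inside:.0%} of bins")

tps = np.quantile(design["time"], [0.25, 0.5, 0.75])
calib = e.calibration_and_prediction_error(fit, design, tps)
print("\ncalibration (predicted - observed survival):")
print(calib.round(3).to_string(index=False))

boot = e.bootstrap_fits(
    design,
    lambda d: e.fit_parametric_os(d, "log-logistic", e.OS_COVARIATES).estimates,
    n_boot=50,
    seed=31,
)
print(f"\nbootstrap ({boot['n_boot']} subsamples, {boot['n_failed']} failed) percentile CIs:")
print(boot["ci"].loc[["p", "lam", "ctfi_ge90"]].round(3).to_string())
# Self-consistency: a model fitted to its own simulated data should sit
# inside its VPC bands and show calibration errors of a few percent.
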