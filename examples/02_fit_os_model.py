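"""Fit the log-logistic AFT overall-survival model and read off the
acceleration factors.

Simulates a cohort under the published model as truth, refits by maximum
likelihood, and compares families by AIC — the parametric counterpart of the
trial's model-selection step.
"""

import erlurbi as e

df = e.simulate_os_dataset(n=2000, seed=11)
design = e.os_design_matrix(df)
design["time"] = df["time"].to_numpy()
design["event"] = df["event"].to_numpy()

fits = [
    e.fit_parametric_os(design, fam, e.OS_COVARIATES)
    for fam in ("log-logistic", "weibull", "lognormal")
]
print(e.compare_models(fits).to_string(index=False))

best = min(fits, key=lambda f: f.aic)
print(f"\nbest family: {best.family}")
print(f"shape p = {best.estimates['p']:.2f} (truth 2.4)")
print(f"scale lam = {best.estimates['lam']:.0f} days (truth 294.2)")
print("\nacceleration factors (AF > 1 = longer survival per unit):")
print(e.acceleration_factors(best).round(2).to_string())
# With shape > 1 the hazard rises to a peak and falls — the crossing-hazards
# pattern that made a proportional-hazards model inadequate here.
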