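"""Fit the sigmoid-Emax response model and inspect the exposure-response
curve.

The model places a saturating exposure effect (Hill coefficient 10, fixed
intercept -10) on the logit of response probability, with separate maximal
effects for resistant (CTFI < 90 d) and sensitive disease.
"""

import numpy as np

import erlurbi as e

df = e.simulate_orr_dataset(n=2000, seed=21)
fit = e.fit_emax_orr(df)

print("parameter estimates (RSE%):")
for k, v in fit.estimates.items():
    print(f"  {k:15s} {v:8.1f}  ({fit.rse_percent[k]:.1f}%)")

params = fit.params()
for auc in (500, 877, 1064, 1500):
    pr = e.orr_probability(auc, "resistant", params)
    ps = e.orr_probability(auc, "sensitive", params)
    print(f"AUCu {auc:5d} ng·h/L -> ORR resistant {pr:5.1%}, sensitive {ps:5.1%}")
# The curve is nearly a step at the EC50 (~877 ng·h/L): patients pass from
# background response to the plateau within a narrow exposure window, which
# is why maximal response is already reached below the median exposure of
# the approved 3.2 mg/m² dose.
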