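# erlurbi

Exposure–response modelling of lurbinectedin ± doxorubicin in relapsed
small-cell lung cancer (SCLC): synthetic trial-like cohorts, compartmental
PK exposure derivation, a log-logistic accelerated-failure-time (AFT) model
for overall survival, a sigmoid-Emax model for objective response,
VPC/bootstrap/calibration validation, and counterfactual dose-regimen
simulation for model-based head-to-head comparisons.

## Who this is for

Pharmacometricians and biostatisticians who want a reproducible, tested
implementation of a published E-R analysis whose patient-level data are not
public: every stage — cohort generation, exposure derivation, model
fitting, validation, counterfactual prediction — is an importable function,
and the published final models ship as ready-to-use parameter objects.

## The models

**Overall survival** is log-logistic AFT:

```
S(t | x) = 1 / (1 + (t / (λ·AF(x)))^p),    AF(x) = exp(α0 + Σ αn xn)
```

with shape p = 2.4 (hazard rises then falls — crossing hazards that ruled
out proportional hazards), scale λ = 294.2 days, and acceleration factors
1.9 (CTFI ≥ 90 d), 0.5 (log LDH), 0.9 (NL ratio), 0.6 (brain metastases),
1.4 (AUCu), 1.2 (AUCDOX) and 0.8 (AUCu·AUCDOX interaction; exposures on a
per-1000-native-units scale — see `docs/methods.md`).

**Objective response** is a sigmoid-Emax term on the logit scale:

```
logit(p) = −10 + Emax(CTFI group) · AUCu¹⁰ / (EC50¹⁰ + AUCu¹⁰)
```

with Emax 8.5 (resistant) / 10.8 (sensitive), EC50 = 877 ng·h/L, and fixed
Hill = 10 and intercept = −10.

Both fitters are written in-house (full right-censored / Bernoulli maximum
likelihood with analytic gradients); Kaplan–Meier, log-rank, Cox and the
proportional-hazards diagnostic delegate to lifelines.

## Worked example

```python
import erlurbi as e

# simulate a combination-arm cohort and refit the published OS model
df = e.simulate_os_dataset(n=2000, seed=7)
design = e.os_design_matrix(df)
design[["time", "event"]] = df[["time", "event"]]

fit = e.fit_parametric_os(design, "log-logistic", e.OS_COVARIATES)
print(fit.estimates["p"])                    # 2.287  (truth 2.4)
print(e.acceleration_factors(fit).round(2))
```

```
                   af    lo    hi
covariate
ctfi_ge90        1.90  1.77  2.04
log_ldh          0.49  0.47  0.51
nl_ratio         0.90  0.89  0.90
brain_mets       0.60  0.55  0.66
auc_u            1.69  1.16  2.46
auc_dox          1.32  1.09  1.59
auc_u_x_auc_dox  0.69  0.55  0.87
```

Each `af` row is the multiplicative effect on survival time per unit of
that covariate (AF > 1 = longer survival); the published truth used to
simulate the data sits inside every interval. The `examples/` directory
walks through each capability — cohort simulation, OS and ORR fitting,
validation (VPC/calibration/bootstrap) and the counterfactual single-agent
3.2 mg/m² comparison — each printing the numbers it computes and what they
mean.

A thin CLI mirrors the pipeline stages:

```bash
erlurbi simulate --n 500 --seed 1 --out cohort.csv
erlurbi fit-os --cohort cohort.csv --out os_fit.json
erlurbi run --config config.yaml      # simulate → fit → validate → compare
```

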