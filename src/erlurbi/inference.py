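"""Model-building and validation scaffolding: univariate screening,
train/test splitting, visual predictive checks, calibration/prediction-error
diagnostics and bootstrap uncertainty.

Procedure constants mirror the published analysis: 250 bootstrap subsamples
and visual predictive checks built from 50 replicates with monthly 95%
prediction-interval bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import train_test_split as _sk_split

from ._rng import child_seeds, rng_for
from .params import MONTH_DAYS, LogLogisticOSParams
from .response import fit_logistic_multivariate, orr_probability
from .survival import SurvivalFitResult, cox_fit, km_estimate

__all__ = [
    "ScreenTable",
    "VPCResult",
    "univariate_screen_os",
    "univariate_screen_orr",
    "train_test_split",
    "vpc_os",
    "vpc_orr",
    "calibration_and_prediction_error",
    "bootstrap_fits",
    "N_BOOT_DEFAULT",
    "N_VPC_REPLICATES_DEFAULT",
]

N_BOOT_DEFAULT = 250
N_VPC_REPLICATES_DEFAULT = 50


@dataclass
class ScreenTable:
    """Univariate screening results, one row per candidate covariate."""

    table: pd.DataFrame  # columns: effect, lo, hi, p, n; index: covariate
    effect_name: str  # "HR" or "OR"
    skipped: list[str] = field(default_factory=list)


@dataclass
class VPCResult:
    """Percentile bands of replicate-simulated outcomes vs the observed curve."""

    grid: np.ndarray  # months (OS) or exposure-bin midpoints (ORR)
    lo: np.ndarray
    mid: np.ndarray
    hi: np.ndarray
    observed: np.ndarray
    n_replicates: int
    percentiles: tuple[float, float] = (2.5, 97.5)
    kind: str = "os"

    def as_frame(self) -> pd.DataFrame:
        label = "month" if self.kind == "os" else "auc_u_mid"
        return pd.DataFrame(
            {label: self.grid, "lo": self.lo, "mid": self.mid, "hi": self.hi, "observed": self.observed}
        )


def univariate_screen_os(
    data: pd.DataFrame,
    candidate_covariates: list[str],
    duration_col: str = "time",
    event_col: str = "event",
) -> ScreenTable:
    """One univariate Cox fit per candidate; sorted by p-value.

    Raw p-values are reported (no multiplicity adjustment), matching common
    screening practice; apply Holm afterwards if desired.
    """
    rows, skipped = [], []
    for c in candidate_covariates:
        if data[c].nunique() <= 1:
            warnings.warn(f"covariate '{c}' is constant; skipped", stacklevel=2)
            skipped.append(c)
            continue
        fit = cox_fit(data, [c], duration_col, event_col)
        hr = fit.meta["hazard_ratios"]
        cph = fit.meta["lifelines"]
        rows.append(
            {
                "covariate": c,
                "effect": float(hr["hr"].iloc[0]),
                "lo": float(hr["lo"].iloc[0]),
                "hi": float(hr["hi"].iloc[0]),
                "p": float(cph.summary["p"].iloc[0]),
                "n": fit.n,
            }
        )
    tab = pd.DataFrame(rows).set_index("covariate").sort_values("p") if rows else pd.DataFrame()
    return ScreenTable(table=tab, effect_name="HR", skipped=skipped)


def univariate_screen_orr(
    data: pd.DataFrame, candidate_covariates: list[str], outcome_col: str = "responder"
) -> ScreenTable:
    """One univariate logistic fit per candidate; odds ratios, sorted by p."""
    rows, skipped = [], []
    for c in candidate_covariates:
        if data[c].nunique() <= 1:
            warnings.warn(f"covariate '{c}' is constant; skipped", stacklevel=2)
            skipped.append(c)
            continue
        fit = fit_logistic_multivariate(data, [c], outcome_col)
        ors = fit.meta["odds_ratios"]
        rows.append(
            {
                "covariate": c,
                "effect": float(ors.loc[c, "or"]),
                "lo": float(ors.loc[c, "lo"]),
                "hi": float(ors.loc[c, "hi"]),
                "p": float(ors.loc[c, "p"]),
                "n": fit.n,
            }
        )
    tab = pd.DataFrame(rows).set_index("covariate").sort_values("p") if rows else pd.DataFrame()
    return ScreenTable(table=tab, effect_name="OR", skipped=skipped)


def train_test_split(
    data: pd.DataFrame,
    test_fraction: float,
    seed: int,
    stratify_by: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test partition, optionally stratified so
    event and CTFI-group proportions carry over."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    strat = None
    if stratify_by:
        strat = data[stratify_by].astype(str).agg("|".join, axis=1)
    train, test = _sk_split(data, test_size=test_fraction, random_state=seed % (2**31), stratify=strat)
    return train, test


def _km_on_grid(times, events, grid_days) -> np.ndarray:
    km = km_estimate(times, events)
    return km.at(grid_days)


def vpc_os(
    fit: SurvivalFitResult | LogLogisticOSParams,
    data: pd.DataFrame,
    n_replicates: int = N_VPC_REPLICATES_DEFAULT,
    seed: int = 0,
    duration_col: str = "time",
    event_col: str = "event",
) -> VPCResult:
    """Visual predictive check of a log-logistic OS fit.

    Simulates ``n_replicates`` outcome sets from the fitted model at the
    observed covariates, replicating each subject's administrative censoring
    time (the observed time for censored subjects, the data cutoff for
    subjects who died), and returns monthly 2.5/50/97.5 percentile bands of
    the replicate Kaplan-Meier curves plus the observed curve.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    from .cohort import simulate_os_outcomes
    from .params import os_design_matrix

    params = fit if isinstance(fit, LogLogisticOSParams) else fit.params()
    t_obs = np.asarray(data[duration_col], dtype=float)
    e_obs = np.asarray(data[event_col], dtype=bool)
    cutoff = float(t_obs.max())
    if "censor_time" in data.columns:
        # administrative censoring times known by design
        cens_time = np.asarray(data["censor_time"], dtype=float)
    else:
        # fallback: observed time for censored subjects, data cutoff for deaths
        cens_time = np.where(e_obs, cutoff, t_obs)

    max_month = int(np.ceil(cutoff / MONTH_DAYS))
    grid_months = np.arange(0, max_month + 1)
    grid_days = grid_months * MONTH_DAYS

    x = os_design_matrix(data)
    lp = params.linear_predictor(x)
    seeds = child_seeds(seed, n_replicates)
    curves = np.empty((n_replicates, grid_days.size))
    for r in range(n_replicates):
        rng = np.random.default_rng(seeds[r])
        u = rng.uniform(size=len(data))
        t_sim = params.lam * np.exp(lp) * (u / (1 - u)) ** (1.0 / params.p)
        t_r = np.minimum(t_sim, cens_time)
        e_r = t_sim <= cens_time
        if not e_r.any():  # pragma: no cover - degenerate
            curves[r] = 1.0
            continue
        curves[r] = _km_on_grid(t_r, e_r, grid_days)

    lo, mid, hi = np.percentile(curves, [2.5, 50.0, 97.5], axis=0)
    observed = _km_on_grid(t_obs, e_obs, grid_days)
    return VPCResult(
        grid=grid_months.astype(float),
        lo=lo,
        mid=mid,
        hi=hi,
        observed=observed,
        n_replicates=n_replicates,
        kind="os",
    )


def vpc_orr(
    params_or_fit,
    data: pd.DataFrame,
    n_replicates: int = N_VPC_REPLICATES_DEFAULT,
    seed: int = 0,
    n_bins: int = 4,
) -> VPCResult:
    """Visual predictive check of the sigmoid-Emax response model: observed
    response rate per exposure-quantile bin vs percentile bands of
    replicate-simulated rates."""
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    params = params_or_fit if not hasattr(params_or_fit, "params") else params_or_fit.params()
    auc = np.asarray(data["auc_u"], dtype=float)
    y = np.asarray(data["responder"], dtype=float)
    p = orr_probability(auc, data["ctfi_group"].to_numpy(), params)

    edges = np.quantile(auc, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-9
    bins = np.clip(np.digitize(auc, edges) - 1, 0, n_bins - 1)
    mids = np.array([np.median(auc[bins == b]) for b in range(n_bins)])

    seeds = child_seeds(seed, n_replicates)
    rates = np.empty((n_replicates, n_bins))
    for r in range(n_replicates):
        rng = np.random.default_rng(seeds[r])
        sim = rng.uniform(size=len(auc)) < p
        rates[r] = [sim[bins == b].mean() for b in range(n_bins)]
    lo, mid, hi = np.percentile(rates, [2.5, 50.0, 97.5], axis=0)
    observed = np.array([y[bins == b].mean() for b in range(n_bins)])
    return VPCResult(
        grid=mids, lo=lo, mid=mid, hi=hi, observed=observed,
        n_replicates=n_replicates, kind="orr",
    )


def calibration_and_prediction_error(
    fit: SurvivalFitResult | LogLogisticOSParams,
    data: pd.DataFrame,
    timepoints_days,
    duration_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Observed vs predicted survival at the requested timepoints.

    Predicted S(t) is the mean model survivor probability over subjects;
    observed is the Kaplan-Meier estimate; ``error`` = predicted - observed.
    Timepoints beyond follow-up are dropped with a warning.
    """
    from .params import os_design_matrix

    params = fit if isinstance(fit, LogLogisticOSParams) else fit.params()
    t_obs = np.asarray(data[duration_col], dtype=float)
    e_obs = np.asarray(data[event_col], dtype=bool)
    tps = np.asarray(timepoints_days, dtype=float)
    keep = tps <= t_obs.max()
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} timepoint(s) beyond max follow-up dropped", stacklevel=2
        )
    tps = tps[keep]
    km = km_estimate(t_obs, e_obs)
    x = os_design_matrix(data)
    lp = params.linear_predictor(x)
    rows = []
    for t in tps:
        z = params.p * (np.log(t) - np.log(params.lam) - lp) if t > 0 else np.full(len(data), -np.inf)
        pred = float(np.mean(expit(-z)))
        obs = float(km.at(t))
        rows.append({"time_days": t, "predicted": pred, "observed": obs, "error": pred - obs})
    return pd.DataFrame(rows)


def bootstrap_fits(
    data: pd.DataFrame,
    fit_fn,
    n_boot: int = N_BOOT_DEFAULT,
    seed: int = 0,
    max_failure_fraction: float = 0.2,
) -> dict:
    """Nonparametric bootstrap of any fitting function.

    ``fit_fn(resampled_df) -> dict[str, float]`` is refit on ``n_boot``
    patient resamples (with replacement). Returns the replicate estimates,
    percentile 95% CIs per parameter and the count of failed replicates
    (excluded); more than ``max_failure_fraction`` failures is a hard error.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = rng_for(seed, "bootstrap")
    n = len(data)
    rows, failures = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            est = fit_fn(sample)
            rows.append(est)
        except Exception:
            failures += 1
    if failures > max_failure_fraction * n_boot:
        raise RuntimeError(
            f"{failures}/{n_boot} bootstrap replicates failed (> {max_failure_fraction:.0%})"
        )
    reps = pd.DataFrame(rows)
    ci = pd.DataFrame(
        {
            "lo": reps.quantile(0.025),
            "median": reps.quantile(0.5),
            "hi": reps.quantile(0.975),
        }
    )
    return {"replicates": reps, "ci": ci, "n_boot": n_boot, "n_failed": failures}
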