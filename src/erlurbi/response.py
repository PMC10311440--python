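"""Objective-response modelling: the sigmoid-Emax logistic model, a
multivariate logistic comparator, and classification diagnostics.

The final response model puts a saturating exposure effect on the logit
scale of the response probability,

    logit(p) = -10 + Emax(group) * auc_u**10 / (ec50**10 + auc_u**10)

where ``group`` is the chemotherapy-free-interval class (< 90 d resistant,
>= 90 d sensitive, each with its own Emax), EC50 is the unbound
lurbinectedin exposure giving half the maximal logit shift, and the Hill
coefficient (10) and intercept (-10) are structural constants. The Hill
term is evaluated as expit(10 * (log auc - log ec50)) so no power of a
thousand-scale exposure is ever formed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import expit
from statsmodels.tools.numdiff import approx_hess1
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .params import EmaxORRParams

__all__ = [
    "LogisticFitResult",
    "orr_probability",
    "fit_emax_orr",
    "fit_logistic_multivariate",
    "classification_metrics",
]


@dataclass
class LogisticFitResult:
    """Estimates and inference for a binary-response model fit."""

    estimates: dict[str, float]
    se: dict[str, float]
    rse_percent: dict[str, float]
    covariance: pd.DataFrame | None
    minus2ll: float
    aic: float
    n: int
    converged: bool
    meta: dict = field(default_factory=dict)

    def params(self) -> EmaxORRParams:
        """The fitted sigmoid-Emax model as a simulation-ready object."""
        if not {"emax_resistant", "emax_sensitive", "ec50"} <= set(self.estimates):
            raise ValueError("not a sigmoid-Emax fit")
        return EmaxORRParams(
            emax_resistant=self.estimates["emax_resistant"],
            emax_sensitive=self.estimates["emax_sensitive"],
            ec50=self.estimates["ec50"],
        )


def _sensitive_mask(ctfi_group) -> np.ndarray:
    g = np.asarray(ctfi_group)
    if g.dtype.kind in "bif":
        return g.astype(bool)
    return g == "sensitive"


def _hill_term(auc_u: np.ndarray, ec50: float, hill: float) -> np.ndarray:
    """auc**h / (ec50**h + auc**h), overflow-safe; exactly 0 at auc = 0."""
    out = np.zeros_like(auc_u, dtype=float)
    pos = auc_u > 0
    out[pos] = expit(hill * (np.log(auc_u[pos]) - math.log(ec50)))
    return out


def orr_probability(auc_u, ctfi_group, params: EmaxORRParams):
    """Response probability under the sigmoid-Emax logistic model.

    ``ctfi_group`` may be "resistant"/"sensitive" labels or a boolean/0-1
    sensitive mask. Monotone non-decreasing in ``auc_u`` for Emax > 0.
    """
    auc = np.atleast_1d(np.asarray(auc_u, dtype=float))
    if np.any(auc < 0):
        raise ValueError("auc_u must be >= 0")
    emax = params.emax(_sensitive_mask(ctfi_group))
    p = expit(params.intercept + emax * _hill_term(auc, params.ec50, params.hill))
    return p if np.ndim(auc_u) else float(p[0])


def fit_emax_orr(data: pd.DataFrame, start: EmaxORRParams | None = None) -> LogisticFitResult:
    """Maximum-likelihood fit of the sigmoid-Emax model.

    ``data`` needs columns ``auc_u`` (ng·h/L), ``ctfi_group`` and
    ``responder``. Free parameters are the two group Emax values and EC50
    (estimated on the log scale; RSE% reported on the natural scale by the
    delta method). Hill and intercept stay fixed at their structural values.
    """
    auc = np.asarray(data["auc_u"], dtype=float)
    y = np.asarray(data["responder"], dtype=float)
    sens = _sensitive_mask(data["ctfi_group"].to_numpy())
    if np.any(auc < 0):
        raise ValueError("auc_u must be >= 0")
    if y.min() == y.max():
        raise ValueError("all outcomes identical: complete separation, model not estimable")
    groups_present = (np.any(sens), np.any(~sens))
    if not all(groups_present):
        warnings.warn(
            "only one CTFI group present; fitting a single shared Emax", stacklevel=2
        )
    hill, intercept = 10.0, -10.0

    def nll(theta):
        emax_r, emax_s, log_ec50 = theta
        B = _hill_term(auc, math.exp(log_ec50), hill)
        logit_p = intercept + np.where(sens, emax_s, emax_r) * B
        # Bernoulli log-likelihood, stable form
        ll = np.sum(y * logit_p - np.logaddexp(0.0, logit_p))
        p = expit(logit_p)
        resid = y - p
        dB_dlog_ec50 = -hill * B * (1 - B)
        g = np.array(
            [
                np.sum(resid * B * (~sens)),
                np.sum(resid * B * sens),
                np.sum(resid * np.where(sens, emax_s, emax_r) * dB_dlog_ec50),
            ]
        )
        return -ll, -g

    if start is None:
        start = EmaxORRParams(8.0, 8.0, float(np.median(auc[auc > 0])))
    theta0 = np.array([start.emax_resistant, start.emax_sensitive, math.log(start.ec50)])
    res = optimize.minimize(nll, theta0, jac=True, method="BFGS", options={"gtol": 1e-7, "maxiter": 500})
    if not res.success and np.max(np.abs(res.jac)) > 1e-3:
        for jitter_seed in range(3):
            rng = np.random.default_rng(jitter_seed)
            trial = optimize.minimize(
                nll, theta0 + rng.normal(0, 0.3, 3), jac=True, method="BFGS",
                options={"gtol": 1e-7, "maxiter": 500},
            )
            if trial.fun < res.fun or trial.success:
                res = trial
            if res.success:
                break

    emax_r, emax_s, log_ec50 = res.x
    ec50 = math.exp(log_ec50)
    H = approx_hess1(res.x, lambda th: nll(th)[0])
    names = ["emax_resistant", "emax_sensitive", "ec50"]
    try:
        cov = np.linalg.inv(H)
        grad_diag = np.array([1.0, 1.0, ec50])  # delta method for ec50
        cov_nat = cov * np.outer(grad_diag, grad_diag)
        se_vals = np.sqrt(np.diag(cov_nat))
        cov_df = pd.DataFrame(cov_nat, index=names, columns=names)
    except np.linalg.LinAlgError:
        se_vals = np.full(3, np.nan)
        cov_df = None

    estimates = dict(zip(names, [emax_r, emax_s, ec50]))
    se = dict(zip(names, map(float, se_vals)))
    rse = {k: 100.0 * se[k] / abs(v) if v else float("nan") for k, v in estimates.items()}
    minus2ll = 2.0 * float(res.fun)
    return LogisticFitResult(
        estimates=estimates,
        se=se,
        rse_percent=rse,
        covariance=cov_df,
        minus2ll=minus2ll,
        aic=minus2ll + 2 * 3,
        n=len(y),
        converged=bool(res.success or np.max(np.abs(res.jac)) < 1e-3),
        meta={"hill": hill, "intercept": intercept, "both_groups": all(groups_present)},
    )


def fit_logistic_multivariate(
    data: pd.DataFrame, covariate_names: list[str], outcome_col: str = "responder"
) -> LogisticFitResult:
    """Standard maximum-likelihood logistic regression (IRLS/Newton) with
    odds ratios and Wald CIs in ``meta["odds_ratios"]``."""
    for c in covariate_names:
        if data[c].nunique() <= 1:
            raise ValueError(f"covariate '{c}' is constant (not identifiable)")
    y = np.asarray(data[outcome_col], dtype=float)
    if y.min() == y.max():
        raise ValueError("all outcomes identical: complete separation")
    X = sm.add_constant(data[list(covariate_names)].astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0)
        except (PerfectSeparationWarning, PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise ValueError(f"logistic fit failed (separation/collinearity): {exc}") from exc
    params = fit.params
    se = fit.bse
    or_tab = pd.DataFrame(
        {
            "or": np.exp(params),
            "lo": np.exp(params - 1.96 * se),
            "hi": np.exp(params + 1.96 * se),
            "p": fit.pvalues,
        }
    )
    estimates = params.to_dict()
    ses = se.to_dict()
    rse = {k: 100.0 * ses[k] / abs(v) if v else float("nan") for k, v in estimates.items()}
    minus2ll = -2.0 * float(fit.llf)
    return LogisticFitResult(
        estimates=estimates,
        se=ses,
        rse_percent=rse,
        covariance=pd.DataFrame(fit.cov_params()),
        minus2ll=minus2ll,
        aic=float(fit.aic),
        n=len(y),
        converged=bool(fit.mle_retvals["converged"]),
        meta={"odds_ratios": or_tab, "statsmodels": fit},
    )


def classification_metrics(probabilities, outcomes, threshold: float = 0.5) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from the thresholded confusion
    matrix; precision with zero predicted positives is reported as 0 with a
    warning."""
    from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score

    p = np.asarray(probabilities, dtype=float)
    yobs = np.asarray(outcomes, dtype=int)
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != yobs.shape:
        raise ValueError("probabilities and outcomes must have equal length")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    yhat = (p >= threshold).astype(int)
    if yhat.sum() == 0 and yobs.sum() > 0:
        warnings.warn("no predicted positives: precision undefined, reported as 0", stacklevel=2)
    return {
        "accuracy": float(accuracy_score(yobs, yhat)),
        "precision": float(precision_score(yobs, yhat, zero_division=0)),
        "recall": float(recall_score(yobs, yhat, zero_division=0)),
        "f1": float(f1_score(yobs, yhat, zero_division=0)),
    }
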