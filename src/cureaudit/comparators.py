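"""Reference estimators of the diagnosis probability at a censoring horizon.

Three conventional models — ever/never logistic regression, Cox
proportional hazards, and a log-normal accelerated-failure-time model —
plus the Kaplan-Meier product-limit curve.  Each model exposes the same
predicted-probability surface through :func:`predict_diag_prob`: for the
time-to-event models the diagnosis probability at horizon ``t_c`` is
``1 - S(t_c | x)``; for the logistic model it is the fitted class
probability (horizon-independent by construction, since the outcome was
already dichotomized at the cutoff); for a mixture cure fit it is the
incidence pi(z), also horizon-free.

Fits are delegated to statsmodels (logistic) and lifelines (Cox with a
Breslow baseline, log-normal AFT, Kaplan-Meier); the contract validated
by the tests is the predicted-probability surface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter, LogNormalAFTFitter

from .curemodel import CureFit, predict_incidence

logger = logging.getLogger(__name__)

__all__ = [
    "SurvFit",
    "KMCurve",
    "fit_logistic_ever_never",
    "fit_cox_ph",
    "fit_lognormal_aft",
    "predict_diag_prob",
    "kaplan_meier",
]


@dataclass
class SurvFit:
    """A fitted comparator model.

    ``coefficients`` is a named series on the model's natural scale
    (log-odds, log-hazard, or log-time).  For Cox fits ``baseline`` holds
    the Breslow cumulative baseline hazard step function; for the AFT fit
    ``scale`` is the log-normal sigma.  ``loglik`` is the (partial)
    log-likelihood at the optimum.  ``flagged`` marks separation or other
    reliability warnings without hiding the fit.
    """

    model_kind: str
    coefficients: pd.Series
    covariates: tuple[str, ...]
    loglik: float
    scale: float | None = None
    baseline: pd.Series | None = None
    flagged: bool = False
    flag_reason: str = ""
    _fitter: object = field(default=None, repr=False)


def _check_cohort(cohort: pd.DataFrame, covariates) -> None:
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if (cohort["observed_time"] <= 0).any():
        raise ValueError("observed_time must be positive")
    if cohort.loc[:, list(covariates)].isna().any().any():
        raise ValueError("NaN in covariates")


def fit_logistic_ever_never(cohort: pd.DataFrame,
                            covariates=("group2",)) -> SurvFit:
    """Logistic regression of the ever/never event indicator.

    The outcome is 'event observed by the (already applied) censoring
    time'; follow-up duration is ignored, so censored subjects count as
    never-diagnosed — the classification framing whose bias the audit
    quantifies.
    """
    _check_cohort(cohort, covariates)
    y = cohort["event"].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    Z = sm.add_constant(cohort.loc[:, list(covariates)].to_numpy(float))
    flagged, reason = False, ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Z).fit(disp=0, maxiter=100)
            params = np.asarray(res.params, float)
            llf = float(res.llf)
            if not res.mle_retvals.get("converged", True) or np.abs(params).max() > 15:
                flagged, reason = True, "possible separation / non-convergence"
        except Exception as exc:  # perfect separation raises in statsmodels
            flagged, reason = True, f"separation: {exc}"
            res = sm.Logit(y, Z).fit_regularized(disp=0, alpha=1e-6, maxiter=200)
            params = np.asarray(res.params, float)
            llf = float(res.llf) if np.isfinite(res.llf) else np.nan
    names = ["const"] + list(covariates)
    if flagged:
        logger.warning("logistic ever/never fit flagged: %s", reason)
    return SurvFit(
        model_kind="logistic_ever_never",
        coefficients=pd.Series(params, index=names),
        covariates=tuple(covariates), loglik=llf,
        flagged=flagged, flag_reason=reason,
    )


def fit_cox_ph(cohort: pd.DataFrame, covariates=("group2",)) -> SurvFit:
    """Cox proportional hazards with Breslow baseline cumulative hazard."""
    _check_cohort(cohort, covariates)
    if cohort["event"].sum() == 0:
        raise ValueError("no events observed; Cox model is degenerate")
    df = cohort.loc[:, ["observed_time", "event", *covariates]]
    cph = CoxPHFitter(baseline_estimation_method="breslow")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="observed_time", event_col="event")
    baseline = cph.baseline_cumulative_hazard_["baseline cumulative hazard"]
    return SurvFit(
        model_kind="cox_ph",
        coefficients=cph.params_.copy(),
        covariates=tuple(covariates),
        loglik=float(cph.log_likelihood_),
        baseline=baseline,
        _fitter=cph,
    )


def fit_lognormal_aft(cohort: pd.DataFrame, covariates=("group2",)) -> SurvFit:
    """Censored log-normal AFT model: ln T = beta' x + sigma * eps."""
    _check_cohort(cohort, covariates)
    if cohort["event"].sum() == 0:
        raise ValueError("no events observed; AFT model is degenerate")
    df = cohort.loc[:, ["observed_time", "event", *covariates]]
    aft = LogNormalAFTFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aft.fit(df, duration_col="observed_time", event_col="event", ancillary=False)
    coefs = aft.params_.loc["mu_"].copy()
    sigma = float(np.exp(aft.params_.loc[("sigma_", "Intercept")]))
    return SurvFit(
        model_kind="lognormal_aft",
        coefficients=coefs,
        covariates=tuple(covariates),
        loglik=float(aft.log_likelihood_),
        scale=sigma,
        _fitter=aft,
    )


def _linear_predictor(fit: SurvFit, covariate_row: pd.Series | dict) -> float:
    x = np.array([float(covariate_row[c]) for c in fit.covariates])
    return float(np.dot(fit.coefficients.loc[list(fit.covariates)].to_numpy(), x))


def predict_diag_prob(fit: SurvFit | CureFit, covariate_row, t_c: float) -> float:
    """Predicted probability of diagnosis by horizon ``t_c``.

    Cox / AFT fits return ``1 - S(t_c | x)``; the ever/never logistic fit
    returns its fitted class probability and the mixture cure fit its
    incidence pi(z) — both independent of ``t_c``.
    """
    if not (t_c > 0):
        raise ValueError(f"t_c must be positive, got {t_c!r}")
    if isinstance(fit, CureFit):
        row = pd.DataFrame([dict(covariate_row)])
        return float(predict_incidence(fit, row)[0])
    if fit.model_kind == "logistic_ever_never":
        lin = float(fit.coefficients["const"]) + _linear_predictor(fit, covariate_row)
        return float(1.0 / (1.0 + np.exp(-lin)))
    if fit.model_kind == "cox_ph":
        times = fit.baseline.index.to_numpy(float)
        values = fit.baseline.to_numpy(float)
        if t_c > times[-1]:
            logger.info("t_c=%.3g beyond Cox baseline support %.3g; carrying last value",
                        t_c, times[-1])
        idx = np.searchsorted(times, t_c, side="right") - 1
        H0 = values[idx] if idx >= 0 else 0.0
        # lifelines' Breslow baseline is reported at the covariate mean;
        # shift the linear predictor accordingly
        mean_lin = float(np.dot(
            fit.coefficients.loc[list(fit.covariates)].to_numpy(),
            fit._fitter._norm_mean.loc[list(fit.covariates)].to_numpy(),
        ))
        lin = _linear_predictor(fit, covariate_row) - mean_lin
        return float(1.0 - np.exp(-H0 * np.exp(lin)))
    if fit.model_kind == "lognormal_aft":
        mu = float(fit.coefficients["Intercept"]) + _linear_predictor(fit, covariate_row)
        from scipy.special import ndtr
        return float(ndtr((np.log(t_c) - mu) / fit.scale))
    raise ValueError(f"unknown model kind {fit.model_kind!r}")


@dataclass
class KMCurve:
    """One Kaplan-Meier product-limit curve (optionally for one stratum)."""

    times: np.ndarray          # increasing, starting at 0
    survival: np.ndarray       # nonincreasing, survival[0] == 1
    at_risk: np.ndarray
    n_events: np.ndarray
    group: object = None

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "survival": self.survival,
            "n_risk": self.at_risk, "n_event": self.n_events,
            "group": self.group,
        })


def kaplan_meier(cohort: pd.DataFrame, by_group: bool = False):
    """Kaplan-Meier estimate of survival; one curve per group if asked."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if by_group:
        return [
            _km_single(sub, group=g)
            for g, sub in cohort.groupby("group", sort=True)
        ]
    return _km_single(cohort)


def _km_single(cohort: pd.DataFrame, group=None) -> KMCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(cohort["observed_time"], cohort["event"])
    tab = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    times = tab.index.to_numpy(float)
    return KMCurve(
        times=times,
        survival=surv.to_numpy(float),
        at_risk=tab["at_risk"].to_numpy(int),
        n_events=tab["observed"].to_numpy(int),
        group=group,
    )
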