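"""Maximum-likelihood mixture cure model: logistic incidence x log-normal latency.

The population survival function is

    S_pop(t | x, z) = 1 - pi(z) + pi(z) * S(t | x)

where pi(z) = expit(gamma' z) is the probability of belonging to the
susceptible ("uncured") subpopulation — the *incidence* — and
S(t | x) = 1 - Phi((ln t - beta' x) / sigma) is the log-normal survival of
the susceptible — the *latency*.  For prediction of whether (not when) a
diagnosis occurs, the incidence pi(z) itself is the predicted diagnosis
probability; unlike plain time-to-event predictors it does not depend on
any censoring horizon.

Estimation maximizes the observed-data censored likelihood directly
(quasi-Newton with analytic gradient and multi-start), rather than EM:
the problem is low-dimensional and smooth, and direct maximization gives
simpler convergence diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, log_expit, ndtr, log_ndtr

logger = logging.getLogger(__name__)

__all__ = [
    "CureDesign",
    "CureFit",
    "FitOptions",
    "DegenerateDataError",
    "cure_loglik",
    "cure_loglik_grad",
    "fit_mixture_cure",
    "predict_incidence",
    "population_survival",
]

_EPS = 1e-12
_LOG_EPS = np.log(_EPS)


class DegenerateDataError(ValueError):
    """Data cannot identify the model (e.g. no events observed)."""


@dataclass(frozen=True)
class CureDesign:
    """Covariate lists for the two model components.

    ``incidence_covariates`` (z) enter the logistic susceptibility model,
    ``latency_covariates`` (x) the log-normal event-time model.  An
    intercept is always prepended to both; the lists may be empty for
    intercept-only components, and may overlap.
    """

    incidence_covariates: tuple[str, ...] = ()
    latency_covariates: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "incidence_covariates", tuple(self.incidence_covariates))
        object.__setattr__(self, "latency_covariates", tuple(self.latency_covariates))

    @property
    def n_params(self) -> int:
        return len(self.incidence_covariates) + len(self.latency_covariates) + 3

    def matrices(self, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Build (Z, X) design matrices with leading intercept columns."""
        n = len(data)
        ones = np.ones((n, 1))
        def mat(cols):
            if not cols:
                return ones
            block = data.loc[:, list(cols)].to_numpy(float)
            if np.isnan(block).any():
                raise ValueError(f"NaN in covariates {cols}")
            return np.hstack([ones, block])
        return mat(self.incidence_covariates), mat(self.latency_covariates)


@dataclass
class CureFit:
    """Fitted mixture cure parameters and diagnostics.

    ``gamma`` are incidence coefficients on the logit scale, ``beta``
    latency location coefficients on the log-time scale, ``log_sigma``
    the log latency scale.  ``covariance`` (when available) is the
    inverse observed information for the stacked parameter vector
    (gamma, beta, log_sigma).
    """

    design: CureDesign
    gamma: np.ndarray
    beta: np.ndarray
    log_sigma: float
    loglik: float
    converged: bool
    n_iter: int
    covariance: np.ndarray | None = None
    start_logliks: list = field(default_factory=list)
    message: str = ""

    @property
    def sigma(self) -> float:
        return float(np.exp(self.log_sigma))

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.gamma, self.beta, [self.log_sigma]])

    def standard_errors(self) -> np.ndarray | None:
        if self.covariance is None:
            return None
        return np.sqrt(np.diag(self.covariance))

    def to_json_dict(self) -> dict:
        return {
            "gamma": self.gamma.tolist(),
            "beta": self.beta.tolist(),
            "log_sigma": self.log_sigma,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "covariance": None if self.covariance is None else self.covariance.ravel().tolist(),
            "design": {
                "incidence_covariates": list(self.design.incidence_covariates),
                "latency_covariates": list(self.design.latency_covariates),
            },
        }


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for :func:`fit_mixture_cure`."""

    n_restarts: int = 4          # jittered restarts beyond the data-driven start
    jitter_scale: float = 0.5
    seed: int = 0
    gtol: float = 1e-6
    ftol: float = 1e-11
    maxiter: int = 500
    compute_covariance: bool = True
    init_params: np.ndarray | None = None  # warm start; skips restarts if given


def _unpack(params: np.ndarray, kz: int, kx: int):
    gamma = params[:kz]
    beta = params[kz:kz + kx]
    log_sigma = params[kz + kx]
    return gamma, beta, log_sigma


def _prepare(data: pd.DataFrame, design: CureDesign):
    t = data["observed_time"].to_numpy(float)
    d = data["event"].to_numpy()
    if np.any(t <= 0) or np.any(~np.isfinite(t)):
        raise ValueError("observed_time must be positive and finite")
    if not np.isin(d, (0, 1)).all():
        raise ValueError("event must be 0/1")
    Z, X = design.matrices(data)
    return t, d.astype(bool), Z, X


def cure_loglik(params: np.ndarray, data: pd.DataFrame, design: CureDesign) -> float:
    """Observed-data log-likelihood of the mixture cure model.

    Events contribute ``ln pi(z) + ln f(t|x)`` with f the log-normal
    density; censored subjects contribute ``ln[1 - pi(z) + pi(z) S(t|x)]``.
    Guarded so the value is finite for any finite parameter vector.
    """
    t, d, Z, X = _prepare(data, design)
    return _loglik_core(np.asarray(params, float), t, d, Z, X)[0]


def cure_loglik_grad(params: np.ndarray, data: pd.DataFrame, design: CureDesign) -> np.ndarray:
    """Analytic gradient of :func:`cure_loglik` in (gamma, beta, log_sigma)."""
    t, d, Z, X = _prepare(data, design)
    return _loglik_core(np.asarray(params, float), t, d, Z, X, grad=True)[1]


def _loglik_core(params, t, d, Z, X, grad: bool = False):
    kz, kx = Z.shape[1], X.shape[1]
    gamma, beta, log_sigma = _unpack(params, kz, kx)
    sigma = np.exp(log_sigma)
    eta = Z @ gamma
    log_t = np.log(t)
    u = (log_t - X @ beta) / sigma

    ll = np.empty(len(t))
    # events: ln pi + standard-normal logpdf(u) - ln sigma - ln t
    ll[d] = (log_expit(eta[d])
             - 0.5 * u[d] ** 2 - 0.5 * np.log(2 * np.pi) - log_sigma - log_t[d])
    # censored: ln(1 - pi * F(u)) with F the lognormal CDF, via log1p
    pi_c = expit(eta[~d])
    F_c = ndtr(u[~d])
    piF = np.clip(pi_c * F_c, 0.0, 1.0 - _EPS)
    ll[~d] = np.log1p(-piF)
    total = float(np.sum(np.maximum(ll, _LOG_EPS * 10)))  # guard -inf

    if not grad:
        return total, None

    g = np.zeros(kz + kx + 1)
    # event terms
    pi_e = expit(eta[d])
    g[:kz] += Z[d].T @ (1.0 - pi_e)
    g[kz:kz + kx] += X[d].T @ (u[d] / sigma)
    g[-1] += np.sum(u[d] ** 2 - 1.0)
    # censored terms: Spop = 1 - pi*F;  d ln Spop = -d(pi F)/Spop
    phi_c = np.exp(-0.5 * u[~d] ** 2) / np.sqrt(2 * np.pi)
    Spop = 1.0 - piF
    g[:kz] += Z[~d].T @ (-(pi_c * (1 - pi_c) * F_c) / Spop)
    # dF/dbeta = -phi(u) x / sigma ; d(-pi F)/dbeta = pi phi x / sigma
    g[kz:kz + kx] += X[~d].T @ ((pi_c * phi_c / sigma) / Spop)
    # dF/dlog_sigma = phi(u) * (-u)  -> contribution pi phi u / Spop
    g[-1] += np.sum((pi_c * phi_c * u[~d]) / Spop)
    return total, g


def _initial_params(t, d, Z, X, rng, n_restarts, jitter_scale):
    """Data-driven start: logistic ever/never for gamma, events-only
    log-normal moments for (beta, sigma); plus jittered restarts."""
    kz, kx = Z.shape[1], X.shape[1]
    # gamma: least-squares on the logit of a smoothed event indicator
    p0 = np.clip(d.mean(), 0.05, 0.95)
    gamma0 = np.zeros(kz)
    gamma0[0] = np.log(p0 / (1 - p0))
    try:
        import statsmodels.api as sm

        res = sm.Logit(d.astype(float), Z).fit(disp=0, maxiter=50)
        if np.all(np.isfinite(res.params)):
            gamma0 = np.asarray(res.params, float)
    except Exception:  # separation etc.: keep the moment start
        pass
    # beta, sigma from events only
    beta0 = np.zeros(kx)
    log_te = np.log(t[d])
    if len(log_te) >= 2:
        Xe = X[d]
        beta0, *_ = np.linalg.lstsq(Xe, log_te, rcond=None)
        resid = log_te - Xe @ beta0
        s0 = max(float(np.std(resid)), 0.05)
    else:
        beta0[0] = float(np.median(log_te)) if len(log_te) else 0.0
        s0 = 0.5
    base = np.concatenate([gamma0, beta0, [np.log(s0)]])
    starts = [base]
    for _ in range(n_restarts):
        starts.append(base + rng.normal(0.0, jitter_scale, size=len(base)))
    return starts


def _numerical_hessian(fun, x0, eps=1e-5):
    k = len(x0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            hi = np.zeros(k); hi[i] = eps
            hj = np.zeros(k); hj[j] = eps
            H[i, j] = H[j, i] = (
                fun(x0 + hi + hj) - fun(x0 + hi - hj)
                - fun(x0 - hi + hj) + fun(x0 - hi - hj)
            ) / (4 * eps * eps)
    return H


def fit_mixture_cure(data: pd.DataFrame, design: CureDesign,
                     options: FitOptions | None = None) -> CureFit:
    """Fit the mixture cure model by direct likelihood maximization.

    Requires at least one event and at least one censored observation;
    with no events the incidence component is unidentifiable.  Multi-start
    L-BFGS-B with a data-driven initial point; the returned fit carries
    every start's achieved log-likelihood so start-robustness can be
    checked.  Never raises on non-convergence — ``converged`` is False.
    """
    opts = options or FitOptions()
    t, d, Z, X = _prepare(data, design)
    if d.sum() == 0:
        raise DegenerateDataError("no events observed; incidence is unidentifiable")
    if d.all():
        raise DegenerateDataError("no censored observations; cure fraction is unidentifiable")

    def nll(p):
        val, g = _loglik_core(p, t, d, Z, X, grad=True)
        return -val, -g

    rng = np.random.default_rng(opts.seed)
    if opts.init_params is not None:
        starts = [np.asarray(opts.init_params, float)]
    else:
        starts = _initial_params(t, d, Z, X, rng, opts.n_restarts, opts.jitter_scale)

    best = None
    start_lls = []
    total_iter = 0
    for s in starts:
        res = optimize.minimize(
            nll, s, jac=True, method="L-BFGS-B",
            options={"maxiter": opts.maxiter, "ftol": opts.ftol, "gtol": opts.gtol},
        )
        start_lls.append(-res.fun)
        total_iter += res.nit
        if best is None or -res.fun > -best.fun:
            best = res

    kz, kx = Z.shape[1], X.shape[1]
    gamma, beta, log_sigma = _unpack(best.x, kz, kx)
    grad_norm = float(np.max(np.abs(best.jac)))
    converged = bool(best.success or grad_norm < 1e-3 * max(1.0, len(t) / 100))

    cov = None
    if opts.compute_covariance:
        H = _numerical_hessian(lambda p: -_loglik_core(p, t, d, Z, X)[0], best.x)
        try:
            cov = np.linalg.inv(H)
            if np.any(np.diag(cov) <= 0):
                cov = None
        except np.linalg.LinAlgError:
            cov = None

    fit = CureFit(
        design=design, gamma=gamma.copy(), beta=beta.copy(),
        log_sigma=float(log_sigma), loglik=float(-best.fun),
        converged=converged, n_iter=int(total_iter),
        covariance=cov, start_logliks=start_lls, message=str(best.message),
    )
    _check_identifiability(fit, t, X)
    return fit


def _check_identifiability(fit: CureFit, t, X) -> None:
    # cure fraction and late survival confound when follow-up ends before
    # the latency distribution's bulk
    fitted_median = float(np.exp(np.median(X @ fit.beta)))
    if t.max() < fitted_median:
        logger.warning(
            "identifiability: max observed time %.3g is below the fitted "
            "latency median %.3g; cure fraction and late survival are "
            "weakly separated", t.max(), fitted_median,
        )


def predict_incidence(fit: CureFit, data: pd.DataFrame) -> np.ndarray:
    """Predicted diagnosis probability pi(z) = expit(gamma' z) per row.

    This is the horizon-free quantity of interest: it does not depend on
    any administrative censoring time.  Refuses unconverged fits.
    """
    if not fit.converged:
        raise RuntimeError(
            f"refusing to predict from unconverged fit (message: {fit.message})"
        )
    Z, _ = fit.design.matrices(data)
    return expit(Z @ fit.gamma)


def population_survival(t, data: pd.DataFrame, fit: CureFit) -> np.ndarray:
    """S_pop(t|x,z) = 1 - pi(z) + pi(z) S(t|x); bounded in [1 - pi, 1]."""
    t = np.asarray(t, float)
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    Z, X = fit.design.matrices(data)
    pi = expit(Z @ fit.gamma)
    u = (np.log(t) - X @ fit.beta) / fit.sigma
    S = ndtr(-u)
    return 1.0 - pi + pi * S
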