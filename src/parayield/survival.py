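"""Kaplan-Meier estimation and censored Weibull accelerated-failure-time regression.

The AFT model is log T = mu + x'beta + sigma*W with W standard minimum
Gumbel, so T is Weibull with shape 1/sigma and scale exp(mu + x'beta).
Coefficients are log-time shifts: negative beta shortens survival.  For a
Weibull AFT the proportional-hazards representation gives the hazard ratio
for a coefficient as exp(-beta/sigma), the transformation used to report
treatment effects on the hazard scale.

Fitting maximizes the right-censored log likelihood
``sum_events log f(t) + sum_censored log S(t)`` by Newton iteration with
backtracking line search on (beta, log sigma), initialized from least
squares on log times; the observed-information inverse supplies the
covariance of the estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import LONG_DAY, PYR_01, PYR_10, cell_label

__all__ = [
    "SurvivalSample",
    "KMCurve",
    "AFTFit",
    "ConvergenceError",
    "build_survival_sample",
    "km_fit",
    "fit_weibull_aft",
    "aft_lrt",
    "hazard_ratios",
    "aft_fit_from_estimates",
    "weibull_aft_loglik",
]

DEFAULT_LEVELS = (PYR_10, PYR_01, LONG_DAY)


class ConvergenceError(RuntimeError):
    """The likelihood optimizer failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class SurvivalSample:
    """Times, event indicators and a named 0/1 design matrix (no intercept)."""

    times: np.ndarray
    events: np.ndarray
    design_matrix: pd.DataFrame
    referent: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if not (len(self.times) == len(self.events) == len(self.design_matrix)):
            raise ValueError("times, events and design_matrix lengths differ")
        if np.any(self.times <= 0):
            raise ValueError("all times must be positive")


def build_survival_sample(
    subjects: pd.DataFrame,
    collection: str | None = None,
    levels: tuple[str, ...] = DEFAULT_LEVELS,
    sex: str | None = "f",
) -> SurvivalSample:
    """Assemble an AFT sample from a subjects table.

    Only females enter the analysis by default (the study models female
    survival; males are reared alongside as mates).  ``levels`` name the
    indicator columns; insects matching none of them form the referent cell.
    """
    df = subjects
    if collection is not None:
        df = df[df["collection"] == collection]
    if sex is not None:
        df = df[df["sex"] == sex]
    df = df.reset_index(drop=True)
    X = pd.DataFrame(
        {
            lvl: (
                (df["chemical"] == lvl)
                | (df["photoperiod"] == lvl)
                | (df["collection"] == lvl)
            ).astype(float)
            for lvl in levels
        }
    )
    chems = [c for c in df["chemical"].unique() if c not in levels]
    photos = [p for p in df["photoperiod"].unique() if p not in levels]
    referent = cell_label(chems[0], photos[0]) if chems and photos else ""
    return SurvivalSample(
        times=df["time_days"].to_numpy(),
        events=df["event"].to_numpy(),
        design_matrix=X,
        referent=referent,
    )


# ------------------------------ Kaplan-Meier ------------------------------


@dataclass
class KMCurve:
    """Product-limit survival estimate with Greenwood standard errors."""

    event_times: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    median: float | None
    median_ci: tuple[float | None, float | None]
    n: int


def km_fit(times, events, alpha: float = 0.05) -> KMCurve:
    """Kaplan-Meier estimate with a log(-log) median confidence interval.

    Ties are resolved deaths-before-censorings.  The median is the earliest
    time where the curve drops to 0.5 or below; its CI inverts the pointwise
    log(-log)-transformed confidence band (the convention of standard
    survival software).  If the curve never reaches 0.5 the median is None
    (flagged, not an error).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.lexsort((1 - events, times))  # deaths first at tied times
    times, events = times[order], events[order]
    n = len(times)

    uniq = np.unique(times[events == 1])
    surv, var_sum, se = [], 0.0, []
    s = 1.0
    for t in uniq:
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / at_risk
        if at_risk > d:
            var_sum += d / (at_risk * (at_risk - d))
        surv.append(s)
        # Greenwood: Var(S) = S^2 * sum d/(r(r-d))
        se.append(s * np.sqrt(var_sum) if s > 0 else 0.0)
    surv = np.asarray(surv)
    se = np.asarray(se)

    z = stats.norm.ppf(1 - alpha / 2)
    lo_band = np.full_like(surv, np.nan)
    hi_band = np.full_like(surv, np.nan)
    inside = (surv > 0) & (surv < 1)
    if inside.any():
        s_in = surv[inside]
        # SE on the log(-log S) scale by the delta method
        se_loglog = se[inside] / (np.abs(np.log(s_in)) * s_in)
        theta = np.exp(z * se_loglog)
        lo_band[inside] = s_in ** theta
        hi_band[inside] = s_in ** (1 / theta)
    lo_band[surv == 0] = 0.0
    hi_band[surv == 0] = 0.0

    def first_crossing(values: np.ndarray) -> float | None:
        idx = np.where(values <= 0.5 + 1e-10)[0]
        return float(uniq[idx[0]]) if idx.size else None

    median = first_crossing(surv)
    with np.errstate(invalid="ignore"):
        ci_lo = first_crossing(np.where(np.isnan(lo_band), np.inf, lo_band))
        ci_hi = first_crossing(np.where(np.isnan(hi_band), np.inf, hi_band))
    return KMCurve(
        event_times=uniq,
        survival=surv,
        greenwood_se=se,
        median=median,
        median_ci=(ci_lo, ci_hi),
        n=n,
    )


# ------------------------------ Weibull AFT -------------------------------


@dataclass
class AFTFit:
    """MLE of the censored Weibull AFT model.

    ``coefficients`` maps "intercept" and each design column to its
    log-time shift; ``log_scale`` is log(sigma).  ``vcov`` is the inverse
    observed information over (coefficients..., log_scale) with
    ``param_names`` giving the row order.
    """

    coefficients: dict[str, float]
    log_scale: float
    se: dict[str, float]
    vcov: np.ndarray
    param_names: list[str]
    loglik: float
    null_loglik: float
    n: int
    n_events: int
    referent: str = ""
    dropped: list[str] = field(default_factory=list)

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale))


def weibull_aft_loglik(theta: np.ndarray, t: np.ndarray, d: np.ndarray, X: np.ndarray) -> float:
    """Censored Weibull AFT log likelihood at theta = (beta..., log sigma)."""
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    w = (np.log(t) - X @ beta) / sigma
    z = np.exp(w)
    return float(np.sum(d * (-log_sigma - np.log(t) + w) - z))


def _grad_hess(theta: np.ndarray, t: np.ndarray, d: np.ndarray, X: np.ndarray):
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    w = (np.log(t) - X @ beta) / sigma
    z = np.exp(w)
    p = X.shape[1]

    g = np.empty(p + 1)
    g[:p] = X.T @ (z - d) / sigma
    g[p] = np.sum(-d + (z - d) * w)

    H = np.empty((p + 1, p + 1))
    H[:p, :p] = -(X.T * z) @ X / sigma**2
    cross = -(X.T @ (z * w + z - d)) / sigma
    H[:p, p] = H[p, :p] = cross
    H[p, p] = np.sum(-z * w**2 - (z - d) * w)
    return g, H


def _newton_aft(t, d, X, theta0, max_iter=200, tol=1e-8, trace=None):
    theta = theta0.copy()
    ll = weibull_aft_loglik(theta, t, d, X)
    for it in range(max_iter):
        g, H = _grad_hess(theta, t, d, X)
        if trace is not None:
            trace.append((it, ll, float(np.max(np.abs(g)))))
        if np.max(np.abs(g)) < tol:
            return theta, ll, H
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            step = g / max(np.max(np.abs(g)), 1.0)
        # Ensure an ascent direction; fall back to gradient if Newton fails.
        if g @ step <= 0:
            step = g / max(np.max(np.abs(g)), 1.0)
        if np.max(np.abs(g)) < 1e-3:
            # local region: pure Newton converges quadratically, and the
            # log likelihood can no longer resolve the improvement
            theta = theta + step
            ll = weibull_aft_loglik(theta, t, d, X)
            continue
        alpha_ls = 1.0
        for _ in range(60):
            cand = theta + alpha_ls * step
            ll_new = weibull_aft_loglik(cand, t, d, X)
            if np.isfinite(ll_new) and ll_new > ll - 1e-13:
                break
            alpha_ls *= 0.5
        else:
            break
        theta, ll = cand, ll_new
    g, H = _grad_hess(theta, t, d, X)
    if np.max(np.abs(g)) < 1e-6:  # looser but still tight; report anyway
        return theta, ll, H
    return None


def fit_weibull_aft(sample: SurvivalSample) -> AFTFit:
    """Maximum-likelihood censored Weibull AFT fit.

    Identically-zero design columns are dropped and reported as aliased
    (their level is absent from the data); any other rank deficiency raises
    naming the offending column.  Non-convergence after the Newton pass and
    a derivative-free restart raises :class:`ConvergenceError` with the
    iteration trace.
    """
    t = sample.times
    d = sample.events.astype(float)
    if d.sum() < 1:
        raise ValueError("AFT fit requires at least one observed event")
    Xdf = sample.design_matrix
    dropped = [c for c in Xdf.columns if (Xdf[c] == 0).all()]
    Xdf = Xdf.drop(columns=dropped)
    names = list(Xdf.columns)
    X = np.column_stack([np.ones(len(t)), Xdf.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"design matrix is rank deficient (aliased among {names})")

    def fit_one(Xmat: np.ndarray):
        # init: least squares of log t ignoring censoring; Gumbel sd = sigma*pi/sqrt(6)
        logt = np.log(t)
        beta0, *_ = np.linalg.lstsq(Xmat, logt, rcond=None)
        resid = logt - Xmat @ beta0
        sigma0 = max(np.std(resid) * np.sqrt(6) / np.pi, 1e-2)
        theta0 = np.append(beta0, np.log(sigma0))
        trace: list = []
        res = _newton_aft(t, d, Xmat, theta0, trace=trace)
        if res is None:
            # Derivative-free restart, then a Newton polish
            nm = optimize.minimize(
                lambda th: -weibull_aft_loglik(th, t, d, Xmat),
                theta0,
                method="Nelder-Mead",
                options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12},
            )
            res = _newton_aft(t, d, Xmat, nm.x, trace=trace)
        if res is None:
            raise ConvergenceError("Weibull AFT fit did not converge", trace)
        return res

    theta, ll, H = fit_one(X)
    vcov = np.linalg.inv(-H)
    _, ll_null, _ = fit_one(np.ones((len(t), 1)))

    param_names = ["intercept", *names, "log_scale"]
    coefficients = {"intercept": float(theta[0])}
    coefficients.update({nm: float(b) for nm, b in zip(names, theta[1:-1])})
    se_vals = np.sqrt(np.diag(vcov))
    se = {nm: float(s) for nm, s in zip(param_names, se_vals)}
    return AFTFit(
        coefficients=coefficients,
        log_scale=float(theta[-1]),
        se=se,
        vcov=vcov,
        param_names=param_names,
        loglik=float(ll),
        null_loglik=float(ll_null),
        n=len(t),
        n_events=int(d.sum()),
        referent=sample.referent,
        dropped=dropped,
    )


def aft_fit_from_estimates(
    coefficients: dict[str, float],
    log_scale: float,
    se: dict[str, float] | None = None,
    referent: str = "",
) -> AFTFit:
    """AFT fit container built from a published coefficient table.

    Off-diagonal covariances are unavailable in print, so the vcov is
    diagonal from the published SEs (zeros when no SEs are given).
    """
    se = dict(se or {})
    names = [*coefficients.keys(), "log_scale"]
    variances = [se.get(nm, 0.0) ** 2 for nm in names]
    return AFTFit(
        coefficients=dict(coefficients),
        log_scale=log_scale,
        se={nm: se.get(nm, 0.0) for nm in names},
        vcov=np.diag(variances),
        param_names=names,
        loglik=np.nan,
        null_loglik=np.nan,
        n=0,
        n_events=0,
        referent=referent,
    )


def aft_lrt(fit: AFTFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of the full AFT model against intercept-only."""
    chi2 = 2.0 * (fit.loglik - fit.null_loglik)
    df = sum(1 for nm in fit.coefficients if nm != "intercept")
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), df, p


def hazard_ratios(fit: AFTFit, alpha: float = 0.05) -> pd.DataFrame:
    """Hazard ratios exp(-beta/sigma) per coefficient, with delta-method CIs.

    The log hazard ratio g = -beta * exp(-log sigma) has gradient
    (-1/sigma, beta/sigma) with respect to (beta, log sigma); the CI
    exponentiates the normal interval on g using the fit's covariance.
    """
    sigma = fit.scale
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = stats.norm.ppf(1 - alpha / 2)
    idx = {nm: i for i, nm in enumerate(fit.param_names)}
    i_ls = idx["log_scale"]
    rows = []
    for nm, beta in fit.coefficients.items():
        if nm == "intercept":
            continue
        g = -beta / sigma
        i_b = idx[nm]
        grad = np.zeros(len(fit.param_names))
        grad[i_b] = -1.0 / sigma
        grad[i_ls] = beta / sigma
        var_g = float(grad @ fit.vcov @ grad)
        se_g = np.sqrt(max(var_g, 0.0))
        rows.append(
            {
                "factor": nm,
                "hr": float(np.exp(g)),
                "lo": float(np.exp(g - z * se_g)),
                "hi": float(np.exp(g + z * se_g)),
                "referent": fit.referent,
            }
        )
    return pd.DataFrame(rows)
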