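"""Egg-production inference: negative-binomial GLM and hurdle variant.

Container egg totals are modeled as NB2 with log link: counts y have mean
mu = exp(x'beta) and variance mu + mu^2/theta.  beta is fit by Fisher-scoring
IRLS alternated with 1-D profile maximum likelihood for theta; the reported
covariance is the inverse observed information at the MLE (conditional on
theta, the convention of standard NB GLM software).

Cells of repeated zero counts (short-day acetone insects never lay) break
the NB fit — the zero cell's log-mean diverges — and raise an explicit
under-dispersion error recommending the hurdle variant, which models the
zero/positive split with a binomial logit and the positive counts with a
zero-truncated NB.

Term-level F tests, estimated marginal means and Tukey-adjusted pairwise
contrasts (with compact letter display) are provided for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .design import LONG_DAY, PYR_01, PYR_10, SHORT_DAY, cell_label
from .posthoc import EMMResult, emm_from_linear

__all__ = [
    "CountSample",
    "NBFit",
    "HurdleFit",
    "UnderdispersionError",
    "build_count_sample",
    "fit_nb_glm",
    "fit_hurdle_nb",
    "term_f_tests",
    "emm_counts",
    "nb_loglik",
    "truncated_nb_mean",
    "eggs_per_female_day",
]

DEFAULT_LEVELS = (PYR_10, PYR_01, SHORT_DAY)


class UnderdispersionError(RuntimeError):
    """The plain NB model cannot represent the data (e.g. an all-zero cell);
    the hurdle model is the recommended remedy."""


@dataclass
class CountSample:
    counts: np.ndarray
    design_matrix: pd.DataFrame
    referent: str = ""
    cell_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != len(self.design_matrix):
            raise ValueError("counts and design_matrix lengths differ")
        if np.any(self.counts < 0) or np.any(self.counts != np.round(self.counts)):
            raise ValueError("counts must be non-negative integers")


def build_count_sample(
    containers: pd.DataFrame,
    collection: str | None = None,
    levels: tuple[str, ...] = DEFAULT_LEVELS,
    drop_all_zero_cells: bool = False,
) -> CountSample:
    """Assemble a count sample from a containers table.

    Indicator columns are 1 when the container's chemical, photoperiod or
    collection matches the level; containers matching no level form the
    referent (long-day acetone by default).  ``drop_all_zero_cells``
    excludes treatment cells whose every replicate is zero before the plain
    NB fit (the workaround used before switching to the hurdle model).
    """
    df = containers
    if collection is not None:
        df = df[df["collection"] == collection]
    df = df.reset_index(drop=True)
    cells = [cell_label(c, p) for c, p in zip(df["chemical"], df["photoperiod"])]
    if drop_all_zero_cells:
        totals = df.groupby([df["chemical"], df["photoperiod"]])["total_eggs"].max()
        dead = {cell_label(c, p) for (c, p), m in totals.items() if m == 0}
        keep = [i for i, cl in enumerate(cells) if cl not in dead]
        df = df.iloc[keep].reset_index(drop=True)
        cells = [cl for cl in cells if cl not in dead]
    match_cols = ["chemical", "photoperiod", "collection"]
    X = pd.DataFrame(
        {
            lvl: df[match_cols].isin([lvl]).any(axis=1).astype(float)
            for lvl in levels
        }
    )
    return CountSample(
        counts=df["total_eggs"].to_numpy(),
        design_matrix=X,
        referent=cell_label("acetone", LONG_DAY),
        cell_labels=cells,
    )


def nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 log likelihood (sum over observations)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * (np.log(theta) - np.log(theta + mu))
            + special.xlogy(y, mu)
            - special.xlogy(y, theta + mu)
        )
    )


def truncated_nb_mean(mu: float, theta: float) -> float:
    """Mean of the zero-truncated NB: mu / (1 - P(Y=0))."""
    p0 = (theta / (theta + mu)) ** theta
    return mu / (1.0 - p0)


@dataclass
class NBFit:
    coefficients: dict[str, float]
    se: dict[str, float]
    vcov: np.ndarray
    param_names: list[str]
    theta: float
    loglik: float
    n: int
    df_resid: int
    dispersion: float              # Pearson X^2 / (n - p)
    referent: str = ""
    dropped: list[str] = field(default_factory=list)
    _X: np.ndarray | None = field(default=None, repr=False)
    _y: np.ndarray | None = field(default=None, repr=False)

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.coefficients[nm] for nm in self.param_names])


THETA_MIN, THETA_MAX = 1e-3, 1e6


def _nb_irls(y: np.ndarray, X: np.ndarray, theta: float, beta0: np.ndarray, max_iter=100, tol=1e-10):
    beta = beta0.copy()
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        W = mu * theta / (theta + mu)
        zwork = eta + (y - mu) / mu
        XtW = X.T * W
        beta_new = np.linalg.solve(XtW @ X, XtW @ zwork)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


def _profile_theta(y: np.ndarray, mu: np.ndarray) -> float:
    res = optimize.minimize_scalar(
        lambda lt: -nb_loglik(y, mu, np.exp(lt)),
        bounds=(np.log(THETA_MIN), np.log(THETA_MAX)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x))


def fit_nb_glm(sample: CountSample, theta: float | None = None) -> NBFit:
    """NB2 GLM maximum likelihood fit (log link).

    ``theta`` fixes the dispersion (used for nested refits in F tests);
    by default theta is profiled out by 1-D maximum likelihood, bounded in
    [1e-3, 1e6] (the upper bound is effectively the Poisson limit).
    """
    y = sample.counts
    if np.all(y == 0):
        raise UnderdispersionError(
            "all counts are zero: the NB model is degenerate (under-dispersion); "
            "use the hurdle model (fit_hurdle_nb)"
        )
    if sample.cell_labels:
        per_cell = pd.Series(y).groupby(pd.Series(sample.cell_labels)).max()
        zero_cells = list(per_cell.index[per_cell == 0])
        if zero_cells:
            raise UnderdispersionError(
                f"treatment cell(s) {zero_cells} contain only zero counts, which the "
                "NB model cannot represent (under-dispersion); use the hurdle model "
                "(fit_hurdle_nb) or drop the cell(s)"
            )
    Xdf = sample.design_matrix
    dropped = [c for c in Xdf.columns if (Xdf[c] == 0).all()]
    Xdf = Xdf.drop(columns=dropped)
    names = list(Xdf.columns)
    X = np.column_stack([np.ones(len(y)), Xdf.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix is rank deficient (aliased among {names})")

    beta = np.linalg.lstsq(X, np.log(y + 0.5), rcond=None)[0]
    if theta is not None:
        th = float(theta)
        beta = _nb_irls(y, X, th, beta)
    else:
        m, v = float(np.mean(y)), float(np.var(y))
        th = float(np.clip(m * m / max(v - m, m / 10), THETA_MIN, THETA_MAX))
        for _ in range(100):
            beta = _nb_irls(y, X, th, beta)
            mu = np.exp(X @ beta)
            th_new = _profile_theta(y, mu)
            if abs(np.log(th_new) - np.log(th)) < 1e-9:
                th = th_new
                break
            th = th_new
        beta = _nb_irls(y, X, th, beta)

    mu = np.exp(X @ beta)
    ll = nb_loglik(y, mu, th)
    # observed information for beta at fixed theta
    info_w = th * mu * (th + y) / (th + mu) ** 2
    info = (X.T * info_w) @ X
    vcov = np.linalg.inv(info)
    p = X.shape[1]
    pearson = float(np.sum((y - mu) ** 2 / (mu + mu**2 / th)))
    param_names = ["intercept", *names]
    se_vals = np.sqrt(np.diag(vcov))
    return NBFit(
        coefficients={nm: float(b) for nm, b in zip(param_names, beta)},
        se={nm: float(s) for nm, s in zip(param_names, se_vals)},
        vcov=vcov,
        param_names=param_names,
        theta=th,
        loglik=ll,
        n=len(y),
        df_resid=len(y) - p,
        dispersion=pearson / max(len(y) - p, 1),
        referent=sample.referent,
        dropped=dropped,
        _X=X,
        _y=y,
    )


# ------------------------------- hurdle -----------------------------------


@dataclass
class HurdleFit:
    zero_coefficients: dict[str, float]
    zero_vcov: np.ndarray
    zero_param_names: list[str]
    zero_loglik: float
    zero_penalized: bool
    count_coefficients: dict[str, float]
    count_vcov: np.ndarray          # over (count coefficients..., log theta)
    count_param_names: list[str]
    theta: float
    count_loglik: float
    n: int
    referent: str = ""
    count_dropped: list[str] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        """Joint log likelihood: the two parts factorize exactly."""
        return self.zero_loglik + self.count_loglik


def _logit_irls(y01: np.ndarray, X: np.ndarray, ridge: float = 0.0, max_iter=200):
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = special.expit(X @ beta)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        W = p * (1 - p)
        g = X.T @ (y01 - p) - ridge * beta
        H = (X.T * W) @ X + ridge * np.eye(X.shape[1])
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = np.clip(special.expit(X @ beta), 1e-12, 1 - 1e-12)
    ll = float(np.sum(y01 * np.log(p) + (1 - y01) * np.log(1 - p)))
    return beta, H, ll


def _truncated_nb_negll(theta_vec: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
    beta, log_theta = theta_vec[:-1], theta_vec[-1]
    th = np.exp(log_theta)
    mu = np.exp(np.clip(X @ beta, -30, 30))
    p0 = (th / (th + mu)) ** th
    ll = nb_loglik(y, mu, th) - float(np.sum(np.log1p(-p0)))
    return -ll


def _num_hessian(f, x0: np.ndarray, h: float = 1e-5) -> np.ndarray:
    n = len(x0)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    return H


def fit_hurdle_nb(sample: CountSample) -> HurdleFit:
    """Two-part hurdle fit: binomial logit for zero vs positive, plus a
    zero-truncated NB on the positive counts.

    The two likelihood factors are disjoint, so the joint log likelihood is
    their sum.  Design columns that are constant among the positive counts
    are aliased out of the count part and reported.  Separation in the zero
    part (cells that are all-zero or all-positive) triggers a ridge-penalized
    logit refit, flagged via ``zero_penalized``.
    """
    y = sample.counts
    pos = y > 0
    if pos.all() or not pos.any():
        raise ValueError("hurdle fit needs at least one zero and one positive count")
    Xdf = sample.design_matrix
    names = list(Xdf.columns)
    X = np.column_stack([np.ones(len(y)), Xdf.to_numpy(dtype=float)])
    zero_names = ["intercept", *names]

    beta_z, Hz, ll_z = _logit_irls(pos.astype(float), X)
    penalized = bool(np.max(np.abs(beta_z)) > 15)
    if penalized:
        beta_z, Hz, ll_z = _logit_irls(pos.astype(float), X, ridge=1e-4)
    zero_vcov = np.linalg.inv(Hz)

    yp = y[pos]
    Xp_df = Xdf.loc[pos]
    count_dropped = [c for c in Xp_df.columns if Xp_df[c].nunique() <= 1]
    Xp_df = Xp_df.drop(columns=count_dropped)
    count_names = ["intercept", *Xp_df.columns]
    Xp = np.column_stack([np.ones(pos.sum()), Xp_df.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(Xp) < Xp.shape[1]:
        raise ValueError("count-part design is rank deficient")

    beta0 = np.linalg.lstsq(Xp, np.log(yp), rcond=None)[0]
    x0 = np.append(beta0, np.log(5.0))
    res = optimize.minimize(
        _truncated_nb_negll,
        x0,
        args=(yp, Xp),
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-13, "gtol": 1e-10},
    )
    res2 = optimize.minimize(
        _truncated_nb_negll, res.x, args=(yp, Xp), method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12},
    )
    xhat = res2.x if res2.fun < res.fun else res.x
    ll_c = -_truncated_nb_negll(xhat, yp, Xp)
    H = _num_hessian(lambda v: _truncated_nb_negll(v, yp, Xp), xhat)
    try:
        count_vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        count_vcov = np.linalg.pinv(H)

    return HurdleFit(
        zero_coefficients={nm: float(b) for nm, b in zip(zero_names, beta_z)},
        zero_vcov=zero_vcov,
        zero_param_names=zero_names,
        zero_loglik=ll_z,
        zero_penalized=penalized,
        count_coefficients={nm: float(b) for nm, b in zip(count_names, xhat[:-1])},
        count_vcov=count_vcov,
        count_param_names=[*count_names, "log_theta"],
        theta=float(np.exp(xhat[-1])),
        count_loglik=ll_c,
        n=len(y),
        referent=sample.referent,
        count_dropped=count_dropped,
    )


# ---------------------------- tests & summaries ----------------------------


def term_f_tests(fit: NBFit, terms: dict[str, list[str]]) -> pd.DataFrame:
    """Term-deletion F tests for an NB fit.

    For each term the model is refit without the term's columns at the full
    model's theta; F = (deviance drop / df1) / dispersion with the full
    model's Pearson dispersion and df2 = n - p.
    """
    if fit._X is None or fit._y is None:
        raise ValueError("fit does not carry its data; refit with fit_nb_glm")
    non_int = [nm for nm in fit.param_names if nm != "intercept"]
    recs = []
    for term, cols in terms.items():
        keep = [nm for nm in non_int if nm not in cols]
        df1 = len([c for c in cols if c in non_int])
        if df1 == 0:
            recs.append({"term": term, "F": 0.0, "df1": 0, "df2": fit.df_resid, "p": 1.0})
            continue
        idx = [0] + [fit.param_names.index(nm) for nm in keep]
        Xr = fit._X[:, idx]
        beta_r = _nb_irls(fit._y, Xr, fit.theta, np.linalg.lstsq(Xr, np.log(fit._y + 0.5), rcond=None)[0])
        ll_r = nb_loglik(fit._y, np.exp(Xr @ beta_r), fit.theta)
        drop = max(2.0 * (fit.loglik - ll_r), 0.0)
        F = (drop / df1) / fit.dispersion
        recs.append(
            {"term": term, "F": float(F), "df1": df1, "df2": fit.df_resid,
             "p": float(stats.f.sf(F, df1, fit.df_resid))}
        )
    return pd.DataFrame(recs)


def _cell_row(param_names: list[str], chemical: str, photoperiod: str) -> np.ndarray:
    row = np.zeros(len(param_names))
    for i, nm in enumerate(param_names):
        if nm == "intercept":
            row[i] = 1.0
        elif nm in (chemical, photoperiod):
            row[i] = 1.0
    return row


def emm_counts(fit: NBFit | HurdleFit, cells: list[tuple[str, str]], alpha: float = 0.05) -> EMMResult:
    """Estimated marginal mean egg counts per treatment cell.

    For the plain NB fit the cell estimate is exp(linear predictor); for the
    hurdle fit it is P(positive) x truncated-NB mean, with the link-scale
    (log) SE by the delta method over the two parts' joint (block-diagonal)
    covariance.  Intervals use a t reference with df = n - p.
    """
    labels = [cell_label(c, p) for c, p in cells]
    if isinstance(fit, NBFit):
        ref_levels = set(fit.referent.split("+"))
        for c, p in cells:
            for lvl in (c, p):
                if lvl not in fit.param_names and lvl not in ref_levels:
                    raise ValueError(f"cell level {lvl!r} is outside the fitted design")
        rows = np.array([_cell_row(fit.param_names, c, p) for c, p in cells])
        df = fit.df_resid
        return emm_from_linear(labels, rows, fit.beta, fit.vcov, df, np.exp, alpha)

    # hurdle: log E[Y] = log pi + log mu - log(1 - p0(mu, theta))
    zn, cn = fit.zero_param_names, fit.count_param_names
    theta_z = np.array([fit.zero_coefficients[nm] for nm in zn])
    theta_c = np.array([*(fit.count_coefficients[nm] for nm in cn[:-1]), np.log(fit.theta)])
    joint = np.concatenate([theta_z, theta_c])
    V = np.zeros((len(joint), len(joint)))
    V[: len(zn), : len(zn)] = fit.zero_vcov
    V[len(zn):, len(zn):] = fit.count_vcov

    def log_mean(v: np.ndarray, chemical: str, photoperiod: str) -> float:
        vz, vc = v[: len(zn)], v[len(zn):]
        rz = _cell_row(zn, chemical, photoperiod)
        rc = _cell_row(cn[:-1], chemical, photoperiod)
        eta_z = rz @ vz
        mu = np.exp(rc @ vc[:-1])
        th = np.exp(vc[-1])
        pi = special.expit(eta_z)
        p0 = (th / (th + mu)) ** th
        return float(np.log(pi) + np.log(mu) - np.log1p(-p0))

    rows, etas = [], []
    h = 1e-6
    for c, p in cells:
        eta = log_mean(joint, c, p)
        grad = np.empty(len(joint))
        for i in range(len(joint)):
            e = np.zeros(len(joint)); e[i] = h
            grad[i] = (log_mean(joint + e, c, p) - log_mean(joint - e, c, p)) / (2 * h)
        rows.append(grad)
        etas.append(eta)
    rows = np.asarray(rows)
    df = fit.n - (len(zn) + len(cn))
    # emm_from_linear expects eta = rows @ beta; supply the nonlinear etas by
    # shifting through a pseudo-parameter trick: use rows for variance only.
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", rows, V, rows), 0.0))
    tcrit = stats.t.ppf(1 - alpha / 2, max(df, 1))
    etas = np.asarray(etas)
    return EMMResult(
        labels=labels,
        estimates=np.exp(etas),
        lo=np.exp(etas - tcrit * se),
        hi=np.exp(etas + tcrit * se),
        link_estimates=etas,
        link_se=se,
        df=max(df, 1),
        rows=rows,
        vcov=V,
    )


def eggs_per_female_day(total_eggs: float, female_days: float) -> float:
    """Descriptive fecundity ratio: eggs laid per cumulative female-day lived."""
    if female_days <= 0:
        raise ValueError("female_days must be positive")
    return float(total_eggs) / float(female_days)
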