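"""Clutch-level viability inference: weighted binomial logistic regression.

Each clutch contributes its egg count as binomial trials and its eclosed
hosts (or emerged parasitoids) as successes; the clutch size is therefore
the weight, and the weighted-logit MLE on aggregated clutches is exactly
the egg-level Bernoulli MLE.  Cells are modeled saturated (one indicator
per non-referent cell), matching per-cell percentage reporting.

Cells at the boundary (no successes at all) have a divergent logit; they
are detected up front, reported with a zero estimate and a rule-of-three
one-sided interval, and enter Tukey contrasts through a flagged
continuity-corrected refit (0.5 added to each outcome class in the
boundary cell only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .design import cell_label
from .posthoc import EMMResult

__all__ = [
    "BinomialSample",
    "LogitFit",
    "build_binomial_sample",
    "fit_weighted_logit",
    "emm_props",
    "binom_loglik",
]


@dataclass
class BinomialSample:
    successes: np.ndarray
    trials: np.ndarray
    cell_labels: list[str]
    outcome_type: str = ""
    referent: str = ""

    def __post_init__(self) -> None:
        self.successes = np.asarray(self.successes, dtype=float)
        self.trials = np.asarray(self.trials, dtype=float)
        if np.any(self.trials < 1):
            raise ValueError("every clutch needs at least one egg")
        if np.any(self.successes < 0) or np.any(self.successes > self.trials):
            raise ValueError("successes must lie in [0, trials]")

    @property
    def cells(self) -> list[str]:
        seen: list[str] = []
        for cl in self.cell_labels:
            if cl not in seen:
                seen.append(cl)
        return seen


def build_binomial_sample(
    clutches: pd.DataFrame,
    outcome_type: str,
    referent_cell: tuple[str, str] = ("acetone", "long_day"),
) -> BinomialSample:
    df = clutches[clutches["outcome_type"] == outcome_type].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no clutches with outcome_type {outcome_type!r}")
    labels = [cell_label(c, p) for c, p in zip(df["chemical"], df["photoperiod"])]
    return BinomialSample(
        successes=df["n_success"].to_numpy(),
        trials=df["n_eggs"].to_numpy(),
        cell_labels=labels,
        outcome_type=outcome_type,
        referent=cell_label(*referent_cell),
    )


def binom_loglik(s: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    """Binomial log likelihood including the combinatorial constant."""
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(
        np.sum(
            special.gammaln(n + 1)
            - special.gammaln(s + 1)
            - special.gammaln(n - s + 1)
            + s * np.log(p)
            + (n - s) * np.log(1 - p)
        )
    )


@dataclass
class LogitFit:
    """Cell-means weighted logit fit.

    ``coefficients`` hold the logit of each estimable cell (referent as
    "intercept", other cells as offsets); ``boundary_cells`` lists cells
    whose raw estimate sits on the boundary (all failures or all
    successes), which are excluded from the MLE and reported separately
    with their raw proportion in ``boundary_props``.
    """

    coefficients: dict[str, float]
    se: dict[str, float]
    vcov: np.ndarray
    param_names: list[str]
    loglik: float
    n_clutches: int
    n_eggs: int
    referent: str = ""
    cells: list[str] = field(default_factory=list)
    cell_eggs: dict[str, float] = field(default_factory=dict)
    boundary_cells: list[str] = field(default_factory=list)
    boundary_props: dict[str, float] = field(default_factory=dict)
    continuity: bool = False


def _cells_design(labels: list[str], cells: list[str], referent: str) -> np.ndarray:
    cols = [c for c in cells if c != referent]
    X = np.ones((len(labels), 1 + len(cols)))
    for j, c in enumerate(cols, start=1):
        X[:, j] = [1.0 if lbl == c else 0.0 for lbl in labels]
    return X


def fit_weighted_logit(sample: BinomialSample, continuity: bool = False) -> LogitFit:
    """IRLS maximum likelihood for the clutch-weighted binomial logit.

    With ``continuity=True`` boundary cells stay in the fit with half an
    egg added to each outcome class (used to form finite contrasts for
    letter displays); the returned fit is flagged.
    """
    cells = sample.cells
    referent = sample.referent if sample.referent in cells else cells[0]
    agg_s = {c: 0.0 for c in cells}
    agg_n = {c: 0.0 for c in cells}
    for s, n, c in zip(sample.successes, sample.trials, sample.cell_labels):
        agg_s[c] += s
        agg_n[c] += n
    boundary = [c for c in cells if agg_s[c] == 0 or agg_s[c] == agg_n[c]]

    s = sample.successes.copy()
    n = sample.trials.copy()
    labels = list(sample.cell_labels)
    if continuity and boundary:
        # half a success and half a failure appended per boundary cell
        for c in boundary:
            s = np.append(s, 0.5)
            n = np.append(n, 1.0)
            labels.append(c)
        est_cells = cells
        boundary_out = boundary
    else:
        keep = [i for i, lbl in enumerate(labels) if lbl not in boundary]
        s, n = s[keep], n[keep]
        labels = [labels[i] for i in keep]
        est_cells = [c for c in cells if c not in boundary]
        boundary_out = boundary
        if not est_cells:
            raise ValueError("every cell is at the boundary; nothing estimable")
        if referent in boundary:
            referent = est_cells[0]

    X = _cells_design(labels, est_cells, referent)
    beta = np.zeros(X.shape[1])
    for _ in range(200):
        p = np.clip(special.expit(X @ beta), 1e-12, 1 - 1e-12)
        W = n * p * (1 - p)
        g = X.T @ (s - n * p)
        H = (X.T * W) @ X
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    p = special.expit(X @ beta)
    ll = binom_loglik(s, n, p)
    vcov = np.linalg.inv((X.T * (n * p * (1 - p))) @ X)
    names = ["intercept", *[c for c in est_cells if c != referent]]
    se_vals = np.sqrt(np.diag(vcov))
    return LogitFit(
        coefficients={nm: float(b) for nm, b in zip(names, beta)},
        se={nm: float(v) for nm, v in zip(names, se_vals)},
        vcov=vcov,
        param_names=names,
        loglik=ll,
        n_clutches=len(sample.trials),
        n_eggs=int(sample.trials.sum()),
        referent=referent,
        cells=est_cells if continuity else [c for c in cells],
        cell_eggs=agg_n,
        boundary_cells=boundary_out,
        boundary_props={c: agg_s[c] / agg_n[c] for c in boundary_out},
        continuity=continuity,
    )


def emm_props(fit: LogitFit, cells: list[str] | None = None, alpha: float = 0.05) -> EMMResult:
    """Per-cell viability proportions with back-transformed intervals.

    Boundary cells are reported at their raw proportion with a one-sided
    rule-of-three interval (upper bound ~= 3/n for an all-failure cell) and
    flagged as degenerate.
    """
    est_cells = [c for c in fit.param_names if c != "intercept"]
    all_cells = cells or fit.cells or [fit.referent, *est_cells]
    rows, labels, etas = [], [], []
    notes: dict[str, str] = {}
    p_names = fit.param_names
    beta = np.array([fit.coefficients[nm] for nm in p_names])
    out_est, out_lo, out_hi, out_se = [], [], [], []
    tcrit = stats.norm.ppf(1 - alpha / 2)
    for c in all_cells:
        if c in fit.boundary_cells and c not in est_cells and c != fit.referent:
            n_eggs = fit.cell_eggs.get(c, np.nan)
            prop = fit.boundary_props.get(c, 0.0)
            if prop == 0.0:
                lo, hi = 0.0, 1.0 - (alpha ** (1.0 / n_eggs)) if n_eggs else np.nan
            else:
                lo, hi = (alpha ** (1.0 / n_eggs)) if n_eggs else np.nan, 1.0
            labels.append(c)
            rows.append(np.zeros(len(p_names)))
            etas.append(-np.inf if prop == 0.0 else np.inf)
            out_est.append(prop)
            out_lo.append(lo)
            out_hi.append(hi)
            out_se.append(np.inf)
            notes[c] = "boundary cell: rule-of-three one-sided interval"
            continue
        row = np.zeros(len(p_names))
        row[0] = 1.0
        if c != fit.referent:
            if c not in p_names:
                raise ValueError(f"cell {c!r} is outside the fitted design")
            row[p_names.index(c)] = 1.0
        eta = float(row @ beta)
        se = float(np.sqrt(max(row @ fit.vcov @ row, 0.0)))
        labels.append(c)
        rows.append(row)
        etas.append(eta)
        out_est.append(float(special.expit(eta)))
        out_lo.append(float(special.expit(eta - tcrit * se)))
        out_hi.append(float(special.expit(eta + tcrit * se)))
        out_se.append(se)
        if c in fit.boundary_cells:
            notes[c] = "boundary cell: continuity-corrected estimate"
    # binomial GLM intervals are asymptotic on the egg scale (emmeans-style z)
    df = np.inf
    return EMMResult(
        labels=labels,
        estimates=np.asarray(out_est),
        lo=np.asarray(out_lo),
        hi=np.asarray(out_hi),
        link_estimates=np.asarray(etas),
        link_se=np.asarray(out_se),
        df=df,
        rows=np.asarray(rows),
        vcov=fit.vcov,
        notes=notes,
    )
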