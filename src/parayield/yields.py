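"""Monte-Carlo propagation of fecundity and emergence uncertainty into
parasitoid yield.

For each treatment cell a draw consists of an egg count per replicate of 20
host females and a per-egg parasitoid emergence probability; their product
is that draw's parasitoid yield.  Eggs are drawn log-normally (normal
sampling error on the count model's log scale) and the emergence
probability logit-normally (normal error on the proportion model's logit
scale) — i.e. each model's estimate is perturbed by its own link-scale
standard error, the two being independent because they come from disjoint
experiments.  With both SEs set to zero the simulation degenerates to the
point product of the two estimates.

Per-cell draws are summarized by their mean, an empirical 95% quantile
interval, and percent increase relative to a referent cell; treatment
separation letters come from a gamma GLM (log link) on the draws with
Tukey-adjusted pairwise contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .design import (
    ACETONE,
    EGG_ESTIMATES,
    LONG_DAY,
    SEPTEMBER,
    SHORT_DAY,
    PARASITOID_EMERGENCE,
    VIABILITY_ESTIMATES,
    cell_label,
)
from .counts import NBFit, HurdleFit, emm_counts
from .posthoc import EMMResult, tukey_pairs
from .proportions import LogitFit, emm_props

__all__ = [
    "CellDistributions",
    "YieldInputs",
    "YieldSummary",
    "treatment_distributions",
    "reference_yield_inputs",
    "simulate_yield",
    "summarize_yield",
]


@dataclass
class CellDistributions:
    """Link-scale sampling distributions for one treatment cell."""

    label: str
    egg_mu: float          # log eggs per replicate
    egg_sigma: float
    logit_mu: float        # logit emergence probability
    logit_sigma: float


@dataclass
class YieldInputs:
    cells: list[CellDistributions]
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (label, reason)
    n_draws: int = 2000

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        for c in self.cells:
            if c.egg_sigma < 0 or c.logit_sigma < 0:
                raise ValueError(f"negative SE for cell {c.label}")


def treatment_distributions(
    count_emm: EMMResult,
    prop_emm: EMMResult,
    cells: list[str] | None = None,
    n_draws: int = 2000,
) -> YieldInputs:
    """Pair each cell's egg EMM with its emergence EMM on their link scales.

    Cells lacking either estimate (the short-day acetone cell laid no eggs
    and was never exposed to parasitoids) are excluded with an explicit
    reason rather than silently dropped.
    """
    egg_idx = {lbl: i for i, lbl in enumerate(count_emm.labels)}
    prop_idx = {lbl: i for i, lbl in enumerate(prop_emm.labels)}
    wanted = cells or [lbl for lbl in count_emm.labels]
    out, excluded = [], []
    for lbl in wanted:
        if lbl not in egg_idx:
            excluded.append((lbl, "no egg-production estimate"))
            continue
        if lbl not in prop_idx or not np.isfinite(prop_emm.link_estimates[prop_idx[lbl]]):
            excluded.append((lbl, "no parasitoid-exposure estimate"))
            continue
        i, j = egg_idx[lbl], prop_idx[lbl]
        out.append(
            CellDistributions(
                label=lbl,
                egg_mu=float(count_emm.link_estimates[i]),
                egg_sigma=float(count_emm.link_se[i]),
                logit_mu=float(prop_emm.link_estimates[j]),
                logit_sigma=float(prop_emm.link_se[j]),
            )
        )
    return YieldInputs(cells=out, excluded=excluded, n_draws=n_draws)


def reference_yield_inputs(n_draws: int = 2000) -> YieldInputs:
    """Yield inputs taken from the published September model estimates.

    Egg link-scale means are the model intercept plus applicable
    coefficients; the link SE of every cell mean is the published intercept
    (referent-cell) SE — in the balanced design every cell carries the same
    replication, and the coefficient SEs are SEs of *differences*, which
    would overstate cell-mean uncertainty.  Emergence logit means/SEs come
    from the published per-cell percentages via the delta method
    (se_logit = se_p / (p(1-p))).
    """
    egg = EGG_ESTIMATES[SEPTEMBER]
    emer = VIABILITY_ESTIMATES[PARASITOID_EMERGENCE]
    cells_out, excluded = [], []
    egg_se = egg["intercept"][1]
    for (chem, photo), (p, se_p, _n) in emer.items():
        mu = egg["intercept"][0]
        for lvl in (chem, photo):
            if lvl in egg:
                mu += egg[lvl][0]
        cells_out.append(
            CellDistributions(
                label=cell_label(chem, photo),
                egg_mu=mu,
                egg_sigma=egg_se,
                logit_mu=float(special.logit(p)),
                logit_sigma=se_p / (p * (1 - p)) if 0 < p < 1 else 0.0,
            )
        )
    excluded.append((cell_label(ACETONE, SHORT_DAY), "no eggs laid / no parasitoid exposures"))
    return YieldInputs(cells=cells_out, excluded=excluded, n_draws=n_draws)


def simulate_yield(inputs: YieldInputs, seed: int = 0) -> dict[str, np.ndarray]:
    """Seeded Monte-Carlo yield draws per treatment cell.

    Each draw is eggs x emergence with eggs ~ logN(egg_mu, egg_sigma) and
    emergence ~ logit-N(logit_mu, logit_sigma).
    """
    rng = np.random.default_rng(seed)
    draws: dict[str, np.ndarray] = {}
    for cell in inputs.cells:
        eggs = np.exp(rng.normal(cell.egg_mu, cell.egg_sigma, size=inputs.n_draws))
        prob = special.expit(rng.normal(cell.logit_mu, cell.logit_sigma, size=inputs.n_draws))
        draws[cell.label] = eggs * prob
    return draws


@dataclass
class YieldSummary:
    table: pd.DataFrame            # cell, mean, lo, hi, pct_increase, letter
    referent: str
    contrasts: pd.DataFrame
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return self.table


def _gamma_glm_oneway(draws: dict[str, np.ndarray]):
    """One-way gamma GLM with log link on pooled draws.

    With a saturated one-way layout the MLE cell means are the sample
    means; the dispersion is the Pearson statistic over N - k, and the
    link-scale variance of a cell mean is dispersion / n_cell.
    """
    labels = list(draws)
    means = np.array([draws[lbl].mean() for lbl in labels])
    ns = np.array([len(draws[lbl]) for lbl in labels])
    pearson = sum(
        float(np.sum(((draws[lbl] - m) / m) ** 2)) for lbl, m in zip(labels, means)
    )
    N, k = int(ns.sum()), len(labels)
    phi = pearson / (N - k)
    eta = np.log(means)
    vcov = np.diag(phi / ns)
    rows = np.eye(k)
    return labels, eta, rows, vcov, N - k


def summarize_yield(
    draws: dict[str, np.ndarray],
    referent: str = cell_label(ACETONE, LONG_DAY),
    alpha: float = 0.05,
) -> YieldSummary:
    """Means, empirical 95% intervals, percent increases and Tukey letters."""
    if referent not in draws:
        raise ValueError(f"referent cell {referent!r} has no draws")
    labels = list(draws)
    means = {lbl: float(np.mean(draws[lbl])) for lbl in labels}
    ref_mean = means[referent]
    if ref_mean == 0:
        raise ValueError("referent mean is zero; percent increase undefined")

    glabels, eta, rows, vcov, df = _gamma_glm_oneway(draws)
    emm = EMMResult(
        labels=glabels,
        estimates=np.exp(eta),
        lo=np.exp(eta - 1.96 * np.sqrt(np.diag(vcov))),
        hi=np.exp(eta + 1.96 * np.sqrt(np.diag(vcov))),
        link_estimates=eta,
        link_se=np.sqrt(np.diag(vcov)),
        df=df,
        rows=rows,
        vcov=vcov,
    )
    contrasts = tukey_pairs(emm, alpha=alpha)
    recs = []
    for lbl in labels:
        lo, hi = np.quantile(draws[lbl], [alpha / 2, 1 - alpha / 2])
        recs.append(
            {
                "cell": lbl,
                "mean": means[lbl],
                "lo": float(lo),
                "hi": float(hi),
                "pct_increase_vs_referent": 100.0 * (means[lbl] / ref_mean - 1.0),
                "letter": contrasts.letters[lbl],
            }
        )
    return YieldSummary(
        table=pd.DataFrame(recs), referent=referent, contrasts=contrasts.pairs, alpha=alpha
    )


def emm_pair_for_yield(
    count_fit: NBFit | HurdleFit,
    prop_fit: LogitFit,
    cells: list[tuple[str, str]],
) -> tuple[EMMResult, EMMResult]:
    """Convenience: matched (egg, emergence) EMMs for yield inputs."""
    return emm_counts(count_fit, cells), emm_props(prop_fit, [cell_label(*c) for c in cells])
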