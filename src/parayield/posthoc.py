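"""Estimated marginal means, Tukey-adjusted pairwise contrasts, letter displays.

EMMs are cell means on the response scale obtained by evaluating the fitted
linear predictor at each factor combination and back-transforming; intervals
are computed on the link scale with a t reference distribution and then
back-transformed, so they respect the link's monotonicity.  All pairwise
contrasts are tested on the link scale with the studentized-range
(Tukey) adjustment, and a compact letter display is derived by the
insert-and-absorb algorithm: cells sharing a letter are not significantly
different at the chosen alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EMMResult", "ContrastTable", "emm_from_linear", "tukey_pairs", "compact_letters"]


@dataclass
class EMMResult:
    """Cell estimates on the response scale plus the link-scale pieces
    needed for contrasts (cell rows, covariance, residual df)."""

    labels: list[str]
    estimates: np.ndarray          # response scale
    lo: np.ndarray
    hi: np.ndarray
    link_estimates: np.ndarray
    link_se: np.ndarray
    df: float
    rows: np.ndarray               # cells x params matrix over the fit's params
    vcov: np.ndarray
    notes: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": self.labels,
                "estimate": self.estimates,
                "lo": self.lo,
                "hi": self.hi,
                "link_estimate": self.link_estimates,
                "link_se": self.link_se,
                "df": self.df,
                "note": [self.notes.get(lbl, "") for lbl in self.labels],
            }
        )


@dataclass
class ContrastTable:
    pairs: pd.DataFrame            # cell_a, cell_b, diff (link), se, t, p_unadj, p_adj
    letters: dict[str, str]
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return self.pairs


def emm_from_linear(
    labels: list[str],
    rows: np.ndarray,
    beta: np.ndarray,
    vcov: np.ndarray,
    df: float,
    inverse_link: Callable[[np.ndarray], np.ndarray] = np.exp,
    alpha: float = 0.05,
    notes: dict[str, str] | None = None,
) -> EMMResult:
    """EMMs for cells given their design rows and a fitted linear model."""
    rows = np.asarray(rows, dtype=float)
    eta = rows @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", rows, vcov, rows), 0.0))
    tcrit = stats.t.ppf(1 - alpha / 2, df) if np.isfinite(df) else stats.norm.ppf(1 - alpha / 2)
    return EMMResult(
        labels=list(labels),
        estimates=np.asarray(inverse_link(eta), dtype=float),
        lo=np.asarray(inverse_link(eta - tcrit * se), dtype=float),
        hi=np.asarray(inverse_link(eta + tcrit * se), dtype=float),
        link_estimates=eta,
        link_se=se,
        df=df,
        rows=rows,
        vcov=vcov,
        notes=dict(notes or {}),
    )


def tukey_pairs(emm: EMMResult, alpha: float = 0.05) -> ContrastTable:
    """All pairwise link-scale contrasts with Tukey (studentized-range) p-values.

    The adjusted p for a pair is P(Q_{k,df} >= sqrt(2)|t|) where t is the
    contrast's t statistic; with k = 2 this reduces to the ordinary
    two-sided t-test.  Letters come from the insert-and-absorb display.
    """
    k = len(emm.labels)
    if k < 2:
        raise ValueError("need at least two cells for contrasts")
    df = emm.df if np.isfinite(emm.df) else 1e6
    recs = []
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            c = emm.rows[i] - emm.rows[j]
            se = float(np.sqrt(max(c @ emm.vcov @ c, 0.0)))
            diff = float(emm.link_estimates[i] - emm.link_estimates[j])
            if se == 0.0:
                t = 0.0 if diff == 0.0 else np.inf
            else:
                t = diff / se
            p_un = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
            p_adj = float(stats.studentized_range.sf(np.sqrt(2) * abs(t), k, df)) if np.isfinite(t) else 0.0
            p_adj = min(max(p_adj, p_un), 1.0)  # adjusted p can never undercut unadjusted
            sig[i, j] = sig[j, i] = p_adj <= alpha
            recs.append(
                {
                    "cell_a": emm.labels[i],
                    "cell_b": emm.labels[j],
                    "diff": diff,
                    "se": se,
                    "t": t,
                    "p_unadj": p_un,
                    "p_adj": p_adj,
                }
            )
    letters = compact_letters(emm.labels, sig, order_by=-emm.estimates)
    return ContrastTable(pairs=pd.DataFrame(recs), letters=letters, alpha=alpha)


def compact_letters(labels: list[str], significant: np.ndarray, order_by: np.ndarray | None = None) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant[i, j]`` is True when cells i and j differ.  Starting from
    a single group of all cells, each significant pair splits every group
    containing both; groups that become subsets of others are absorbed.
    Letters are assigned in ``order_by`` order (default: input order).
    """
    k = len(labels)
    groups: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not significant[i, j]:
                continue
            for g in [g for g in groups if i in g and j in g]:
                groups.remove(g)
                gi, gj = g - {j}, g - {i}
                for cand in (gi, gj):
                    if cand and not any(cand <= other for other in groups):
                        groups.append(cand)
            # absorb any group that became a subset
            groups = [g for g in groups if not any(g < other for other in groups)]
    order = np.argsort(order_by) if order_by is not None else np.arange(k)
    # order groups by their best-ranked member so 'a' goes to the top cell
    rank = {int(idx): r for r, idx in enumerate(order)}
    groups.sort(key=lambda g: min(rank[m] for m in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lbl: "" for lbl in labels}
    for gi, g in enumerate(groups):
        for m in sorted(g, key=lambda m: rank[m]):
            letters[labels[m]] += alphabet[gi % len(alphabet)]
    return letters
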