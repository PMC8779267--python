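"""Synthetic event-table generator for the rearing experiment.

The raw data behind the original study were never released, so the analysis
pipeline runs on synthetic tables generated here: the generator inverts the
very models the analysis fits (Weibull accelerated-failure-time death times,
negative-binomial — optionally hurdle — container egg totals, binomial
clutch outcomes), so parameter-recovery tests are meaningful end to end.

All generation is driven by :class:`numpy.random.Generator` seeded
explicitly; identical ``(design, params, seed)`` triples produce identical
tables (and identical CSV bytes).
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .design import (
    ConfigurationError,
    GeneratorParams,
    HOST_ECLOSION,
    PARASITOID_EMERGENCE,
    StudyDesign,
)

__all__ = [
    "generate_survival",
    "generate_fecundity",
    "generate_clutch_outcomes",
    "simulate_study",
    "SUBJECT_COLUMNS",
    "CONTAINER_COLUMNS",
    "CLUTCH_COLUMNS",
]

SUBJECT_COLUMNS = [
    "subject_id",
    "container_id",
    "sex",
    "collection",
    "photoperiod",
    "chemical",
    "time_days",
    "event",
]
CONTAINER_COLUMNS = [
    "container_id",
    "collection",
    "photoperiod",
    "chemical",
    "total_eggs",
    "n_clutches",
    "female_days",
]
CLUTCH_COLUMNS = [
    "clutch_id",
    "collection",
    "photoperiod",
    "chemical",
    "n_eggs",
    "outcome_type",
    "n_success",
]

# Parasitoid exposures used clutches of at least this many eggs.
MIN_PARASITISM_CLUTCH = 15


def _check_labels(coeffs: dict[str, float], design: StudyDesign, what: str) -> None:
    known = set(design.chemicals) | set(design.photoperiods)
    unknown = set(coeffs) - known
    if unknown:
        raise ConfigurationError(f"unknown treatment label(s) in {what}: {sorted(unknown)}")


def _linear_predictor(intercept: float, coeffs: dict[str, float], chemical: str, photoperiod: str) -> float:
    lp = intercept
    for level, beta in coeffs.items():
        if level in (chemical, photoperiod):
            lp += beta
    return lp


def _container_id(params: GeneratorParams, chemical: str, photoperiod: str, k: int) -> str:
    return f"{params.collection}:{chemical}:{photoperiod}:c{k + 1}"


def _draw_death_times(rng: np.random.Generator, n: int, log_loc: float, sigma: float) -> np.ndarray:
    # log T = mu + sigma*W with W ~ Gumbel(min): T = exp(mu) * (-log U)^sigma
    u = rng.uniform(size=n)
    return np.exp(log_loc) * (-np.log(u)) ** sigma


def generate_survival(design: StudyDesign, params: GeneratorParams, seed: int) -> pd.DataFrame:
    """Per-insect (possibly right-censored) death records for one collection.

    Death times follow the Weibull AFT model in ``params``; times beyond the
    follow-up horizon are recorded censored at ``design.followup_days``.
    Males receive the same death-time distribution as females (the analysis
    stages use females only) and are flagged via the ``sex`` column.
    """
    _check_labels(params.aft_coeffs, design, "aft_coeffs")
    rng = np.random.default_rng(seed)
    sigma = float(np.exp(params.aft_log_scale))
    rows: list[tuple] = []
    sid = 0
    for chemical, photoperiod in design.cells:
        log_loc = _linear_predictor(params.aft_intercept, params.aft_coeffs, chemical, photoperiod)
        for k in range(design.containers_per_cell):
            cid = _container_id(params, chemical, photoperiod, k)
            n_f, n_m = design.females_per_container, design.males_per_container
            times = _draw_death_times(rng, n_f + n_m, log_loc, sigma)
            for i, t in enumerate(times):
                sex = "f" if i < n_f else "m"
                event = 1 if t <= design.followup_days else 0
                t_obs = float(min(t, design.followup_days))
                rows.append(
                    (f"s{sid}", cid, sex, params.collection, photoperiod, chemical, t_obs, event)
                )
                sid += 1
    return pd.DataFrame(rows, columns=SUBJECT_COLUMNS)


def _truncated_poisson(rng: np.random.Generator, mean: float, low: int) -> int:
    """Poisson draw conditioned on being >= low (rejection with a shift guard)."""
    if mean <= low:
        # Degenerate regime: shift a small Poisson above the floor.
        return low + int(rng.poisson(max(mean - low, 0.5)))
    for _ in range(1000):
        x = int(rng.poisson(mean))
        if x >= low:
            return x
    return low


def _partition_into_clutches(rng: np.random.Generator, total: int, mean_size: float) -> list[int]:
    """Split a container egg total into clutch sizes (iid truncated Poisson,
    last clutch takes the remainder)."""
    sizes: list[int] = []
    remaining = total
    while remaining > 0:
        s = _truncated_poisson(rng, mean_size, 1)
        if s >= remaining:
            sizes.append(remaining)
            remaining = 0
        else:
            sizes.append(s)
            remaining -= s
    return sizes


def _draw_nb(rng: np.random.Generator, mean: float, theta: float, truncated: bool) -> int:
    """Negative binomial via gamma-Poisson mixture; optionally zero-truncated."""
    for _ in range(10000):
        lam = rng.gamma(shape=theta, scale=mean / theta)
        y = int(rng.poisson(lam))
        if not truncated or y > 0:
            return y
    return 1  # unreachable for any sane mean


def generate_fecundity(
    design: StudyDesign,
    params: GeneratorParams,
    seed: int,
    subjects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-container egg-production records for one collection.

    Container totals are negative binomial with the log-mean structure in
    ``params``; cells listed in ``zero_prob`` produce zero eggs with that
    probability and zero-truncated totals otherwise (hurdle structure).
    ``female_days`` (cumulative days lived by the 20 females over follow-up)
    is taken from ``subjects`` when given, otherwise drawn from the same
    survival model.
    """
    _check_labels(params.egg_coeffs, design, "egg_coeffs")
    rng = np.random.default_rng(seed)
    sigma = float(np.exp(params.aft_log_scale))

    fd_lookup: dict[str, float] = {}
    if subjects is not None:
        fem = subjects[subjects["sex"] == "f"]
        fd_lookup = fem.groupby("container_id")["time_days"].sum().to_dict()

    rows: list[tuple] = []
    for chemical, photoperiod in design.cells:
        mu = float(np.exp(_linear_predictor(params.egg_log_mean_intercept, params.egg_coeffs, chemical, photoperiod)))
        p_zero = params.zero_prob.get((chemical, photoperiod), 0.0)
        hurdle_active = p_zero > 0.0
        log_loc = _linear_predictor(params.aft_intercept, params.aft_coeffs, chemical, photoperiod)
        for k in range(design.containers_per_cell):
            cid = _container_id(params, chemical, photoperiod, k)
            if hurdle_active and rng.uniform() < p_zero:
                total = 0
            else:
                total = _draw_nb(rng, mu, params.nb_dispersion, truncated=hurdle_active)
            n_clutches = len(_partition_into_clutches(rng, total, params.clutch_size_mean))
            if cid in fd_lookup:
                female_days = float(fd_lookup[cid])
            else:
                t = _draw_death_times(rng, design.females_per_container, log_loc, sigma)
                female_days = float(np.minimum(t, design.followup_days).sum())
            rows.append((cid, params.collection, photoperiod, chemical, total, n_clutches, female_days))
    return pd.DataFrame(rows, columns=CONTAINER_COLUMNS)


def _clutch_sizes_for_target(rng: np.random.Generator, target: int, mean_size: float, low: int) -> list[int]:
    """Clutch sizes accumulating to (at least) a target egg total.

    The final clutch is trimmed to hit the target exactly where the trim
    stays at or above the size floor; otherwise the floor wins and the cell
    slightly overshoots its target.
    """
    sizes: list[int] = []
    total = 0
    while total < target:
        s = _truncated_poisson(rng, mean_size, low)
        if total + s >= target:
            s = max(target - total, low)
        sizes.append(s)
        total += s
    return sizes


def generate_clutch_outcomes(design: StudyDesign, params: GeneratorParams, seed: int) -> pd.DataFrame:
    """Per-clutch eclosion/emergence outcome records for one collection.

    For every cell in the outcome's probability map, clutches are generated
    until the cell's egg target is met and each clutch's success count is
    Binomial(clutch size, cell probability).  Parasitoid-exposed clutches
    have at least 15 eggs.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    cid = 0
    specs = [
        (HOST_ECLOSION, params.host_eclosion_prob, params.eclosion_eggs_per_cell, 1),
        (PARASITOID_EMERGENCE, params.emergence_prob, params.emergence_eggs_per_cell, MIN_PARASITISM_CLUTCH),
    ]
    for outcome_type, prob_map, target_map, low in specs:
        targets = dict(target_map)
        if not targets:
            # Default scale when no per-cell egg totals are configured.
            targets = {cell: int(12 * params.clutch_size_mean) for cell in prob_map}
        missing = set(targets) - set(prob_map)
        if missing:
            raise ConfigurationError(
                f"no {outcome_type} probability for cell(s) {sorted(missing)}"
            )
        for chemical, photoperiod in design.cells:
            cell = (chemical, photoperiod)
            if cell not in targets:
                continue
            p = prob_map[cell]
            for n_eggs in _clutch_sizes_for_target(rng, targets[cell], params.clutch_size_mean, low):
                n_success = int(rng.binomial(n_eggs, p))
                rows.append(
                    (f"k{cid}", params.collection, photoperiod, chemical, n_eggs, outcome_type, n_success)
                )
                cid += 1
    return pd.DataFrame(rows, columns=CLUTCH_COLUMNS)


def simulate_study(
    design: StudyDesign,
    params_by_collection: dict[str, GeneratorParams],
    seed: int,
) -> dict[str, pd.DataFrame]:
    """Generate the three event tables for every collection in one shot.

    A single master seed is split into independent per-collection,
    per-table child seeds via :class:`numpy.random.SeedSequence` so any
    stage can be regenerated in isolation.
    """
    subjects, containers, clutches = [], [], []
    for name in sorted(params_by_collection):
        params = params_by_collection[name]
        ss = np.random.SeedSequence([seed, zlib.crc32(name.encode()) % (2**31)])
        s_surv, s_fec, s_clutch = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3)]
        subj = generate_survival(design, params, s_surv)
        subjects.append(subj)
        containers.append(generate_fecundity(design, params, s_fec, subjects=subj))
        clutches.append(generate_clutch_outcomes(design, params, s_clutch))
    return {
        "subjects": pd.concat(subjects, ignore_index=True),
        "containers": pd.concat(containers, ignore_index=True),
        "clutches": pd.concat(clutches, ignore_index=True),
    }
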