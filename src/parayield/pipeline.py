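"""End-to-end orchestration: simulate -> fit -> Monte-Carlo yield -> report.

Stages are plain functions over DataFrames so the analysis drivers, the CLI
and the tests all share one code path.  A single master seed fans out into
per-stage child seeds through :class:`numpy.random.SeedSequence`, so any
stage can be re-run in isolation and the full bundle is bit-stable under a
fixed configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .design import (
    ACETONE,
    AUGUST,
    GeneratorParams,
    HOST_ECLOSION,
    LONG_DAY,
    PARASITOID_EMERGENCE,
    SHORT_DAY,
    SEPTEMBER,
    StudyDesign,
    cell_label,
    reference_params,
)
from .counts import (
    UnderdispersionError,
    build_count_sample,
    emm_counts,
    fit_hurdle_nb,
    fit_nb_glm,
    term_f_tests,
)
from .posthoc import tukey_pairs
from .proportions import build_binomial_sample, emm_props, fit_weighted_logit
from .simulate import simulate_study
from .survival import aft_lrt, build_survival_sample, fit_weibull_aft, hazard_ratios, km_fit
from .validate import validate_tables
from .yields import simulate_yield, summarize_yield, treatment_distributions

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Run configuration: either input CSV paths or a synthetic block."""

    subjects: str | None = None
    containers: str | None = None
    clutches: str | None = None
    synthetic: bool = True
    collections: tuple[str, ...] = (AUGUST, SEPTEMBER)
    hurdle: bool = True
    alpha: float = 0.05
    n_draws: int = 2000
    seed: int = 1
    referent: tuple[str, str] = (ACETONE, LONG_DAY)
    out: str = "results/pipeline"
    plots: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not self.synthetic and not (self.subjects and self.containers and self.clutches):
            raise ValueError("either synthetic=True or all three input paths are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        design = raw.get("design", {})
        params = raw.get("params", {})
        cfg = {k: v for k, v in raw.items() if k not in ("design", "params")}
        if "collections" in design:
            cfg["collections"] = tuple(design["collections"])
        if "referent" in cfg:
            cfg["referent"] = tuple(cfg["referent"])
        cfg.update(params)
        return cls(**cfg)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out", None)
        payload.pop("plots", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(c.generate_state(1)[0] % 2**31) for c in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle; returns the manifest."""
    t0 = time.time()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 4)
    timings: dict[str, float] = {}
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"parayield": _version(), "numpy": np.__version__, "pandas": pd.__version__},
        "stages": [],
    }
    design = StudyDesign(collections=tuple(config.collections))

    # --- data -------------------------------------------------------------
    t = time.time()
    try:
        if config.synthetic:
            params = {c: reference_params(c) for c in config.collections}
            tables = simulate_study(design, params, seeds[0])
            io.write_tables(tables, outdir)
        else:
            tables = {
                "subjects": io.read_subjects(config.subjects),
                "containers": io.read_containers(config.containers),
                "clutches": io.read_clutches(config.clutches),
            }
        report = validate_tables(
            tables["subjects"], tables["containers"], tables["clutches"],
            followup_days=design.followup_days,
            max_female_days=design.females_per_container * design.followup_days,
        )
        report.to_csv(outdir / "validation.csv", index=False)
        errors = report[report["severity"] == "error"]
        if not errors.empty:
            raise ValueError(f"validation failed: {errors.to_dict('records')}")
    except Exception as e:  # noqa: BLE001
        raise StageError("data", e) from e
    timings["data"] = time.time() - t
    manifest["stages"].append("data")

    # --- survival ---------------------------------------------------------
    t = time.time()
    try:
        t1_rows, hr_frames, km_rows = [], [], []
        for coll in config.collections:
            sample = build_survival_sample(tables["subjects"], collection=coll)
            fit = fit_weibull_aft(sample)
            chi2, dof, p = aft_lrt(fit)
            for nm in fit.param_names:
                coef = fit.log_scale if nm == "log_scale" else fit.coefficients[nm]
                t1_rows.append(
                    {"collection": coll, "factor": nm, "coefficient": coef,
                     "se": fit.se[nm], "z": coef / fit.se[nm] if fit.se[nm] else np.nan,
                     "p": 2 * _norm_sf(abs(coef / fit.se[nm])) if fit.se[nm] else np.nan,
                     "lrt_chi2": chi2, "lrt_df": dof, "lrt_p": p, "referent": fit.referent}
                )
            hr = hazard_ratios(fit, alpha=config.alpha)
            hr.insert(0, "collection", coll)
            hr_frames.append(hr)
            fem = tables["subjects"].query("collection == @coll and sex == 'f'")
            for (chem, photo), grp in fem.groupby(["chemical", "photoperiod"]):
                curve = km_fit(grp["time_days"], grp["event"], alpha=config.alpha)
                for tt, s, se in zip(curve.event_times, curve.survival, curve.greenwood_se):
                    km_rows.append(
                        {"collection": coll, "cell": cell_label(chem, photo),
                         "time": tt, "survival": s, "se": se,
                         "median": curve.median,
                         "median_lo": curve.median_ci[0], "median_hi": curve.median_ci[1]}
                    )
        if len(config.collections) > 1:
            # collection-month effect on survival, pooled over treatments
            pooled = build_survival_sample(tables["subjects"], levels=(SEPTEMBER,))
            pfit = fit_weibull_aft(pooled)
            chi2, dof, p = aft_lrt(pfit)
            pd.DataFrame(
                [{"factor": SEPTEMBER, "coefficient": pfit.coefficients[SEPTEMBER],
                  "lrt_chi2": chi2, "lrt_df": dof, "lrt_p": p}]
            ).to_csv(outdir / "survival_month_effect.csv", index=False)
        pd.DataFrame(t1_rows).to_csv(outdir / "survival_coefficients.csv", index=False)
        pd.concat(hr_frames).to_csv(outdir / "hazard_ratios.csv", index=False)
        pd.DataFrame(km_rows).to_csv(outdir / "km_curves.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("survival", e) from e
    timings["survival"] = time.time() - t
    manifest["stages"].append("survival")

    # --- counts -----------------------------------------------------------
    t = time.time()
    count_fits = {}
    try:
        t2_rows, emm_rows, contrast_rows, letter_rows = [], [], [], []
        for coll in config.collections:
            sample = build_count_sample(tables["containers"], collection=coll)
            try:
                fit = fit_nb_glm(sample)
                kind = "nb"
            except UnderdispersionError:
                if not config.hurdle:
                    raise
                fit = fit_hurdle_nb(sample)
                kind = "hurdle"
            count_fits[coll] = fit
            coefs = fit.coefficients if kind == "nb" else fit.count_coefficients
            ses = fit.se if kind == "nb" else {}
            for nm, b in coefs.items():
                se = ses.get(nm, np.nan)
                t2_rows.append(
                    {"collection": coll, "model": kind, "factor": nm, "coefficient": b,
                     "se": se, "z": b / se if se and np.isfinite(se) else np.nan,
                     "p": 2 * _norm_sf(abs(b / se)) if se and np.isfinite(se) else np.nan,
                     "theta": fit.theta, "referent": fit.referent}
                )
            # Term F tests need the plain NB; when the hurdle was selected the
            # all-zero cell is dropped for this secondary fit (the pre-hurdle
            # workaround) so photoperiod/chemical F tests remain reportable.
            ffit = fit if kind == "nb" else fit_nb_glm(
                build_count_sample(tables["containers"], collection=coll, drop_all_zero_cells=True)
            )
            ftab = term_f_tests(ffit, {"chemical": ["pyr_1.0", "pyr_0.1"], "photoperiod": ["short_day", "long_day"]})
            ftab.insert(0, "collection", coll)
            ftab.to_csv(outdir / f"egg_term_tests_{coll}.csv", index=False)
            cells = [(c, p) for c, p in design.cells if (c, p) != (ACETONE, SHORT_DAY)]
            emm = emm_counts(fit, cells, alpha=config.alpha)
            contrasts = tukey_pairs(emm, alpha=config.alpha)
            ef = emm.to_frame(); ef.insert(0, "collection", coll)
            emm_rows.append(ef)
            cf = contrasts.to_frame(); cf.insert(0, "collection", coll)
            contrast_rows.append(cf)
            for cell, letter in contrasts.letters.items():
                letter_rows.append({"collection": coll, "cell": cell, "letter": letter})
        if len(config.collections) > 1:
            # collection-month effect on egg totals, pooled containers
            pooled = build_count_sample(
                tables["containers"], levels=(SEPTEMBER,), drop_all_zero_cells=True
            )
            mfit = fit_nb_glm(pooled)
            mtab = term_f_tests(mfit, {"collection": [SEPTEMBER]})
            mtab.to_csv(outdir / "egg_month_effect.csv", index=False)
        pd.DataFrame(t2_rows).to_csv(outdir / "egg_coefficients.csv", index=False)
        pd.concat(emm_rows).to_csv(outdir / "egg_emm.csv", index=False)
        pd.concat(contrast_rows).to_csv(outdir / "egg_contrasts.csv", index=False)
        pd.DataFrame(letter_rows).to_csv(outdir / "egg_letters.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("counts", e) from e
    timings["counts"] = time.time() - t
    manifest["stages"].append("counts")

    # --- proportions --------------------------------------------------------
    t = time.time()
    prop_emms = {}
    try:
        for outcome in (HOST_ECLOSION, PARASITOID_EMERGENCE):
            cl = tables["clutches"]
            if outcome not in set(cl["outcome_type"]):
                continue
            sample = build_binomial_sample(cl, outcome)
            fit = fit_weighted_logit(sample)
            letter_fit = fit_weighted_logit(sample, continuity=True) if fit.boundary_cells else fit
            emm = emm_props(fit, alpha=config.alpha)
            letters = tukey_pairs(emm_props(letter_fit, alpha=config.alpha), alpha=config.alpha)
            prop_emms[outcome] = emm_props(letter_fit, alpha=config.alpha) if fit.boundary_cells else emm
            frame = emm.to_frame()
            frame["letter"] = [letters.letters.get(c, "") for c in frame["cell"]]
            frame["eggs"] = [fit.cell_eggs.get(c, np.nan) for c in frame["cell"]]
            frame.insert(0, "outcome", outcome)
            frame.to_csv(outdir / f"viability_{outcome}.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("proportions", e) from e
    timings["proportions"] = time.time() - t
    manifest["stages"].append("proportions")

    # --- yield --------------------------------------------------------------
    t = time.time()
    try:
        if SEPTEMBER in count_fits and PARASITOID_EMERGENCE in prop_emms:
            # all design cells: cells lacking an estimate are excluded with a
            # recorded reason by treatment_distributions
            egg_emm = emm_counts(count_fits[SEPTEMBER], design.cells, alpha=config.alpha)
            inputs = treatment_distributions(
                egg_emm, prop_emms[PARASITOID_EMERGENCE], n_draws=config.n_draws
            )
            draws = simulate_yield(inputs, seed=seeds[3])
            summary = summarize_yield(draws, referent=cell_label(*config.referent), alpha=config.alpha)
            long = pd.concat(
                [pd.DataFrame({"cell": lbl, "draw": np.arange(len(v)), "yield": v}) for lbl, v in draws.items()],
                ignore_index=True,
            )
            long.to_csv(outdir / "yields.csv", index=False)
            payload = {
                "referent": summary.referent,
                "excluded": [{"cell": c, "reason": r} for c, r in inputs.excluded],
                "cells": summary.table.to_dict("records"),
            }
            (outdir / "yield_summary.json").write_text(json.dumps(payload, indent=2))
            if config.plots:
                _plot_yield(draws, outdir / "yield_boxplot.png")
    except Exception as e:  # noqa: BLE001
        raise StageError("yield", e) from e
    timings["yield"] = time.time() - t
    manifest["stages"].append("yield")

    manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    manifest["wall_s"] = round(time.time() - t0, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _norm_sf(z: float) -> float:
    from scipy import stats

    return float(stats.norm.sf(z))


def _version() -> str:
    from . import __version__

    return __version__


def _plot_yield(draws: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.boxplot(list(draws.values()), tick_labels=list(draws.keys()))
    ax.set_ylabel("parasitoids per 20 host females")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
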