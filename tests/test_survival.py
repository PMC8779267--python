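"""Kaplan-Meier and Weibull AFT: oracles, cross-validation, recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from parayield.design import AFT_ESTIMATES, StudyDesign, reference_params
from parayield.simulate import generate_survival
from parayield.survival import (
    AFTFit,
    SurvivalSample,
    aft_fit_from_estimates,
    aft_lrt,
    build_survival_sample,
    fit_weibull_aft,
    hazard_ratios,
    km_fit,
)


# ------------------------------ Kaplan-Meier ------------------------------


def test_km_complete_data_is_empirical_survivor():
    curve = km_fit([1.0, 2.0, 3.0], [1, 1, 1])
    np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
    assert curve.median == 2.0


def test_km_single_censored_subject_has_no_median():
    curve = km_fit([5.0], [0])
    assert curve.median is None
    assert len(curve.event_times) == 0  # curve never leaves 1


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.lists(st.floats(0.1, 100.0), min_size=1, max_size=40))
def test_km_without_censoring_equals_empirical(times):
    times = np.round(np.asarray(times), 3)
    curve = km_fit(times, np.ones(len(times), dtype=int))
    for t, s in zip(curve.event_times, curve.survival):
        assert s == pytest.approx(np.mean(times > t), abs=1e-12)


def test_km_median_recovers_generating_weibull():
    mu, sigma = math.log(39.0), 0.44
    rng = np.random.default_rng(5)
    times = np.exp(mu) * (-np.log(rng.uniform(size=200))) ** sigma
    curve = km_fit(times, np.ones(200, dtype=int))
    expected = math.exp(mu) * math.log(2) ** sigma
    assert abs(curve.median - expected) < 4.0  # ~3 SE of a sample median at n=200


def test_km_matches_lifelines_with_censoring():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(9)
    times = rng.weibull(1.5, size=120) * 30
    events = (times < 25).astype(int)
    times = np.minimum(times, 25)
    ours = km_fit(times, events)
    kmf = lifelines.KaplanMeierFitter().fit(times, events)
    theirs = kmf.survival_function_.loc[ours.event_times, "KM_estimate"].to_numpy()
    np.testing.assert_allclose(ours.survival, theirs, atol=1e-10)
    assert ours.median == pytest.approx(kmf.median_survival_time_)
    ci = lifelines.utils.median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    assert ours.median_ci[0] == pytest.approx(lo)
    assert (ours.median_ci[1] is None and np.isinf(hi)) or ours.median_ci[1] == pytest.approx(hi)


# ------------------------------ Weibull AFT -------------------------------


def _censored_weibull_data(seed, n, mu, sigma, horizon):
    rng = np.random.default_rng(seed)
    t = np.exp(mu) * (-np.log(rng.uniform(size=n))) ** sigma
    events = (t <= horizon).astype(int)
    return np.minimum(t, horizon), events


def _oracle_negll(theta, t, d, X):
    """Independent censored Weibull likelihood via scipy.stats.weibull_min."""
    beta, log_sigma = theta[:-1], theta[-1]
    k = 1.0 / np.exp(log_sigma)
    lam = np.exp(X @ beta)
    ll = np.sum(
        d * stats.weibull_min.logpdf(t, k, scale=lam)
        + (1 - d) * stats.weibull_min.logsf(t, k, scale=lam)
    )
    return -ll


@pytest.mark.parametrize("with_covariate", [False, True])
def test_aft_mle_matches_bruteforce_oracle(with_covariate):
    t, d = _censored_weibull_data(21, 28, math.log(20), 0.6, horizon=40)
    if with_covariate:
        x = np.repeat([0.0, 1.0], 14)
        t = t * np.exp(0.4 * x)  # acceleration by the covariate
        X = pd.DataFrame({"treated": x})
    else:
        X = pd.DataFrame(index=range(len(t)))
    fit = fit_weibull_aft(SurvivalSample(t, d, X))
    ours = np.array([*fit.coefficients.values(), fit.log_scale])

    Xmat = np.column_stack([np.ones(len(t)), X.to_numpy()]) if with_covariate else np.ones((len(t), 1))
    res = optimize.minimize(
        _oracle_negll, np.append(np.zeros(Xmat.shape[1]) + math.log(15), 0.0),
        args=(t, d, Xmat), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
    )
    np.testing.assert_allclose(ours, res.x, atol=1e-4)
    assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)


def test_aft_matches_lifelines():
    lifelines = pytest.importorskip("lifelines")
    design = StudyDesign(collections=("september",), containers_per_cell=5)
    subj = generate_survival(design, reference_params(), 33)
    sample = build_survival_sample(subj)
    fit = fit_weibull_aft(sample)

    df = pd.DataFrame(sample.design_matrix)
    df["T"] = sample.times
    df["E"] = sample.events
    aft = lifelines.WeibullAFTFitter().fit(df, "T", "E")
    for nm in sample.design_matrix.columns:
        assert fit.coefficients[nm] == pytest.approx(aft.params_[("lambda_", nm)], abs=5e-4)
    assert fit.coefficients["intercept"] == pytest.approx(
        aft.params_[("lambda_", "Intercept")], abs=5e-4
    )
    # lifelines parameterizes the shape rho = 1/sigma
    assert fit.log_scale == pytest.approx(-aft.params_[("rho_", "Intercept")], abs=5e-4)
    assert fit.loglik == pytest.approx(aft.log_likelihood_, abs=1e-4)
    for nm in sample.design_matrix.columns:
        assert fit.se[nm] == pytest.approx(aft.summary.loc[("lambda_", nm), "se(coef)"], rel=0.02)


def test_aft_recovers_september_preset_parameters():
    # ~2000 females under the published September model
    design = StudyDesign(collections=("september",), containers_per_cell=17)
    params = reference_params()
    subj = generate_survival(design, params, 55)
    fit = fit_weibull_aft(build_survival_sample(subj))
    truth = {
        "intercept": params.aft_intercept,
        **params.aft_coeffs,
        "log_scale": params.aft_log_scale,
    }
    for nm, true_val in truth.items():
        est = fit.log_scale if nm == "log_scale" else fit.coefficients[nm]
        assert abs(est - true_val) < 3 * fit.se[nm], nm


def test_aft_all_zero_columns_collapse_to_intercept_only():
    t, d = _censored_weibull_data(3, 60, math.log(15), 0.5, horizon=30)
    X = pd.DataFrame({"unused_a": np.zeros(60), "unused_b": np.zeros(60)})
    fit = fit_weibull_aft(SurvivalSample(t, d, X))
    assert fit.dropped == ["unused_a", "unused_b"]
    chi2, df, p = aft_lrt(fit)
    assert chi2 == pytest.approx(0.0, abs=1e-8)
    assert df == 0 and p == 1.0


def test_aft_lrt_printed_value_is_significant():
    fit = AFTFit(
        coefficients={"intercept": 0.0, "a": 0.0, "b": 0.0, "c": 0.0},
        log_scale=0.0, se={}, vcov=np.eye(5), param_names=[], loglik=-100.0,
        null_loglik=-100.0 - 162.6 / 2, n=0, n_events=0,
    )
    chi2, df, p = aft_lrt(fit)
    assert chi2 == pytest.approx(162.6)
    assert df == 3
    assert p < 1e-4


# ----------------------------- hazard ratios ------------------------------


def test_hazard_ratio_of_zero_coefficient_is_one():
    fit = aft_fit_from_estimates({"intercept": 3.0, "x": 0.0}, log_scale=-0.5)
    assert hazard_ratios(fit).set_index("factor").loc["x", "hr"] == 1.0


@settings(max_examples=40, derandomize=True, deadline=None)
@given(beta=st.floats(-2, 2), log_scale=st.floats(-1.5, 1.0))
def test_hazard_ratio_reciprocal_symmetry(beta, log_scale):
    hr_pos = hazard_ratios(aft_fit_from_estimates({"intercept": 0, "x": beta}, log_scale))
    hr_neg = hazard_ratios(aft_fit_from_estimates({"intercept": 0, "x": -beta}, log_scale))
    prod = hr_pos.loc[0, "hr"] * hr_neg.loc[0, "hr"]
    assert prod == pytest.approx(1.0, rel=1e-12)


def test_hazard_ratios_from_published_tables():
    sep = {k: v[0] for k, v in AFT_ESTIMATES["september"].items() if k not in ("log_scale",)}
    hr = hazard_ratios(
        aft_fit_from_estimates(sep, AFT_ESTIMATES["september"]["log_scale"][0])
    ).set_index("factor")["hr"]
    assert hr["pyr_1.0"] == pytest.approx(4.06, abs=0.02)
    assert hr["pyr_0.1"] == pytest.approx(1.67, abs=0.02)
    assert hr["long_day"] == pytest.approx(1.85, abs=0.02)
    aug = {k: v[0] for k, v in AFT_ESTIMATES["august"].items() if k not in ("log_scale",)}
    hr_a = hazard_ratios(
        aft_fit_from_estimates(aug, AFT_ESTIMATES["august"]["log_scale"][0])
    ).set_index("factor")["hr"]
    assert hr_a["pyr_1.0"] == pytest.approx(1.90, abs=0.02)


def test_hazard_ratio_ci_from_delta_method():
    # one-coefficient fit with known SEs: the CI must bracket the HR and
    # shrink to a point when all SEs are zero
    fit = aft_fit_from_estimates(
        {"intercept": 4.3, "x": -0.6}, -0.8, se={"x": 0.06, "log_scale": 0.04}
    )
    row = hazard_ratios(fit).iloc[0]
    assert row["lo"] < row["hr"] < row["hi"]
    point = hazard_ratios(aft_fit_from_estimates({"intercept": 4.3, "x": -0.6}, -0.8)).iloc[0]
    assert point["lo"] == pytest.approx(point["hr"]) == pytest.approx(point["hi"])
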