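"""NB GLM, hurdle and F tests: oracles, invariants, cross-validation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from parayield.design import reference_params, StudyDesign
from parayield.counts import (
    CountSample,
    UnderdispersionError,
    build_count_sample,
    eggs_per_female_day,
    emm_counts,
    fit_hurdle_nb,
    fit_nb_glm,
    term_f_tests,
    truncated_nb_mean,
)
from parayield.simulate import generate_fecundity


def _intercept_only(counts):
    return CountSample(np.asarray(counts), pd.DataFrame(index=range(len(counts))))


def test_intercept_only_mle_is_sample_mean():
    fit = fit_nb_glm(_intercept_only([10, 20, 30, 40]))
    assert fit.coefficients["intercept"] == pytest.approx(math.log(25), abs=1e-8)


def test_all_zero_counts_raise_underdispersion_error():
    with pytest.raises(UnderdispersionError, match="hurdle"):
        fit_nb_glm(_intercept_only([0, 0, 0, 0]))


def test_nb_mle_matches_bruteforce_oracle():
    # two-group sample, n = 12; oracle maximizes the same likelihood written
    # independently through scipy.stats.nbinom over (b0, b1, log theta)
    counts = np.array([3, 7, 5, 2, 9, 4, 22, 15, 30, 18, 25, 12])
    X = pd.DataFrame({"treated": np.repeat([0.0, 1.0], 6)})
    fit = fit_nb_glm(CountSample(counts, X))

    def negll(v):
        mu = np.exp(v[0] + v[1] * X["treated"].to_numpy())
        th = np.exp(v[2])
        return -np.sum(stats.nbinom.logpmf(counts, th, th / (th + mu)))

    res = optimize.minimize(
        negll, [1.5, 1.0, 1.0], method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
    )
    assert fit.coefficients["intercept"] == pytest.approx(res.x[0], abs=1e-4)
    assert fit.coefficients["treated"] == pytest.approx(res.x[1], abs=1e-4)
    assert math.log(fit.theta) == pytest.approx(res.x[2], abs=1e-3)
    assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)


def test_nb_loglik_dominates_poisson():
    # Poisson is the theta -> infinity boundary of the NB family
    counts = np.array([0, 3, 1, 9, 2, 14, 5, 0, 7, 2])
    fit = fit_nb_glm(_intercept_only(counts))
    lam = counts.mean()
    poisson_ll = float(np.sum(stats.poisson.logpmf(counts, lam)))
    assert fit.loglik >= poisson_ll - 1e-10


def test_nb_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(4)
    x = rng.binomial(1, 0.5, size=300).astype(float)
    mu = np.exp(2.0 + 0.8 * x)
    counts = rng.poisson(rng.gamma(6.0, mu / 6.0))
    fit = fit_nb_glm(CountSample(counts, pd.DataFrame({"x": x})))
    res = sm.NegativeBinomial(counts, sm.add_constant(x)).fit(disp=0)
    assert fit.coefficients["intercept"] == pytest.approx(res.params[0], abs=2e-3)
    assert fit.coefficients["x"] == pytest.approx(res.params[1], abs=2e-3)
    assert fit.theta == pytest.approx(1 / res.params[2], rel=0.02)


def test_zero_cell_breaks_nb_but_hurdle_succeeds(september_design, september_params):
    cont = generate_fecundity(september_design, september_params, 61)
    sample = build_count_sample(cont, collection="september")
    with pytest.raises(UnderdispersionError, match="hurdle"):
        fit_nb_glm(sample)
    hf = fit_hurdle_nb(sample)
    assert hf.loglik == pytest.approx(hf.zero_loglik + hf.count_loglik)
    # generating parameter recovery for the count part (log-mean structure)
    assert hf.count_coefficients["intercept"] == pytest.approx(5.172, abs=0.5)


def test_hurdle_zero_intercept_is_logit_of_positive_fraction():
    rng = np.random.default_rng(8)
    counts = rng.poisson(20, size=200) * rng.binomial(1, 0.5, size=200)
    fit = fit_hurdle_nb(_intercept_only(counts))
    frac = (counts > 0).mean()
    assert fit.zero_coefficients["intercept"] == pytest.approx(math.log(frac / (1 - frac)), abs=1e-6)
    assert not fit.zero_penalized


def test_truncated_count_part_recovers_mean():
    # zero-truncated NB draws with mean 176: the fitted truncated mean
    # mu/(1 - (theta/(theta+mu))^theta) must land within 3 SE of the formula
    mu, theta, n = 176.0, 5.0, 10_000
    rng = np.random.default_rng(10)
    draws = []
    while len(draws) < n:
        y = rng.poisson(rng.gamma(theta, mu / theta, size=2 * n))
        draws.extend(y[y > 0].tolist())
    counts = np.array(draws[:n])
    fit = fit_hurdle_nb(
        CountSample(np.append(counts, 0), pd.DataFrame(index=range(n + 1)))
    )
    fitted_mean = truncated_nb_mean(
        math.exp(fit.count_coefficients["intercept"]), fit.theta
    )
    expected = truncated_nb_mean(mu, theta)
    se = counts.std() / math.sqrt(n)
    assert abs(fitted_mean - expected) < 3 * se


def test_term_f_is_zero_when_term_absent():
    counts = np.array([12, 15, 9, 22, 30, 25, 17, 11])
    fit = fit_nb_glm(_intercept_only(counts))
    tab = term_f_tests(fit, {"ghost": ["not_in_model"]})
    assert tab.loc[0, "F"] == 0.0 and tab.loc[0, "p"] == 1.0


def test_term_f_type_one_error_calibrated():
    # null simulation: covariate has no effect; empirical alpha near 0.05
    rng = np.random.default_rng(12)
    n_sims, rejections = 400, 0
    x = np.repeat([0.0, 1.0], 10)
    X = pd.DataFrame({"x": x})
    for _ in range(n_sims):
        counts = rng.poisson(rng.gamma(8.0, 30.0 / 8.0, size=20))
        fit = fit_nb_glm(CountSample(counts, X))
        tab = term_f_tests(fit, {"x": ["x"]})
        rejections += tab.loc[0, "p"] < 0.05
    assert 0.02 < rejections / n_sims < 0.09


def test_september_terms_significant_at_paper_effect_sizes(september_design, september_params):
    hits = 0
    for seed in range(20):
        cont = generate_fecundity(september_design, september_params, 700 + seed)
        sample = build_count_sample(cont, collection="september", drop_all_zero_cells=True)
        fit = fit_nb_glm(sample)
        tab = term_f_tests(
            fit, {"chemical": ["pyr_1.0", "pyr_0.1"], "photoperiod": ["short_day"]}
        )
        hits += (tab["p"] < 0.01).all()
    assert hits >= 18  # >= 90% of replicates


def test_emm_cells_and_ratios(september_design, september_params):
    cont = generate_fecundity(september_design, september_params, 77)
    sample = build_count_sample(cont, collection="september", drop_all_zero_cells=True)
    fit = fit_nb_glm(sample)
    cells = [("acetone", "long_day"), ("pyr_1.0", "long_day")]
    emm = emm_counts(fit, cells)
    assert emm.estimates[0] == pytest.approx(math.exp(fit.coefficients["intercept"]), rel=1e-10)
    ratio = emm.estimates[1] / emm.estimates[0]
    assert ratio == pytest.approx(math.exp(fit.coefficients["pyr_1.0"]), rel=1e-10)
    assert np.all(emm.lo < emm.estimates) and np.all(emm.estimates < emm.hi)
    with pytest.raises(ValueError, match="outside the fitted design"):
        emm_counts(fit, [("no_such_chemical", "long_day")])


def test_descriptive_egg_ratios():
    assert eggs_per_female_day(7101, 15_780) == pytest.approx(0.45, abs=0.005)
    assert eggs_per_female_day(462, 3554) == pytest.approx(0.13, abs=0.005)
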