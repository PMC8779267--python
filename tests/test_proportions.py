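"""Weighted binomial logit: oracles, aggregation invariance, boundary cells."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

from parayield.design import (
    HOST_ECLOSION,
    PARASITOID_EMERGENCE,
    VIABILITY_ESTIMATES,
    cell_label,
)
from parayield.posthoc import tukey_pairs
from parayield.proportions import (
    BinomialSample,
    binom_loglik,
    build_binomial_sample,
    emm_props,
    fit_weighted_logit,
)
from parayield.simulate import generate_clutch_outcomes


def _one_cell(successes, trials, label="only"):
    return BinomialSample(
        np.asarray(successes, dtype=float),
        np.asarray(trials, dtype=float),
        [label] * len(successes),
        referent=label,
    )


def test_single_cell_intercept_is_logit_of_pooled_proportion():
    fit = fit_weighted_logit(_one_cell([35], [100]))
    assert fit.coefficients["intercept"] == pytest.approx(special.logit(0.35), abs=1e-10)


def test_saturated_single_cell_se_is_binomial_se():
    # delta method: se(p) = p(1-p) * se(logit) must equal sqrt(p(1-p)/n)
    fit = fit_weighted_logit(_one_cell([30, 12], [150, 50]))
    p = 42 / 200
    se_p = p * (1 - p) * fit.se["intercept"]
    assert se_p == pytest.approx(math.sqrt(p * (1 - p) / 200), abs=1e-10)


def test_mle_matches_bruteforce_oracle_small_sample():
    s = np.array([2.0, 10.0, 7.0, 1.0, 15.0, 9.0])
    n = np.array([20.0, 25.0, 18.0, 16.0, 30.0, 22.0])
    labels = ["a", "a", "a", "b", "b", "b"]
    sample = BinomialSample(s, n, labels, referent="a")
    fit = fit_weighted_logit(sample)

    X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])

    def negll(beta):
        return -binom_loglik(s, n, special.expit(X @ beta))

    res = optimize.minimize(negll, [0.0, 0.0], method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
    assert fit.coefficients["intercept"] == pytest.approx(res.x[0], abs=1e-6)
    assert fit.coefficients["b"] == pytest.approx(res.x[1], abs=1e-6)
    assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)


def test_clutch_aggregation_equals_egg_level_bernoulli():
    # the weighted MLE must be invariant to splitting clutches into eggs
    s = np.array([3.0, 8.0, 1.0, 12.0])
    n = np.array([10.0, 20.0, 15.0, 25.0])
    labels = ["a", "a", "b", "b"]
    agg = fit_weighted_logit(BinomialSample(s, n, labels, referent="a"))
    eggs_s, eggs_n, eggs_l = [], [], []
    for si, ni, li in zip(s, n, labels):
        eggs_s += [1.0] * int(si) + [0.0] * int(ni - si)
        eggs_n += [1.0] * int(ni)
        eggs_l += [li] * int(ni)
    egg = fit_weighted_logit(BinomialSample(np.array(eggs_s), np.array(eggs_n), eggs_l, referent="a"))
    for nm in agg.coefficients:
        assert agg.coefficients[nm] == pytest.approx(egg.coefficients[nm], abs=1e-9)


def test_preset_cell_estimates_recovered_at_large_n(september_design, september_params):
    # ~10^4 eggs per cell: back-transformed cell estimates within 2 SE of
    # the generating emergence probabilities
    params = september_params.copy(
        emergence_eggs_per_cell={c: 10_000 for c in september_params.emergence_prob},
        host_eclosion_prob={},
        eclosion_eggs_per_cell={},
    )
    clutch = generate_clutch_outcomes(september_design, params, 41)
    sample = build_binomial_sample(clutch, PARASITOID_EMERGENCE)
    fit = fit_weighted_logit(sample)
    emm = emm_props(fit)
    est = dict(zip(emm.labels, emm.estimates))
    for (chem, photo), p in september_params.emergence_prob.items():
        lbl = cell_label(chem, photo)
        se = math.sqrt(p * (1 - p) / 10_000)
        assert abs(est[lbl] - p) < 2.5 * se, lbl


def test_boundary_cell_gets_rule_of_three_interval():
    sample = BinomialSample(
        np.array([25.0, 0.0]), np.array([100.0, 90.0]), ["ok", "none"], referent="ok"
    )
    fit = fit_weighted_logit(sample)
    assert fit.boundary_cells == ["none"]
    emm = emm_props(fit)
    i = emm.labels.index("none")
    assert emm.estimates[i] == 0.0
    assert emm.lo[i] == 0.0
    assert emm.hi[i] == pytest.approx(1 - 0.05 ** (1 / 90), rel=1e-6)  # ~3/n
    assert "boundary" in emm.notes["none"]


def test_boundary_cell_continuity_fit_supports_letters():
    sample = BinomialSample(
        np.array([25.0, 0.0, 1.0]),
        np.array([100.0, 90.0, 80.0]),
        ["high", "zero", "low"],
        referent="high",
    )
    fit = fit_weighted_logit(sample, continuity=True)
    assert fit.continuity and "zero" in fit.boundary_cells
    res = tukey_pairs(emm_props(fit))
    # the two near-zero cells are indistinguishable; the high cell differs
    assert set(res.letters["zero"]) & set(res.letters["low"])
    assert not set(res.letters["high"]) & set(res.letters["zero"])


def test_identical_cells_share_letter():
    sample = BinomialSample(
        np.array([20.0, 20.0]), np.array([60.0, 60.0]), ["a", "b"], referent="a"
    )
    res = tukey_pairs(emm_props(fit_weighted_logit(sample)))
    assert set(res.letters["a"]) & set(res.letters["b"])


def test_matches_statsmodels_binomial_glm():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(6)
    n = rng.integers(15, 40, size=30).astype(float)
    x = rng.binomial(1, 0.5, size=30).astype(float)
    p = special.expit(-1.0 + 0.8 * x)
    s = rng.binomial(n.astype(int), p).astype(float)
    labels = ["t" if xi else "c" for xi in x]
    fit = fit_weighted_logit(BinomialSample(s, n, labels, referent="c"))
    res = sm.GLM(
        np.column_stack([s, n - s]), sm.add_constant(x), family=sm.families.Binomial()
    ).fit()
    assert fit.coefficients["intercept"] == pytest.approx(res.params[0], abs=1e-8)
    assert fit.coefficients["t"] == pytest.approx(res.params[1], abs=1e-8)
    assert fit.se["t"] == pytest.approx(res.bse[1], rel=1e-6)
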