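"""Generator correctness: determinism, closed-form convergence, invariants."""

import math

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest
from hypothesis import given, settings, strategies as st

from parayield.design import (
    ACETONE,
    LONG_DAY,
    PARASITOID_EMERGENCE,
    SHORT_DAY,
    ConfigurationError,
    GeneratorParams,
    StudyDesign,
    reference_params,
)
from parayield import io
from parayield.simulate import (
    _partition_into_clutches,
    generate_clutch_outcomes,
    generate_fecundity,
    generate_survival,
    simulate_study,
)

ONE_CELL = StudyDesign(
    collections=("september",),
    photoperiods=(LONG_DAY,),
    chemicals=(ACETONE,),
    containers_per_cell=300,
    followup_days=200,
)


@pytest.mark.parametrize("gen", [generate_survival, generate_fecundity, generate_clutch_outcomes])
def test_same_seed_same_table(september_design, september_params, gen):
    a = gen(september_design, september_params, 7)
    b = gen(september_design, september_params, 7)
    pdt.assert_frame_equal(a, b)
    assert a.to_csv(index=False) == b.to_csv(index=False)


def test_exponential_special_case_median():
    # sigma = 1 reduces the Weibull to an exponential with mean exp(mu):
    # the median is exp(mu) * ln 2.
    params = GeneratorParams(aft_intercept=math.log(20), aft_log_scale=0.0)
    design = StudyDesign(
        collections=("september",),
        photoperiods=(LONG_DAY,),
        chemicals=(ACETONE,),
        containers_per_cell=300,
        followup_days=10_000,
    )
    subj = generate_survival(design, params, 11)
    assert subj["event"].all()
    med = subj["time_days"].median()
    # SE of the sample median ~ 0.5 / (f(m) sqrt(n)) ~= 0.26 at n = 9000
    assert abs(med - 20 * math.log(2)) < 0.8


def test_preset_weibull_median_short_day_acetone(september_params):
    # closed-form Weibull median: exp(mu) * (ln 2)^sigma
    sigma = math.exp(september_params.aft_log_scale)
    expected = math.exp(september_params.aft_intercept) * math.log(2) ** sigma
    design = StudyDesign(
        collections=("september",),
        photoperiods=(SHORT_DAY,),
        chemicals=(ACETONE,),
        containers_per_cell=500,
        followup_days=120,
    )
    params = september_params.copy(aft_coeffs={}, egg_coeffs={})  # referent cell only
    subj = generate_survival(design, params, 13)
    med = subj.loc[subj["sex"] == "f", "time_days"].median()
    assert expected == pytest.approx(63.1, abs=0.5)  # sanity on the closed form itself
    assert abs(med - expected) < 1.5


def test_unknown_coeff_label_raises(september_design, september_params):
    bad = september_params.copy(aft_coeffs={"no_such_treatment": 1.0})
    with pytest.raises(ConfigurationError):
        generate_survival(september_design, bad, 1)


def test_fecundity_mean_matches_nb_mean(september_params):
    # referent cell, no hurdle: E[eggs] = exp(intercept) ~= 176.3
    params = september_params.copy(zero_prob={}, aft_coeffs={}, egg_coeffs={})
    cont = generate_fecundity(ONE_CELL, params, 17)
    mu = math.exp(september_params.egg_log_mean_intercept)
    n = len(cont)
    se = math.sqrt((mu**2 / september_params.nb_dispersion + mu) / n)
    assert abs(cont["total_eggs"].mean() - mu) < 3 * se


def test_fecundity_poisson_limit():
    # theta -> infinity collapses NB variance to the mean
    params = GeneratorParams(egg_log_mean_intercept=math.log(50), nb_dispersion=1e6)
    cont = generate_fecundity(ONE_CELL, params, 19)
    ratio = cont["total_eggs"].var() / cont["total_eggs"].mean()
    assert 0.75 < ratio < 1.25


def test_zero_prob_cell_and_clutch_invariant(september_design, september_params):
    cont = generate_fecundity(september_design, september_params, 23)
    zero_cell = (cont["chemical"] == ACETONE) & (cont["photoperiod"] == SHORT_DAY)
    assert (cont.loc[zero_cell, "total_eggs"] == 0).all()
    assert ((cont["total_eggs"] == 0) == (cont["n_clutches"] == 0)).all()
    max_fd = september_design.females_per_container * september_design.followup_days
    assert (cont["female_days"] <= max_fd + 1e-9).all()


def test_clutch_outcomes_match_binomial(september_design, september_params):
    cell = (ACETONE, LONG_DAY)
    params = september_params.copy(
        emergence_eggs_per_cell={cell: 10_000},
        eclosion_eggs_per_cell={cell: 500},
    )
    clutch = generate_clutch_outcomes(september_design, params, 29)
    emer = clutch[clutch["outcome_type"] == PARASITOID_EMERGENCE]
    p = september_params.emergence_prob[cell]
    n = emer["n_eggs"].sum()
    phat = emer["n_success"].sum() / n
    assert n >= 10_000
    assert abs(phat - p) < 2 * math.sqrt(p * (1 - p) / n)
    assert (emer["n_eggs"] >= 15).all()


@pytest.mark.parametrize("prob,expect", [(0.0, "none"), (1.0, "all")])
def test_clutch_outcome_probability_extremes(september_design, september_params, prob, expect):
    cell = (ACETONE, LONG_DAY)
    params = september_params.copy(
        emergence_prob={cell: prob},
        emergence_eggs_per_cell={cell: 300},
        host_eclosion_prob={},
        eclosion_eggs_per_cell={},
    )
    clutch = generate_clutch_outcomes(september_design, params, 31)
    if expect == "none":
        assert (clutch["n_success"] == 0).all()
    else:
        assert (clutch["n_success"] == clutch["n_eggs"]).all()


def test_missing_probability_for_targeted_cell_raises(september_design, september_params):
    params = september_params.copy(
        emergence_prob={},
        emergence_eggs_per_cell={(ACETONE, LONG_DAY): 100},
    )
    with pytest.raises(ConfigurationError):
        generate_clutch_outcomes(september_design, params, 1)


def test_csv_round_trip(tmp_path, september_design, september_params):
    tables = simulate_study(september_design, {"september": september_params}, 37)
    paths = io.write_tables(tables, tmp_path)
    pdt.assert_frame_equal(io.read_subjects(paths["subjects"]), tables["subjects"])
    pdt.assert_frame_equal(io.read_containers(paths["containers"]), tables["containers"])
    pdt.assert_frame_equal(io.read_clutches(paths["clutches"]), tables["clutches"])


@settings(max_examples=30, derandomize=True, deadline=None)
@given(total=st.integers(1, 2000), mean=st.floats(1.0, 60.0), seed=st.integers(0, 2**20))
def test_clutch_partition_conserves_eggs(total, mean, seed):
    rng = np.random.default_rng(seed)
    sizes = _partition_into_clutches(rng, total, mean)
    assert sum(sizes) == total
    assert all(s >= 1 for s in sizes)
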