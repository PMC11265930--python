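"""Chi-square, Mann-Whitney, binomial GLM and model competition."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given
from hypothesis import strategies as st_

from latchseq.stats import (
    SeparationError,
    akaike_weights,
    chisq_uniform_gof,
    fit_binomial_glm,
    forward_stepwise,
    lrt,
    mann_whitney,
)

# ---------------------------------------------------------------- chi-square


def test_chisq_uniform_exact_uniform_counts():
    res = chisq_uniform_gof([5, 5, 5, 5])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 3


def test_chisq_rejects_degenerate_input():
    with pytest.raises(ValueError):
        chisq_uniform_gof([0, 0, 0])
    with pytest.raises(ValueError):
        chisq_uniform_gof([5])


@given(
    st_.lists(st_.integers(0, 500), min_size=2, max_size=8).filter(
        lambda c: sum(c) > 0
    )
)
def test_chisq_matches_textbook_formula(counts):
    res = chisq_uniform_gof(counts)
    e = sum(counts) / len(counts)
    expected = sum((o - e) ** 2 / e for o in counts)
    assert res.statistic == pytest.approx(expected, abs=1e-9)
    assert res.p_value == pytest.approx(
        sps.chi2.sf(expected, len(counts) - 1), abs=1e-12
    )


# -------------------------------------------------------------- Mann-Whitney


def enumeration_p(x, y):
    """Exact two-sided p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array(
        [
            ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
            for comb in itertools.combinations(range(len(pooled)), n1)
        ]
    )
    cdf = np.mean(us <= u_obs)
    sf = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2 * min(cdf, sf))


def test_mann_whitney_fully_separated_samples():
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)


def test_mann_whitney_identical_samples_midrank_statistic():
    res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(9 / 2)  # n1 n2 / 2


def test_mann_whitney_antisymmetry():
    x, y = [0.1, 2.3, 3.1, 4.0], [1.1, 2.9, 5.6]
    a = mann_whitney(x, y)
    b = mann_whitney(y, x)
    assert a.statistic + b.statistic == pytest.approx(len(x) * len(y))
    assert a.p_value == pytest.approx(b.p_value)


def test_mann_whitney_rejects_empty_sample():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


def test_mann_whitney_exact_equals_enumeration():
    rng = np.random.default_rng(42)
    for n1 in range(1, 6):
        for n2 in range(1, 6):
            if n1 + n2 > 10:
                continue
            for _ in range(5):
                pooled = rng.permutation(
                    np.arange(1.0, n1 + n2 + 1)
                )  # distinct values: tie-free
                x, y = pooled[:n1], pooled[n1:]
                res = mann_whitney(x, y)
                u, p = enumeration_p(x, y)
                assert res.statistic == pytest.approx(u)
                assert res.p_value == pytest.approx(p, abs=1e-12)


# ---------------------------------------------------------------------- GLM


def test_intercept_only_fit_closed_form():
    y = np.array([1] * 5 + [0] * 5)
    X = pd.DataFrame(index=range(10))
    fit = fit_binomial_glm(X, y, predictors=())
    assert fit.params["const"] == pytest.approx(0.0, abs=1e-8)
    expected_dev = -2 * 10 * np.log(0.5)
    assert fit.deviance == pytest.approx(expected_dev, abs=1e-6)
    assert fit.aic == pytest.approx(expected_dev + 2, abs=1e-6)
    assert fit.aicc == pytest.approx(expected_dev + 2 + 0.5, abs=1e-6)


def test_perfect_separation_raises():
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    X = pd.DataFrame({"x": y.astype(float)})
    with pytest.raises(SeparationError):
        fit_binomial_glm(X, y)


def test_glm_recovers_simulated_coefficients():
    rng = np.random.default_rng(123)
    n = 2000
    x = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(-1 + 0.8 * x)))
    y = rng.random(n) < p
    fit = fit_binomial_glm(pd.DataFrame({"x": x}), y.astype(float))
    assert fit.params["const"] == pytest.approx(-1.0, abs=0.15)
    assert fit.params["x"] == pytest.approx(0.8, abs=0.15)
    lo, hi = fit.conf_int.loc["x"]
    assert lo < 0.8 < hi


def test_aicc_exceeds_aic_and_needs_enough_observations():
    y = np.array([1, 0, 1, 0, 1, 1, 0, 0])
    X = pd.DataFrame({"x": [0.1, 0.9, 0.8, 0.2, 0.3, 0.7, 0.4, 0.6]})
    fit = fit_binomial_glm(X, y)
    assert fit.aicc > fit.aic
    tiny = pd.DataFrame({"x": [0.1, 0.9, 0.4]})
    with pytest.raises(ValueError):
        fit_binomial_glm(tiny, np.array([1, 0, 1]))


# ---------------------------------------------------------------- stepwise


def test_stepwise_finds_single_strong_predictor():
    rng = np.random.default_rng(5)
    n = 200
    x = rng.normal(size=n)
    noise = {f"z{k}": rng.normal(size=n) for k in range(3)}
    p = 1 / (1 + np.exp(-(2.0 * x)))
    y = (rng.random(n) < p).astype(float)
    X = pd.DataFrame({"x": x, **noise})
    comp = forward_stepwise(X, y)
    assert "x" in comp.selected
    assert comp.fits[0].name == "null"
    assert comp.steps[0]["added"] == "x"


def test_stepwise_all_noise_retains_null():
    rng = np.random.default_rng(9)
    n = 35
    y = (rng.random(n) < 0.3).astype(float)
    X = pd.DataFrame({f"z{k}": rng.normal(size=n) for k in range(3)})
    comp = forward_stepwise(X, y)
    assert comp.selected == "null"


def test_stepwise_tie_breaks_by_input_order():
    rng = np.random.default_rng(1)
    n = 120
    x = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(1.5 * x)))
    y = (rng.random(n) < p).astype(float)
    X = pd.DataFrame({"a": x, "b": x.copy()})
    comp = forward_stepwise(X, y)
    assert comp.steps[0]["added"] == "a"


# --------------------------------------------------------------------- LRT


def test_lrt_identical_models_is_null():
    y = np.array([1, 0, 1, 0, 1, 0, 1, 1])
    X = pd.DataFrame({"x": np.arange(8.0)})
    null = fit_binomial_glm(X, y, predictors=())
    full = fit_binomial_glm(X, y, predictors=("x",))
    res = lrt(null, full)
    assert res.statistic >= 0.0
    assert res.df == 1
    with pytest.raises(ValueError):
        lrt(full, null)


def test_lrt_chi_square_tail_value():
    """Deviances 13.863 vs 7.313 give LRT = 6.55, p about 0.0105."""
    from latchseq.stats import ModelFit

    def stub(name, dev, k):
        return ModelFit(
            name=name, predictors=(), params=pd.Series(dtype=float),
            bse=pd.Series(dtype=float), conf_int=pd.DataFrame(),
            llf=-dev / 2, deviance=dev, k=k, n=35, aic=0, aicc=0,
        )

    res = lrt(stub("null", 13.863, 1), stub("full", 7.313, 2))
    assert res.statistic == pytest.approx(6.55, abs=1e-9)
    assert res.p_value == pytest.approx(0.0105, abs=2e-4)


# ------------------------------------------------------------ Akaike weights


def test_akaike_weights_known_values():
    assert akaike_weights([10.0]) == pytest.approx([1.0])
    w = akaike_weights([100.0, 102.0])
    assert w == pytest.approx([0.7310585786, 0.2689414214], abs=1e-9)


@given(
    st_.lists(
        st_.floats(-100, 100, allow_nan=False), min_size=1, max_size=10
    )
)
def test_akaike_weights_sum_to_one_and_shift_invariant(values):
    w = akaike_weights(values)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    w2 = akaike_weights([v + 17.5 for v in values])
    assert np.allclose(w, w2, atol=1e-9)
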