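"""Unit and property tests for the difference-with-indecision model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from otss.indecision_model import (
    DegenerateModelError,
    FitOptions,
    ModelParams,
    NonIdentifiableError,
    Order,
    ResponseCounts,
    StimulusCell,
    dk_peak_location,
    fit_model,
    negative_log_likelihood,
    response_probabilities,
)
from otss.observer_sim import aggregate_counts, counts_records, design_preset, simulate_trials

from conftest import make_counts

PHI = norm.cdf


def params_strategy():
    finite = dict(allow_nan=False, allow_infinity=False)
    return st.builds(
        lambda mu, sigma, c, w: ModelParams(mu, sigma, c - w, c + w),
        mu=st.floats(-20, 20, **finite),
        sigma=st.floats(0.2, 20, **finite),
        c=st.floats(-5, 5, **finite),
        w=st.floats(0, 8, **finite),
    )


# ---------------------------------------------------------------------------
# response probabilities
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "params, cell, expected",
    [
        # coincident criteria: symmetric split, no DK
        (ModelParams(0, 1, 0, 0), StimulusCell(0, Order.REF_SECOND), (0.5, 0.5, 0.0)),
        # unit criteria at x=0: standard-normal closed form, both orders
        (
            ModelParams(0, 1, -1, 1),
            StimulusCell(0, Order.REF_FIRST),
            (PHI(-1), PHI(-1), PHI(1) - PHI(-1)),
        ),
        (
            ModelParams(0, 1, -1, 1),
            StimulusCell(0, Order.REF_SECOND),
            (PHI(-1), PHI(-1), PHI(1) - PHI(-1)),
        ),
    ],
)
def test_closed_form_examples(params, cell, expected):
    p = response_probabilities(params, cell)
    assert p == pytest.approx(expected, abs=1e-12)


def test_probabilities_match_monte_carlo_oracle(example_params):
    """Analytic triple agrees with brute-force sampling of the generative
    rule (draw D, apply the two-criterion partition, map by order)."""
    rng = np.random.default_rng(7)
    n = 10**6
    for x, order in [(-4.0, Order.REF_FIRST), (-4.0, Order.REF_SECOND), (2.0, Order.REF_FIRST)]:
        p = example_params
        d = order.sign * (x - p.mu) + p.sigma * rng.standard_normal(n)
        second_lower = (d < p.delta1).mean()
        second_higher = (d > p.delta2).mean()
        dk = 1.0 - second_lower - second_higher
        if order is Order.REF_SECOND:
            emp = (second_higher, second_lower, dk)
        else:
            emp = (second_lower, second_higher, dk)
        ana = response_probabilities(p, StimulusCell(x, order))
        for a, e in zip(ana, emp):
            pv = max(a * (1 - a), e * (1 - e), 1e-12)
            se = math.sqrt(pv / n)
            assert abs(a - e) <= 4 * se + 1e-9


@settings(max_examples=200, derandomize=True)
@given(params=params_strategy(), x=st.floats(-40, 40, allow_nan=False))
def test_normalization_and_bounds(params, x):
    for order in Order:
        p = response_probabilities(params, StimulusCell(x, order))
        assert all(-1e-12 <= v <= 1 + 1e-12 for v in p)
        assert sum(p) == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=100, derandomize=True)
@given(params=params_strategy())
def test_monotonicity_in_x(params):
    xs = np.linspace(-30, 30, 61)
    for order in Order:
        triples = [response_probabilities(params, StimulusCell(x, order)) for x in xs]
        ph = np.array([t[0] for t in triples])
        pl = np.array([t[1] for t in triples])
        assert np.all(np.diff(ph) >= -1e-12)
        assert np.all(np.diff(pl) <= 1e-12)


@settings(max_examples=100, derandomize=True)
@given(
    mu=st.floats(-10, 10, allow_nan=False),
    sigma=st.floats(0.2, 10, allow_nan=False),
    w=st.floats(0, 5, allow_nan=False),
    x=st.floats(-20, 20, allow_nan=False),
)
def test_symmetric_criteria_make_orders_identical(mu, sigma, w, x):
    params = ModelParams(mu, sigma, -w, w)
    p1 = response_probabilities(params, StimulusCell(x, Order.REF_FIRST))
    p2 = response_probabilities(params, StimulusCell(x, Order.REF_SECOND))
    assert p1 == pytest.approx(p2, abs=1e-12)


@settings(max_examples=100, derandomize=True)
@given(params=params_strategy(), dx=st.floats(0, 25, allow_nan=False))
def test_order_averaged_dk_even_about_mu(params, dx):
    """Averaging DK over presentation orders cancels criterion bias: the
    averaged curve is an even function of x - mu."""

    def avg_dk(x):
        return 0.5 * sum(
            response_probabilities(params, StimulusCell(x, o))[2] for o in Order
        )

    assert avg_dk(params.mu + dx) == pytest.approx(avg_dk(params.mu - dx), abs=1e-12)


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        ModelParams(0, -1, 0, 1)
    with pytest.raises(ValueError):
        ModelParams(0, 1, 2, 1)
    with pytest.raises(ValueError):
        StimulusCell(float("nan"), Order.REF_FIRST)
    with pytest.raises(ValueError):
        ResponseCounts(StimulusCell(0, Order.REF_FIRST), -1, 0, 0)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def test_nll_single_bernoulli_term():
    # coincident criteria at x=mu: p_ref_higher = 0.5 exactly
    data = make_counts([(0.0, Order.REF_SECOND, 1, 0, 0)])
    nll = negative_log_likelihood(ModelParams(0, 1, 0, 0), data)
    assert nll == pytest.approx(math.log(2), abs=1e-12)


def test_zero_count_cell_contributes_nothing():
    base = make_counts([(1.0, Order.REF_FIRST, 3, 2, 1)])
    padded = base + make_counts([(5.0, Order.REF_SECOND, 0, 0, 0)])
    p = ModelParams(0, 2, -1, 1)
    assert negative_log_likelihood(p, padded) == pytest.approx(
        negative_log_likelihood(p, base)
    )


def test_nll_matches_per_trial_enumeration(rng, example_params):
    """Per-cell multinomial form equals direct summation of per-trial log
    probabilities (the combinatorial constant is omitted in both)."""
    data = []
    total = 0.0
    for x in (-6.0, -2.0, 0.0, 4.0):
        for order in Order:
            counts = rng.integers(0, 20, size=3)
            data.append(
                ResponseCounts(StimulusCell(x, order), *[int(c) for c in counts])
            )
            probs = response_probabilities(example_params, StimulusCell(x, order))
            for n_i, p_i in zip(counts, probs):
                total -= n_i * math.log(max(p_i, 1e-9))
    assert negative_log_likelihood(example_params, data) == pytest.approx(total)


def test_empty_data_rejected(example_params):
    with pytest.raises(ValueError):
        negative_log_likelihood(example_params, [])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _simulated_counts(truth, seed, condition="IsoFlat"):
    design = design_preset("exp1")
    trials = simulate_trials(design, {c: truth for c in design.conditions}, seed)
    return counts_records(aggregate_counts(trials), condition)


def test_fit_recovers_generating_parameters():
    truth = ModelParams(mu=-8.13, sigma=5.0, delta1=-1.5, delta2=2.5)
    res = fit_model(_simulated_counts(truth, seed=11), FitOptions(seed=0))
    assert res.converged
    assert res.delta_perceived_contrast == res.params.mu
    assert res.params.mu == pytest.approx(truth.mu, abs=1.0)


def test_fit_refuses_single_order(example_params):
    data = make_counts(
        [(x, Order.REF_FIRST, 5, 5, 2) for x in (-4.0, 0.0, 4.0)]
    )
    with pytest.raises(NonIdentifiableError, match="order"):
        fit_model(data)


def test_fit_refuses_single_contrast_level():
    data = make_counts(
        [(0.0, Order.REF_FIRST, 5, 5, 2), (0.0, Order.REF_SECOND, 5, 5, 2)]
    )
    with pytest.raises(NonIdentifiableError, match="level"):
        fit_model(data)


def test_fit_refuses_all_dk():
    data = make_counts(
        [(x, o, 0, 0, 10) for x in (-4.0, 4.0) for o in Order]
    )
    with pytest.raises(NonIdentifiableError, match="DK"):
        fit_model(data)


def test_zero_dk_data_pins_criteria_together():
    truth = ModelParams(mu=-3.0, sigma=4.0, delta1=0.5, delta2=0.5)
    counts = _simulated_counts(truth, seed=3)
    assert sum(c.n_dk for c in counts) == 0
    res = fit_model(counts, FitOptions(seed=0))
    assert res.criteria_collapsed
    assert res.params.delta1 == res.params.delta2
    assert res.params.mu == pytest.approx(truth.mu, abs=1.0)


def test_fit_result_serialization_roundtrip():
    truth = ModelParams(mu=-2.0, sigma=5.0, delta1=-1.5, delta2=2.5)
    counts = _simulated_counts(truth, seed=5)
    res = fit_model(counts, FitOptions(seed=0))
    d = res.to_dict(counts)
    assert d["delta_perceived_contrast"] == d["params"]["mu"]
    assert math.isfinite(d["neg_log_likelihood"])
    assert len(d["cells"]) == len(counts)
    for cell in d["cells"]:
        assert sum(cell["predicted"]) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# DK peak
# ---------------------------------------------------------------------------


def test_dk_peak_symmetric_criteria_centered_on_mu():
    res = dk_peak_location(ModelParams(-5, 3, -1, 1))
    assert res.unique
    assert res.location == pytest.approx(-5.0, abs=1e-6)


def test_dk_peak_biased_criteria_still_at_mu():
    """With the criteria midpoint off zero the two single-order DK curves
    shift in opposite directions, but their average peaks at mu."""
    res = dk_peak_location(ModelParams(2, 4, -0.5, 2.5))
    assert res.unique
    assert res.location == pytest.approx(2.0, abs=1e-4)


def test_dk_peak_detects_bimodality():
    res = dk_peak_location(ModelParams(0, 0.5, 4, 6))
    assert not res.unique
    assert len(res.locations) == 2
    lo, hi = res.locations
    assert lo == pytest.approx(-hi, abs=1e-3)
    with pytest.raises(ValueError, match="not unique"):
        _ = res.location


def test_dk_peak_degenerate_criteria_error():
    with pytest.raises(DegenerateModelError):
        dk_peak_location(ModelParams(0, 1, 1, 1))
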