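"""Derived demographic quantities: closed-form reductions, delta-method
exactness on affine maps, and admissible-range property tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mecmr.derived import (delta_method, expected_future_events, isrp,
                           prob_future_reproduction, survival_transition_curve)
from mecmr.design import logistic_age

probs = st.floats(0.01, 0.99)


def test_isrp_examples():
    assert isrp(0.0, 0.5).value == pytest.approx(1.0)  # annual breeding
    assert isrp(0.5, 0.5).value == pytest.approx(2.0)
    # age-40 high-quality point estimates
    assert isrp(0.19, 0.62).value == pytest.approx(1.3065, abs=1e-4)
    with pytest.raises(ValueError):
        isrp(0.2, 0.0)


def test_prob_future_reproduction_reductions():
    assert prob_future_reproduction(0.0, 0.3, 0.9).value == pytest.approx(0.9)
    assert prob_future_reproduction(0.4, 0.6, 1.0).value == pytest.approx(1.0)
    assert prob_future_reproduction(1.0, 1.0, 0.9).value == pytest.approx(0.81)


def test_expected_future_events():
    assert expected_future_events(1.0).value == pytest.approx(1.0)
    assert expected_future_events(0.5).value == pytest.approx(2.0)
    est = expected_future_events(0.88)
    assert est.value == pytest.approx(1.136, abs=1e-3)
    assert est.inputs["alternative"] == pytest.approx(0.88 / 0.12)
    with pytest.raises(ValueError):
        expected_future_events(0.0)


@settings(derandomize=True, max_examples=200)
@given(probs, probs, probs)
def test_admissible_ranges(psi_nb, psi_b, phi):
    assert isrp(psi_nb, psi_b).value >= 1.0
    p = prob_future_reproduction(psi_nb, psi_b, phi).value
    assert 0.0 <= p <= 1.0


def test_monotonicity_on_grid():
    grid = np.linspace(0.05, 0.95, 10)
    for psi_nb in (0.2, 0.6):
        vals_phi = [prob_future_reproduction(psi_nb, 0.5, ph).value for ph in grid]
        assert np.all(np.diff(vals_phi) >= -1e-12)
        vals_b = [prob_future_reproduction(psi_nb, b, 0.9).value for b in grid]
        assert np.all(np.diff(vals_b) >= -1e-12)
    vals_nb = [prob_future_reproduction(nb, 0.5, 0.9).value for nb in grid]
    assert np.all(np.diff(vals_nb) <= 1e-12)


def test_delta_method_exact_for_affine():
    vcov = np.array([[0.04]])
    assert delta_method(lambda t: 3.0 * t[0] + 1.0, [2.0], vcov) == pytest.approx(0.6)
    assert delta_method(lambda t: t[0], [2.0], vcov) == pytest.approx(0.2)
    V = np.array([[0.04, 0.01], [0.01, 0.09]])
    a = np.array([2.0, -1.0])
    want = np.sqrt(a @ V @ a)
    assert delta_method(lambda t: a @ t, [0.5, 0.5], V) == pytest.approx(want)


def test_delta_method_matches_parametric_bootstrap():
    """ISRP delta SE against a 10,000-draw parametric bootstrap."""
    theta = np.array([0.3, 0.6])  # (psi_nb, psi_b)
    V = np.array([[0.0025, 0.0005], [0.0005, 0.0016]])
    se_delta = isrp(*theta, vcov=V).se
    rng = np.random.default_rng(4)
    draws = rng.multivariate_normal(theta, V, size=10_000)
    draws = draws[(draws[:, 1] > 0.05)]
    boot = 1.0 + draws[:, 0] / draws[:, 1]
    assert se_delta == pytest.approx(boot.std(ddof=1), rel=0.05)


def test_survival_transition_curve_endpoints(fitted_small):
    """Curve endpoints agree with direct link evaluation of the fitted
    coefficients."""
    cfg, model, res = fitted_small
    ages = [17, 34]
    tab = survival_transition_curve(res, ages)
    b = res.params
    for a in ages:
        got = tab[(tab.target == "psi_b") & (tab.stratum == "high")
                  & (tab.age == a)]["estimate"].iloc[0]
        want = logistic_age((b["psi_b[high]:b0"], b["psi_b[high]:b1"]), a)
        assert got == pytest.approx(want, abs=1e-10)
        lo = tab[(tab.target == "psi_b") & (tab.stratum == "high")
                 & (tab.age == a)]["lower"].iloc[0]
        hi = tab[(tab.target == "psi_b") & (tab.stratum == "high")
                 & (tab.age == a)]["upper"].iloc[0]
        assert lo < want < hi


def test_survival_transition_curve_requires_quality_split(fitted_small):
    from tests.conftest import toy_design
    from mecmr.capture import CaptureHistory, CaptureHistorySet
    from mecmr.design import ParamForm
    from mecmr.model import MECMRModel

    h = CaptureHistory("x", 2000, (1, 2))
    data = CaptureHistorySet([h], (2000, 2001))
    design = toy_design(psi_r=ParamForm("psi_r"))
    res = MECMRModel(data, design).fit(n_starts=1, seed=0)
    with pytest.raises(ValueError, match="quality"):
        survival_transition_curve(res, [10])
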