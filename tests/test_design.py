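"""Parameter forms, link functions, matrix assembly and basis transforms."""

import numpy as np
import pytest

from mecmr.design import (ModelDesign, ParamForm, assemble_psi, build_matrices,
                          linear_logistic_through, logistic_age, mlogit3,
                          mlogit3_inv, paper_year_blocks,
                          quadratic_logistic_through)
from tests.conftest import random_free_design, random_theta


def test_logistic_age_symmetry_and_monotonicity():
    assert logistic_age((0.0, 0.0), 13) == pytest.approx(0.5)
    ages = np.arange(46)
    vals = logistic_age((1.0, -0.2), ages)
    assert np.all(np.diff(vals) < 0)
    assert np.all((vals > 0) & (vals < 1))


def test_logistic_age_quadratic_vertex():
    ages = np.arange(46)
    vals = logistic_age((0.0, 1.0, -0.1), ages)
    assert np.argmax(vals) == 5  # vertex of 1*x - 0.1*x^2


def test_logistic_age_wrong_coefficient_count():
    with pytest.raises(ValueError):
        logistic_age((1.0,), 5)
    with pytest.raises(ValueError):
        logistic_age((1.0, 2.0, 3.0, 4.0), 5)


def test_anchor_constructors_pass_through_points():
    b = linear_logistic_through((17, 0.78), (34, 0.66))
    assert logistic_age(b, 17) == pytest.approx(0.78)
    assert logistic_age(b, 34) == pytest.approx(0.66)
    q = quadratic_logistic_through((7, 0.02), (16, 0.19), vertex=20,
                                   link=mlogit3_inv)
    assert mlogit3(q[0] + q[1] * 7 + q[2] * 49) == pytest.approx(0.02)
    assert mlogit3(q[0] + q[1] * 16 + q[2] * 256) == pytest.approx(0.19)
    assert -q[1] / (2 * q[2]) == pytest.approx(20)


def test_mlogit3_stays_below_one_third():
    eta = np.linspace(-20, 20, 101)
    p = mlogit3(eta)
    assert np.all(p < 1 / 3) and np.all(p > 0)


def test_juvenile_row_under_recruitment_tie():
    psi = assemble_psi(0.3, (0.5, 0.5), (0.2, 0.2))
    np.testing.assert_allclose(psi[0], [0.1, 0.3, 0, 0, 0.3, 0.3, 0, 0], atol=1e-12)


def test_recruitment_above_one_third_rejected():
    with pytest.raises(ValueError, match="1/3"):
        assemble_psi(0.4, (0.5, 0.5), (0.2, 0.2))


def test_all_rows_stochastic_for_random_theta():
    rng = np.random.default_rng(0)
    design = random_free_design()
    compiled = design.compile((2000, 2010), max_age=12)
    for _ in range(20):
        theta = random_theta(compiled, rng)
        for age in (0, 5, 12):
            for year in (2000, 2003, 2010):
                phi, psi, p = build_matrices(compiled, theta, age, year)
                for m in (phi, psi, p):
                    np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
                    assert np.all(m >= 0)


def test_degenerate_breeders_absorbing():
    """With survival one and departures zero, phi @ psi keeps breeders in
    their quality class forever."""
    from mecmr.design import assemble_phi

    phi = assemble_phi((1, 1, 1, 1))
    psi = assemble_psi(0.0, (0.7, 0.7), (0.0, 0.0))
    M = phi @ psi
    assert M[4, 4] == 1.0 and M[5, 5] == 1.0


def test_basis_transform_round_trip_and_invariance():
    rng = np.random.default_rng(1)
    design = random_free_design()
    compiled = design.compile((2000, 2010), max_age=12)
    theta = random_theta(compiled, rng)
    back = compiled.from_internal(compiled.to_internal(theta))
    np.testing.assert_allclose(back, theta, atol=1e-10)
    s1 = compiled.schedules(theta)
    s2 = compiled.schedules(compiled.from_internal(compiled.to_internal(theta)))
    for k in s1:
        np.testing.assert_allclose(s1[k], s2[k], atol=1e-10)


def test_paper_year_blocks_clip_to_range():
    assert paper_year_blocks(1966, 2018) == [
        (1966, 1984), (1985, 2001), (2002, 2003), (2004, 2018)]
    assert paper_year_blocks(1990, 2000) == [(1990, 2000)]


def test_design_serialization_round_trip():
    d = random_free_design()
    d2 = ModelDesign.from_dict(d.to_dict())
    assert d2.to_dict() == d.to_dict()
    c1 = d.compile((2000, 2010), 12)
    c2 = d2.compile((2000, 2010), 12)
    assert c1.labels == c2.labels


def test_recruitment_age_form_warning():
    with pytest.warns(UserWarning, match="recruitment"):
        ParamForm("psi_r", age="linear")


def test_detection_cannot_take_age_form():
    with pytest.raises(ValueError):
        ParamForm("p", age="linear")
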