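"""Leslie-matrix construction and life-history traits against hand-computed
values and definitional calibrations."""

import numpy as np
import pytest

from mecmr.leslie import LeslieModel, ReducibleMatrixError, build_leslie, gini_index


def model_from_lx_mx(lx, mx, afr=None, tail_phi=0.0):
    """Survival schedule implied by a survivorship vector."""
    lx = np.asarray(lx, float)
    phi = np.empty_like(lx)
    phi[:-1] = lx[1:] / lx[:-1]
    phi[-1] = tail_phi
    if afr is None:
        afr = int(np.argmax(np.asarray(mx) > 0))
    return LeslieModel(phi, np.asarray(mx, float), afr)


def test_growth_rate_euler_lotka_hand_case():
    L = model_from_lx_mx([1.0, 0.5], [0.0, 4.0])
    lam, r = L.growth_rates()
    assert lam == pytest.approx(2.0, abs=1e-10)
    assert r == pytest.approx(np.log(2.0))
    assert abs(L.euler_lotka_residual()) < 1e-10


def test_fecundity_scaling_identity():
    lx = [1.0, 0.6, 0.3, 0.12]
    mx = [0.0, 1.0, 2.0, 1.5]
    for c in (0.5, 2.0):
        L = model_from_lx_mx(lx, np.asarray(mx) * c)
        lam = L.lam
        x = np.arange(4)
        assert np.sum(lam ** (-x.astype(float)) * L.lx * L.mx) == pytest.approx(1.0, abs=1e-9)


def test_replacement_level():
    """Single reproductive age with l_k m_k = 1 gives lambda = 1."""
    lx = [1.0, 0.5, 0.25]
    mx = [0.0, 1.0, 2.0]  # R0 = 0.5 + 0.5 = 1
    L = model_from_lx_mx(lx, mx)
    assert L.lam == pytest.approx(1.0, abs=1e-10)


def test_r0_and_generation_time():
    L = model_from_lx_mx([1.0, 0.5], [0.0, 4.0])
    R0, T = L.r0_and_generation_time()
    assert R0 == pytest.approx(2.0)
    assert T == pytest.approx(1.0)  # ln 2 / ln 2
    L2 = model_from_lx_mx([1.0, 0.5, 0.25], [0.0, 1.0, 2.0])
    R02, T2 = L2.r0_and_generation_time()
    assert R02 == pytest.approx(1.0)
    # lambda = 1: fecundity-weighted mean age
    assert T2 == pytest.approx((1 * 0.5 + 2 * 0.5) / 1.0)


def test_r0_doubles_with_fecundity():
    base = model_from_lx_mx([1.0, 0.5, 0.25], [0.0, 1.0, 2.0])
    dbl = model_from_lx_mx([1.0, 0.5, 0.25], [0.0, 2.0, 4.0])
    assert dbl.r0_and_generation_time()[0] == pytest.approx(
        2 * base.r0_and_generation_time()[0])


def test_life_expectancies():
    # constant survival 0.5 over many classes: e0 -> 2
    n = 60
    phi = np.full(n, 0.5)
    mx = np.zeros(n)
    mx[1:] = 1.0
    L = LeslieModel(phi, mx, afr=1)
    e0, e_adult = L.life_expectancies()
    assert e0 == pytest.approx(2.0, abs=1e-6)
    # survival zero everywhere: only the current year is lived
    phi0 = np.zeros(3)
    L0 = LeslieModel(phi0, np.array([0.0, 1.0, 0.0]), afr=1)
    assert L0.life_expectancies()[0] == pytest.approx(1.0)
    # phi = (1, 0.5, 0): e0 = 1 + 1 + 0.5 = 2.5
    L1 = model_from_lx_mx([1.0, 1.0, 0.5], [0.0, 1.0, 1.0])
    assert L1.life_expectancies()[0] == pytest.approx(2.5)


def test_gini_hand_values():
    assert gini_index([0.0, 0.0, 1.0]) == pytest.approx(2 / 3)
    assert gini_index([0.3, 0.3, 0.3, 0.3]) == pytest.approx(0.0)
    assert gini_index([0.2, 0.8]) == pytest.approx(0.3)
    # scale invariance
    assert gini_index([2.0, 8.0]) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        gini_index([0.0, 0.0])


def test_reproductive_value_hand_case():
    L = model_from_lx_mx([1.0, 0.5, 0.25], [0.0, 1.0, 2.0])  # lambda = 1
    tab = L.reproductive_value()
    assert tab["vx"].iloc[0] == pytest.approx(1.0, abs=1e-9)  # Euler-Lotka
    assert tab["vx"].iloc[1] == pytest.approx(2.0, abs=1e-9)
    # past the last reproduction there is no residual value
    assert tab["residual_vx"].iloc[2] == pytest.approx(0.0, abs=1e-12)


def test_shapes_vanish_on_constant_rate_schedules():
    n = 40
    phi = np.full(n, 0.8)
    mx = np.zeros(n)
    mx[5:] = 2.0
    L = LeslieModel(phi, mx, afr=5)
    _, _, shape_surv, shape_rep = L.pace_shape()
    assert abs(shape_surv) < 1e-6
    assert abs(shape_rep) < 1e-6


def test_shape_signs():
    n = 40
    ages = np.arange(n, dtype=float)
    # Gompertz-increasing hazard -> positive survival shape
    hazard = 0.02 * np.exp(0.15 * ages)
    phi = np.exp(-hazard)
    mx = np.zeros(n)
    mx[5:] = 2.0
    L = LeslieModel(phi, mx, afr=5)
    assert L.pace_shape()[2] > 0
    # reproduction shifted late -> negative reproduction shape
    mx_late = np.zeros(n)
    mx_late[5:] = np.linspace(0.1, 4.0, n - 5)
    L2 = LeslieModel(np.full(n, 0.8), mx_late, afr=5)
    assert L2.pace_shape()[3] < 0
    # reproduction front-loaded -> positive
    mx_early = np.zeros(n)
    mx_early[5:] = np.linspace(4.0, 0.1, n - 5)
    L3 = LeslieModel(np.full(n, 0.8), mx_early, afr=5)
    assert L3.pace_shape()[3] > 0


def test_build_leslie_fecundity_adjustment():
    phi = np.full(46, 0.9)
    eggs = np.zeros(46)
    eggs[7:] = 340.0
    L = build_leslie(phi, eggs, isrp_population=1.7, afr=7)
    assert L.mx[7] == pytest.approx(100.0)  # 340 / 2 / 1.7
    assert np.all(L.mx[:7] == 0)
    assert L.F[0, :6].sum() == 0.0


def test_no_reproduction_raises_reducibility_error():
    with pytest.raises(ReducibleMatrixError):
        build_leslie(np.full(10, 0.9), np.zeros(10), 1.7, afr=3)


def test_unreachable_reproductive_classes_named():
    phi = np.array([0.9, 0.0, 0.9, 0.9])  # survivorship dies at age 2
    mx = np.array([0.0, 0.0, 1.0, 1.0])
    with pytest.raises(ReducibleMatrixError) as exc:
        LeslieModel(phi, mx, afr=2).verify()
    assert 2 in exc.value.classes or 3 in exc.value.classes


def test_euler_lotka_residual_property(small_cohort):
    """Every built model satisfies the Euler-Lotka equation to 1e-8."""
    rng = np.random.default_rng(8)
    for _ in range(20):
        n = int(rng.integers(10, 50))
        phi = rng.uniform(0.3, 0.95, n)
        mx = np.zeros(n)
        afr = int(rng.integers(1, min(6, n - 1)))
        mx[afr:] = rng.uniform(0.1, 3.0, n - afr)
        L = LeslieModel(phi, mx, afr)
        assert abs(L.euler_lotka_residual()) < 1e-8
        tab = L.reproductive_value()
        assert tab["vx"].iloc[0] == pytest.approx(1.0, abs=1e-8)
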