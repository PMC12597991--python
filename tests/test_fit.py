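"""Maximum-likelihood fitting: closed forms, fixed points, multistart
behaviour, identifiability diagnostics and information criteria."""

import numpy as np
import pytest

from mecmr.capture import CaptureHistory, CaptureHistorySet
from mecmr.design import ParamForm, mlogit3
from mecmr.model import MECMRModel, check_identifiability, model_table, qaicc, qsic
from mecmr.simulate import default_config, generating_design, generating_theta, simulate_cohort
from tests.conftest import toy_design


def test_two_occasion_recruitment_closed_form():
    """With everything else pinned and perfect detection, the MLE of the tied
    recruitment parameter is (number leaving J) / (3 N)."""
    n_stay, n_sa, n_b = 40, 15, 35
    hists = (
        [CaptureHistory(f"s{i}", 2000, (1, 1)) for i in range(n_stay)]
        + [CaptureHistory(f"a{i}", 2000, (1, 2)) for i in range(n_sa)]
        + [CaptureHistory(f"b{i}", 2000, (1, 4)) for i in range(n_b)]
    )
    data = CaptureHistorySet(hists, (2000, 2001))
    design = toy_design(psi_r=ParamForm("psi_r"), p=ParamForm("p", fixed=1.0))
    model = MECMRModel(data, design)
    res = model.fit(n_starts=4, seed=0)
    want = (n_sa + n_b) / (3 * (n_stay + n_sa + n_b))
    assert mlogit3(res.params.iloc[0]) == pytest.approx(want, abs=1e-5)


def test_refit_from_optimum_is_fixed_point(fitted_small):
    cfg, model, res = fitted_small
    refit = model.fit(n_starts=0, start_params=res.params.values,
                      compute_vcov=False)
    assert refit.deviance == pytest.approx(res.deviance, abs=1e-4)


def test_parameter_recovery_single_cohort(fitted_small):
    """A single n=400 cohort: every generating coefficient within 4 SE (the
    dedicated acceptance test measures coverage over 20 cohorts)."""
    cfg, model, res = fitted_small
    truth = generating_theta(cfg)
    z = np.abs((res.params.values - truth) / res.bse.values)
    assert res.vcov_ok
    assert np.all(z < 4.0), dict(zip(res.labels, z.round(2)))


def test_more_starts_never_worse():
    cfg = default_config(n_individuals=60, seed=21)
    _, hist = simulate_cohort(cfg)
    model = MECMRModel(hist, generating_design(cfg))
    d1 = model.fit(n_starts=1, seed=5, compute_vcov=False).deviance
    d3 = model.fit(n_starts=3, seed=5, compute_vcov=False).deviance
    assert d3 <= d1 + 1e-6


def test_vcov_is_symmetric_psd(fitted_small):
    _, _, res = fitted_small
    V = res.cov_params().values
    np.testing.assert_allclose(V, V.T, atol=1e-10)
    assert np.all(np.linalg.eigvalsh(V) > -1e-10)


def test_identifiability_flags_uninformed_parameter():
    """With survival pinned at 1 nobody dies, so the dead-recovery rate has
    no information: its SE collapses and pinning it leaves the deviance
    unchanged."""
    cfg = default_config(n_individuals=80, seed=31)
    cfg.surv_coeffs = (30.0, 0.0)  # survival ~ 1: no deaths, no FD events
    _, hist = simulate_cohort(cfg)
    design = toy_design(psi_r=ParamForm("psi_r"), p_fd=ParamForm("p_fd"),
                        phi=ParamForm("phi", fixed=1.0))
    model = MECMRModel(hist, design)
    with pytest.warns(UserWarning, match="singular Hessian"):
        res = model.fit(n_starts=2, seed=1)
    rep = check_identifiability(res)
    assert "p_fd:b0" in rep.non_identifiable


def test_identifiability_clean_on_well_posed_fit(fitted_small):
    _, _, res = fitted_small
    rep = check_identifiability(res)
    assert rep.ok and not rep.suspect


def test_qsic_and_qaicc_arithmetic():
    assert qsic(100, 1.0, 100, 5) == pytest.approx(100 + 5 * np.log(100))
    assert qsic(100, 2.0, 100, 5) == pytest.approx(50 + 5 * np.log(100))
    assert qaicc(100, 1.0, 100, 5) == pytest.approx(100 + 10 + 60 / 94)
    with pytest.raises(ValueError):
        qaicc(100, 1.0, 6, 5)
    with pytest.raises(ValueError):
        qsic(100, 0.5, 100, 5)


class _FakeFit:
    def __init__(self, name, deviance, K, nobs):
        from mecmr.design import ModelDesign

        self.design = ModelDesign(name=name)
        self.deviance = deviance
        self.K = K
        self.nobs = nobs


def test_model_table_strong_evidence_rule():
    """Fits separated by less than 7 QSIC units are never flagged as
    strongly distinguished."""
    a = _FakeFit("a", 100.0, 5, 100)
    b = _FakeFit("b", 106.9, 5, 100)  # dQSIC = 6.9
    tab = model_table([a, b], c_hat=1.0)
    assert not tab["strongly_outperformed"].any()
    c = _FakeFit("c", 107.2, 5, 100)  # dQSIC = 7.2
    tab2 = model_table([a, c], c_hat=1.0)
    assert tab2.loc[1, "strongly_outperformed"]
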