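import numpy as np
import pytest

from mecmr.capture import CaptureHistory, CaptureHistorySet
from mecmr.design import ModelDesign, ParamForm, build_matrices, mlogit3_inv
from mecmr.simulate import default_config, generating_design, generating_theta, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated cohort at modest size, shared across tests."""
    cfg = default_config(n_individuals=400, seed=11)
    truth, hist = simulate_cohort(cfg)
    return cfg, truth, hist


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    from mecmr.model import MECMRModel

    cfg, truth, hist = small_cohort
    model = MECMRModel(hist, generating_design(cfg))
    res = model.fit(n_starts=1, seed=3, start_params=generating_theta(cfg))
    return cfg, model, res


def toy_design(**overrides):
    """Small fully-pinned design with selected targets freed."""
    forms = {
        "phi": ParamForm("phi", fixed=0.9),
        "psi_r": ParamForm("psi_r", fixed=0.15),
        "psi_b": ParamForm("psi_b", fixed=0.5),
        "psi_nb": ParamForm("psi_nb", fixed=0.3),
        "p": ParamForm("p", fixed=0.9),
        "p_sa": ParamForm("p_sa", fixed=1.0),
        "p_fd": ParamForm("p_fd", fixed=0.5),
    }
    forms.update(overrides)
    return ModelDesign(forms=forms, name="toy")


def random_free_design():
    """Unpinned design exercising every form family."""
    return ModelDesign(forms={
        "phi": ParamForm("phi", age="linear"),
        "psi_r": ParamForm("psi_r", age="quadratic"),
        "psi_b": ParamForm("psi_b", age="linear", by_quality=True),
        "psi_nb": ParamForm("psi_nb", by_quality=True),
        "p": ParamForm("p", time="blocks", by_quality=True),
        "p_sa": ParamForm("p_sa"),
        "p_fd": ParamForm("p_fd"),
    }, name="random")


def random_theta(compiled, rng):
    """Raw-basis coefficients giving moderate, well-conditioned probabilities."""
    theta = np.empty(compiled.K)
    for b in compiled.blocks:
        for j, lab in enumerate(b.labels):
            i = b.offset + j
            if b.kind == "linear" and j == 1:
                theta[i] = rng.uniform(-0.15, 0.15)
            elif b.kind == "quadratic" and j >= 1:
                theta[i] = rng.uniform(-0.05, 0.05) if j == 1 else rng.uniform(-0.01, 0.005)
            else:
                theta[i] = rng.uniform(-1.5, 1.5)
    return theta


def sample_history(compiled, theta, rng, first_year, n_occasions):
    """Draw one event sequence from the model itself (always possible)."""
    from mecmr.likelihood import emission_tensor, transition_tensor

    s = compiled.schedules(theta)
    M = transition_tensor(s)
    E = emission_tensor(s)
    state = 0
    events = [1]
    yi0 = first_year - compiled.first_year
    for t in range(1, n_occasions):
        age = t - 1
        state = rng.choice(8, p=M[min(age, compiled.max_age)][state])
        events.append(rng.choice(6, p=E[yi0 + t][state]))
    return CaptureHistory("X0", first_year, tuple(int(e) for e in events))


def brute_force_loglik(history, compiled, theta):
    """Exhaustive 8^(T-1) path sum through the per-occasion matrices built by
    the public single-(age, year) constructor -- independent of the forward
    recursion under test."""
    T = len(history.events)
    Ms, Es = [], []
    for t in range(1, T):
        phi, psi, p = build_matrices(compiled, theta, age=t - 1,
                                     year=history.birth_year + t)
        Ms.append(phi @ psi)
        Es.append(p)
    n_paths = 8 ** (T - 1)
    if T == 1:
        return 0.0
    paths = np.indices((8,) * (T - 1)).reshape(T - 1, n_paths)
    prob = np.ones(n_paths)
    prev = np.zeros(n_paths, dtype=int)  # start in J
    for t in range(T - 1):
        cur = paths[t]
        prob *= Ms[t][prev, cur] * Es[t][cur, history.events[t + 1]]
        prev = cur
    total = prob.sum()
    return np.log(total) if total > 0 else -np.inf
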