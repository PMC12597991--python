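"""Interval construction and the Cox / zero-truncated-Poisson stages."""

import numpy as np
import pandas as pd
import pytest

from mecmr.capture import BreedingRecord, CaptureHistory, CaptureHistorySet
from mecmr.interarrival import (build_interval_table, fit_cox, fit_ztp,
                                percent_change, ph_check)


def history_with_breeding(breeding_ages, birth=1990, end=2010, death_age=None):
    T = end - birth + 1
    events = [1] * T
    for a in breeding_ages:
        events[a] = 4
    for a in range(min(breeding_ages, default=T), T):
        if events[a] == 1 and a > 0:
            events[a] = 0
    if death_age is not None:
        events[death_age] = 5
        for a in range(death_age + 1, T):
            events[a] = 0
    events[0] = 1
    h = CaptureHistory("f1", birth, tuple(events))
    recs = [BreedingRecord("f1", birth + a, 2, 200) for a in breeding_ages]
    return recs, CaptureHistorySet([h], (birth, end))


def test_interval_construction_example():
    """Breeding at ages 10, 11, 14: closed intervals of 1 and 3 years with
    experience 1 and 2; the trailing interval is censored at the study end."""
    recs, hist = history_with_breeding([10, 11, 14])
    tab = build_interval_table(recs, hist)
    closed = tab[~tab.censored]
    assert list(closed.interval_years) == [1, 3]
    assert list(closed.experience) == [1, 2]
    assert list(closed.age) == [10, 11]
    assert (closed.afr == 10).all()
    cens = tab[tab.censored]
    assert len(cens) == 1
    assert cens.interval_years.iloc[0] == (2010 - 1990) - 14


def test_single_breeding_year_gives_censored_only():
    recs, hist = history_with_breeding([12])
    tab = build_interval_table(recs, hist)
    assert len(tab) == 1 and tab.censored.all()


def test_no_breeding_gives_empty_table():
    tab = build_interval_table([], CaptureHistorySet(
        [CaptureHistory("a", 1990, (1, 1, 1))], (1990, 1992)))
    assert len(tab) == 0


def test_censoring_stops_at_death():
    recs, hist = history_with_breeding([10], death_age=13)
    tab = build_interval_table(recs, hist)
    assert tab.interval_years.iloc[0] == 3


def test_record_in_non_breeding_year_rejected():
    recs, hist = history_with_breeding([10])
    bad = recs + [BreedingRecord("f1", 1990 + 12, 1, 100)]
    with pytest.raises(ValueError, match="code 4"):
        build_interval_table(bad, hist)


def test_cumulative_effort_columns():
    recs, hist = history_with_breeding([10, 11, 14])
    tab = build_interval_table(recs, hist).sort_values("start_year")
    assert list(tab.clutches_cum) == [2, 4, 6]
    assert list(tab.eggs_cum) == [200, 400, 600]


def test_percent_change_examples():
    assert percent_change(0.0) == 0.0
    assert percent_change(np.log(1.21)) == pytest.approx(21.0)
    assert percent_change(np.log(0.88)) == pytest.approx(-12.0)


def cox_table(rng, n, beta, censor_frac=0.0):
    g = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / np.exp(beta * g))
    cens = rng.random(n) < censor_frac
    return pd.DataFrame({
        "id": [f"i{k}" for k in range(n)],
        "interval_years": t,
        "censored": cens,
        "group": g,
    })


def test_cox_null_covariate_hr_near_one():
    rng = np.random.default_rng(5)
    tab = cox_table(rng, 1500, beta=0.0)
    fit = fit_cox(tab, ["group"])
    assert abs(fit.params["group"]) < 3 * fit.bse["group"]
    assert abs(fit.hr["group"] - 1.0) < 0.2


def test_cox_all_censored_errors():
    rng = np.random.default_rng(6)
    tab = cox_table(rng, 50, beta=0.0, censor_frac=1.0)
    with pytest.raises(ValueError, match="censored"):
        fit_cox(tab, ["group"])


def test_cox_requires_covariates():
    rng = np.random.default_rng(7)
    with pytest.raises(ValueError, match="covariate"):
        fit_cox(cox_table(rng, 50, 0.0), [])


def test_ph_check_runs_and_is_well_behaved_under_proportionality():
    rng = np.random.default_rng(8)
    tab = cox_table(rng, 800, beta=np.log(2.0))
    fit = fit_cox(tab, ["group"])
    ph = ph_check(fit)
    assert ph.global_df == 1
    assert 0.0 <= ph.global_p <= 1.0


def ztp_draw(rng, lam):
    lam = np.asarray(lam, dtype=float)
    out = np.zeros(lam.shape, dtype=int)
    todo = np.ones(lam.shape, dtype=bool)
    while todo.any():
        draw = rng.poisson(lam[todo])
        out[np.flatnonzero(todo)[draw > 0]] = draw[draw > 0]
        idx = np.flatnonzero(todo)
        todo[idx[draw > 0]] = False
    return out


def test_ztp_requires_positive_outcomes():
    tab = pd.DataFrame({"interval_years": [0, 1, 2], "censored": [False] * 3,
                        "age": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="zero-truncated"):
        fit_ztp(tab, ["age"])


def test_ztp_intercept_only_recovers_truncated_mean():
    rng = np.random.default_rng(9)
    y = ztp_draw(rng, np.full(3000, 2.0))
    tab = pd.DataFrame({"interval_years": y, "censored": False,
                        "age": np.zeros(len(y))})
    fit = fit_ztp(tab, [])
    lam_hat = np.exp(fit.params["const"])
    assert lam_hat == pytest.approx(2.0, abs=0.15)


def test_ztp_vif_reported_for_multiple_covariates():
    rng = np.random.default_rng(10)
    n = 500
    age = rng.uniform(8, 30, n)
    exp_ = rng.uniform(1, 10, n)
    lam = np.exp(0.1 + 0.02 * age - 0.03 * exp_)
    y = ztp_draw(rng, lam)
    tab = pd.DataFrame({"interval_years": y, "censored": False,
                        "age": age, "experience": exp_})
    fit = fit_ztp(tab, ["age", "experience"])
    assert np.isfinite(fit.vif["age"]) and fit.vif["age"] < 2.0
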