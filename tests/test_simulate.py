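"""Synthetic-cohort generator: determinism, structural validity, anchored
defaults, and law-of-large-numbers convergence to the generating rates."""

import numpy as np
import pytest

from mecmr.capture import validate_set
from mecmr.design import logistic_age
from mecmr.simulate import (SimConfig, default_config, simulate_breeding_output,
                            simulate_cohort)

ALLOWED = {
    "J": {"J", "SA", "B"},
    "SA": {"SA", "B"},
    "NB": {"NB", "B", "FD"},
    "B": {"B", "NB", "FD"},
    "FD": {"D"},
    "D": {"D"},
}


def test_default_config_matches_reported_point_estimates():
    cfg = default_config()
    assert cfg.surv_coeffs[1] == pytest.approx(-0.49)
    assert cfg.arrival_prob(17, "high") == pytest.approx(0.78, abs=1e-6)
    assert cfg.arrival_prob(34, "high") == pytest.approx(0.66, abs=1e-6)
    assert cfg.arrival_prob(17, "low") == pytest.approx(0.33, abs=1e-6)
    assert cfg.recruit_prob(7) == pytest.approx(0.02, abs=1e-6)
    assert cfg.recruit_prob(16) == pytest.approx(0.19, abs=1e-6)
    assert cfg.departure_prob(40, "high") == pytest.approx(0.19, abs=1e-6)
    assert cfg.quality_mix == 0.5


def test_same_seed_identical_outputs():
    cfg = default_config(n_individuals=100, seed=5)
    t1, h1 = simulate_cohort(cfg)
    t2, h2 = simulate_cohort(cfg)
    assert h1 == h2
    assert [t.state_by_year for t in t1] == [t.state_by_year for t in t2]
    b1 = simulate_breeding_output(t1, cfg)
    b2 = simulate_breeding_output(t2, cfg)
    assert b1 == b2


def test_state_sequences_respect_transition_graph(small_cohort):
    cfg, truth, hist = small_cohort
    assert validate_set(hist).ok
    for tr in truth:
        seq = tr.state_by_year
        assert seq[0] == "J"
        for a, b in zip(seq, seq[1:]):
            assert b in ALLOWED[a], (a, b)
        # FD lasts exactly one occasion unless the study ends there
        for k, s in enumerate(seq[:-1]):
            if s == "FD":
                assert seq[k + 1] == "D"
        if "NB" in seq or "B" in seq:
            assert tr.recruit_age is not None


def test_degenerate_breeder_absorbing():
    """No departures, certain detection: every recruited animal is seen as a
    breeder every year from recruitment until freshly dead."""
    cfg = default_config(n_individuals=150, seed=9)
    cfg.departure_coeffs_by_quality = {"low": (-30.0, 0.0), "high": (-30.0, 0.0)}
    cfg.detect_by_block_and_quality = {"low": (1.0,) * 4, "high": (1.0,) * 4}
    truth, hist = simulate_cohort(cfg)
    for tr, h in zip(truth, hist):
        for k, s in enumerate(tr.state_by_year):
            if s == "B":
                assert h.events[k] == 4
            if s == "NB":
                pytest.fail("departure disabled but a non-breeder appeared")


def test_empirical_rates_match_generating_values():
    """Law of large numbers at n=10000: empirical annual adult survival,
    arrival and departure frequencies sit within 3 Monte-Carlo SEs of the
    configured probabilities."""
    cfg = default_config(n_individuals=10_000, seed=13)
    truth, hist = simulate_cohort(cfg)
    # pooled adult survival close to the anchored 0.91
    surv = died = 0
    arr_trials = {"low": [0, 0], "high": [0, 0]}  # [arrivals, at-risk] at age 20
    for tr in truth:
        seq = tr.state_by_year
        for k in range(len(seq) - 1):
            if seq[k] in ("NB", "B"):
                if seq[k + 1] in ("NB", "B"):
                    surv += 1
                else:
                    died += 1
            if seq[k] == "NB" and k == 20 and seq[k + 1] != "FD":
                arr_trials[tr.quality][1] += 1
                arr_trials[tr.quality][0] += int(seq[k + 1] == "B")
    pooled = surv / (surv + died)
    assert pooled == pytest.approx(0.91, abs=0.02)
    for q in ("low", "high"):
        k, n = arr_trials[q][0], arr_trials[q][1]
        p = cfg.arrival_prob(20, q)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(k / n - p) < 3 * se, (q, k / n, p)


def test_breeding_output_only_for_breeding_years(small_cohort):
    cfg, truth, hist = small_cohort
    records = simulate_breeding_output(truth, cfg)
    byear = {(t.individual_id): t for t in truth}
    for r in records:
        tr = byear[r.individual_id]
        assert tr.state_by_year[r.season_year - tr.birth_year] == "B"
        assert 1 <= r.n_clutches <= cfg.max_clutches
        assert r.n_eggs >= r.n_clutches
    non_breeders = [t for t in truth if "B" not in t.state_by_year]
    ids_with_records = {r.individual_id for r in records}
    assert all(t.individual_id not in ids_with_records for t in non_breeders)


def test_breeding_output_mean_eggs():
    """Mean eggs per season ~ mean clutches x mean clutch size (Monte Carlo)."""
    cfg = default_config(n_individuals=400, seed=17)
    cfg.mean_clutches = 5.0
    cfg.max_clutches = 50  # effectively untruncated for this check
    cfg.mean_clutch_size = 100.0
    truth, _ = simulate_cohort(cfg)
    recs = simulate_breeding_output(truth, cfg)
    eggs = np.array([r.n_eggs for r in recs])
    # zero-truncated Poisson(5) mean = 5/(1-e^-5)
    want = 5.0 / (1 - np.exp(-5)) * 100.0
    assert eggs.mean() == pytest.approx(want, rel=0.03)


def test_invalid_config_rejected_before_simulation():
    cfg = default_config()
    cfg.quality_mix = 1.5
    with pytest.raises(ValueError, match="quality_mix"):
        simulate_cohort(cfg)
    cfg2 = default_config()
    cfg2.recruit_coeffs = (10.0, 0.0, 0.0)  # would push psi_r toward 1/3
    # mlogit link keeps psi_r < 1/3, so this remains valid
    simulate_cohort(SimConfig.from_dict({**cfg2.to_dict(), "n_individuals": 5}))
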