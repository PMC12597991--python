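"""Derived demographic quantities from fitted transition parameters, with
delta-method uncertainty.

For a surviving female with age-class departure probability psi_nb (breeder
-> non-breeder) and arrival probability psi_b (non-breeder -> breeder):

* inter-seasonal reproductive period  ISRP = 1 + psi_nb / psi_b,
  the expected number of years between successive breeding seasons;
* probability of a subsequent reproductive event
  P = (1 - psi_nb) phi + psi_nb psi_b phi^2 / (1 - (1 - psi_b) phi),
  combining breeding again next year with returning after any number of
  skipped years, discounted by annual survival phi;
* the expected number of future reproductive events, taken geometric with
  mean 1/P (the conventional mean number of remaining events for a
  per-cycle success probability P, P/(1-P), is reported alongside).

Standard errors propagate through the delta method with a numerically
differentiated gradient (central differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import expit, mlogit3

__all__ = ["DerivedEstimate", "delta_method", "isrp",
           "prob_future_reproduction", "expected_future_events",
           "survival_transition_curve"]


@dataclass
class DerivedEstimate:
    name: str
    value: float
    se: float
    ci: tuple[float, float]
    inputs: dict = field(default_factory=dict)

    def __repr__(self):
        return (f"DerivedEstimate({self.name}={self.value:.4f}, se={self.se:.4f}, "
                f"ci=({self.ci[0]:.4f}, {self.ci[1]:.4f}))")


def delta_method(fn: Callable[[np.ndarray], float], theta: Sequence[float],
                 vcov: np.ndarray, step: float = 1e-6) -> float:
    """SE of fn(theta): sqrt(g' Sigma g) with g a central-difference gradient."""
    theta = np.asarray(theta, dtype=float)
    vcov = np.atleast_2d(np.asarray(vcov, dtype=float))
    g = np.empty(theta.size)
    for k in range(theta.size):
        tp = theta.copy()
        tp[k] += step
        tm = theta.copy()
        tm[k] -= step
        g[k] = (fn(tp) - fn(tm)) / (2 * step)
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite gradient in delta method")
    return float(np.sqrt(g @ vcov @ g))


def _wald_ci(value: float, se: float, alpha: float,
             bounds: tuple[float, float] | None) -> tuple[float, float]:
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = value - z * se, value + z * se
    if bounds is not None:
        lo, hi = max(lo, bounds[0]), min(hi, bounds[1])
    return (float(lo), float(hi))


def isrp(psi_nb: float, psi_b: float, vcov: np.ndarray | None = None,
         alpha: float = 0.05) -> DerivedEstimate:
    """Inter-seasonal reproductive period 1 + psi_nb/psi_b (years, >= 1).

    ``vcov`` is the 2x2 covariance of (psi_nb, psi_b) on the probability
    scale; omit it to treat the inputs as fixed (se = 0).
    """
    if not (0 <= psi_nb <= 1 and 0 <= psi_b <= 1):
        raise ValueError("transition probabilities must be in [0,1]")
    if psi_b <= 0:
        raise ValueError("arrival probability is zero: interval undefined")
    value = 1.0 + psi_nb / psi_b
    se = 0.0
    if vcov is not None:
        se = delta_method(lambda t: 1.0 + t[0] / t[1], (psi_nb, psi_b), vcov)
    return DerivedEstimate("ISRP", float(value), se,
                           _wald_ci(value, se, alpha, (1.0, np.inf)),
                           {"psi_nb": psi_nb, "psi_b": psi_b})


def _p_future(psi_nb: float, psi_b: float, phi: float) -> float:
    denom = 1.0 - (1.0 - psi_b) * phi
    if denom <= 0:
        raise ValueError("zero denominator: (1-psi_b)*phi reaches 1")
    return (1.0 - psi_nb) * phi + psi_nb * psi_b * phi**2 / denom


def prob_future_reproduction(psi_nb: float, psi_b: float, phi: float,
                             vcov: np.ndarray | None = None,
                             alpha: float = 0.05) -> DerivedEstimate:
    """Probability that a breeder has a subsequent reproductive event."""
    for name, v in (("psi_nb", psi_nb), ("psi_b", psi_b), ("phi", phi)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name}={v} outside [0,1]")
    value = _p_future(psi_nb, psi_b, phi)
    se = 0.0
    if vcov is not None:
        se = delta_method(lambda t: _p_future(*t), (psi_nb, psi_b, phi), vcov)
    return DerivedEstimate("P_future", float(value), se,
                           _wald_ci(value, se, alpha, (0.0, 1.0)),
                           {"psi_nb": psi_nb, "psi_b": psi_b, "phi": phi})


def expected_future_events(P: float, se_P: float | None = None,
                           alpha: float = 0.05) -> DerivedEstimate:
    """Geometric expectation of future reproductive events, mean 1/P.

    The alternative convention (mean number of further successes before the
    first failure, P/(1-P)) is carried in ``inputs['alternative']``.
    """
    if not 0 < P <= 1:
        raise ValueError("P must lie in (0, 1]")
    value = 1.0 / P
    se = 0.0
    if se_P:
        se = delta_method(lambda t: 1.0 / t[0], (P,), np.array([[se_P**2]]))
    alt = P / (1.0 - P) if P < 1 else np.inf
    return DerivedEstimate("E_future_events", float(value), se,
                           _wald_ci(value, se, alpha, (1.0, np.inf)),
                           {"P": P, "alternative": float(alt)})


def survival_transition_curve(results, ages: Sequence[int],
                              alpha: float = 0.05) -> pd.DataFrame:
    """Paired age curves of annual survival and each breeding transition by
    quality, with delta-method CIs (on the link scale, then back-transformed).

    ``results`` is an MECMRResults whose design carries age-dependent forms
    for survival and quality-stratified arrival/departure.
    """
    compiled = results.model.compiled
    missing = []
    for target in ("phi", "psi_b", "psi_nb"):
        if results.design.forms[target].fixed is not None:
            missing.append(f"{target}: fixed in the design, no curve to draw")
    for target in ("psi_b", "psi_nb"):
        if not results.design.forms[target].by_quality:
            missing.append(f"{target}: needs quality stratification")
    if missing:
        raise ValueError("design lacks required structure: " + "; ".join(missing))

    vcov = results.cov_params().values
    theta = results.params.values
    rows = []
    for b in compiled.blocks:
        if b.target not in ("phi", "psi_b", "psi_nb"):
            continue
        link = mlogit3 if b.target == "psi_r" else expit
        idx = np.arange(b.offset, b.offset + b.size)
        sub_v = vcov[np.ix_(idx, idx)]
        coef = theta[idx]
        for a in ages:
            if b.kind == "linear":
                x = np.array([1.0, a])
            elif b.kind == "quadratic":
                x = np.array([1.0, a, a * a])
            elif b.kind == "constant":
                x = np.array([1.0])
            else:  # factor
                x = np.array([1.0 if lo <= a <= hi else 0.0 for lo, hi in b.bins])
            eta = float(x @ coef)
            se_eta = float(np.sqrt(x @ sub_v @ x))
            z = stats.norm.ppf(1 - alpha / 2)
            rows.append({
                "target": b.target,
                "stratum": b.stratum or "all",
                "age": a,
                "estimate": float(link(eta)),
                "lower": float(link(eta - z * se_eta)),
                "upper": float(link(eta + z * se_eta)),
            })
    return pd.DataFrame(rows)
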