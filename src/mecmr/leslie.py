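"""Age-classified Leslie matrix A = U + F and life-history traits.

The census is birth-pulse with offspring entering age class 0: a female of
age x survives the year with probability phi_x (sub-diagonal of U) and, if
she survives to age x+1, contributes m_{x+1} female eggs to class 0, so the
fecundity row is F[0, x] = phi_x * m_{x+1}.  With survivorship
l_x = prod_{k<x} phi_k this makes the dominant eigenvalue lambda of A
satisfy the discrete Euler-Lotka equation

    sum_x lambda^(-x) l_x m_x = 1.

The maternity schedule is built from raw per-season egg counts: eggs are
halved (a 50:50 egg sex ratio under incubation near the pivotal
temperature) and divided by the population-level inter-seasonal
reproductive period, because females do not breed every year:
m_x = (eggs_x / 2) / ISRP for x >= the age at first reproduction.

Traits: population growth rate lambda and Malthusian rate r = ln(lambda);
net reproductive rate R0 = sum l_x m_x (female eggs per female per
lifetime); generation time ln(R0)/ln(lambda); life expectancies from the
fundamental matrix N = (I - U)^(-1) (column sums count the starting year);
the Gini index of the survivorship-weighted fecundity schedule l_x m_x
(0 = perfectly even reproduction across ages, 1 - 1/n = a single
reproductive event); age-specific reproductive value v_x / v_0 and its
residual (future-only) form; and pace/shape measures of aging and
fecundity (shape 0 on constant-rate schedules, positive when mortality
rises with age, negative when reproduction shifts late).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["LeslieModel", "TraitSet", "build_leslie", "gini_index"]


class ReducibleMatrixError(ValueError):
    def __init__(self, classes, message):
        self.classes = classes
        super().__init__(message)


@dataclass
class TraitSet:
    lambda_: float
    r: float
    R0: float
    T_gen: float
    T_stable: float  # mean age of mothers of offspring, lambda-discounted
    e0: float
    e_adult: float
    G: float
    pace_aging: float
    pace_fec: float
    shape_surv: float
    shape_rep: float

    def to_dict(self) -> dict:
        return {
            "lambda": self.lambda_, "r": self.r, "R0": self.R0,
            "generation_time": self.T_gen, "stable_age_generation_time": self.T_stable,
            "life_expectancy_birth": self.e0, "life_expectancy_adult": self.e_adult,
            "gini": self.G, "pace_aging": self.pace_aging, "pace_fecundity": self.pace_fec,
            "shape_survival": self.shape_surv, "shape_reproduction": self.shape_rep,
        }


class LeslieModel:
    """U (survival), F (fecundity) and A = U + F over n age classes."""

    def __init__(self, phi_by_age: Sequence[float], mx: Sequence[float], afr: int):
        phi = np.asarray(phi_by_age, dtype=float)
        mx = np.asarray(mx, dtype=float)
        if phi.shape != mx.shape:
            raise ValueError("survival and maternity schedules differ in length")
        if np.any((phi < 0) | (phi > 1)):
            raise ValueError("survival probabilities must lie in [0,1]")
        if np.any(mx[:afr] != 0):
            raise ValueError("maternity must be zero before the age at first reproduction")
        self.phi = phi
        self.mx = mx
        self.afr = int(afr)
        n = phi.size
        self.n_classes = n
        self.U = np.zeros((n, n))
        for x in range(n - 1):
            self.U[x + 1, x] = phi[x]
        self.F = np.zeros((n, n))
        # mother of age x survives (phi_x) and lays m_{x+1} at her next birthday
        for x in range(n - 1):
            self.F[0, x] = phi[x] * mx[x + 1]
        self.A = self.U + self.F
        self.lx = np.concatenate([[1.0], np.cumprod(phi[:-1])])
        self._verified = False

    # --- structural checks -------------------------------------------------
    def verify(self) -> "LeslieModel":
        """The life cycle must contain a reproductive loop through age 0
        (irreducibility of the reproductive core) and the loop lengths must
        be coprime (aperiodicity, hence ergodic convergence to the stable
        age structure).  Post-reproductive trailing classes are a transient
        tail and are allowed."""
        fertile = [x for x in range(self.n_classes) if self.F[0, x] > 0 and self.lx[x] > 0]
        if not fertile:
            unreachable = [x for x in range(self.n_classes)
                           if self.mx[x] > 0 and self.lx[x] == 0]
            if unreachable:
                msg = ("Leslie matrix is reducible: reproductive age classes "
                       f"{unreachable} are unreachable (survivorship hits zero "
                       "before them)")
            else:
                msg = ("Leslie matrix is reducible: no reproduction anywhere, "
                       "so no age class returns to age 0")
            raise ReducibleMatrixError(unreachable or list(range(self.n_classes)), msg)
        loops = [x + 1 for x in fertile]
        g = int(np.gcd.reduce(loops))
        if g > 1:
            raise ReducibleMatrixError(
                fertile, f"Leslie matrix is not ergodic: reproduction is periodic "
                f"with period {g}")
        self._verified = True
        return self

    # --- traits ------------------------------------------------------------
    @property
    def lam(self) -> float:
        if not self._verified:
            self.verify()
        return float(np.max(np.linalg.eigvals(self.A).real))

    def growth_rates(self) -> tuple[float, float]:
        lam = self.lam
        return lam, float(np.log(lam))

    def euler_lotka_residual(self, lam: float | None = None) -> float:
        lam = self.lam if lam is None else lam
        x = np.arange(self.n_classes)
        return float(np.sum(lam ** (-x.astype(float)) * self.lx * self.mx) - 1.0)

    def r0_and_generation_time(self) -> tuple[float, float]:
        R0 = float(np.sum(self.lx * self.mx))
        if R0 <= 0:
            raise ValueError("net reproductive rate is zero")
        lam = self.lam
        if abs(lam - 1.0) > 1e-12:
            T = float(np.log(R0) / np.log(lam))
        else:
            x = np.arange(self.n_classes, dtype=float)
            T = float(np.sum(x * self.lx * self.mx) / np.sum(self.lx * self.mx))
        return R0, T

    def stable_age_generation_time(self) -> float:
        lam = self.lam
        x = np.arange(self.n_classes, dtype=float)
        w = lam ** (-x) * self.lx * self.mx
        return float(np.sum(x * w) / np.sum(w))

    def life_expectancies(self) -> tuple[float, float]:
        """(e0, e_adult) as fundamental-matrix column sums; the starting year
        counts, so e0 = sum_x l_x and the whole-life/post-maturity figures
        decompose as e0 ~ afr + (e_adult - ...) style arithmetic."""
        I = np.eye(self.n_classes)
        try:
            N = np.linalg.inv(I - self.U)
        except np.linalg.LinAlgError:
            raise ValueError("I - U is singular (survival reaches 1 in the last class)")
        e0 = float(N[:, 0].sum())
        e_adult = float(N[:, self.afr].sum())
        return e0, e_adult

    def reproductive_value(self) -> pd.DataFrame:
        """v_x/v_0 = (lambda^x / l_x) sum_{y>=x} lambda^(-y) l_y m_y, with the
        residual form excluding current-age reproduction; undefined (NaN)
        where survivorship has hit zero."""
        lam = self.lam
        x = np.arange(self.n_classes, dtype=float)
        disc = lam ** (-x) * self.lx * self.mx
        tail = np.cumsum(disc[::-1])[::-1]
        tail_excl = tail - disc
        with np.errstate(divide="ignore", invalid="ignore"):
            vx = np.where(self.lx > 0, lam**x / self.lx * tail, np.nan)
            rvx = np.where(self.lx > 0, lam**x / self.lx * tail_excl, np.nan)
        return pd.DataFrame({"age": x.astype(int), "vx": vx, "residual_vx": rvx,
                             "lx": self.lx, "mx": self.mx, "lxmx": self.lx * self.mx})

    def pace_shape(self) -> tuple[float, float, float, float]:
        """(pace_aging, pace_fec, shape_surv, shape_rep).

        Pace of aging is adult life expectancy; pace of fecundity is the
        survivorship-weighted mean age at egg production minus the age at
        first reproduction.  Shapes compare standardized curves with their
        constant-rate references: adult log-survivorship against the
        straight line of a constant hazard (positive = mortality rises with
        age), and the cumulative fecundity curve against an even schedule
        (negative = output shifted late in life).
        """
        e0, e_adult = self.life_expectancies()
        lxmx = self.lx * self.mx
        tot = lxmx.sum()
        if tot <= 0:
            raise ValueError("no reproduction in the schedule")
        x = np.arange(self.n_classes, dtype=float)
        pace_fec = float(np.sum((x - self.afr) * lxmx) / tot)

        # shape of aging: adult survivorship on the log scale
        l_ad = self.lx[self.afr :] / self.lx[self.afr]
        pos = l_ad > 0
        l_ad = l_ad[: np.argmin(pos) if not pos.all() else None]
        if l_ad.size < 3 or l_ad[-1] >= 1.0:
            shape_surv = 0.0
        else:
            u = np.linspace(0.0, 1.0, l_ad.size)
            v = np.log(l_ad) / np.log(l_ad[-1])
            shape_surv = float(0.5 - np.trapezoid(v, u))

        # shape of reproduction: standardized cumulative fecundity over the
        # adult window, anchored at zero the year before first reproduction
        m_ad = self.mx[self.afr :]
        if m_ad.size < 2 or m_ad.sum() <= 0:
            shape_rep = 0.0
        else:
            C = np.concatenate([[0.0], np.cumsum(m_ad)]) / m_ad.sum()
            u = np.linspace(0.0, 1.0, C.size)
            shape_rep = float(np.trapezoid(C, u) - 0.5)
        return e_adult, pace_fec, shape_surv, shape_rep

    def traits(self) -> TraitSet:
        lam, r = self.growth_rates()
        R0, T = self.r0_and_generation_time()
        e0, e_adult = self.life_expectancies()
        G = gini_index(self.lx[self.afr :] * self.mx[self.afr :])
        pace_a, pace_f, sh_s, sh_r = self.pace_shape()
        return TraitSet(lam, r, R0, T, self.stable_age_generation_time(),
                        e0, e_adult, G, pace_a, pace_f, sh_s, sh_r)

    def schedule_frame(self) -> pd.DataFrame:
        return self.reproductive_value()


def build_leslie(phi_by_age: Sequence[float], eggs_by_age: Sequence[float],
                 isrp_population: float, afr: int = 7) -> LeslieModel:
    """Assemble the Leslie model from raw schedules.

    ``eggs_by_age`` are per-season egg counts (both sexes); maternity is
    eggs/2 (female eggs) divided by the population-level ISRP (>= 1 years
    between breeding seasons).  ``afr`` is the minimum age at first
    reproduction; maternity below it is forced to zero.
    """
    phi = np.asarray(phi_by_age, dtype=float)
    eggs = np.asarray(eggs_by_age, dtype=float)
    if phi.shape != eggs.shape:
        raise ValueError("schedules must cover the same age range")
    if isrp_population < 1:
        raise ValueError("ISRP must be >= 1 year")
    mx = eggs / 2.0 / isrp_population
    mx[:afr] = 0.0
    return LeslieModel(phi, mx, afr).verify()


def gini_index(schedule: Sequence[float]) -> float:
    """Gini concentration of a nonnegative schedule (ascending-sorted ranks):
    G = 2 sum_i i*v_i / (n sum_i v_i) - (n+1)/n, in [0, 1 - 1/n]."""
    v = np.sort(np.asarray(schedule, dtype=float))
    n = v.size
    if n < 2:
        raise ValueError("need at least two schedule entries")
    if np.any(v < 0):
        raise ValueError("schedule entries must be nonnegative")
    tot = v.sum()
    if tot <= 0:
        raise ValueError("schedule sums to zero")
    i = np.arange(1, n + 1, dtype=float)
    return float(2.0 * np.sum(i * v) / (n * tot) - (n + 1.0) / n)
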