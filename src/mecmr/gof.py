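"""Goodness-of-fit components for the time-dependent multistate null, and
the overdispersion coefficient c-hat.

Three classical contingency-table components are computed on the adult
observable process (events 3 = seen as non-breeder, 4 = seen as breeder):

* 3.SR (transience): at each occasion and observable state, are animals
  encountered for the first time as adults re-encountered later at the same
  rate as previously-encountered animals?
* 3.SM: among animals that are re-encountered, does the time to the next
  encounter (1, 2, 3+ occasions) differ between newly and previously
  encountered animals?
* WBWA ("where before, where after"): given the state an animal is seen in
  now, is the state at its next encounter independent of the state at its
  previous encounter?  Dependence indicates a memory effect beyond a
  first-order Markov chain.

Each component sums per-occasion chi-square tables.  Tables are dropped
when a margin is empty; expected counts below 2 trigger column pooling
(3.SM) or exclusion (2x2 tables), the classical small-sample rule.  The
overdispersion coefficient is the summed statistic over the summed degrees
of freedom, floored at 1 for use in quasi-likelihood criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .capture import CaptureHistorySet
from .likelihood import pack_histories

__all__ = ["GofComponent", "test_3sr", "test_3sm", "test_wbwa", "c_hat",
           "gof_summary", "GofSummary"]

_ADULT_EVENTS = (3, 4)


@dataclass
class GofComponent:
    name: str
    chi2: float
    df: int
    p_value: float
    tables: list[np.ndarray] = field(default_factory=list)
    warning: str | None = None

    @classmethod
    def from_tables(cls, name: str, tables: list[np.ndarray]) -> "GofComponent":
        chi2 = 0.0
        df = 0
        for t in tables:
            c, d = _table_chi2(t)
            chi2 += c
            df += d
        if df == 0:
            return cls(name, 0.0, 0, 1.0, tables,
                       warning="no usable contingency table")
        return cls(name, float(chi2), int(df), float(stats.chi2.sf(chi2, df)), tables)


def _table_chi2(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square with margin checks; pooled tables arrive ready."""
    t = np.asarray(table, dtype=float)
    if t.sum() == 0 or np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 0.0, 0
    exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    chi2 = float(((t - exp) ** 2 / exp).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return chi2, df


def _expected_ok(table: np.ndarray, minimum: float = 2.0) -> bool:
    t = np.asarray(table, dtype=float)
    if t.sum() == 0 or np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return False
    exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    return bool(np.all(exp >= minimum))


def _pool_columns(table: np.ndarray, minimum: float = 2.0) -> np.ndarray | None:
    """Merge the rightmost columns until all expected counts reach the
    minimum; None when even the fully pooled table is unusable."""
    t = np.asarray(table, dtype=float)
    while t.shape[1] >= 2:
        if _expected_ok(t, minimum):
            return t
        if t.shape[1] == 2:
            return None
        t = np.hstack([t[:, :-2], (t[:, -2] + t[:, -1])[:, None]])
    return None


def _adult_encounter_arrays(history_set: CaptureHistorySet):
    events, birth_idx = pack_histories(history_set)
    seen = np.isin(events, _ADULT_EVENTS)
    return events, seen


def _first_adult_occ(seen: np.ndarray) -> np.ndarray:
    """Index of each animal's first adult encounter (-1 if none)."""
    any_seen = seen.any(axis=1)
    first = np.where(any_seen, seen.argmax(axis=1), -1)
    return first


def test_3sr(history_set: CaptureHistorySet) -> GofComponent:
    """Transience: newly vs previously encountered x re-encountered vs not."""
    events, seen = _adult_encounter_arrays(history_set)
    n, T = events.shape
    if T < 3:
        raise ValueError("need at least 3 occasions")
    first = _first_adult_occ(seen)
    tables = []
    for t in range(T - 1):
        at_t = seen[:, t]
        if not at_t.any():
            continue
        later = seen[:, t + 1 :].any(axis=1)
        for ev in _ADULT_EVENTS:
            grp = at_t & (events[:, t] == ev)
            if not grp.any():
                continue
            new = grp & (first == t)
            old = grp & (first < t)
            tab = np.array([
                [np.sum(new & later), np.sum(new & ~later)],
                [np.sum(old & later), np.sum(old & ~later)],
            ], dtype=float)
            if _expected_ok(tab):
                tables.append(tab)
    return GofComponent.from_tables("3.SR", tables)


def test_3sm(history_set: CaptureHistorySet) -> GofComponent:
    """Time to next encounter (1, 2, 3+) for newly vs previously encountered."""
    events, seen = _adult_encounter_arrays(history_set)
    n, T = events.shape
    if T < 3:
        raise ValueError("need at least 3 occasions")
    first = _first_adult_occ(seen)
    # time of next adult encounter strictly after t
    nxt = np.full((n, T), -1, dtype=int)
    for t in range(T - 2, -1, -1):
        nxt[:, t] = np.where(seen[:, t + 1], t + 1,
                             nxt[:, t + 1] if t + 1 < T - 1 else -1)
    tables = []
    for t in range(T - 1):
        at_t = seen[:, t]
        reenc = at_t & (nxt[:, t] >= 0)
        if not reenc.any():
            continue
        lag = np.where(reenc, nxt[:, t] - t, 0)
        lag_cat = np.clip(lag, 1, 3)  # 1, 2, 3+
        for ev in _ADULT_EVENTS:
            grp = reenc & (events[:, t] == ev)
            if not grp.any():
                continue
            new = grp & (first == t)
            old = grp & (first < t)
            tab = np.array([
                [np.sum(new & (lag_cat == c)) for c in (1, 2, 3)],
                [np.sum(old & (lag_cat == c)) for c in (1, 2, 3)],
            ], dtype=float)
            pooled = _pool_columns(tab)
            if pooled is not None:
                tables.append(pooled)
    return GofComponent.from_tables("3.SM", tables)


def test_wbwa(history_set: CaptureHistorySet) -> GofComponent:
    """Memory: previous-encounter state x next-encounter state, stratified by
    the state observed now (a first-order Markov chain makes past and future
    independent given the present)."""
    events, seen = _adult_encounter_arrays(history_set)
    n, T = events.shape
    if T < 3:
        raise ValueError("need at least 3 occasions")
    prev_state = np.full((n, T), -1, dtype=int)
    for t in range(1, T):
        prev_state[:, t] = np.where(seen[:, t - 1], events[:, t - 1],
                                    prev_state[:, t - 1])
    next_state = np.full((n, T), -1, dtype=int)
    for t in range(T - 2, -1, -1):
        next_state[:, t] = np.where(seen[:, t + 1], events[:, t + 1],
                                    next_state[:, t + 1] if t + 1 < T - 1 else -1)
    tables = []
    for t in range(1, T - 1):
        for ev in _ADULT_EVENTS:
            grp = seen[:, t] & (events[:, t] == ev) \
                & (prev_state[:, t] >= 0) & (next_state[:, t] >= 0)
            if not grp.any():
                continue
            tab = np.array([
                [np.sum(grp & (prev_state[:, t] == pv) & (next_state[:, t] == nx))
                 for nx in _ADULT_EVENTS]
                for pv in _ADULT_EVENTS
            ], dtype=float)
            if _expected_ok(tab):
                tables.append(tab)
    return GofComponent.from_tables("WBWA", tables)


def c_hat(components: list[GofComponent], floor: float = 1.0
          ) -> tuple[float, float]:
    """(floored, raw) overdispersion coefficient: summed chi2 over summed df."""
    chi2 = sum(c.chi2 for c in components)
    df = sum(c.df for c in components)
    if df <= 0:
        raise ValueError("total degrees of freedom is zero")
    raw = chi2 / df
    return max(raw, floor), raw


@dataclass
class GofSummary:
    components: list[GofComponent]
    total: GofComponent
    c_hat: float
    c_hat_raw: float

    def to_dict(self) -> dict:
        return {
            "components": [
                {"name": c.name, "chi2": c.chi2, "df": c.df, "p_value": c.p_value}
                for c in self.components + [self.total]
            ],
            "c_hat": self.c_hat,
            "c_hat_raw": self.c_hat_raw,
        }


def gof_summary(history_set: CaptureHistorySet) -> GofSummary:
    comps = [test_3sr(history_set), test_3sm(history_set), test_wbwa(history_set)]
    chi2 = sum(c.chi2 for c in comps)
    df = sum(c.df for c in comps)
    total = GofComponent("total", chi2, df,
                         float(stats.chi2.sf(chi2, df)) if df else 1.0)
    floored, raw = c_hat(comps)
    return GofSummary(comps, total, floored, raw)
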