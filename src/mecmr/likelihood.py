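"""Forward-algorithm likelihood for the multi-event hidden Markov model.

Each capture history contributes the probability of its observed event
sequence, conditional on first capture as a juvenile at age 0 (the initial
vector puts mass 1 on state J).  One annual step multiplies the current
state distribution by the combined survival-and-transition matrix
``M(age) = phi(age) @ psi(age)`` and masks it by the event-probability
column of the observed event.  The recursion is scaled occasion by
occasion, so log-likelihoods are stable for histories of 60+ occasions.

The score is computed analytically from forward-backward expected
transition and emission counts (the same quantities a Baum-Welch E-step
produces), chained through finite differences of the small deterministic
matrix-builders.  That keeps one gradient at roughly the cost of three
likelihood evaluations regardless of the number of coefficients.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .capture import CaptureHistorySet
from .design import CompiledDesign, N_EVENTS, N_STATES

__all__ = [
    "pack_histories",
    "transition_tensor",
    "emission_tensor",
    "loglik_histories",
    "LikelihoodEngine",
]

_NEG_INF = -1e300


def pack_histories(history_set: CaptureHistorySet) -> tuple[np.ndarray, np.ndarray]:
    """Dense (n, T) event array aligned on calendar year; -1 marks pre-birth
    occasions.  Also returns each individual's birth occasion index."""
    first, last = history_set.occasion_range
    T = last - first + 1
    n = len(history_set)
    events = np.full((n, T), -1, dtype=np.int64)
    birth_idx = np.empty(n, dtype=np.int64)
    for i, h in enumerate(history_set):
        b = h.birth_year - first
        birth_idx[i] = b
        events[i, b : b + len(h.events)] = h.events
    return events, birth_idx


def transition_tensor(schedules: dict[str, np.ndarray]) -> np.ndarray:
    """M[a] = phi(a) @ psi(a) for every age, stacked (n_ages, 8, 8)."""
    phi = schedules["phi"]  # (4, n_ages): NB-, NB+, B-, B+
    psi_r = schedules["psi_r"]
    psi_b = schedules["psi_b"]  # (2, n_ages): low, high
    psi_nb = schedules["psi_nb"]
    na = phi.shape[1]
    PHI = np.zeros((na, N_STATES, N_STATES))
    PSI = np.zeros((na, N_STATES, N_STATES))
    PHI[:, 0, 0] = 1.0
    PHI[:, 1, 1] = 1.0
    for k, st in enumerate((2, 3, 4, 5)):
        PHI[:, st, st] = phi[k]
        PHI[:, st, 6] = 1.0 - phi[k]
    PHI[:, 6, 7] = 1.0
    PHI[:, 7, 7] = 1.0
    r = psi_r
    PSI[:, 0, 0] = 1.0 - 3.0 * r
    PSI[:, 0, 1] = r
    PSI[:, 0, 4] = r
    PSI[:, 0, 5] = r
    PSI[:, 1, 1] = 1.0 - 2.0 * r
    PSI[:, 1, 4] = r
    PSI[:, 1, 5] = r
    PSI[:, 2, 2] = 1.0 - psi_b[0]
    PSI[:, 2, 4] = psi_b[0]
    PSI[:, 3, 3] = 1.0 - psi_b[1]
    PSI[:, 3, 5] = psi_b[1]
    PSI[:, 4, 2] = psi_nb[0]
    PSI[:, 4, 4] = 1.0 - psi_nb[0]
    PSI[:, 5, 3] = psi_nb[1]
    PSI[:, 5, 5] = 1.0 - psi_nb[1]
    PSI[:, 6, 6] = 1.0
    PSI[:, 7, 7] = 1.0
    return PHI @ PSI


def emission_tensor(schedules: dict[str, np.ndarray]) -> np.ndarray:
    """E[y] = event matrix for every occasion year, stacked (n_years, 8, 6)."""
    p = schedules["p"]  # (4, n_years): NB-, NB+, B-, B+
    p_sa = schedules["p_sa"]
    p_fd = schedules["p_fd"]
    ny = p.shape[1]
    E = np.zeros((ny, N_STATES, N_EVENTS))
    E[:, 0, 1] = 1.0
    E[:, 1, 0] = 1.0 - p_sa
    E[:, 1, 2] = p_sa
    # NB-, NB+ emit event 3 when detected; B-, B+ emit event 4
    E[:, 2, 0], E[:, 2, 3] = 1.0 - p[0], p[0]
    E[:, 3, 0], E[:, 3, 3] = 1.0 - p[1], p[1]
    E[:, 4, 0], E[:, 4, 4] = 1.0 - p[2], p[2]
    E[:, 5, 0], E[:, 5, 4] = 1.0 - p[3], p[3]
    E[:, 6, 0], E[:, 6, 5] = 1.0 - p_fd, p_fd
    E[:, 7, 0] = 1.0
    return E


@njit(cache=True)
def _forward(events, birth_idx, M, E, out_ll):
    """Scaled forward pass; per-individual log-likelihoods into out_ll."""
    n, T = events.shape
    max_age = M.shape[0] - 1
    for i in range(n):
        b = birth_idx[i]
        alpha = np.zeros(N_STATES)
        alpha[0] = 1.0  # conditioned on release in J at birth
        ll = 0.0
        for t in range(b + 1, T):
            a = t - 1 - b
            if a > max_age:
                a = max_age
            ev = events[i, t]
            new = np.zeros(N_STATES)
            for j in range(N_STATES):
                s = 0.0
                for k in range(N_STATES):
                    s += alpha[k] * M[a, k, j]
                new[j] = s * E[t, j, ev]
            c = 0.0
            for j in range(N_STATES):
                c += new[j]
            if c <= 0.0:
                ll = _NEG_INF
                break
            for j in range(N_STATES):
                alpha[j] = new[j] / c
            ll += np.log(c)
        out_ll[i] = ll


@njit(cache=True)
def _forward_backward(events, birth_idx, M, E, countsM, countsE):
    """Forward-backward expected transition counts by age and emission counts
    by year; returns the total log-likelihood."""
    n, T = events.shape
    max_age = M.shape[0] - 1
    total = 0.0
    alpha = np.zeros((T, N_STATES))
    cs = np.zeros(T)
    for i in range(n):
        b = birth_idx[i]
        for t in range(b, T):
            for j in range(N_STATES):
                alpha[t, j] = 0.0
        alpha[b, 0] = 1.0
        cs[b] = 1.0
        ok = True
        for t in range(b + 1, T):
            a = t - 1 - b
            if a > max_age:
                a = max_age
            ev = events[i, t]
            c = 0.0
            for j in range(N_STATES):
                s = 0.0
                for k in range(N_STATES):
                    s += alpha[t - 1, k] * M[a, k, j]
                s *= E[t, j, ev]
                alpha[t, j] = s
                c += s
            if c <= 0.0:
                ok = False
                break
            cs[t] = c
            for j in range(N_STATES):
                alpha[t, j] /= c
            total += np.log(c)
        if not ok:
            return _NEG_INF
        # backward with the forward scaling constants
        beta = np.ones(N_STATES)
        for t in range(T - 1, b, -1):
            a = t - 1 - b
            if a > max_age:
                a = max_age
            ev = events[i, t]
            # emission counts at occasion t (gamma = alpha*beta, already normalized)
            for j in range(N_STATES):
                g = alpha[t, j] * beta[j]
                if g > 0.0:
                    countsE[t, j, ev] += g
            newbeta = np.zeros(N_STATES)
            for k in range(N_STATES):
                s = 0.0
                for j in range(N_STATES):
                    mej = M[a, k, j] * E[t, j, ev] * beta[j]
                    s += mej
                    # expected transition count k->j at age a
                    x = alpha[t - 1, k] * mej
                    if x > 0.0:
                        countsM[a, k, j] += x / cs[t]
                newbeta[k] = s / cs[t]
            beta = newbeta
    return total


def loglik_histories(events, birth_idx, M, E) -> np.ndarray:
    """Per-individual log-likelihood contributions (−inf for impossible)."""
    out = np.empty(events.shape[0])
    _forward(events, birth_idx, M, E, out)
    out[out <= _NEG_INF] = -np.inf
    return out


class LikelihoodEngine:
    """Binds a compiled design to packed histories; evaluates log-likelihood
    and analytic score on the design's internal (scaled-age) basis."""

    def __init__(self, compiled: CompiledDesign, history_set: CaptureHistorySet):
        self.compiled = compiled
        self.events, self.birth_idx = pack_histories(history_set)
        self.n = self.events.shape[0]
        self._T = compiled.transform_matrix()

    def tensors(self, theta_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        s = self.compiled.schedules(theta_raw)
        return transition_tensor(s), emission_tensor(s)

    def loglik_raw(self, theta_raw: np.ndarray) -> float:
        M, E = self.tensors(theta_raw)
        ll = loglik_histories(self.events, self.birth_idx, M, E)
        return float(ll.sum())

    def loglik(self, theta_internal: np.ndarray) -> float:
        return self.loglik_raw(self._T @ np.asarray(theta_internal, float))

    def loglik_and_score(self, theta_internal: np.ndarray, fd_step: float = 1e-6
                         ) -> tuple[float, np.ndarray]:
        """Log-likelihood and its gradient on the internal basis.

        The forward-backward pass yields expected counts; the chain rule to
        coefficients runs through central finite differences of the (cheap,
        smooth) tensor builders, which is exact to O(step^2).
        """
        theta_internal = np.asarray(theta_internal, float)
        theta_raw = self._T @ theta_internal
        M, E = self.tensors(theta_raw)
        countsM = np.zeros_like(M)
        countsE = np.zeros_like(E)
        total = _forward_backward(self.events, self.birth_idx, M, E, countsM, countsE)
        if total <= _NEG_INF:
            return -np.inf, np.zeros_like(theta_internal)
        with np.errstate(divide="ignore", invalid="ignore"):
            RM = np.where(M > 0, countsM / np.maximum(M, 1e-300), 0.0)
            RE = np.where(E > 0, countsE / np.maximum(E, 1e-300), 0.0)
        K = self.compiled.K
        grad = np.empty(K)
        for k in range(K):
            tp = theta_internal.copy()
            tp[k] += fd_step
            tm = theta_internal.copy()
            tm[k] -= fd_step
            Mp, Ep = self.tensors(self._T @ tp)
            Mm, Em = self.tensors(self._T @ tm)
            dM = (Mp - Mm) / (2 * fd_step)
            dE = (Ep - Em) / (2 * fd_step)
            grad[k] = float(np.sum(RM * dM) + np.sum(RE * dE))
        return float(total), grad
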