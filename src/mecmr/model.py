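"""Maximum-likelihood fitting of the multi-event model, statsmodels-style.

``MECMRModel(data, design).fit()`` maximises the summed history
log-likelihoods by quasi-Newton iteration from several random link-scale
starting points and returns an :class:`MECMRResults` carrying the raw-age
coefficient vector, its Wald covariance (central finite-difference Hessian
of the analytic score), the deviance, and the per-start convergence log.

Model selection uses the overdispersion-corrected Schwarz criterion

    QSIC = deviance / c_hat + ln(N) * K,

with N the number of capture histories (the independent sampling units of
the conditional likelihood) and the conservative decision rule that only a
difference of more than 7 QSIC units counts as strong evidence for one
model over another.  QAICc (deviance/c_hat + 2K + 2K(K+1)/(N-K-1)) is
reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .capture import CaptureHistorySet
from .design import ModelDesign
from .likelihood import LikelihoodEngine

__all__ = [
    "MECMRModel",
    "MECMRResults",
    "StartRecord",
    "qsic",
    "qaicc",
    "model_table",
    "check_identifiability",
    "IdentifiabilityReport",
]

QSIC_STRONG_EVIDENCE = 7.0


@dataclass
class StartRecord:
    start: np.ndarray
    deviance: float
    converged: bool
    n_iter: int


class MECMRModel:
    """Multi-event capture-mark-recapture model bound to a history set."""

    def __init__(self, data: CaptureHistorySet, design: ModelDesign,
                 max_age: int | None = None):
        self.data = data
        self.design = design
        first, last = data.occasion_range
        if max_age is None:
            max_age = last - min(h.birth_year for h in data)
        self.compiled = design.compile(data.occasion_range, max_age)
        self.engine = LikelihoodEngine(self.compiled, data)
        self.nobs = len(data)

    @classmethod
    def from_histories(cls, histories, occasion_range, design, **kw):
        return cls(CaptureHistorySet(list(histories), occasion_range), design, **kw)

    # --- likelihood --------------------------------------------------------
    def loglike(self, params_raw) -> float:
        """Log-likelihood at a raw-age-basis coefficient vector."""
        return self.engine.loglik_raw(np.asarray(params_raw, float))

    def _negll_and_grad(self, theta_internal, free=None, base=None):
        if free is not None:
            full = base.copy()
            full[free] = theta_internal
        else:
            full = theta_internal
        ll, g = self.engine.loglik_and_score(full)
        if not np.isfinite(ll):
            return 1e12, np.zeros(len(theta_internal))
        g = g[free] if free is not None else g
        return -ll, -g

    # --- fitting -----------------------------------------------------------
    def fit(self, n_starts: int = 10, seed: int | None = None,
            start_params: np.ndarray | None = None, maxiter: int = 1000,
            tol: float = 1e-8, fixed: dict[str, float] | None = None,
            compute_vcov: bool = True) -> "MECMRResults":
        """Maximise the likelihood from ``n_starts`` random initialisations
        (uniform on [-3, 3] on the internal link scale).

        ``start_params`` (raw basis) adds one extra deterministic start.
        ``fixed`` pins named coefficients (raw basis) at given values.
        """
        K = self.compiled.K
        labels = self.compiled.labels
        rng = np.random.default_rng(seed)

        if fixed:
            for lab in fixed:
                if lab not in labels:
                    raise KeyError(f"unknown coefficient {lab!r}")
            # pinning is expressed on the raw basis: optimize free raw coords
            raw_mode = True
        else:
            raw_mode = False

        starts: list[np.ndarray] = []
        if start_params is not None:
            starts.append(self.compiled.to_internal(np.asarray(start_params, float)))
        while len(starts) < n_starts + (start_params is not None):
            starts.append(rng.uniform(-3, 3, size=K))

        records: list[StartRecord] = []
        best = None
        for s0 in starts:
            if raw_mode:
                res = self._fit_fixed_raw(s0, fixed, maxiter, tol)
            else:
                res = optimize.minimize(
                    self._negll_and_grad, s0, jac=True, method="L-BFGS-B",
                    options={"maxiter": maxiter, "ftol": tol * 1e-2, "gtol": 1e-6},
                )
            dev = 2.0 * res.fun
            records.append(StartRecord(np.array(s0), dev, bool(res.success), res.nit))
            if res.success and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            # fall back to the lowest objective even if the line search stalled
            devs = [rec.deviance for rec in records]
            if not np.isfinite(np.min(devs)):
                raise RuntimeError(
                    "no start converged; per-start deviances: "
                    + ", ".join(f"{d:.3f}" for d in devs)
                )
            warnings.warn("no start reported clean convergence; using best deviance")
            order = int(np.argmin(devs))
            if raw_mode:
                best = self._fit_fixed_raw(starts[order], fixed, maxiter, tol)
            else:
                best = optimize.minimize(
                    self._negll_and_grad, starts[order], jac=True, method="L-BFGS-B",
                    options={"maxiter": maxiter, "ftol": tol * 1e-2, "gtol": 1e-6},
                )

        if raw_mode:
            theta_raw = np.asarray(best.x_raw_full, float)
        else:
            theta_raw = self.compiled.from_internal(best.x)
        if not fixed:
            theta_raw = self._canonicalize_quality(theta_raw)
        llf = -float(best.fun)

        vcov = None
        vcov_ok = False
        if compute_vcov:
            vcov, vcov_ok = self._wald_vcov(theta_raw, fixed)
        return MECMRResults(self, theta_raw, llf, records, vcov, vcov_ok,
                            fixed=dict(fixed) if fixed else {})

    def _fit_fixed_raw(self, s0_internal, fixed, maxiter, tol):
        """Optimize on the raw basis with some coordinates pinned."""
        labels = self.compiled.labels
        K = self.compiled.K
        fixed_mask = np.zeros(K, dtype=bool)
        base = self.compiled.from_internal(np.asarray(s0_internal, float))
        for lab, val in fixed.items():
            i = labels.index(lab)
            fixed_mask[i] = True
            base[i] = val
        free = ~fixed_mask

        def negll(free_raw):
            full = base.copy()
            full[free] = free_raw
            ll = self.engine.loglik_raw(full)
            return 1e12 if not np.isfinite(ll) else -ll

        def grad(free_raw):
            full = base.copy()
            full[free] = free_raw
            ll, g_int = self.engine.loglik_and_score(self.compiled.to_internal(full))
            # chain to raw basis: d ll/d raw = T^{-T} d ll/d internal
            g_raw = np.linalg.solve(self.compiled.transform_matrix().T, g_int)
            return -g_raw[free]

        res = optimize.minimize(
            negll, base[free], jac=grad, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": tol * 1e-2, "gtol": 1e-6},
        )
        full = base.copy()
        full[free] = res.x
        res.x_raw_full = full
        return res

    def _canonicalize_quality(self, theta_raw: np.ndarray) -> np.ndarray:
        """Resolve latent-class label switching.

        The likelihood is invariant to swapping the two quality classes in
        every quality-stratified parameter simultaneously, so the optimiser
        can return either mirror image of the optimum.  The high-quality
        class is defined as the one with the larger mean arrival probability
        (falling back to detection, then survival), and coefficients are
        swapped into that ordering; the likelihood is unchanged.
        """
        c = self.compiled
        s = c.schedules(theta_raw)
        for key, low, high in (("psi_b", s["psi_b"][0], s["psi_b"][1]),
                               ("p", s["p"][0], s["p"][2]),
                               ("phi", s["phi"][0], s["phi"][1])):
            if self.design.forms[key].by_quality:
                if key == "p":
                    low, high = s["p"][[0, 2]].mean(axis=0), s["p"][[1, 3]].mean(axis=0)
                diff = float(np.mean(high) - np.mean(low))
                if abs(diff) > 1e-12:
                    if diff >= 0:
                        return theta_raw
                    break
        else:
            return theta_raw
        swapped = theta_raw.copy()
        by_key = {(b.target, b.stratum): b for b in c.blocks}
        for b in c.blocks:
            if "low" in b.stratum:
                partner = by_key.get((b.target, b.stratum.replace("low", "high")))
                if partner is not None:
                    lo = slice(b.offset, b.offset + b.size)
                    hi = slice(partner.offset, partner.offset + partner.size)
                    swapped[lo], swapped[hi] = theta_raw[hi], theta_raw[lo].copy()
        return swapped

    def _wald_vcov(self, theta_raw, fixed=None, step: float = 1e-5):
        """Covariance from the observed information: central differences of
        the analytic score on the internal basis, mapped back to raw."""
        Tm = self.compiled.transform_matrix()
        theta_int = self.compiled.to_internal(theta_raw)
        K = self.compiled.K
        H = np.zeros((K, K))
        for k in range(K):
            tp = theta_int.copy()
            tp[k] += step
            tm = theta_int.copy()
            tm[k] -= step
            _, gp = self.engine.loglik_and_score(tp)
            _, gm = self.engine.loglik_and_score(tm)
            H[k] = (gp - gm) / (2 * step)
        H = 0.5 * (H + H.T)
        info = -H
        if fixed:
            labels = self.compiled.labels
            fixed_mask = np.zeros(K, dtype=bool)
            for lab in fixed:
                fixed_mask[labels.index(lab)] = True
            # information of the free raw block via the basis map
            Jr = np.linalg.inv(Tm)  # internal = Jr @ raw
            info_raw = Jr.T @ info @ Jr
            free = ~fixed_mask
            vc = np.full((K, K), np.nan)
            try:
                vc_free = np.linalg.inv(info_raw[np.ix_(free, free)])
            except np.linalg.LinAlgError:
                return None, False
            vc[np.ix_(free, free)] = vc_free
            vc[np.ix_(fixed_mask, fixed_mask)] = 0.0
            return vc, True
        evals, evecs = np.linalg.eigh(info)
        tol = 1e-10 * max(np.max(np.abs(evals)), 1.0)
        if np.any(evals < -tol):
            warnings.warn("Hessian not positive semi-definite at the optimum")
        null = evals <= tol
        if null.any():
            # null information directions get zero variance (the SE=0 symptom
            # the identifiability check looks for); flag the covariance
            warnings.warn(
                f"singular Hessian: {int(null.sum())} null direction(s); "
                "pseudo-inverse covariance, treat flagged SEs as unavailable")
            inv_e = np.where(null, 0.0, 1.0 / np.where(null, 1.0, evals))
            cov_int = (evecs * inv_e) @ evecs.T
            return Tm @ cov_int @ Tm.T, False
        cov_int = (evecs / evals) @ evecs.T
        return Tm @ cov_int @ Tm.T, True


class MECMRResults:
    """Estimates, uncertainty and diagnostics for a fitted multi-event model."""

    def __init__(self, model: MECMRModel, theta_raw, llf, starts, vcov, vcov_ok,
                 fixed=None):
        self.model = model
        self.design = model.design
        self._theta = np.asarray(theta_raw, float)
        self.llf = float(llf)
        self.starts = starts
        self._vcov = vcov
        self.vcov_ok = bool(vcov_ok)
        self.fixed = fixed or {}
        self.labels = list(model.compiled.labels)
        self.nobs = model.nobs

    # --- statsmodels-flavoured surface ------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self._theta, index=self.labels, name="estimate")

    @property
    def deviance(self) -> float:
        return -2.0 * self.llf

    @property
    def K(self) -> int:
        return self.model.compiled.K - len(self.fixed)

    @property
    def converged(self) -> bool:
        return any(s.converged for s in self.starts)

    def cov_params(self) -> pd.DataFrame:
        if self._vcov is None:
            raise ValueError("covariance unavailable (singular Hessian)")
        return pd.DataFrame(self._vcov, index=self.labels, columns=self.labels)

    @property
    def bse(self) -> pd.Series:
        if self._vcov is None:
            return pd.Series(np.nan, index=self.labels, name="se")
        return pd.Series(np.sqrt(np.clip(np.diag(self._vcov), 0, None)),
                         index=self.labels, name="se")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def schedules(self) -> dict[str, np.ndarray]:
        """Estimated probability schedules by age / year at the optimum."""
        return self.model.compiled.schedules(self._theta)

    def multimodality(self, tol: float = 1e-3) -> float:
        """Spread of converged per-start deviances (0 means all starts agree)."""
        devs = [s.deviance for s in self.starts if s.converged]
        return float(np.ptp(devs)) if devs else np.nan

    def summary(self, alpha: float = 0.05) -> str:
        ci = self.conf_int(alpha)
        tab = pd.DataFrame({
            "estimate": self.params,
            "se": self.bse,
            "z": self.params / self.bse,
            f"[{alpha / 2:g}": ci["lower"],
            f"{1 - alpha / 2:g}]": ci["upper"],
        })
        head = (
            f"Multi-event CMR model: {self.design.name}\n"
            f"histories: {self.nobs}   K: {self.K}   "
            f"logL: {self.llf:.3f}   deviance: {self.deviance:.3f}\n"
            f"converged starts: {sum(s.converged for s in self.starts)}"
            f"/{len(self.starts)}   deviance spread: {self.multimodality():.2e}\n"
        )
        return head + tab.to_string(float_format=lambda v: f"{v: .4f}")

    def coefficient_table(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "label": self.labels,
            "estimate": self._theta,
            "se": self.bse.values,
            "ci_lower": ci["lower"].values,
            "ci_upper": ci["upper"].values,
        })


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def qsic(deviance: float, c_hat: float, N: int, K: int) -> float:
    """Quasi-Schwarz information criterion deviance/c_hat + ln(N)*K."""
    if c_hat < 1:
        raise ValueError("c_hat must be >= 1 (floor underdispersion at 1)")
    return deviance / c_hat + np.log(N) * K


def qaicc(deviance: float, c_hat: float, N: int, K: int) -> float:
    """Quasi-AIC with small-sample correction; undefined when N <= K+1."""
    if N <= K + 1:
        raise ValueError("QAICc undefined for N <= K+1")
    return deviance / c_hat + 2 * K + 2 * K * (K + 1) / (N - K - 1)


def model_table(fits: dict[str, MECMRResults] | list[MECMRResults],
                c_hat: float = 1.0) -> pd.DataFrame:
    """Ranked comparison; ``strongly_outperformed`` marks models more than 7
    QSIC units behind the best (the conservative decision rule)."""
    if isinstance(fits, dict):
        items = list(fits.items())
    else:
        items = [(f.design.name, f) for f in fits]
    rows = []
    for name, f in items:
        row = {
            "model": name,
            "deviance": f.deviance,
            "K": f.K,
            "N": f.nobs,
            "QSIC": qsic(f.deviance, c_hat, f.nobs, f.K),
        }
        try:
            row["QAICc"] = qaicc(f.deviance, c_hat, f.nobs, f.K)
        except ValueError:
            warnings.warn(f"QAICc omitted for {name}: N <= K+1")
            row["QAICc"] = np.nan
        rows.append(row)
    tab = pd.DataFrame(rows).sort_values("QSIC").reset_index(drop=True)
    tab["dQSIC"] = tab["QSIC"] - tab["QSIC"].iloc[0]
    tab["strongly_outperformed"] = tab["dQSIC"] > QSIC_STRONG_EVIDENCE
    return tab


# ---------------------------------------------------------------------------
# identifiability diagnostics
# ---------------------------------------------------------------------------


@dataclass
class IdentifiabilityReport:
    suspect: list[str] = field(default_factory=list)
    non_identifiable: list[str] = field(default_factory=list)
    deviance_changes: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.non_identifiable


def check_identifiability(results: MECMRResults, se_floor: float = 1e-6,
                          dev_tol: float = 1e-3, maxiter: int = 500
                          ) -> IdentifiabilityReport:
    """Flag coefficients whose reported SE is (numerically) zero, refit with
    each pinned at its estimate, and call the coefficient non-identifiable
    when the deviance does not change."""
    report = IdentifiabilityReport()
    bse = results.bse
    for lab in results.labels:
        if lab in results.fixed:
            continue
        se = bse[lab]
        if not np.isfinite(se) or se < se_floor:
            report.suspect.append(lab)
    for lab in report.suspect:
        refit = results.model.fit(
            n_starts=0, start_params=results.params.values, maxiter=maxiter,
            fixed={**results.fixed, lab: float(results.params[lab])},
            compute_vcov=False,
        )
        change = abs(refit.deviance - results.deviance)
        report.deviance_changes[lab] = change
        if change <= dev_tol:
            report.non_identifiable.append(lab)
    return report
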