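"""Inter-breeding-interval analysis: interval construction, cluster-robust
Cox proportional hazards, proportional-hazards diagnostics, and a
zero-truncated (positive) Poisson regression.

An interval runs from one breeding season to the next (1 = consecutive
years); the final open interval from the last observed breeding season to
death or the study end is right-censored and enters only the hazard model.
Covariates are measured at the interval's start: the female's age, her
breeding experience (number of breeding seasons through the start,
inclusive), age at first reproduction, and current/cumulative reproductive
effort (clutches and eggs).

The Cox model h(t|x) = h0(t) exp(x'b) is fit by partial likelihood with
standard errors from the sandwich estimator clustered on individual; effect
sizes are reported as hazard ratios exp(b) and percent changes
(exp(b)-1)*100.  The count model is a zero-truncated Poisson with log link,
P(y|lam) = lam^y exp(-lam) / (y! (1 - exp(-lam))), appropriate because an
interval is at least one year by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats
from statsmodels.discrete.truncated_model import TruncatedLFPoisson
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .capture import BreedingRecord, CaptureHistorySet

__all__ = ["build_interval_table", "fit_cox", "ph_check", "fit_ztp",
           "percent_change", "HazardFit", "ZTPFit", "PHTest"]

COVARIATES = ("age", "experience", "afr", "clutches_current", "eggs_current",
              "clutches_cum", "eggs_cum")


def percent_change(beta: float) -> float:
    """Signed percent change in the rate per unit covariate: (exp(b)-1)*100."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return float((np.exp(beta) - 1.0) * 100.0)


def build_interval_table(records: list[BreedingRecord],
                         histories: CaptureHistorySet) -> pd.DataFrame:
    """One closed interval per consecutive breeding-year pair, plus one
    right-censored interval from the last breeding year to death/study end."""
    by_id: dict[str, list[BreedingRecord]] = {}
    for r in records:
        by_id.setdefault(r.individual_id, []).append(r)
    hist = {h.individual_id: h for h in histories}
    end_year = histories.occasion_range[1]
    rows = []
    for ident, recs in by_id.items():
        h = hist.get(ident)
        if h is None:
            raise ValueError(f"breeding record for unknown individual {ident!r}")
        recs = sorted(recs, key=lambda r: r.season_year)
        for r in recs:
            if h.events[r.season_year - h.birth_year] != 4:
                raise ValueError(
                    f"{ident}: breeding record in {r.season_year} but the "
                    "capture history does not show a breeder event (code 4)"
                )
        years = [r.season_year for r in recs]
        afr = years[0] - h.birth_year
        cl_cum = np.cumsum([r.n_clutches for r in recs])
        eg_cum = np.cumsum([r.n_eggs for r in recs])
        death = next((y for y, e in zip(h.years, h.events) if e == 5), None)
        for i, r in enumerate(recs):
            start = r.season_year
            base = {
                "id": ident,
                "start_year": start,
                "age": start - h.birth_year,
                "experience": i + 1,
                "afr": afr,
                "clutches_current": r.n_clutches,
                "eggs_current": r.n_eggs,
                "clutches_cum": int(cl_cum[i]),
                "eggs_cum": int(eg_cum[i]),
            }
            if i + 1 < len(recs):
                rows.append({**base, "interval_years": years[i + 1] - start,
                             "censored": False})
            else:
                stop = death if death is not None else end_year
                if stop > start:
                    rows.append({**base, "interval_years": stop - start,
                                 "censored": True})
    cols = ["id", "start_year", "interval_years", "censored", "age", "experience",
            "afr", "clutches_current", "eggs_current", "clutches_cum", "eggs_cum"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class HazardFit:
    params: pd.Series
    bse: pd.Series  # cluster-robust
    hr: pd.Series
    hr_ci: pd.DataFrame
    pct_change: pd.Series
    llf: float
    pseudo_r2: float
    nobs: int
    n_events: int
    fitter: CoxPHFitter = field(repr=False, default=None)
    data: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        tab = pd.DataFrame({
            "coef": self.params, "robust se": self.bse, "HR": self.hr,
            "HR lower": self.hr_ci["lower"], "HR upper": self.hr_ci["upper"],
            "% change": self.pct_change,
        })
        return (f"Cox proportional hazards (cluster-robust)\n"
                f"observations: {self.nobs}  events: {self.n_events}  "
                f"logL: {self.llf:.2f}  Nagelkerke R2: {self.pseudo_r2:.3f}\n"
                + tab.to_string(float_format=lambda v: f"{v: .4f}"))


def fit_cox(table: pd.DataFrame, covariates: list[str]) -> HazardFit:
    """Cox PH on the interval table with sandwich SEs clustered on individual.

    Ties among the (integer) interval lengths are handled with the Efron
    approximation.
    """
    if not covariates:
        raise ValueError("at least one covariate required")
    df = table.copy()
    df["event"] = (~df["censored"]).astype(int)
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValueError("all intervals censored: no events to fit")
    if df.loc[df["event"] == 1, "interval_years"].nunique() < 2:
        raise ValueError("need at least two distinct event times")
    cols = ["interval_years", "event", "id"] + list(covariates)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[cols], duration_col="interval_years", event_col="event",
                cluster_col="id", robust=True)
    params = cph.params_.rename("coef")
    bse = cph.standard_errors_.rename("se")
    ci = pd.DataFrame({
        "lower": np.exp(params - 1.959963984540054 * bse),
        "upper": np.exp(params + 1.959963984540054 * bse),
    })
    llf = float(cph.log_likelihood_)
    n = len(df)
    lrt = cph.log_likelihood_ratio_test()
    ll0 = llf - float(lrt.test_statistic) / 2.0
    r2_cs = 1.0 - np.exp(-(float(lrt.test_statistic)) / n)
    r2_max = 1.0 - np.exp(2.0 * ll0 / n)
    pseudo_r2 = float(r2_cs / r2_max) if r2_max > 0 else np.nan
    return HazardFit(
        params=params, bse=bse, hr=np.exp(params).rename("HR"), hr_ci=ci,
        pct_change=params.map(percent_change).rename("pct"),
        llf=llf, pseudo_r2=pseudo_r2, nobs=n, n_events=n_events,
        fitter=cph, data=df[cols],
    )


@dataclass
class PHTest:
    per_covariate: pd.DataFrame  # chi2, df, p per covariate
    global_chi2: float
    global_df: int
    global_p: float


def ph_check(fit: HazardFit) -> PHTest:
    """Score tests on scaled Schoenfeld residuals against (rank) time; the
    global statistic sums the per-covariate components with df = number of
    covariates."""
    if fit.fitter is None or fit.data is None:
        raise ValueError("fit carries no fitter/data to diagnose")
    res = proportional_hazard_test(fit.fitter, fit.data, time_transform="rank")
    tab = res.summary.copy()
    tab = tab.rename(columns={"test_statistic": "chi2"})
    chi2 = float(tab["chi2"].sum())
    df = int(len(tab))
    return PHTest(tab, chi2, df, float(stats.chi2.sf(chi2, df)))


@dataclass
class ZTPFit:
    params: pd.Series
    bse: pd.Series
    multiplier: pd.Series  # exp(beta): multiplicative change in the mean rate
    pct_change: pd.Series
    llf: float
    vif: pd.Series
    nobs: int
    results: object = field(repr=False, default=None)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({"lower": self.params - z * self.bse,
                             "upper": self.params + z * self.bse})

    def summary(self) -> str:
        tab = pd.DataFrame({
            "coef": self.params, "se": self.bse, "exp(coef)": self.multiplier,
            "% change": self.pct_change, "VIF": self.vif,
        })
        return (f"Zero-truncated Poisson (log link)\n"
                f"observations: {self.nobs}  logL: {self.llf:.2f}\n"
                + tab.to_string(float_format=lambda v: f"{v: .4f}"))


def fit_ztp(table: pd.DataFrame, covariates: list[str]) -> ZTPFit:
    """Zero-truncated Poisson regression of closed interval lengths."""
    df = table.loc[~table["censored"]].copy() if "censored" in table else table.copy()
    y = df["interval_years"].to_numpy(dtype=float)
    if len(y) == 0:
        raise ValueError("no closed intervals to fit")
    if np.any(y < 1):
        raise ValueError("interval lengths must be >= 1 (the model is "
                         "zero-truncated)")
    X = pd.DataFrame({"const": np.ones(len(df))})
    for c in covariates:
        X[c] = df[c].to_numpy(dtype=float)
    model = TruncatedLFPoisson(y, X.to_numpy(), truncation=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=False, maxiter=500)
    names = list(X.columns)
    params = pd.Series(res.params, index=names, name="coef")
    bse = pd.Series(res.bse, index=names, name="se")
    if len(covariates) >= 2:
        Xm = X.to_numpy()
        vif = pd.Series(
            [np.nan] + [variance_inflation_factor(Xm, i) for i in range(1, Xm.shape[1])],
            index=names, name="VIF")
    else:
        vif = pd.Series(np.nan, index=names, name="VIF")
    return ZTPFit(
        params=params, bse=bse,
        multiplier=np.exp(params).rename("exp(coef)"),
        pct_change=params.map(percent_change).rename("pct"),
        llf=float(res.llf), vif=vif, nobs=len(df), results=res,
    )
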