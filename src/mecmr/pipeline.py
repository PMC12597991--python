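"""End-to-end orchestration of the synthetic study.

``run_pipeline`` executes every stage in order — simulate a cohort,
goodness-of-fit and overdispersion, multi-event model fitting and QSIC
model selection, derived demography from the best model, Leslie-matrix
life-history traits from the simulated breeding output, and the
inter-arrival Cox / zero-truncated-Poisson models — writing every
intermediate artifact plus a run manifest to the output directory.  All
hand-offs go through files; the manifest records seeds, versions, problem
sizes and per-stage wall time so any stage can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .capture import (CaptureHistorySet, read_breeding_records,
                      read_capture_histories, summarize_set, validate_set,
                      write_breeding_records, write_capture_histories)
from .derived import DerivedEstimate, delta_method, isrp, prob_future_reproduction
from .design import ModelDesign
from .gof import gof_summary
from .interarrival import build_interval_table, fit_cox, fit_ztp, ph_check
from .leslie import build_leslie
from .model import MECMRModel, MECMRResults, model_table
from .simulate import (SimConfig, default_config, generating_design,
                       simulate_breeding_output, simulate_cohort)

log = logging.getLogger("mecmr.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "derived_table", "schedules_from_study"]


@dataclass
class PipelineConfig:
    simulation: SimConfig = field(default_factory=default_config)
    designs: list[ModelDesign] | None = None
    chat_source: str | float = "gof"
    afr: int = 7
    n_age_classes: int = 46
    adult_age_range: tuple[int, int] = (7, 40)
    cox_covariates: tuple[str, ...] = ("age", "experience")
    n_starts: int = 3
    seed: int = 0
    output_dir: str | Path = "mecmr_run"
    make_figures: bool = True

    def resolved_designs(self) -> list[ModelDesign]:
        return self.designs or [generating_design(self.simulation)]


def derived_table(results: MECMRResults, ages, alpha: float = 0.05) -> pd.DataFrame:
    """Per-age, per-quality ISRP and probability of future reproduction from a
    fitted model, with delta-method SEs propagated through the full
    coefficient covariance."""
    compiled = results.model.compiled
    theta = results.params.values
    have_vcov = results.vcov_ok
    vcov = results.cov_params().values if have_vcov else None
    rows = []
    for qi, q in enumerate(("low", "high")):
        for a in ages:
            ai = min(int(a), compiled.max_age)

            def isrp_fn(t, ai=ai, qi=qi):
                s = compiled.schedules(t)
                return 1.0 + s["psi_nb"][qi, ai] / s["psi_b"][qi, ai]

            def pfut_fn(t, ai=ai, qi=qi):
                s = compiled.schedules(t)
                nb, b = s["psi_nb"][qi, ai], s["psi_b"][qi, ai]
                ph = s["phi"][qi, ai]
                return (1 - nb) * ph + nb * b * ph**2 / (1 - (1 - b) * ph)

            v_isrp = isrp_fn(theta)
            v_p = pfut_fn(theta)
            se_isrp = delta_method(isrp_fn, theta, vcov) if have_vcov else 0.0
            se_p = delta_method(pfut_fn, theta, vcov) if have_vcov else 0.0
            rows.append({"quality": q, "age": int(a),
                         "isrp": v_isrp, "isrp_se": se_isrp,
                         "p_future": v_p, "p_future_se": se_p})
    return pd.DataFrame(rows)


def schedules_from_study(results: MECMRResults, breeding, histories,
                         n_age_classes: int, afr: int) -> pd.DataFrame:
    """Age schedules (phi, eggs per season) for the Leslie stage.

    Survival below the age at first reproduction is one, mirroring the
    likelihood's conditioning on surviving to recruit; per-season egg counts
    are observed age-specific means, with unobserved adult ages filled by
    the overall adult mean.
    """
    s = results.schedules()
    ages = np.arange(n_age_classes)
    phi_cell = s["phi"].mean(axis=0)  # pooled over quality/state cells
    phi = np.ones(n_age_classes)
    idx = np.minimum(ages[afr:], results.model.compiled.max_age)
    phi[afr:] = phi_cell[idx]
    birth = {h.individual_id: h.birth_year for h in histories}
    eggs = np.zeros(n_age_classes)
    agg: dict[int, list[int]] = {}
    for r in breeding:
        a = r.season_year - birth[r.individual_id]
        agg.setdefault(a, []).append(r.n_eggs)
    adult_mean = float(np.mean([e for v in agg.values() for e in v])) if agg else 0.0
    for a in range(afr, n_age_classes):
        eggs[a] = float(np.mean(agg[a])) if a in agg else adult_mean
    return pd.DataFrame({"age": ages, "phi": phi, "eggs": eggs})


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": {},
        "versions": _versions(),
    }
    report: dict = {}

    def stage(name):
        log.info("stage %s", name)
        return _StageTimer(name, manifest)

    try:
        with stage("simulate"):
            sim = config.simulation
            truth, hist = simulate_cohort(sim, seed=config.seed)
            breeding = simulate_breeding_output(truth, sim, seed=config.seed + 1,
                                                histories=hist)
            write_capture_histories(out / "histories.csv", hist)
            write_breeding_records(out / "breeding.csv", breeding)
            _write_json(out / "sim_config.json", sim.to_dict())
            summ = summarize_set(hist)
            report["simulation"] = {
                "n_individuals": summ.n_individuals,
                "mean_recaptures": summ.mean_recaptures,
                "dead_recoveries": summ.n_dead_recoveries,
            }
            manifest["stages"]["simulate"]["n_individuals"] = sim.n_individuals

        with stage("gof"):
            g = gof_summary(hist)
            _write_json(out / "gof.json", g.to_dict())
            report["gof"] = g.to_dict()
            c_hat = g.c_hat if config.chat_source == "gof" else float(config.chat_source)
            report["c_hat_used"] = c_hat

        with stage("fit"):
            fits: dict[str, MECMRResults] = {}
            for i, design in enumerate(config.resolved_designs()):
                model = MECMRModel(hist, design)
                res = model.fit(n_starts=config.n_starts, seed=config.seed + 10 + i)
                fits[design.name] = res
                res.coefficient_table().to_csv(
                    out / f"coefficients_{design.name}.csv", index=False)
                _write_json(out / f"fit_{design.name}.json", {
                    "design": design.to_dict(), "deviance": res.deviance,
                    "K": res.K, "N": res.nobs, "converged": res.converged,
                    "starts": [{"deviance": s.deviance, "converged": s.converged,
                                "n_iter": s.n_iter} for s in res.starts],
                })
            report["fits"] = {k: {"deviance": v.deviance, "K": v.K} for k, v in fits.items()}

        with stage("compare"):
            table = model_table(fits, c_hat=c_hat)
            table.to_csv(out / "model_table.csv", index=False)
            best_name = table["model"].iloc[0]
            best = fits[best_name]
            report["best_model"] = best_name

        with stage("derive"):
            ages = range(config.adult_age_range[0], config.adult_age_range[1] + 1)
            dtab = derived_table(best, ages)
            dtab.to_csv(out / "derived.csv", index=False)
            pop_isrp = float(dtab.groupby("quality")["isrp"].mean().mean())
            report["derived"] = {
                "isrp_by_quality": dtab.groupby("quality")["isrp"].mean().to_dict(),
                "p_future_by_quality": dtab.groupby("quality")["p_future"].mean().to_dict(),
                "population_isrp": pop_isrp,
            }

        with stage("traits"):
            sched = schedules_from_study(best, breeding, hist,
                                         config.n_age_classes, config.afr)
            sched.to_csv(out / "schedules.csv", index=False)
            L = build_leslie(sched["phi"].values, sched["eggs"].values,
                             max(pop_isrp, 1.0), config.afr)
            traits = L.traits()
            _write_json(out / "traits.json", traits.to_dict())
            L.schedule_frame().to_csv(out / "per_age_traits.csv", index=False)
            report["traits"] = traits.to_dict()

        with stage("intervals"):
            itab = build_interval_table(breeding, hist)
            itab.to_csv(out / "intervals.csv", index=False)
            cox = fit_cox(itab, list(config.cox_covariates))
            ph = ph_check(cox)
            ztp = fit_ztp(itab, list(config.cox_covariates))
            _write_json(out / "interarrival.json", {
                "cox": {"coef": cox.params.to_dict(), "robust_se": cox.bse.to_dict(),
                        "hr": cox.hr.to_dict(), "pct_change": cox.pct_change.to_dict(),
                        "pseudo_r2": cox.pseudo_r2, "n": cox.nobs,
                        "events": cox.n_events},
                "ph_test": {"global_chi2": ph.global_chi2, "df": ph.global_df,
                            "p": ph.global_p},
                "ztp": {"coef": ztp.params.to_dict(), "se": ztp.bse.to_dict(),
                        "pct_change": ztp.pct_change.to_dict(),
                        "vif": ztp.vif.to_dict(), "n": ztp.nobs},
            })
            report["interarrival"] = {
                "cox_hr": cox.hr.to_dict(), "ztp_pct": ztp.pct_change.to_dict(),
                "ph_global_p": ph.global_p,
            }

        if config.make_figures:
            with stage("figures"):
                _figures(out, best, dtab, L, itab, config)
    except Exception as exc:
        manifest["failed_stage"] = getattr(exc, "_stage", "unknown")
        _write_json(out / "manifest.json", manifest)
        raise
    _write_json(out / "manifest.json", manifest)
    _write_json(out / "report.json", report)
    return report


class _StageTimer:
    def __init__(self, name, manifest):
        self.name = name
        self.manifest = manifest

    def __enter__(self):
        self.t0 = time.perf_counter()
        self.manifest["stages"].setdefault(self.name, {})
        return self

    def __exit__(self, exc_type, exc, tb):
        self.manifest["stages"][self.name]["seconds"] = (
            round(time.perf_counter() - self.t0, 3))
        if exc is not None:
            exc._stage = self.name
        return False


def _versions() -> dict:
    import lifelines
    import numpy
    import pandas
    import scipy
    import statsmodels

    return {m.__name__: m.__version__
            for m in (numpy, scipy, pandas, statsmodels, lifelines)}


def _figures(out: Path, best: MECMRResults, dtab, L, itab, config) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .derived import survival_transition_curve

    ages = list(range(config.adult_age_range[0], config.adult_age_range[1] + 1))
    try:
        curves = survival_transition_curve(best, ages)
    except ValueError:
        curves = None

    if curves is not None:
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
        for ax, target, title in zip(
                axes, ("psi_b", "psi_nb", "phi"),
                ("arrival (NB->B)", "departure (B->NB)", "annual survival")):
            sub = curves[curves["target"] == target]
            for stratum, grp in sub.groupby("stratum"):
                ax.plot(grp["age"], grp["estimate"], label=stratum)
                ax.fill_between(grp["age"], grp["lower"], grp["upper"], alpha=0.2)
            ax.set_title(title)
            ax.set_xlabel("age (years)")
            ax.set_ylim(0, 1)
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "fig_age_transitions.png", dpi=120)
        plt.close(fig)

        # survival vs transitions (age as the hidden gradient)
        fig, ax = plt.subplots(figsize=(5, 4))
        phi = curves[curves["target"] == "phi"]
        for target, style in (("psi_b", "--"), ("psi_nb", ":")):
            for stratum, grp in curves[curves["target"] == target].groupby("stratum"):
                ax.plot(phi["estimate"].values[: len(grp)], grp["estimate"].values,
                        style, label=f"{target} {stratum}")
        ax.set_xlabel("annual survival")
        ax.set_ylabel("transition probability")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "fig_survival_vs_transitions.png", dpi=120)
        plt.close(fig)

    frame = L.schedule_frame()
    fig, ax1 = plt.subplots(figsize=(5.5, 4))
    ax1.plot(frame["age"], frame["residual_vx"], color="tab:blue")
    ax1.set_xlabel("age (years)")
    ax1.set_ylabel("residual reproductive value", color="tab:blue")
    ax2 = ax1.twinx()
    ax2.plot(frame["age"], frame["lxmx"], color="tab:orange")
    ax2.set_ylabel("l(x) m(x) (female eggs)", color="tab:orange")
    fig.tight_layout()
    fig.savefig(out / "fig_reproductive_value.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    closed = itab[~itab["censored"]]
    ax.scatter(closed["experience"], closed["interval_years"],
               s=8, alpha=0.3, label="observed")
    ax.set_xlabel("breeding experience (seasons)")
    ax.set_ylabel("interval to next breeding (years)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "fig_intervals.png", dpi=120)
    plt.close(fig)
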