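# mecmr

Multi-event capture–mark–recapture (MECMR) models of age- and
quality-dependent breeding probability in long-lived iteroparous animals,
with the demographic machinery that typically surrounds such an analysis:
goodness-of-fit and overdispersion, derived breeding-interval quantities,
Leslie-matrix life-history traits, and inter-arrival-time regression.

## Who this is for

Population ecologists with annual encounter histories of known-age
individuals — think a captive sea-turtle breeding colony, a long-term
seabird colony study — who want to ask: *how does the probability of
breeding change with age, and how much of the observed pattern is fixed
individual quality rather than senescence?* Because the raw data behind
studies like this are usually proprietary, the package ships a synthetic
cohort generator with known truth, so every estimator has a
parameter-recovery test surface and the full analysis can be run end to
end without any data download.

## The model

Each animal's yearly record is one coded event: `0` not observed, `1`
juvenile (J), `2` subadult (SA), `3` adult non-breeder (NB), `4` adult
breeder (B), `5` recovered dead. Underneath is a hidden Markov chain on
eight states — J, SA, NB±, B±, freshly dead, dead — where ± is a fixed
two-class latent *quality* mixture expressed once an animal recruits into
the breeding population. One annual step factorises into survival φ,
transition conditional on survival ψ, and detection p:

* adult survival φ(x) = expit(β₀ + β₁·x), with age x in years;
* recruitment ψR(x) (quadratic in age, multinomial-logit link on the tied
  juvenile row);
* arrival ψB (NB → B) and departure ψNB (B → NB), age-linear-logistic and
  quality-specific;
* detection by year block and quality; dead recovery only in the death
  year.

Histories contribute forward-algorithm likelihoods conditional on first
capture at birth; fits use multiple random starts, analytic scores via
forward–backward expected counts, and Wald covariances. Model comparison
uses the overdispersion-corrected Schwarz criterion
QSIC = deviance/ĉ + ln(N)·K with the conservative ΔQSIC > 7 rule, where
ĉ = Σχ²/Σdf from the transience (3.SR, 3.SM) and memory (WBWA) components.

Derived quantities: inter-seasonal reproductive period
ISRP = 1 + ψNB/ψB, probability of a future reproductive event, geometric
expectation of remaining events; Leslie matrix A = U + F with
Euler–Lotka-consistent fecundity (Σ λ⁻ˣ lx mx = 1), growth rate λ, R0,
generation time, life expectancies, Gini index of iteroparity,
reproductive value, pace and shape of aging and fecundity; and Cox
(cluster-robust) plus zero-truncated Poisson models of the intervals
between breeding seasons. See `docs/methods.md` for the full account.

## Worked example

```python
from mecmr import (MECMRModel, default_config, generating_design,
                   simulate_cohort, gof_summary, isrp)

cfg = default_config(n_individuals=400, seed=7)   # study-anchored defaults
truth, histories = simulate_cohort(cfg)

g = gof_summary(histories)
print(round(g.c_hat, 3))                          # 1.771

res = MECMRModel(histories, generating_design(cfg)).fit(n_starts=3, seed=7)
print(res.summary())
# Multi-event CMR model: generating
# histories: 400   K: 22   logL: -5409.776   deviance: 10819.552
# converged starts: 3/3   deviance spread: 2.03e-06
# ...
print(res.params["phi:b1"], res.bse["phi:b1"])    # -0.456 +- 0.024

s = res.schedules()
print(isrp(s["psi_nb"][1, 17], s["psi_b"][1, 17]).value)   # 1.408
```

Reading the numbers: the overdispersion ĉ = 1.77 > 1 reflects the latent
quality mixture the homogeneous GOF null cannot absorb. The fitted
survival slope −0.456 ± 0.024 recovers the generating −0.49 (logits per
year of age); the fitted age-17 arrival probabilities are 0.76
(high-quality) and 0.32 (low), against generating values 0.78 and 0.33.
The implied inter-seasonal reproductive period for a high-quality age-17
female is 1.41 years — she breeds nearly annually — while low-quality
females wait several times longer.

The same stages are exposed on the command line (`mecmr simulate`, `gof`,
`fit`, `compare`, `identify`, `derive`, `traits`, `intervals`, `run-all`),
and `mecmr run-all --out run/ --seed 1` writes every intermediate artifact
(histories and breeding CSVs, GOF report, coefficient tables, QSIC model
table, derived-quantity and trait JSONs, interval models, figures, run
manifest) to a directory.

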