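# Methods

## The model

`mecmr` implements a multi-event (hidden-Markov) capture–mark–recapture
model for annual encounter histories of known-age, long-lived iteroparous
females, motivated by captive sea-turtle breeding colonies but applicable
to any design where animals are followed from birth, recruit into a
breeding population, and then alternate between breeding and non-breeding
years until death or the end of the study.

The latent state space has eight ordered states

```
J, SA, NB-, NB+, B-, B+, FD, D
```

— juvenile, subadult, adult non-breeder and breeder each split into a
**low (−)** and **high (+)** latent quality class, freshly dead, and dead.
Quality is a fixed two-class mixture: it is assigned when the animal
recruits into the breeding population and never changes (the transition
matrix gives quality changes probability zero). The observation process
emits one of six coded events per year: `0` not observed, `1`–`4` seen as
J/SA/NB/B, `5` recovered dead.

One annual step factorises into survival (`phi`), transition conditional on
survival (`psi`), and detection (`p`):

* **Survival** is 1 for J and SA — the likelihood conditions on surviving
  to recruit — and age-dependent for adults. Death moves an animal to FD,
  where it can be recovered (event 5, probability `p_fd`) in the death year
  only, then to the absorbing D.
* **Recruitment** ties the three exit routes from J (to SA, B−, B+) and the
  two from SA to a single age-dependent probability `psi_r`, so the
  juvenile row is `(1−3·psi_r, psi_r, 0, 0, psi_r, psi_r, 0, 0)`. Note the
  tie forces equal latent-class weights at recruitment.
* **Arrival** `psi_b` (non-breeder breeds next year) and **departure**
  `psi_nb` (breeder skips next year) are age-dependent and
  quality-specific.
* **Detection** varies by year block and quality; juveniles are detected
  with probability 1 (their histories are anchored at birth), subadults
  with `p_sa` (default fixed at 1).

Each history contributes a forward-algorithm likelihood conditional on
release in J at age 0; the recursion is rescaled every occasion, so
histories of 60+ occasions are stable on the log scale.

### Links and coefficient bases

Two-outcome rows use the logit link; the juvenile row uses a multinomial
logit with "remain juvenile" as the reference cell, i.e.
`psi_r = exp(eta)/(1 + 3·exp(eta))`, which keeps the row stochastic
(`psi_r < 1/3`) for every finite coefficient vector — the optimiser can
never produce an invalid matrix. Age enters link functions **uncentered in
years** (`x = 0..45`), so slopes are logits per year of age and directly
comparable across studies. Purely for numerical conditioning, optimisation
runs on a centred/scaled basis `u = (age − 20)/10`; the affine map back to
the raw basis (and its Jacobian, for the covariance) is exact.

### Fitting, uncertainty, identifiability

`MECMRModel.fit()` maximises the summed log-likelihoods with L-BFGS-B from
`n_starts` random initialisations drawn uniformly on [−3, 3] on the scaled
link basis (default 10; per-start deviances are recorded so multimodality
is visible). The score is analytic: a forward–backward pass yields expected
transition counts by age and emission counts by year, chained through
central finite differences of the small deterministic matrix builders, so a
gradient costs about three likelihood evaluations regardless of the number
of coefficients. The Wald covariance is the inverse observed information
(central differences of the analytic score, step 1e-5 on the scaled basis).
When the information matrix has null directions the pseudo-inverse is used
and flagged: null directions get zero variance, reproducing the "SE = 0"
symptom that `check_identifiability` then probes by refitting with each
suspect coefficient pinned and comparing deviances.

**Label switching.** The likelihood is invariant to swapping the two
quality classes in every quality-stratified parameter simultaneously, so
roughly half of all random starts converge to the mirror image of the
optimum. Fits are canonicalized afterwards: the high-quality class is the
one with the larger mean arrival probability (falling back to detection,
then survival), matching the definition of quality as higher breeding
propensity. The likelihood is unchanged by the swap.

### Model selection

`QSIC = deviance/ĉ + ln(N)·K`, with `N` the number of capture histories —
histories, not detections, are the independent units of the conditional
likelihood. Only a difference larger than 7 QSIC units is flagged as strong
evidence for one model over another. `QAICc` is reported alongside and
omitted with a warning when `N ≤ K + 1`.

## Goodness of fit and overdispersion

Three contingency-table components are computed on the adult observable
process (events 3 and 4), each summed over occasions and stratified by the
state observed at the current occasion:

* **3.SR** (transience): first-time-encountered vs previously-encountered
  adults × re-encountered later vs never again (2×2 per occasion/state).
* **3.SM**: among re-encountered animals, time to next encounter
  (1, 2, 3+) × new/old, with lag columns pooled right-to-left while any
  expected count is below 2.
* **WBWA** (memory): previous-encounter state × next-encounter state.
  Stratifying by the current state is essential: under a first-order Markov
  chain past and future are independent *given the present*, but not
  marginally, so the pooled table would reject a true null.

Tables with an empty margin or (for 2×2) any expected count below 2 are
excluded — the classical small-sample rule. Calibration was verified by
simulation from a homogeneous first-order null (500 cohorts of 500
individuals): each component's mean χ²/df is statistically
indistinguishable from 1 (observed 1.013, 1.006, 1.014). The
overdispersion coefficient is `ĉ = Σχ²/Σdf`, floored at 1 for use in QSIC;
the raw value is always reported alongside.

## Derived demography

For age- and quality-specific departure `psi_nb`, arrival `psi_b` and
survival `phi`:

* inter-seasonal reproductive period `ISRP = 1 + psi_nb/psi_b` (years,
  ≥ 1);
* probability of a subsequent reproductive event
  `P = (1−psi_nb)·phi + psi_nb·psi_b·phi² / (1 − (1−psi_b)·phi)`;
* expected future reproductive events, geometric with mean `1/P` as the
  primary definition. The conventional mean number of remaining successes
  at per-cycle success probability `P` would be `P/(1−P)`; both are
  reported, neither silently substituted for the other.

Standard errors propagate by the delta method with central-difference
gradients (`numdifftools`-style differentiation is done in ~15 lines of
package code); the ISRP delta SE was validated against a 10,000-draw
parametric bootstrap (agreement within 5%). Population-level summaries
average the age-specific quantities unweighted over the adult age range.
CIs for derived quantities are Wald on the natural scale, truncated to the
admissible range.

## Leslie matrix and life-history traits

The age-classified model uses a birth-pulse census with offspring entering
class 0. A female of age x survives with probability `phi_x`
(sub-diagonal of U) and, upon reaching age x+1, contributes `m_{x+1}`
female eggs, so the fecundity row is `F[0,x] = phi_x·m_{x+1}`. With
survivorship `l_x = Π_{k<x} phi_k`, the dominant eigenvalue λ of
`A = U + F` then satisfies the discrete Euler–Lotka equation
`Σ λ^(−x) l_x m_x = 1` (asserted to 1e-8 on every built model). Maternity
is built from raw per-season egg counts as `m_x = (eggs_x/2)/ISRP` — halved
for a 50:50 egg sex ratio, discounted by the population-level ISRP because
females do not breed annually — and forced to zero below the age at first
reproduction (`afr`, default 7).

Before any trait is computed the life cycle is verified: there must be a
reproductive loop through age 0 (otherwise a structured error names the
disconnected classes) and the loop lengths must be coprime (aperiodicity,
hence ergodic convergence). Post-reproductive trailing classes are treated
as a permissible transient tail.

Traits: λ and `r = ln λ`; `R0 = Σ l_x m_x`; generation time
`ln(R0)/ln(λ)` (primary), with the λ-discounted mean age of mothers also
reported; life expectancies as fundamental-matrix column sums
(`N = (I−U)^{-1}`), which count the starting year, so whole-life and
post-maturity expectancies decompose additively across `afr`; the Gini
index of the ascending-sorted `l_x m_x` schedule (0 = perfectly even,
`1 − 1/n` = single-age reproduction; sorting is required for the
[0, 1] interpretation to hold on front-loaded schedules); reproductive
value `v_x/v_0 = (λ^x/l_x) Σ_{y≥x} λ^(−y) l_y m_y` with a residual
(future-only) form.

**Pace and shape.** Pace of aging is adult life expectancy; pace of
fecundity is the survivorship-weighted mean age at egg production minus
`afr`. The shape measures are defined so that constant-rate schedules give
exactly zero: `shape_surv` is `0.5` minus the area under the standardised
adult log-survivorship curve (log scale makes a constant hazard exactly
linear; positive = mortality rises with age), and `shape_rep` is the area
under the standardised cumulative-fecundity curve minus `0.5` (negative =
reproduction shifted late). The frequently cited "area between observed and
constant-rate survivorship curves matched on life expectancy" is not usable
verbatim: both curves enclose identical area by construction, so the signed
difference is identically zero. Published implementations differ in their
standardisation choices, so only the zero/sign calibrations — which all
variants share — are asserted, not agreement with any one software package.

## Inter-arrival models

Breeding records are turned into intervals: one closed interval per
consecutive pair of observed breeding seasons (1 = consecutive years) and
one right-censored interval from the last breeding season to death or the
study end. Covariates are measured at the interval's start (age,
experience = breeding seasons through the start, age at first reproduction,
current and cumulative clutches/eggs), which avoids conditioning on the
future.

The Cox model is fit with `lifelines` (Efron tie handling — the intervals
are heavily tied integers, and Efron is the more accurate approximation;
Breslow is not available in lifelines) with sandwich standard errors
clustered on individual. Diagnostics: scaled-Schoenfeld score tests per
covariate against rank time, a global statistic with df = number of
covariates, and Nagelkerke's pseudo-R². The count model is a
zero-truncated Poisson (`statsmodels` `TruncatedLFPoisson`, log link) on
closed intervals only — a count model has no censoring concept — with
effects reported as `(exp(β)−1)·100` percent changes and collinearity
screened by VIF (the informal VIF < 2 comfort threshold is reported, not
enforced).

## The synthetic cohort generator

`default_config()` encodes the study conditions: 156 females born
1966–2002, followed to 2018; recruitment quadratic through (age 7, 0.02)
and (age 16, 0.19) with vertex at age 20 on the juvenile-row multinomial
logit; adult survival logit-linear with slope −0.49 per year and intercept
12.25 (calibrated once so pooled annual adult survival ≈ 0.91); arrival
lines through (17, 0.78)–(34, 0.66) for high quality and (17, 0.33)–(34,
0.19) for low; departure slope −0.03 anchored at the age-40 values 0.19
(high) and 0.45 (low) — the age-40 points are reported estimates, the
slope is a package choice (the sign and rough magnitude follow from the
reported increase with age of the probability of remaining in the current
state); detection per year block (facility setup to 1984, 1985–2001, the
2002–2003 hurricane block with a distinct drop, 2004 onward) of 0.90–0.98
(low) and 0.96–0.99 (high) with 0.45/0.55 in the hurricane block; dead
recovery 0.5, constant over years (the per-block option exists, but
with these birth cohorts the earliest block contains essentially no deaths
and a per-block rate is structurally non-identifiable); quality mix 0.5 —
the value the recruitment tie implies; up to 10 clutches per season
(zero-truncated Poisson, mean 5) of ~120 ± 20 eggs.

Two deliberate consequences of these conditions:

* Under a raw-age slope of −0.49 logits/year, adult survival falls from
  ≈0.97 at age 18 to ≈0.4 by the mid-20s: the synthetic cohort has a
  compressed adult lifespan relative to a real turtle colony. A slope this
  large is only plausible if the original covariate was standardised, but
  raw age in years is the package's convention and the generator follows
  its own fitted scale, so the simulated study is internally consistent:
  the generating design refit on its own cohorts recovers every
  coefficient.
* The simulator never kills pre-recruitment animals, mirroring the model's
  conditioning (`phi = 1` for J and SA). The simulated population is the
  conditional population the likelihood describes, not a full cohort, so
  quantities like life expectancy at birth inherit that conditioning.

What the generator does **not** emulate: shared year-to-year environmental
stochasticity (year enters only through detection blocks), individual
heterogeneity beyond the two-class mixture, experience-driven acceleration
of breeding (intervals shorten with age in the generator because departure
declines; the antagonistic age × experience pattern of real data is not
built in), multi-site sampling, or tag loss. Passing tests therefore
demonstrate that the estimators recover the stated generative process at
the stated sample sizes — not that the process captures every feature of a
real colony.

## Numerical choices and problem sizes

* Convergence: L-BFGS-B, `ftol` 1e-10 (relative), `gtol` 1e-6; per-start
  records expose deviance spread.
* Hessian step 1e-5 (scaled basis); forward–backward chain-rule step 1e-6;
  delta-method step 1e-6.
* The test suite exercises parameter recovery at 20 cohorts of n = 1000
  (nominal-95% Wald coverage per coefficient), the likelihood against an
  exhaustive 8^T path enumeration for 200 random short histories, GOF
  calibration at 500 null cohorts of n = 500, and interval-model recovery
  at n = 2000 — sizes chosen to make Monte-Carlo error small relative to
  the assertions while keeping the default run fast.
* `scripts/acceptance.py` re-runs the full study at n = 800.

## Known limitations

* No parametric mortality laws (Gompertz etc.), no second-order "memory"
  transition structure (the WBWA signal is absorbed into ĉ), and no
  individual random effects beyond the two-class mixture.
* Detection-block boundaries assume annual occasions and a single site.
* The ZTP stage conditions on closed intervals, so very long intervals
  censored by the study end are informatively missing from the count model
  (they do enter the Cox stage).
* Wald intervals on the probability scale can be poor near 0/1; derived
  CIs are truncated to the admissible range rather than transformed.
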