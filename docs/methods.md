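# Methods

This note documents the model, the estimators, the distributional and
numerical conventions, and the choices made where the design was genuinely
open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The state-transition model

Eight mutually exclusive states: asymptomatic, signs/symptoms (any signs,
organomegaly or cytopenia), recovery (full reversal of signs/symptoms,
possible only under ERT because splenectomy and bone complications are
irreversible), splenectomy, bone complication (a single one), multiple
complications (several bone complications, or combinations with
splenectomy, Parkinson disease or pulmonary hypertension), malignancy
(multiple myeloma/amyloidosis or hepatocellular carcinoma), and death
(absorbing).  Cycle length is one year; the closed cohort runs from birth
to age 85.  Key structural assumptions:

* **Survival first.** Within a cycle, death is evaluated before disease
  movement: from any alive state the death probability is the life-table
  q(age); disease transitions apply conditional on survival.  The
  alternative ordering is a one-line change isolated in
  `cohort_engine.build_matrix`.
* **Malignancy excess mortality is additive** on q(age), capped at 1.
  Only the direction ("higher than background") is documented for the
  source cohort; the packaged value 0.15/yr reflects the poor prognosis of
  multiple myeloma and hepatocellular carcinoma and is a required,
  configurable fixture field.
* **No half-cycle correction.** State membership and rewards are read at
  cycle start; the source model is described without one, and fidelity to
  the described model was preferred over methodological preference.
* **ERT starts at symptom onset** in the base case: the asymptomatic state
  uses natural-history exit probabilities in every arm, ERT medication
  costs never accrue in the asymptomatic state, and they continue during
  recovery (therapy maintains the recovered state).
* If sampled outgoing disease probabilities from a state sum to more than
  1 they are rescaled proportionally with a warning, preserving relative
  risks.

## Outcomes and discounting

YFEOD sums occupancy over {asymptomatic, signs/symptoms, recovery}; QALYs
weight occupancy by state utilities (EQ-5D; UK time-trade-off tariff by
default, Dutch replication tariff as a config switch; dead ≡ 0,
non-configurable); costs weight occupancy by per-state annual components
(2009 euros throughout — no indexation).  Discounting uses
(1+r)^−k for cycle k with the first cycle undiscounted — the common cohort
convention; the source is silent, and the convention is isolated in
`economics.discounted_sum`.  Effects discount at 1.5%/yr, costs at 4%/yr.
Production loss enters only in its scenario and only for cycle ages 25–64
(a 40-year productive window).  ICERs are ΔC/ΔE; dominance is flagged when
the signs disagree.

One transcription choice: the published out-of-hospital cost table pools
"(no) signs/symptoms" into one row (€121/yr).  The packaged fixture
assigns it to the signs/symptoms state only, so the asymptomatic state's
annual cost equals its hospital-procedure row (€1,470) exactly.

## Calibration estimators

* **Competing-risk incidence.** Time from state entry to each destination
  is estimated with the cause-specific-hazard cumulative-incidence
  (Aalen–Johansen) estimator — the standard competing-risk correction of
  Kaplan–Meier; death and the other destinations act as competing risks.
  Ties are broken by counting events before censorings.  A naive 1−KM
  (competing events censored) is provided for sensitivity only.  The
  estimator is implemented in-package because the downstream reading rule
  needs the at-risk step function; `lifelines.AalenJohansenFitter` serves
  as an independent cross-check in the tests.
* **Reading rule.** If the incidence curve reaches 0.5, the reading is
  (0.5, the time at which it does); a step that jumps over 0.5 is read at
  the linearly interpolated crossing time.  Otherwise the curve is read at
  the last time with ≥ 4 patients still at risk; fewer than 4 ever at risk
  raises an insufficient-data signal.
* **Markov correction.** The cumulative proportion P over t years becomes
  a constant annual probability p = 1 − (1 − P)^(1/t).  The linear ratio
  P/t appears in some descriptions of this procedure but is not the
  conditional-probability correction; it is available as a diagnostic by
  composing the pieces manually.  The conversion is defined for reference
  times of at least one cycle (sub-year exponents are also numerically
  ill-conditioned near P = 1).
* **Estimator bias.** The median-time rule is not consistent under strong
  competing risks: reading p from 1−(1−P)^(1/t) at the median-crossing
  time underestimates the cause-specific annual probability by roughly a
  factor ln 2 / (r·(−ln(1−0.5/r))), where r is the destination's share of
  the total exit probability (≈5% low at r = 0.9, ≈12% at r = 0.8, ≈21% at
  r = 0.7).  Interpolating the crossing time removes the additional
  discretization bias of reading at whole-year steps.  This analysis
  shaped the synthetic truth values (below): with per-state exit
  structures dominated by one destination and all annual probabilities
  ≤ 0.1, the absolute bias stays under the 0.01 recovery tolerance the
  test suite enforces at n = 10,000.
* **Utilities.** Two-stage averaging — per patient per state, then over
  patients — so observation counts do not weight patients.  95% CIs are
  bias-corrected and accelerated (BCa) bootstrap over patients
  (`scipy.stats.bootstrap`, 2,000 replicates by default, seeded); a single
  patient yields a mean with the CI flagged unavailable.
* **Costs.** ERT: episode-length-weighted mean vials/month per patient,
  averaged over patients, ×12 × €1,985 per 400 IU vial.  Hospital:
  per-patient product sum of procedures × unit costs divided by years of
  state follow-up, then averaged over patients.  Out-of-hospital:
  per-patient mean quarterly cost × 4, then averaged.  Production loss
  (human capital): employed patients lose sick days/fortnight × 26 × the
  overall mean working hours/day × €30/h; GD-disabled patients lose a
  full-time equivalent (52 × mean workdays/week × mean hours/day × €30);
  patients out of work for other reasons lose nothing.  The friction-cost
  method is deliberately out of scope.

## Parameter distributions

Transition probabilities are beta-distributed.  `fit_beta_from_ci` matches
the printed mean exactly (α = m·n, β = (1−m)·n) and solves the
concentration n numerically so the central 95% interval reproduces the
printed limits; when no beta is compatible within 5×10⁻³ per limit it
falls back to method-of-moments on the implied SD (ucl−lcl)/3.92 and flags
the fit.  Utilities and costs use triangular distributions with the mean
as mode and the 95% limits as support; parameters without a printed
interval (e.g. the single-patient malignancy utility) are degenerate and
stay at their mean.

## PSA design

1,000 second-order draws × 100 first-order trials by default.  First-order
trials are individual microsimulations sharing the per-draw matrices with
the cohort engine; a cohort-mode evaluation (deterministic per draw) is
offered where only second-order uncertainty matters and is used for the
fast CEAC quantile readouts in the acceptance script (500 draws) and 300
draws × 100 trials for the microsimulation quadrant shares — sizes chosen
to keep a full rerun in the minutes range while leaving Monte Carlo error
well inside the reported precision.  Within a draw both arms reuse the
same sampled utility/cost tables and, optionally (default on), common
random numbers for the trials, reducing the variance of ΔC and ΔE.  The
CEAC uses strict NMB > 0, equivalent to the ICER-threshold rule when
ΔE > 0 and well-defined otherwise; boundary points of the CE plane count
toward the positive quadrant.  The WTP grid runs 0–10,000,000 €/QALY in
10,000 steps.

## The packaged fixture and the synthetic placeholders

Transcribed from the published cohort tables: per-state utilities (UK and
NL tariffs), ERT vials/year and annual medication costs, hospital and
out-of-hospital annual costs, production-loss annual costs, and the €1,985
vial price.  Three inputs of the source analysis are not publicly printed
and are shipped as clearly labelled synthetic stand-ins:

* `transitions_synthetic.csv` — annual transition probabilities chosen on
  clinical plausibility (a slowly progressing disease: symptom onset
  ~0.05/yr from birth; under ERT a dominant recovery path ~0.1/yr with
  strongly reduced progression; untreated progression to splenectomy /
  complications a few percent per year; malignancy rare from every state)
  and on the estimator-bias analysis above.  Beta shapes assume an
  effective sample size of 60, in line with a national cohort observed
  over two decades.
* `life_table_synthetic.csv` — Gompertz–Makeham
  q(x) = 1.5×10⁻⁴ + 2.2×10⁻⁵·e^(0.097x) with an infant bump q(0) = 0.004,
  shaped like Dutch all-cause mortality around 2009.
* historical 1991 starting distributions (config) — two synthetic
  prevalence mixes, variant II sicker than variant I.

Swapping in transcribed values reproduces a specific publication; with the
placeholders, absolute outputs are illustrative while every structural and
statistical property (conservation, monotonicity, estimator correctness,
recovery, PSA mechanics) is fully exercised.

## What the synthetic registry emulates — and what it does not

`synthetic_data.simulate_registry` draws trajectories from the truth
strategy at annual resolution with the same life-table mechanism as the
engine; censoring is administrative at the follow-up horizon (default 60
years) plus uniform whole-year censoring for 10% of patients.  Quarterly
EQ-5D observations (25% response rate) add normal noise (SD 0.05) clipped
to the tariff range [−0.594, 1]; clipping keeps the two-stage mean within
~0.002 of truth for the states nearest the bounds.  Dose records vary
log-normally across patients (SD 0.2) and switch dose mid-episode in long
episodes to exercise the episode-length weighting.  Procedure and
outpatient volumes are Poisson with unit costs set so annual costs match
truth in expectation.  Work profiles (60% employed, 15% GD-disabled where
production loss is positive) back out sick-leave means from the truth
costs; extreme states (e.g. the malignancy production loss, dominated by a
single real patient) cannot be reached under the 14-day fortnight cap, so
production-loss recovery is approximate by construction.

Not emulated: staggered calendar entry and confounding by indication,
treatment switching or the imiglucerase-shortage period, missing-data
mechanisms beyond uniform non-response, and sub-annual event timing.
Passing recovery tests therefore demonstrates estimator correctness under
the model's own assumptions, not robustness to the messiness of real
registry data.

## Numerical conventions and degenerate inputs

Probability mass is conserved to 1e-10 over 85 cycles (validated on every
trace); dead occupancy is checked monotone.  Start distributions must sum
to 1 within 1e-12.  A cumulative proportion of exactly 1 annualizes to 1
with a warning (instantaneous transition).  Beta/triangular draws are
clipped only by their natural supports; sampled strategies re-validate all
invariants.  Registry estimates for states without data are reported as
missing, never silently zero.  All randomness flows through
`numpy.random.Generator` objects; fixed seeds give bit-identical results,
and PSA draw/trial substreams are derived per draw so arms can share
common random numbers.

## Known limitations

* The headline numbers of the source analysis are reproducible only with
  its unpublished transition appendix and national life table; the bundled
  placeholders make the pipeline runnable, not the publication's numbers.
* The median-time reading rule is the source procedure, but it is biased
  under strong competing risks (analysis above); a person-year MLE would
  be consistent and is used as an independent check in the tests, not as
  the calibration estimator.
* One-year cycles cannot represent multiple transitions within a year;
  rapid sequences (e.g. splenectomy followed by a bone complication in the
  same year) are collapsed.
* Utilities and non-ERT costs are assumed equal for treated and untreated
  patients within a state — inherited from the source design, where it
  also motivates sharing sampled tables across arms in the PSA.
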