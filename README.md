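# gdcea — cost-effectiveness of enzyme replacement therapy in type 1 Gaucher disease

`gdcea` is a tested, reusable implementation of a lifetime cost-utility
analysis of enzyme replacement therapy (ERT, e.g. imiglucerase) versus
standard medical care in type 1 Gaucher disease (GD I), the
non-neuronopathic form of a rare lysosomal storage disorder.  It is aimed
at health economists and modellers who want to rerun, stress-test or
re-parameterise this kind of orphan-drug evaluation rather than rebuild it
in a spreadsheet or TreeAge.

## The model

Disease progression is a discrete-time Markov state-transition model with
eight mutually exclusive states

```
asymptomatic → signs/symptoms → {recovery*, splenectomy, bone complication}
             → multiple complications → malignancy → death
```

(*recovery is reachable only under ERT; bone complications and splenectomy
are irreversible).  Cycles are one year; a closed cohort starts
asymptomatic at birth and is followed to age 85.  Within a cycle survival
is evaluated first — death occurs with the age-specific background
probability q(age) from a life table, plus an additive excess in the
malignancy state — and disease transitions apply conditional on survival.

Lifetime outcomes per strategy arm are

* **YFEOD** — years free of end-organ damage: expected time in the
  asymptomatic, signs/symptoms and recovery states,
* **QALYs** — occupancy-weighted EQ-5D utilities u(s) (UK time-trade-off
  tariff, with a Dutch-tariff variant; death = 0),
* **costs** — occupancy-weighted annual costs per state (2009 euros):
  hospital procedures, out-of-hospital care, ERT medication (ERT arms
  only, priced per 400 IU vial at €1,985), and optionally human-capital
  production loss for ages 25–64.

Effects are discounted at 1.5%/yr and costs at 4%/yr (rewards at cycle
start, so cycle k carries (1+r)^−k).  Strategies are compared by the
incremental cost-effectiveness ratio ICER = ΔC/ΔE with ΔE in YFEOD or
QALYs.  Parameter uncertainty is propagated with a Monte Carlo PSA —
beta-distributed annual transition probabilities, triangular utilities and
costs, 1,000 second-order draws × 100 first-order microsimulation trials —
summarised as a cost-effectiveness plane and a cost-effectiveness
acceptability curve (CEAC) via net monetary benefit λ·ΔE − ΔC.

The package also contains the upstream estimation pipeline: a calibration
module that turns patient-level registry records (state episodes,
quarterly EQ-5D scores, ERT dose episodes, procedure logs, work records)
into transition probabilities (competing-risk cumulative incidence +
median-time rule + the Markov correction p = 1−(1−P)^(1/t)), two-stage
utility means with BCa bootstrap CIs, and per-state annual costs — plus a
synthetic registry generator with known ground truth for end-to-end
testing.

**Note on the packaged fixture.** Per-state utilities, costs and ERT vial
consumption are transcribed from the published Dutch cohort tables.  The
annual transition probabilities, the background-mortality life table and
the historical 1991 starting distributions are **synthetic placeholders**
(clearly labelled in their file names): the source values live in an
unpublished appendix and a national statistics table that are not bundled
here.  Absolute model outputs therefore illustrate the machinery; swap in
a transcribed `transitions.csv` / `life_table.csv` to reproduce a specific
publication.

## Worked example

```python
import gdcea

config, strategies, life_table = gdcea.load_default_parameters()
result = gdcea.run_scenario(
    gdcea.ScenarioSpec("base"), strategies, config, life_table
)
print(result.to_frame().round(2).to_string(index=False))
```

```
scenario  discounted  yfeod_ert  yfeod_no_ert  delta_yfeod  qalys_ert  qalys_no_ert  delta_qalys   costs_ert  costs_no_ert  delta_costs  icer_per_yfeod  icer_per_qaly
    base       False      62.83         35.85        26.98      65.34         58.06         7.29  8133402.76     234184.43   7899218.33       292834.65     1084302.33
    base        True      39.28         26.03        13.25      39.46         36.15         3.31  1862234.12      64476.63   1797757.49       135717.71      543287.65
```

Reading the undiscounted row: on the packaged (placeholder) natural
history, an untreated patient accrues 35.85 years free of end-organ damage
and 58.06 QALYs over a lifetime at €234,184, while starting ERT at symptom
onset yields 62.83 YFEOD and 65.34 QALYs at €8.13M — so each extra
damage-free year costs €292,835 and each extra QALY €1,084,302.
Discounting (effects 1.5%, costs 4%) shrinks the ratios to €135,718 and
€543,288.

The same analysis from a shell:

```sh
gdcea run --scenario ert_cost_reduction --out results.csv
gdcea psa --draws 1000 --trials 100 --seed 7 \
      --out-plane plane.csv --out-ceac ceac.csv
gdcea synth --n 1000 --seed 7 --out registry/
gdcea calibrate --registry registry/ --strategy ert_base --out fitted/
```

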