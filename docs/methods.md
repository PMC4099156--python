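# Methods

## Model structure

Disease management in mCRPC is represented by treatment-related health
states in a fixed, forward-only order; a patient can stay, advance to
the next line, or die, in monthly cycles. Two pathways are built in:

* **current** — AA → AAwd → Docetaxel → Abiraterone → OtherTx
  (the sequence publicly reimbursed in Quebec in 2013);
* **alternate** — AA → AAwd → Abiraterone → Docetaxel → Cabazitaxel →
  OtherTx (third-line hormone therapy moved before chemotherapy,
  second chemotherapy appended).

`OtherTx` is a catch-all (re-treatment / best supportive care) with
zero primary-drug cost; follow-up stops there at death or after 24
cycles, whichever comes first. A single absorbing death state covers
all causes. The simulation is individual-level (Monte-Carlo
microsimulation): tracker variables record each patient's paid cycles
per state, last line received, and death/censoring, so every cost is
reconstructible as cycles × monthly rate.

### Cycle convention

A cycle is **pay-then-draw**: the patient accrues the month's costs in
the current state, then one uniform draw resolves the competing exits
with death evaluated first (thresholds `p_death`, then
`p_death + (1−p_death)·p_progress`). Progression is blocked until the
state's protocol minimum `min_cycles` has been paid; death is never
blocked. Two consequences used throughout the tests:

* `P(die in state) = p_death × E[paid cycles]` exactly (each paid
  month is followed by exactly one draw);
* the occupancy law has closed-form survival
  `P(D ≥ t) = (1−q)^(t−1)` for `t ≤ max(m,1)` and
  `(1−q)^(m−1) s^(t−m)` beyond it, with `s` the stay probability —
  all calibration statistics are evaluated from it analytically.

Death is assumed to strike part-way through the following month, after
the monthly castration depot and the q4w denosumab have been
administered but before another month of primary treatment: the death
month therefore accrues supportive cost only. This convention is what
reconciles the per-line cost table with the whole-period totals in the
reference outputs (the difference between the two is exactly one
supportive-month times the overall death fraction, ≈ 0.9 months), and
it makes the reported mean mCRPC duration (28.1 months, current
pathway) the mean of *paid months + death month*.

## Costing

All prices are 2013 CAD. A model month is **30.42 days** — the unique
two-decimal value that reproduces every derivable printed monthly cost
simultaneously (abiraterone $3,448, cabazitaxel $8,460, docetaxel
$774, denosumab $585); body surface area is **1.9 m²**; a 3-month
goserelin depot covers exactly 3 model months ($1,113/3 = $371).

Two pricing dialects exist for i.v. drugs and both are implemented
behind `pricing_mode`:

* `table2` — the printed price-list dialect (docetaxel pro-rated by
  milligrams: $774/month);
* `simulation` (default) — whole vials charged per administration
  (docetaxel $868.84 + co-medications = $874.87/month), the dialect
  the reference simulated costs imply (7 paid months × $874.87 =
  $6,124, the reference median docetaxel-line cost).

Per-state primary rates bundle the line's drug with its oral
co-medication and i.v. premedications (docetaxel and cabazitaxel:
prednisone + dexamethasone, cabazitaxel additionally diphenhydramine
and famotidine; abiraterone: prednisone). Bicalutamide's printed
$58.71/month is not derivable from its $1.61 tablet price at any
day-count and is carried verbatim. Supportive therapy uses
**expectation weighting**: every alive patient accrues
`0.95 × $371 + 0.90 × $585` per month rather than 95%/90% of patients
being assigned the therapy individually — the reference per-line
supportive costs are exact multiples of $352.45/$526.50, which rules
out per-patient Bernoulli assignment.

## Transition probabilities and calibration

Monthly death probabilities come from trial evidence under the
constant-rate assumption: from a median survival `M`,
`p = 1 − exp(−ln2/M)` (AAwd 16.7 → 0.0407, docetaxel 18.9 → 0.0360,
post-docetaxel abiraterone 14.8 → 0.0458, cabazitaxel 15.1 → 0.0449);
from a fraction `P` dead at horizon `T`, `p = 1 − (1−P)^{1/T}`.
`OtherTx` inherits the death probability of the last preceding active
line (no direct evidence exists for it; configurable in the model
file). This choice independently reproduces the reference `OtherTx`
occupancy (mean ≈ 14.8 months, median 15, IQR ~6–24 under the 24-cycle
cap) with no further tuning.

Two states have no usable trial survival median — AA (mortality
reported only as "50% by end of study") and pre-docetaxel abiraterone
(median OS not reached in its trial). Their death probabilities are
**calibration outputs**: fixed so that the per-line death fraction
implied by the reference utilization sequence (100 → 88.1 → 72.7 →
54.2 → 29.4% for the current pathway) is reproduced, giving 0.0140/mo
(AA) and 0.0172/mo (pre-docetaxel abiraterone). The whole-model check
`survival_calibration` (geometric bisection on a death-probability
multiplier against the simulated median OS) confirms the current
pathway sits at the 25-month median overall survival target.

Treatment-duration parameters `(min_cycles, p_progress)` are
calibrated per state:

* `calibrate_state` implements the generic evidence route: smallest
  integer minimum whose residual-median conversion
  `p = 1 − exp(−ln2/(median − m))` puts the closed-form occupancy
  median within ±0.5 cycles of the trial median. The exact occupancy
  median (death active during the minimum phase) is used rather than
  the simplified `m + geometric-tail` median so that the analytic
  target coincides with what the engine simulates.
* The **built-in states** instead pin `p_progress` by closed-form
  inversion of the mean occupancy (`fit_progression_to_mean`) against
  the reference per-line occupancy means (per-line castration cost ÷
  $352.45: AA 8.52, AAwd 4.33, docetaxel 7.06, post-docetaxel
  abiraterone 10.04, pre-docetaxel abiraterone 20.15, cabazitaxel
  5.69 months), with `min_cycles` (4, 3, 7, 4, 8, 3) chosen to match
  the reference duration quartiles. Matching the occupancy *mean*
  automatically matches the per-line death/progression split (see the
  cycle-convention identity), which is why utilization, durations,
  survival and every cost table follow from this single anchor per
  state. The raw trial medians alone do not determine these values
  (the original model's probabilities were never published, and e.g.
  the AA trial's 12-month response duration is conditional on
  response); the calibrated values are therefore shipped as derived
  fixtures in `data/*.model`, regenerable with
  `mcrpcsim export current <path>`.

## Sensitivity scenarios

Four declarative, pure transformations of a model spec (`apply_scenario`
never mutates its input):

1. **transition multiplier** — scales a state's `p_progress` by
   1 ± 0.1/0.2, clipped to keep `p_progress + p_death ≤ 1`;
2. **docetaxel re-treatment** — a fraction of docetaxel progressors
   enters a cloned docetaxel state (same cost/duration parameters)
   that exits straight to `OtherTx`, *bypassing* the later expensive
   lines — the only routing under which re-treatment lowers total cost,
   as the reference scenario table shows it must;
3. **late entry** — a fraction of the cohort starts directly at the
   index line (docetaxel / abiraterone), with full supportive accrual
   from their later entry point (total cost roughly stable, monthly
   cost sharply higher);
4. **skip** — a fraction of AA progressors bypasses the withdrawal
   period; the complement follows the base path.

## Replicate confidence intervals

The 95% CI of a mean outcome is the 2.5th/97.5th percentile of sample
means over 1,000 independent replicate cohorts (seeded substreams of a
`SeedSequence`). The per-sample size defaults to 10,000: with a
per-patient cost SD of ≈ $40k this yields the ≈ $800 half-width on a
$48k mean seen in the reference CIs.

## Numerical choices

* One uniform draw per patient-cycle resolves death/progression; a
  second draw is consumed only on branching advances (scenario
  routing) and for late-entry starting states.
* IQRs and CI bounds use linear-interpolation percentiles
  (`numpy.percentile` default).
* Censored patients (alive at the `OtherTx` cap) enter survival
  statistics at their censored value — a lower bound, matching a
  follow-up that simply stops there.
* Monthly cost per patient = mean total cost ÷ mean mCRPC months;
  national total = per-patient mean × 4,000, exactly.
* Simulation sizes: 100,000-patient cohorts for headline tables
  (Monte-Carlo SE of the mean total cost ≈ $130), 10,000–100,000 per
  sensitivity scenario, 50 × 100,000 single-state runs for the
  calibration-recovery property.

## What the random-model generator does and does not emulate

`random_model` draws structurally valid forward chains (2–8 states,
integer median durations 2–24 months, monthly costs up to $10,000,
mortality fractions 0.2–0.8 at a 36-month horizon) and calibrates them
through the same `calibrate_state` route as real evidence. It exercises
every engine invariant (conservation, monotonicity, homogeneity,
recovery) but does not emulate correlated evidence, time-varying
hazards, or cost structures with premedication bundles; property-test
passes certify the simulation machinery, not the clinical realism of
any particular chain.

## Known limitations

* Constant per-state hazards (plus protocol minima) are the only
  time-dependence; no parametric survival fitting is attempted —
  medians are the only evidence the pathway definitions provide.
* The within-state *timing* of deaths is not pinned by any published
  table. All cohort-level outputs match the reference values, but the
  decomposition of cumulative cost by last line received — which
  conditions on where a patient died — deviates at its endpoints
  (e.g. the patients-who-only-received-AA group simulates ≈ $7.0k
  vs ≈ $5.7k in the reference figure). A calibration target for the
  death-time distribution would be needed to close this gap.
* Adverse-event costs, palliative radiotherapy, discounting,
  utilities/QALYs and cost-effectiveness ratios are out of scope;
  drugs never modelled in the reference pathways (enzalutamide,
  radium-223, sipuleucel-T, orteronel) are not represented.
* Prices are frozen 2013 Quebec list prices; no markup, dispensing-fee
  or provincial-variation modelling.
* The cabazitaxel-line primary rate reconstructed from the price list
  ($8,473.93/month) sits ≈ $150/month below what the reference
  per-line cabazitaxel cost implies (5 × $8,625); the discrepancy is
  not explainable from the printed rows and is left as-is (the
  alternate-pathway total remains within the reference CI).
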