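# mcrpcsim

Monte-Carlo microsimulation of drug costs over the metastatic
castration-resistant prostate cancer (mCRPC) treatment sequence.

Men who die of prostate cancer do so after their disease escapes
androgen deprivation. From that point the management is a sequence of
treatment lines — second-line hormone blockade (bicalutamide, AA), its
withdrawal period (AAwd), docetaxel chemotherapy, third-line hormone
therapy (abiraterone), cabazitaxel — with continuous supportive therapy
(LHRH-agonist medical castration and bone-targeted denosumab)
throughout. Each new line is expensive, and reimbursement decisions are
usually made one drug at a time; this package models the *whole
pathway* so that the cumulative drug bill of one mCRPC episode, and its
sensitivity to how patients flow between lines, can be estimated. It is
aimed at health-economics and outcomes researchers who need a
transparent, scriptable alternative to spreadsheet or TreeAge-style
state-transition models.

## Model

The pathway is a forward-only Markov chain of treatment-related states
$s_1 \to s_2 \to \dots \to s_K$ (ending in a catch-all `OtherTx` state)
plus an absorbing death state, stepped in one-month cycles by
individual-level Monte-Carlo microsimulation with tracker variables.
In each cycle a patient in state $s$ pays the state's primary-drug
monthly cost $c_s$ plus coverage-weighted supportive rates
$(0.95 \times \$371) + (0.90 \times \$585)$, then a single uniform draw
resolves the competing exits, death first:

$$P(\text{die}) = q_s, \qquad
  P(\text{advance}) = (1-q_s)\,p_s \cdot \mathbf{1}[t \ge m_s], \qquad
  P(\text{stay}) = \text{rest},$$

where $t$ is the number of paid months in the state and $m_s$ a
protocol minimum during which progression is forbidden but death is
not. Monthly probabilities come from trial medians under the standard
constant-rate (declining-exponential) conversion, $p = 1 -
e^{-\ln 2/\text{median}}$, or from a fraction $P$ dead at horizon $T$,
$p = 1-(1-P)^{1/T}$. Death is taken to strike part-way through a month
in which the supportive depots have already been given, so supportive
(but not primary) cost accrues for the death month. Patients alive two
years after entering `OtherTx` are censored. Cohort means, medians and
percentile CIs (from 1,000 replicate samples of equal size) reproduce
the published per-line utilization, duration, survival and cost tables
for the two built-in 2013 Quebec pathways, and four families of
sensitivity scenarios re-route patient flow declaratively
(progression-probability multipliers, docetaxel re-treatment, late
entry, withdrawal-period skipping).

## Worked example

```python
import mcrpcsim as m

spec = m.builtin_model("current")          # AA→AAwd→Docetaxel→Abiraterone→OtherTx
summary = m.simulate_cohort(spec, 100_000, seed=1)
print(m.utilization_and_survival_table(summary).round(1))
print(m.total_cost_table(summary).round(1))
```

```
             pct_receiving  dur_mean  dur_median  dur_q25  dur_q75  surv_mean  surv_median
state
AA                   100.0       8.5         7.0      5.0     11.0       28.0         25.0
AAwd                  88.1       4.3         4.0      3.0      5.0       22.0         18.0
Docetaxel             72.5       7.0         7.0      7.0      8.0       21.3         18.0
Abiraterone           53.9      10.0         8.0      5.0     13.0       18.8         16.0
OtherTx               29.0      14.8        15.0      7.0     24.0       15.4         16.0

               mean   median  iqr_low  iqr_high  monthly_mean  national_total  share_pct
category
primary     23592.4  14307.8    880.6   36575.1         841.3      94369771.6       48.9
castration   9883.3   8811.2   4934.3   14098.0         352.4      39533371.9       20.5
bone        14764.0  13162.5   7371.0   21060.0         526.5      59056094.0       30.6
total       48239.8  36854.7  13888.8   72650.4        1720.3     192959237.5      100.0
```

Reading: every patient starts on AA; 72.5% ever receive docetaxel
(median 7 months on treatment, the protocol minimum) and 29.0% survive
all active lines into `OtherTx`. The mean drug bill of one mCRPC
episode is ≈ $48,240 (2013 CAD) over a mean 28.0 months (median overall
survival 25 months, IQR 14–40), i.e. ≈ $1,720 per patient-month.
Medical castration alone is 20.5% of the total and bone-targeted
therapy 30.6% — supportive therapy costs more than half as much again
as the headline cancer drugs. `national_total` scales the per-patient
mean to the annual Canadian cohort of 4,000 mCRPC patients
(≈ $193M/year). Switching to `builtin_model("alternate")` (abiraterone
before docetaxel, cabazitaxel appended) raises the mean episode cost to
≈ $103,800.

The same run is available from the shell:

```sh
mcrpcsim run --model current --n 100000 --seed 1
mcrpcsim sensitivity --model current --n 10000 --seed 1
mcrpcsim cost-table
```

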