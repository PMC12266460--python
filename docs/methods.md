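# Methods

## Model structure and assumptions

The analysis is a deterministic (cohort-expectation) state-transition model:
a closed cohort starts at month 0 entirely in the <5% weight-loss state (by
definition, everyone is at baseline weight) and its expected occupancy over
the four states {<5%, 5–10%, >10%, dead} is propagated at 6-month cycles to
month 70 (the 22-month trial plus eight post-trial cycles). Death/loss to
follow-up is the only absorbing state; no half-cycle correction is applied
by default (a `half_cycle` flag switches cost/QALY attribution to interval
midpoints).

Assumptions worth making explicit:

* **Trial window as observed blocks.** Months 0→4, 4→16 and 16→22 are three
  schedule segments whose matrices come straight from the data, each applied
  in one step (the 4→16 block spans two nominal cycles but is estimated and
  applied as one observed block). This makes the trace reproduce the
  empirical occupancies at months 4, 16 and 22 exactly — the
  estimation/propagation anchoring property the test suite asserts.
* **Last-observed extrapolation.** Every post-trial cycle reuses the
  month-16→22 matrix. This is a conservative assumption: it freezes the
  post-intervention regain dynamics observed in the final trial phase.
* **Homogeneous mortality.** One annual death/attrition probability for all
  participants and both arms, applied only post-trial (none was observed
  in-trial) as a multiplicative competing risk on the alive rows. The
  default, 1 − 0.957^(1/5) ≈ 0.00875/year, is back-computed from the modeled
  4.3% five-year absorbing fraction. With eight post-trial cycles this
  yields ≈3.4% dead at month 70, not 4.3% — the published model's cycle
  count and life-table inputs are not recoverable from the printed
  summaries, so the absolute absorbing fraction is approximate; it is a
  config parameter (`annual_mortality_prob`).
* **Category boundaries.** Percent loss L = (baseline − current)/baseline;
  L < 0.05 (including gain) → <5%, 0.05 ≤ L ≤ 0.10 → 5–10%, L > 0.10 → >10%.
  Ties at the printed endpoints go to the moderate bin.

## Economic parameters

| parameter | default | units | notes |
| --- | --- | --- | --- |
| discount rate | 0.03 | per year | costs and QALYs, from month 0; OWSA varies to 0.01/0.05 |
| WTP threshold | 150,000 | USD/QALY | strict inequality at the boundary |
| horizon | 70 | months | 22-month trial + 8 cycles; configurable |
| five-year window | (10, 70) | months | 60 months of accumulation, 0–5 QALY scale |
| end-of-trial window | (10, 22) | months | 12 months, 0–1 QALY scale |
| annual mortality | 0.00875 | probability | from the 4.3% 5-year absorbing fraction |

State-conditional inputs (packaged fixtures): utilities HT-VAS
64.71/73.73/82.96 and SF-36 61.94/73.86/79.68 for <5%/5–10%/>10%; monthly
out-of-pocket costs $44.97+$57.37, $40.71+$33.69, $35.20+$43.81
(medication + other), i.e. $102.34, $74.40 and $79.01 per month. Program
delivery per participant: $351.82 control vs $880.43 coaching (incremental
$528.61), booked undiscounted since all delivery happens within the first
16 months.

A window is split at the trace's stored times; each sub-interval is valued
at the occupancy stored at its end and discounted at its end (attribution
convention of a spreadsheet cohort model). Within-trial accumulation
therefore starts at month 10 valuing (10,16] at the month-16 occupancy.
Of note: the trial's published end-of-trial QALYs (0.7497/0.7268 coaching,
0.7095/0.6872 control) equal exactly one undiscounted year at the month-16
occupancy-weighted mean score; the default window (10,22) with discounting
from month 0 gives slightly lower values. Since windows and the discount
anchor are fully configurable and no incremental conclusion changes, the
default keeps a single consistent discounting convention rather than
matching that printed presentation.

## Calibrated fixture matrices

The full month-16→22 transition matrices were never published — only the
occupancy margins and the two >10%→5–10% regain probabilities (0.2571
control, 0.2273 coaching). For fixture-only runs the package solves for the
**minimum-movement** matrix: the row-stochastic alive-block closest to the
identity (Frobenius norm, SLSQP) satisfying the occupancy margins with the
published entries pinned. This is a reconstruction, not the trial's matrix:
it makes the <5% row maximally sticky, so absolute five-year occupancies
(and hence absolute costs/QALYs) differ from the published modeled values
while month-16/22 anchoring and the incremental structure are preserved.
Analyses needing the real dynamics should supply participant-level records,
from which all matrices are estimated empirically.

## Synthetic trial generator

The generator emulates the trial: arms of 153 (education control) and 149
(individual coaching); baseline weight ~ N(99.8, 14.6²) kg, age ~ N(55.4,
10.3²) years (both truncated to plausible ranges), 82.7% female. Weight-loss
categories at month 16 are drawn from the observed occupancies and coupled
to month 22 through the same calibrated matrices the estimator recovers, so
generator and estimator are mutually consistent; month-4 occupancy (never
published) defaults to (0.30, 0.30, 0.40), a plausible end-of-active-phase
split that feeds only the trace, not the economic windows. Percent loss
within a category is uniform over the category interval, with the open >10%
category truncated at 25% loss. Survey scores are truncated normal
(sd 15 — a typical population SD for these 0–100 instruments, not reported
in the trial summaries) around the state means; monthly costs are
zero-inflated (p₀ = 0.2) gamma mixtures whose overall mean equals the state
mean, with CV 1.0 on the positive part; survey and cost fields are missing
completely at random at rate 0.05.

What the generator does **not** emulate: informative dropout, within-trial
mortality, arm-specific utility or cost distributions, correlation between
a participant's repeated scores, or secular weight drift between
assessments. Passing tests therefore demonstrate correctness of the
estimation → propagation → valuation machinery under the model's own
assumptions, not robustness of the trial's conclusions to violations of
those assumptions.

## Sensitivity analyses

**PSA.** Per replication, each state's utility means are redrawn from
normals truncated to [0,100] centered at the base-case means with
standard-error-scale spread (sd 15/√100 = 1.5), and each state's monthly
cost components from zero-inflated gamma (p₀ = 0.2, CV 1.0) with base-case
means; one draw is shared by both arms, so incremental differences are
driven by occupancy. Transition probabilities are not resampled (the
uncertain "key parameters" are the valuation inputs; occupancies are
trial-anchored). 1,000 replications, seeded and exactly reproducible.
Distribution fitting for user data: truncated-normal by direct likelihood
maximization (moment initialization, Nelder-Mead), zero-inflated gamma with
the zero fraction matched exactly and gamma MLE on the positive part;
degenerate samples (constant, or all-zero) produce explicit point-mass
specs so a zero-variance PSA reproduces the base case exactly.

**OWSA.** Eleven rows: base; each arm's phase-2 program cost ±20%
(applied to the cost totals; per-participant values re-derived, e.g.
$555.31 → $666.37 / $444.25 for coaching); all-state monthly medication and
other-healthcare costs ±20%; discount rate 1% and 5%. Pure cost scenarios
leave incremental QALYs bit-identical by construction.

## Numerical choices

* Row-stochasticity enforced at 1e-9; occupancies renormalized each step so
  conservation is exact; the DEAD row is stored exactly as (0,0,0,1).
* Empty origin states during estimation get a self-loop row with a warning
  (conservative, preserves stochasticity).
* Currency arithmetic rounds half-up to cents only at reporting boundaries
  (per-participant divisions, OWSA "new value" columns); accumulators run in
  floats.
* Probability rescaling across horizons assumes a constant hazard:
  p' = 1 − (1 − p)^(t'/t).
* ICER dominance: "dominant" when ΔC ≤ 0 < ΔE, "dominated" when ΔE < 0 ≤ ΔC,
  undefined-ratio label when |ΔE| < 1e-9.

## Known limitations

* Absolute five-year occupancies, costs and QALYs from fixture-only runs
  reflect the calibrated reconstruction of unpublished matrices, not the
  trial's own model; incremental program-cost arithmetic, ICER ratio
  identities, and all structural invariants are exact.
* The published summary tables themselves contain small internal
  inconsistencies (per-arm SF-36 five-year values vs. their printed
  increment; the one-way table's base row vs. the main results table);
  where a ratio check is performed it uses the internally consistent pair.
* Mortality is age- and sex-homogeneous; the group-coaching arm of the
  original trial is out of scope (it was excluded as no more effective than
  control).
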