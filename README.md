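# leapcea

Cost-effectiveness analysis of telephone-based individual weight-loss
maintenance coaching for rural adults with obesity, versus an education-only
control, built as a tested, reusable pipeline around a discrete-time Markov
cohort model.

The package is aimed at health-economics and prevention researchers who want
to rerun, perturb, or extend a trial-anchored weight-maintenance
cost-effectiveness model — from participant-level longitudinal records (real
or synthetic) through transition estimation, cohort simulation, costing and
QALY accumulation, to ICERs with probabilistic and one-way sensitivity
analysis.

## The model

Participants occupy one of four mutually exclusive states defined by percent
weight reduction from baseline (month 0) weight:

* **<5%** — limited or no weight loss (weight gain included),
* **5–10%** — moderate weight loss (both endpoints inclusive),
* **>10%** — large weight loss,
* **dead** — death or loss to follow-up, the single absorbing state.

Within the trial window, transition matrices between the assessments at
months 0, 4, 16 and 22 are estimated as empirical row-wise proportions,

> P(i→j) = #(state i at t₁ and state j at t₂) / #(state i at t₁),

so the simulated cohort reproduces the observed occupancies at every
assessment exactly. Past month 22 the last observed (month 16→22, one
6-month cycle) matrix is reapplied each cycle out to month 70, with a
constant background mortality probability layered on as a competing risk
(annual probability back-computed from the modeled 4.3% five-year absorbing
fraction via the constant-hazard conversion `p_cycle = 1 − (1 − p_annual)^(1/2)`).

Economics attach to the occupancy trace per cycle:

* **program delivery costs** per participant = arm totals / arm size
  (phase 1 active-loss program plus phase 2 maintenance intervention),
  booked undiscounted;
* **out-of-pocket costs**: state-conditional self-reported monthly medication
  + other healthcare costs, occupancy-weighted, discounted at 3%/year;
* **QALYs**: state-conditional 0–100 health scores (HT-VAS visual analogue
  and SF-36 general health) divided by 100, accumulated over years lived.

Cost-effectiveness is the incremental ratio ICER = ΔC/ΔE against a
willingness-to-pay threshold of $150,000/QALY (strict inequality), with net
monetary benefit ΔE·λ − ΔC as the equivalent decision rule. The PSA
resamples state utilities (normal truncated to [0,100]) and state monthly
costs (zero-inflated gamma), shared across arms within a replication, and
reruns the economics end-to-end 1,000 times; the OWSA moves one parameter at
a time (program and monthly costs ±20%, discount rate to 1% / 5%).

Because the participant-level trial data are not redistributable, the
package ships the published summary inputs (state utilities and costs,
program cost ledgers, observed occupancies) as fixtures, and a synthetic
trial generator that emulates the trial's statistical structure for
end-to-end testing; see `docs/methods.md`.

## Worked example

Run the deterministic pipeline from the packaged summary fixtures (no
participant-level file needed), then the PSA:

```bash
$ leapcea run --out demo
incremental cost (5y): $366.21
  htvas: dQALY=0.0940 ICER=3894.618260319129
  sf36: dQALY=0.0943 ICER=3883.1334246573197

$ leapcea psa --out demo --seed 7
cost-effective (htvas): 100.0% of replications
cost-effective (sf36): 100.0% of replications
```

Over the five-year horizon the coaching arm costs $366.21 more per
participant (the $528.61 incremental program cost, partly offset by lower
out-of-pocket spending while more participants hold ≥5% weight loss) and
gains about 0.094 QALYs, giving ICERs near $3,900/QALY — far below the
$150,000/QALY threshold, and still below it in every one-way scenario and
in effectively all PSA replications. Absolute five-year levels depend on
the full month-16→22 transition matrices, which were never published;
the fixture run uses minimum-movement matrices calibrated to the observed
occupancy margins (see `docs/methods.md`), so incremental results are
anchored while absolute occupancies are a reconstruction.

The same pipeline runs from participant-level data: `leapcea synth --out d
--seed 1` writes a 302-row synthetic cohort CSV, and a config with
`cohort_path: d/cohort.csv` makes `leapcea run` estimate all transition
matrices from the records instead. `leapcea owsa` and `leapcea report`
produce the tornado-ready scenario table and a markdown summary.

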