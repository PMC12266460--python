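"""Costing and QALY accumulation over a cohort trace.

Three ingredients are attached to a state-occupancy trace:

* per-arm program delivery costs, divided equally across the arm's
  participants and booked undiscounted (they are incurred in-trial);
* state-conditional out-of-pocket monthly costs (medication + other
  healthcare), accumulated per cycle, occupancy-weighted and discounted;
* state-conditional 0-100 health scores (HT-VAS visual-analogue and SF-36
  general health) treated as utilities on division by 100, accumulated into
  QALYs the same way.

The DEAD state contributes zero cost and zero utility.  A window is split
into the trace's stored intervals; each sub-interval is valued at the
occupancy stored at its end, with the discount factor taken at the interval
end by default or at its midpoint when half-cycle correction is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .markov_engine import CohortTrace, occupancy_at
from .states import ALIVE_STATES, WeightState

MEASURES = ("htvas", "sf36")


def per_participant_cost(total_usd: float, n: int) -> float:
    """Divide a delivery-cost total equally across participants, to the cent."""
    if n < 1:
        raise ValueError("participant count must be at least 1")
    if total_usd < 0:
        raise ValueError("total cost must be non-negative")
    return round_cents(total_usd / n)


def round_cents(value: float) -> float:
    """Round half-up to two decimals (ledger convention, not banker's)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ProgramCosts:
    """Per-arm program delivery totals and their per-participant shares."""

    phase1_total_usd: float
    phase2_total_usd: float
    n_participants: int

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")
        if self.phase1_total_usd < 0 or self.phase2_total_usd < 0:
            raise ValueError("cost totals must be non-negative")

    @property
    def phase1_per_participant(self) -> float:
        return per_participant_cost(self.phase1_total_usd, self.n_participants)

    @property
    def phase2_per_participant(self) -> float:
        return per_participant_cost(self.phase2_total_usd, self.n_participants)

    @property
    def total_per_participant(self) -> float:
        return per_participant_cost(
            self.phase1_total_usd + self.phase2_total_usd, self.n_participants
        )

    def scaled(self, phase1: float = 1.0, phase2: float = 1.0) -> "ProgramCosts":
        return ProgramCosts(
            self.phase1_total_usd * phase1,
            self.phase2_total_usd * phase2,
            self.n_participants,
        )


@dataclass(frozen=True)
class StateEconomics:
    """State-conditional utilities (two 0-100 measures) and monthly costs.

    ``utilities`` maps alive state -> {"htvas": score, "sf36": score};
    ``monthly_costs`` maps alive state -> {"rx": usd, "other": usd}.
    """

    utilities: dict
    monthly_costs: dict

    def __post_init__(self) -> None:
        for state in ALIVE_STATES:
            if state not in self.utilities or state not in self.monthly_costs:
                raise ValueError(f"missing economics for state {state.label}")
            for measure in MEASURES:
                score = self.utilities[state][measure]
                if not 0.0 <= score <= 100.0:
                    raise ValueError(
                        f"{measure} score for {state.label} must be in [0, 100], "
                        f"got {score}"
                    )
            for component in ("rx", "other"):
                cost = self.monthly_costs[state][component]
                if cost < 0:
                    raise ValueError(
                        f"{component} cost for {state.label} must be >= 0, got {cost}"
                    )

    def utility(self, state: WeightState, measure: str) -> float:
        if measure not in MEASURES:
            raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
        if state == WeightState.DEAD:
            return 0.0
        return float(self.utilities[state][measure])

    def monthly_cost(self, state: WeightState) -> float:
        return total_monthly_state_cost(self, state)

    def utility_vector(self, measure: str) -> np.ndarray:
        return np.array([self.utility(s, measure) for s in WeightState])

    def cost_vector(self) -> np.ndarray:
        return np.array([self.monthly_cost(s) for s in WeightState])

    def with_values(self, utilities=None, monthly_costs=None) -> "StateEconomics":
        return StateEconomics(
            utilities if utilities is not None else self.utilities,
            monthly_costs if monthly_costs is not None else self.monthly_costs,
        )

    def scaled_costs(self, rx: float = 1.0, other: float = 1.0) -> "StateEconomics":
        costs = {
            state: {
                "rx": self.monthly_costs[state]["rx"] * rx,
                "other": self.monthly_costs[state]["other"] * other,
            }
            for state in ALIVE_STATES
        }
        return self.with_values(monthly_costs=costs)


def total_monthly_state_cost(econ: StateEconomics, state: WeightState) -> float:
    """Total (medication + other) monthly out-of-pocket cost in a state."""
    if state == WeightState.DEAD:
        return 0.0
    entry = econ.monthly_costs[state]
    return float(entry["rx"] + entry["other"])


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discounting anchored at ``time_zero_month``."""

    annual_rate: float = 0.03
    time_zero_month: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.annual_rate < 1.0:
            raise ValueError("annual_rate must be in [0, 1)")


def discount_factor(spec: DiscountSpec, month: float) -> float:
    """Present-value factor ``(1 + r)^(-(month - t0)/12)``."""
    if month < spec.time_zero_month:
        raise ValueError(
            f"month {month} precedes time zero {spec.time_zero_month}"
        )
    return (1.0 + spec.annual_rate) ** (-(month - spec.time_zero_month) / 12.0)


def _window_intervals(trace: CohortTrace, window) -> list:
    """Split ``window`` at the trace's stored times.

    Returns ``(end_month, months_long, occupancy_at_end)`` triples.  The
    window must end at a stored time; its start may fall inside a stored
    interval (that partial sub-interval is valued at the interval-end
    occupancy, consistent with end-of-cycle attribution).
    """
    start, end = window
    if end <= start:
        raise ValueError(f"window end must exceed start, got {window}")
    times = trace.times_months
    if start < times[0] - 1e-9 or end > times[-1] + 1e-9:
        raise ValueError(
            f"window {window} outside trace span [{times[0]}, {times[-1]}]"
        )
    if not np.any(np.isclose(times, end, atol=1e-9)):
        raise ValueError(
            f"window end {end} is not a stored trace time; stored times: "
            f"{times.tolist()}"
        )
    cuts = [t for t in times if start + 1e-9 < t <= end + 1e-9]
    intervals = []
    prev = start
    for t in cuts:
        intervals.append((float(t), float(t - prev), occupancy_at(trace, t)))
        prev = t
    return intervals


def accumulate_costs(
    trace: CohortTrace,
    econ: StateEconomics,
    prog: ProgramCosts | None,
    spec: DiscountSpec,
    window,
    half_cycle: bool = False,
) -> float:
    """Discounted per-participant costs over ``window`` (USD).

    Program delivery costs (if given) enter undiscounted; out-of-pocket state
    costs accrue per sub-interval as occupancy-weighted monthly cost x months
    x discount factor.
    """
    cost_vec = econ.cost_vector()
    total = prog.total_per_participant if prog is not None else 0.0
    for end, months, occ in _window_intervals(trace, window):
        attr = end - months / 2.0 if half_cycle else end
        total += float(occ @ cost_vec) * months * discount_factor(spec, attr)
    return total


def accumulate_qalys(
    trace: CohortTrace,
    econ: StateEconomics,
    measure: str,
    spec: DiscountSpec,
    window,
    half_cycle: bool = False,
) -> float:
    """Discounted QALYs over ``window``: scores/100 weight the years lived.

    One year in a state scoring 100, undiscounted, is exactly 1.0 QALY.
    """
    util_vec = econ.utility_vector(measure) / 100.0
    total = 0.0
    for end, months, occ in _window_intervals(trace, window):
        attr = end - months / 2.0 if half_cycle else end
        total += float(occ @ util_vec) * (months / 12.0) * discount_factor(spec, attr)
    return total
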