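"""Packaged default inputs: the trial's published summary figures.

These CSVs carry the base-case parameters of the Rural LEAP (rural lifestyle
eating and activity program) economic evaluation: state-conditional survey
scores and out-of-pocket monthly costs, program delivery cost ledgers per arm
and phase, observed state occupancies at the month-16 and month-22
assessments, and the published cost-effectiveness and one-way-sensitivity
summary rows used for self-consistency checks.

Full month-16 to month-22 transition matrices were not published; only the
large-to-moderate regain probabilities were.  ``default_transition_matrix``
therefore calibrates a minimum-movement matrix consistent with the observed
occupancy margins and those pinned entries.
"""

from __future__ import annotations

import functools
from importlib import resources

import numpy as np
import pandas as pd

from .economics import ProgramCosts, StateEconomics
from .states import ALIVE_STATES, Arm, WeightState
from .transitions import TransitionMatrix, calibrate_matrix, rescale_probability

#: Published large-loss -> moderate-loss regain probabilities over months 16-22.
PUBLISHED_GT10_TO_MODERATE = {
    Arm.EDUCATION_CONTROL: 0.2571,
    Arm.INDIVIDUAL_COACHING: 0.2273,
}

#: Five-year absorbing (mortality / loss to follow-up) fraction used to
#: back out the annual background death probability.
FIVE_YEAR_ABSORBING_FRACTION = 0.043


def _read(name: str) -> pd.DataFrame:
    with resources.files("leapcea.data").joinpath(name).open("r") as handle:
        return pd.read_csv(handle)


@functools.lru_cache(maxsize=None)
def load_state_economics() -> StateEconomics:
    """Base-case state-conditional utilities and monthly out-of-pocket costs."""
    frame = _read("state_econ.csv")
    utilities, costs = {}, {}
    for row in frame.itertuples():
        state = WeightState.from_label(row.state)
        utilities[state] = {"htvas": row.htvas, "sf36": row.sf36}
        costs[state] = {"rx": row.rx_monthly, "other": row.other_monthly}
    return StateEconomics(utilities, costs)


@functools.lru_cache(maxsize=None)
def load_program_costs() -> dict:
    """Per-arm program delivery costs aggregated from the line-item ledger."""
    frame = _read("program_costs.csv")
    out = {}
    for arm_value, group in frame.groupby("arm", sort=False):
        arm = Arm.parse(arm_value)
        n = int(group["n_participants"].iloc[0])
        phase_totals = group.groupby("phase")["total_usd"].sum()
        out[arm] = ProgramCosts(
            phase1_total_usd=float(phase_totals.get(1, 0.0)),
            phase2_total_usd=float(phase_totals.get(2, 0.0)),
            n_participants=n,
        )
    return out


@functools.lru_cache(maxsize=None)
def load_occupancy_targets() -> dict:
    """Observed ``{(arm, month): occupancy vector over 4 states}``."""
    frame = _read("occupancy_targets.csv")
    out = {}
    for row in frame.itertuples():
        vec = np.array([row.lt5, row.m5_10, row.gt10, row.dead])
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"occupancy target for ({row.arm}, {row.month}) sums to {vec.sum()}"
            )
        out[(Arm.parse(row.arm), int(row.month))] = vec
    return out


def load_published_cea() -> pd.DataFrame:
    """Published per-arm costs and QALYs (end-of-trial and five-year)."""
    return _read("published_cea.csv")


def load_published_owsa() -> pd.DataFrame:
    """Published one-way sensitivity rows (incrementals and ICERs)."""
    return _read("published_owsa.csv")


@functools.lru_cache(maxsize=None)
def default_transition_matrix(arm: Arm) -> TransitionMatrix:
    """Calibrated month-16 -> month-22 matrix for fixture-only runs.

    Minimum-movement solution over the alive states matching the observed
    occupancy margins, with the published large-to-moderate entry pinned.
    """
    arm = Arm.parse(arm)
    targets = load_occupancy_targets()
    occ16 = targets[(arm, 16)][:3]
    occ22 = targets[(arm, 22)][:3]
    fixed = {
        (WeightState.LOSS_GT10, WeightState.LOSS_5_10): PUBLISHED_GT10_TO_MODERATE[arm]
    }
    return calibrate_matrix(occ16, occ22, fixed=fixed, interval_months=6.0)


def default_annual_mortality() -> float:
    """Annual absorbing probability implied by the 5-year 4.3% fraction."""
    return rescale_probability(FIVE_YEAR_ABSORBING_FRACTION, from_years=5.0, to_years=1.0)
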