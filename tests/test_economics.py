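"""Program costing, discounting, and cost/QALY accumulation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from leapcea import datasets
from leapcea.economics import (
    DiscountSpec,
    ProgramCosts,
    StateEconomics,
    accumulate_costs,
    accumulate_qalys,
    discount_factor,
    per_participant_cost,
    total_monthly_state_cost,
)
from leapcea.markov_engine import CohortTrace
from leapcea.states import ALIVE_STATES, Arm, WeightState


def constant_trace(occupancy, months=(0.0, 6.0, 12.0)):
    occ = np.tile(np.asarray(occupancy, dtype=float), (len(months), 1))
    return CohortTrace(np.asarray(months), occ)


def uniform_econ(score=100.0, rx=0.0, other=0.0):
    return StateEconomics(
        utilities={s: {"htvas": score, "sf36": score} for s in ALIVE_STATES},
        monthly_costs={s: {"rx": rx, "other": other} for s in ALIVE_STATES},
    )


@pytest.mark.parametrize(
    "total, n, expected",
    [
        (82_741.19, 149, 555.31),  # coaching phase-2 delivery
        (4_085.13, 153, 26.70),  # control phase-2 delivery
        (131_184.44, 149, 880.43),  # coaching phases 1+2
        (53_828.87, 153, 351.82),  # control phases 1+2
        (0.0, 10, 0.0),
    ],
)
def test_per_participant_cost_to_the_cent(total, n, expected):
    assert per_participant_cost(total, n) == expected


def test_per_participant_cost_rejects_zero_participants():
    with pytest.raises(ValueError):
        per_participant_cost(100.0, 0)


def test_packaged_program_costs_reproduce_ledger_arithmetic():
    program = datasets.load_program_costs()
    coaching = program[Arm.INDIVIDUAL_COACHING]
    control = program[Arm.EDUCATION_CONTROL]
    assert coaching.phase2_per_participant == 555.31
    assert control.phase2_per_participant == 26.70
    assert coaching.total_per_participant == 880.43
    assert control.total_per_participant == 351.82
    assert coaching.total_per_participant - control.total_per_participant == pytest.approx(
        528.61
    )
    assert coaching.phase1_per_participant == control.phase1_per_participant == 325.12


def test_total_monthly_state_cost_from_packaged_table():
    econ = datasets.load_state_economics()
    assert total_monthly_state_cost(econ, WeightState.LOSS_LT5) == pytest.approx(102.34)
    assert total_monthly_state_cost(econ, WeightState.LOSS_5_10) == pytest.approx(74.40)
    assert total_monthly_state_cost(econ, WeightState.LOSS_GT10) == pytest.approx(79.01)
    assert total_monthly_state_cost(econ, WeightState.DEAD) == 0.0
    assert total_monthly_state_cost(uniform_econ(), WeightState.LOSS_LT5) == 0.0


def test_discount_factor_values():
    spec = DiscountSpec(annual_rate=0.03)
    assert discount_factor(spec, 0.0) == 1.0
    assert discount_factor(spec, 12.0) == pytest.approx(0.970874, abs=1e-6)
    assert discount_factor(spec, 60.0) == pytest.approx(0.862609, abs=1e-6)
    with pytest.raises(ValueError):
        discount_factor(DiscountSpec(time_zero_month=12.0), 6.0)


def test_accumulate_costs_program_only(fixture_base_case):
    """With state costs zeroed, the total is the program cost per participant."""
    program = datasets.load_program_costs()
    trace = fixture_base_case.traces[Arm.INDIVIDUAL_COACHING]
    total = accumulate_costs(
        trace,
        uniform_econ(),
        program[Arm.INDIVIDUAL_COACHING],
        DiscountSpec(),
        window=(10.0, 22.0),
    )
    assert total == 880.43
    total_control = accumulate_costs(
        trace,
        uniform_econ(),
        program[Arm.EDUCATION_CONTROL],
        DiscountSpec(),
        window=(10.0, 22.0),
    )
    assert total_control == 351.82


def test_undiscounted_constant_cost_is_plain_product():
    trace = constant_trace([1.0, 0.0, 0.0, 0.0])
    econ = uniform_econ(rx=44.97, other=57.37)  # 102.34/month in lt5
    total = accumulate_costs(
        trace, econ, None, DiscountSpec(annual_rate=0.0), window=(0.0, 12.0)
    )
    assert total == pytest.approx(12 * 102.34)  # 1228.08


def test_all_dead_occupancy_accrues_program_costs_only():
    trace = constant_trace([0.0, 0.0, 0.0, 1.0])
    econ = uniform_econ(rx=50.0, other=50.0)
    prog = ProgramCosts(1000.0, 500.0, 10)
    total = accumulate_costs(trace, econ, prog, DiscountSpec(), window=(0.0, 12.0))
    assert total == prog.total_per_participant == 150.0


def test_discounting_bounds_over_48_months():
    trace = constant_trace([1.0, 0.0, 0.0, 0.0], months=np.arange(0.0, 54.0, 6.0))
    econ = uniform_econ(rx=10.0)
    undiscounted = accumulate_costs(
        trace, econ, None, DiscountSpec(annual_rate=0.0), window=(0.0, 48.0)
    )
    discounted = accumulate_costs(
        trace, econ, None, DiscountSpec(annual_rate=0.03), window=(0.0, 48.0)
    )
    assert 1.03**-4 * undiscounted <= discounted <= undiscounted


def test_qaly_scale_anchor_and_state_scores():
    trace = constant_trace([1.0, 0.0, 0.0, 0.0])
    spec = DiscountSpec(annual_rate=0.0)
    assert accumulate_qalys(trace, uniform_econ(100.0), "htvas", spec, (0.0, 12.0)) == 1.0
    econ = datasets.load_state_economics()
    gt10 = constant_trace([0.0, 0.0, 1.0, 0.0])
    assert accumulate_qalys(gt10, econ, "htvas", spec, (0.0, 12.0)) == pytest.approx(
        0.8296
    )
    lt5 = constant_trace([1.0, 0.0, 0.0, 0.0])
    diff = accumulate_qalys(gt10, econ, "htvas", spec, (0.0, 12.0)) - accumulate_qalys(
        lt5, econ, "htvas", spec, (0.0, 12.0)
    )
    assert diff == pytest.approx((82.96 - 64.71) / 100.0)


def test_qalys_bounded_by_window_years(fixture_base_case):
    econ = datasets.load_state_economics()
    for trace in fixture_base_case.traces.values():
        qalys = accumulate_qalys(
            trace, econ, "sf36", DiscountSpec(annual_rate=0.0), (10.0, 70.0)
        )
        assert 0.0 < qalys <= 5.0


def test_dead_contributes_zero_qalys():
    trace = constant_trace([0.0, 0.0, 0.0, 1.0])
    assert (
        accumulate_qalys(
            trace, uniform_econ(100.0), "htvas", DiscountSpec(), (0.0, 12.0)
        )
        == 0.0
    )


def test_unknown_measure_rejected():
    trace = constant_trace([1.0, 0.0, 0.0, 0.0])
    with pytest.raises(ValueError, match="measure"):
        accumulate_qalys(trace, uniform_econ(), "eq5d", DiscountSpec(), (0.0, 12.0))


def test_window_outside_trace_rejected():
    trace = constant_trace([1.0, 0.0, 0.0, 0.0])
    with pytest.raises(ValueError, match="outside"):
        accumulate_costs(trace, uniform_econ(), None, DiscountSpec(), (0.0, 60.0))
    with pytest.raises(ValueError, match="stored"):
        accumulate_costs(trace, uniform_econ(), None, DiscountSpec(), (0.0, 9.0))


@given(st.floats(0.0, 1.0), st.floats(10.0, 90.0), st.floats(10.0, 90.0))
def test_accumulators_linear_in_occupancy_and_values(alpha, score_a, score_b):
    """Superposition: accumulation is linear in occupancy and state values."""
    occ_a = np.array([1.0, 0.0, 0.0, 0.0])
    occ_b = np.array([0.0, 1.0, 0.0, 0.0])
    blend = alpha * occ_a + (1 - alpha) * occ_b
    econ = StateEconomics(
        utilities={
            WeightState.LOSS_LT5: {"htvas": score_a, "sf36": score_a},
            WeightState.LOSS_5_10: {"htvas": score_b, "sf36": score_b},
            WeightState.LOSS_GT10: {"htvas": 90.0, "sf36": 90.0},
        },
        monthly_costs={s: {"rx": 10.0, "other": 5.0} for s in ALIVE_STATES},
    )
    spec = DiscountSpec()
    window = (0.0, 12.0)
    q = {
        key: accumulate_qalys(constant_trace(occ), econ, "htvas", spec, window)
        for key, occ in (("a", occ_a), ("b", occ_b), ("mix", blend))
    }
    assert q["mix"] == pytest.approx(alpha * q["a"] + (1 - alpha) * q["b"], abs=1e-9)


def test_half_cycle_correction_uses_midpoint_discounting():
    trace = constant_trace([1.0, 0.0, 0.0, 0.0])
    econ = uniform_econ(rx=100.0)
    spec = DiscountSpec(annual_rate=0.03)
    end = accumulate_costs(trace, econ, None, spec, (0.0, 12.0))
    mid = accumulate_costs(trace, econ, None, spec, (0.0, 12.0), half_cycle=True)
    assert mid > end  # midpoint discounting discounts less
    expected_mid = 600.0 * discount_factor(spec, 3.0) + 600.0 * discount_factor(spec, 9.0)
    assert mid == pytest.approx(expected_mid)
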