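"""Categorization, empirical estimation, probability conversion, mortality."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from leapcea.states import ALIVE_STATES, Arm, WeightState
from leapcea.transitions import (
    TransitionMatrix,
    apply_mortality,
    calibrate_matrix,
    categorize,
    estimate_matrix,
    rescale_probability,
    to_annual,
)

from conftest import random_stochastic_matrix


class FakeRecord:
    """Minimal record stub: estimation only needs the weight map."""

    def __init__(self, baseline, w16, w22, w4=None):
        self.weight_kg_by_month = {0: baseline, 16: w16, 22: w22}
        if w4 is not None:
            self.weight_kg_by_month[4] = w4


def weight_for_loss(baseline, loss):
    return baseline * (1.0 - loss)


@pytest.mark.parametrize(
    "baseline, current, expected",
    [
        (99.8, 99.8, WeightState.LOSS_LT5),  # zero change
        (100.0, 104.0, WeightState.LOSS_LT5),  # weight gain counts as no loss
        (100.0, 95.01, WeightState.LOSS_LT5),
        (100.0, 95.0, WeightState.LOSS_5_10),  # 5% boundary goes to moderate
        (100.0, 90.0, WeightState.LOSS_5_10),  # 10% boundary goes to moderate
        (100.0, 89.9, WeightState.LOSS_GT10),  # 10.1% loss
    ],
)
def test_categorize_boundaries(baseline, current, expected):
    assert categorize(baseline, current) == expected


@pytest.mark.parametrize("baseline, current", [(0.0, 90.0), (100.0, 0.0), (-1.0, 90.0)])
def test_categorize_rejects_nonpositive_weights(baseline, current):
    with pytest.raises(ValueError):
        categorize(baseline, current)


def test_matrix_rejects_nonstochastic_rows():
    probs = np.eye(4)
    probs[0, 0] = 0.9
    with pytest.raises(ValueError, match="sum"):
        TransitionMatrix(probs, 6.0)


def test_matrix_requires_absorbing_dead_row():
    probs = np.eye(4)
    probs[3] = [0.1, 0.0, 0.0, 0.9]
    with pytest.raises(ValueError, match="DEAD"):
        TransitionMatrix(probs, 6.0)


def test_estimated_regain_probability_matches_observed_proportion():
    """9 of 35 large-loss participants regaining to moderate gives 0.2571."""
    records = []
    for i in range(35):
        loss22 = 0.07 if i < 9 else 0.15  # 9 regain to moderate, 26 stay large
        records.append(
            FakeRecord(100.0, weight_for_loss(100.0, 0.12), weight_for_loss(100.0, loss22))
        )
    # pad the other origin states so no self-loop rows are needed
    records.append(FakeRecord(100.0, 100.0, 100.0))
    records.append(FakeRecord(100.0, weight_for_loss(100.0, 0.07), 100.0))
    matrix = estimate_matrix(records, 16, 22)
    assert matrix.entry(WeightState.LOSS_GT10, WeightState.LOSS_5_10) == pytest.approx(
        0.2571, abs=5e-5
    )
    assert matrix.entry(WeightState.LOSS_GT10, WeightState.LOSS_GT10) == pytest.approx(
        26 / 35
    )
    assert matrix.interval_months == 6.0


def test_estimate_identity_when_no_one_moves():
    records = [
        FakeRecord(100.0, weight_for_loss(100.0, loss), weight_for_loss(100.0, loss))
        for loss in (0.0, 0.07, 0.15)
    ]
    matrix = estimate_matrix(records, 16, 22)
    assert np.array_equal(matrix.probs, np.eye(4))


def test_estimate_empty_origin_state_gets_self_loop_with_warning():
    records = [FakeRecord(100.0, 100.0, weight_for_loss(100.0, 0.07))]
    with pytest.warns(UserWarning, match="self-loop"):
        matrix = estimate_matrix(records, 16, 22)
    assert matrix.entry(WeightState.LOSS_GT10, WeightState.LOSS_GT10) == 1.0
    assert matrix.entry(WeightState.LOSS_LT5, WeightState.LOSS_5_10) == 1.0


def test_estimate_requires_usable_records():
    with pytest.raises(ValueError, match="no records"):
        estimate_matrix([], 16, 22)


def test_estimate_invariant_to_order_and_duplication():
    rng = np.random.default_rng(5)
    records = [
        FakeRecord(
            100.0,
            weight_for_loss(100.0, rng.uniform(0, 0.2)),
            weight_for_loss(100.0, rng.uniform(0, 0.2)),
        )
        for _ in range(50)
    ]
    base = estimate_matrix(records, 16, 22)
    shuffled = list(records)
    rng.shuffle(shuffled)
    assert estimate_matrix(shuffled, 16, 22) == base
    assert estimate_matrix(records * 3, 16, 22) == base


def test_to_annual_identity_and_hand_product():
    identity = TransitionMatrix(np.eye(4), 6.0)
    assert np.array_equal(to_annual(identity).probs, np.eye(4))
    probs = np.eye(4)
    probs[0] = [0.9, 0.0, 0.0, 0.1]
    annual = to_annual(TransitionMatrix(probs, 6.0))
    assert annual.interval_months == 12.0
    assert annual.entry(WeightState.LOSS_LT5, WeightState.LOSS_LT5) == pytest.approx(0.81)
    assert annual.entry(WeightState.LOSS_LT5, WeightState.DEAD) == pytest.approx(0.19)


@given(st.integers(0, 10_000))
def test_to_annual_matches_two_step_path_enumeration(seed):
    """Squaring equals brute-force enumeration of all intermediate states."""
    matrix = random_stochastic_matrix(np.random.default_rng(seed))
    annual = to_annual(matrix)
    brute = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            brute[i, j] = sum(matrix.probs[i, k] * matrix.probs[k, j] for k in range(4))
    assert np.allclose(annual.probs, brute, atol=1e-12)
    assert np.allclose(annual.probs.sum(axis=1), 1.0, atol=1e-9)


def test_rescale_probability_examples():
    assert rescale_probability(0.0, 1.0, 5.0) == 0.0
    annual = rescale_probability(0.043, 5.0, 1.0)
    assert annual == pytest.approx(0.00875, abs=5e-5)
    assert 1.0 - (1.0 - annual) ** 5 == pytest.approx(0.043)
    half_year = rescale_probability(0.19, 1.0, 0.5)
    assert half_year == pytest.approx(0.1)
    assert 1.0 - (1.0 - 0.1) ** 2 == pytest.approx(0.19)


@given(st.floats(0.0, 0.999), st.floats(0.1, 10.0), st.floats(0.1, 10.0))
def test_rescale_probability_stays_in_unit_interval(p, a, b):
    q = rescale_probability(p, a, b)
    assert 0.0 <= q <= 1.0
    assert rescale_probability(q, b, a) == pytest.approx(p, abs=1e-9)


def test_apply_mortality_extremes_and_hand_value():
    identity = TransitionMatrix(np.eye(4), 6.0)
    assert apply_mortality(identity, 0.0) == identity
    all_dead = apply_mortality(identity, 1.0)
    for state in ALIVE_STATES:
        assert all_dead.entry(state, WeightState.DEAD) == 1.0
    adjusted = apply_mortality(identity, 0.00438)
    for state in ALIVE_STATES:
        assert adjusted.entry(state, state) == pytest.approx(0.99562)
        assert adjusted.entry(state, WeightState.DEAD) == pytest.approx(0.00438)


@given(st.integers(0, 10_000), st.floats(0.0, 0.999))
def test_apply_mortality_preserves_alive_conditional_rows(seed, q):
    """Conditioning the adjusted matrix on survival recovers the original."""
    matrix = random_stochastic_matrix(np.random.default_rng(seed))
    adjusted = apply_mortality(matrix, q)
    assert np.allclose(adjusted.probs.sum(axis=1), 1.0, atol=1e-9)
    alive = adjusted.probs[:3, :3]
    survival = alive.sum(axis=1, keepdims=True)
    original_alive = matrix.probs[:3, :3]
    original_survival = original_alive.sum(axis=1, keepdims=True)
    assert np.allclose(alive / survival, original_alive / original_survival, atol=1e-9)


@pytest.mark.parametrize("arm", list(Arm))
def test_calibrated_matrix_reproduces_margins_and_pinned_entry(arm):
    from leapcea import datasets

    targets = datasets.load_occupancy_targets()
    matrix = datasets.default_transition_matrix(arm)
    occ16 = targets[(arm, 16)][:3]
    occ22 = targets[(arm, 22)][:3]
    assert np.allclose(occ16 @ matrix.probs[:3, :3], occ22, atol=1e-6)
    assert matrix.entry(WeightState.LOSS_GT10, WeightState.LOSS_5_10) == pytest.approx(
        datasets.PUBLISHED_GT10_TO_MODERATE[arm], abs=1e-6
    )


def test_calibrate_matrix_rejects_bad_inputs():
    with pytest.raises(ValueError, match="probability vector"):
        calibrate_matrix([0.5, 0.5, 0.5], [0.3, 0.3, 0.4])


def test_transitions_csv_round_trip(tmp_path):
    from leapcea.transitions import read_transitions, write_transitions

    rng = np.random.default_rng(3)
    matrices = {
        Arm.EDUCATION_CONTROL: {
            (0, 4): random_stochastic_matrix(rng, 4.0),
            (16, 22): random_stochastic_matrix(rng, 6.0),
        }
    }
    path = tmp_path / "transitions.csv"
    write_transitions(path, matrices)
    back = read_transitions(path)
    for key, matrix in matrices[Arm.EDUCATION_CONTROL].items():
        assert np.allclose(
            back[Arm.EDUCATION_CONTROL][key].probs, matrix.probs, atol=1e-12
        )
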