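"""Weight-change categorization and transition-probability machinery.

Transition probabilities between weight-loss states are estimated empirically
as row-wise proportions of observed moves between assessment months.  A
matrix estimated over one interval can be composed to longer intervals
(``to_annual``) or rescaled under a constant-hazard assumption
(``rescale_probability``), and background mortality is layered on as a
multiplicative competing risk (``apply_mortality``).

Category boundaries follow the trial's convention: percent loss below 5%
(including weight gain) is limited/no loss, 5-10% inclusive is moderate loss,
and strictly more than 10% is large loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from .states import ALIVE_STATES, N_STATES, Arm, WeightState

_ROW_TOL = 1e-9

#: Row of the transition matrix for the absorbing state.
_DEAD_ROW = np.array([0.0, 0.0, 0.0, 1.0])


def categorize(baseline_kg: float, current_kg: float) -> WeightState:
    """Classify percent weight loss ``(baseline - current) / baseline``.

    Ties at the printed 5% and 10% category endpoints go to the moderate bin.
    """
    if baseline_kg <= 0 or current_kg <= 0:
        raise ValueError(
            f"weights must be positive, got baseline={baseline_kg}, "
            f"current={current_kg}"
        )
    loss = (baseline_kg - current_kg) / baseline_kg
    if loss < 0.05:
        return WeightState.LOSS_LT5
    if loss <= 0.10:
        return WeightState.LOSS_5_10
    return WeightState.LOSS_GT10


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 4x4 matrix over the weight states spanning an interval.

    Rows index the origin state, columns the destination.  The DEAD row is
    required to be exactly absorbing.
    """

    probs: np.ndarray
    interval_months: float

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.shape != (N_STATES, N_STATES):
            raise ValueError(f"expected a 4x4 matrix, got shape {probs.shape}")
        if self.interval_months <= 0:
            raise ValueError("interval_months must be positive")
        if np.any(probs < -_ROW_TOL) or np.any(probs > 1 + _ROW_TOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        row_sums = probs.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=_ROW_TOL, rtol=0.0):
            raise ValueError(f"rows must sum to 1, got sums {row_sums}")
        if not np.array_equal(probs[WeightState.DEAD], _DEAD_ROW):
            raise ValueError("DEAD row must be exactly (0, 0, 0, 1)")
        probs.setflags(write=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TransitionMatrix):
            return NotImplemented
        return (
            self.interval_months == other.interval_months
            and np.array_equal(self.probs, other.probs)
        )

    def entry(self, origin: WeightState, destination: WeightState) -> float:
        return float(self.probs[origin, destination])


@dataclass(frozen=True)
class TransitionSchedule:
    """Observed transition segments plus the post-observation extrapolation.

    ``segments`` are contiguous ``(start_month, end_month, matrix)`` blocks
    starting at month 0; ``extrapolation`` (one model cycle long) is applied
    for every cycle past the last segment.
    """

    segments: tuple
    extrapolation: TransitionMatrix

    def __post_init__(self) -> None:
        segments = tuple(self.segments)
        object.__setattr__(self, "segments", segments)
        if not segments:
            raise ValueError("schedule needs at least one segment")
        expected_start = 0.0
        for start, end, matrix in segments:
            if start != expected_start:
                raise ValueError(
                    f"segments must be contiguous from month 0; got a segment "
                    f"starting at {start}, expected {expected_start}"
                )
            if end <= start:
                raise ValueError("segment end must exceed its start")
            if matrix.interval_months != end - start:
                raise ValueError(
                    f"segment [{start}, {end}] matrix spans "
                    f"{matrix.interval_months} months"
                )
            expected_start = end

    @property
    def last_observed_month(self) -> float:
        return self.segments[-1][1]


def estimate_matrix(records: Iterable, from_month: int, to_month: int) -> TransitionMatrix:
    """Empirical transition matrix between two assessment months.

    Entry (i, j) is the proportion of participants in state i at
    ``from_month`` observed in state j at ``to_month``; the DEAD row is forced
    absorbing.  Origin states with no observed participants get a self-loop
    row (with a warning) so the matrix stays stochastic.
    """
    if to_month <= from_month:
        raise ValueError("to_month must exceed from_month")
    counts = np.zeros((N_STATES, N_STATES))
    for rec in records:
        weights: Mapping[int, float] = rec.weight_kg_by_month
        baseline = weights.get(0)
        w_from = weights.get(from_month)
        w_to = weights.get(to_month)
        if baseline is None or w_from is None or w_to is None:
            continue
        counts[categorize(baseline, w_from), categorize(baseline, w_to)] += 1
    if counts.sum() == 0:
        raise ValueError(
            f"no records with weights at months 0, {from_month} and {to_month}"
        )
    probs = np.zeros((N_STATES, N_STATES))
    for state in ALIVE_STATES:
        n_origin = counts[state].sum()
        if n_origin == 0:
            warnings.warn(
                f"no participants observed in state {state.label} at month "
                f"{from_month}; using a self-loop row",
                stacklevel=2,
            )
            probs[state, state] = 1.0
        else:
            probs[state] = counts[state] / n_origin
    probs[WeightState.DEAD] = _DEAD_ROW
    return TransitionMatrix(probs, float(to_month - from_month))


def to_annual(matrix: TransitionMatrix) -> TransitionMatrix:
    """Compose a 6-month matrix with itself to span a year."""
    squared = matrix.probs @ matrix.probs
    squared[WeightState.DEAD] = _DEAD_ROW
    squared /= squared.sum(axis=1, keepdims=True)
    return TransitionMatrix(squared, matrix.interval_months * 2)


def rescale_probability(p: float, from_years: float, to_years: float) -> float:
    """Convert a transition probability across horizons at constant hazard.

    ``1 - (1 - p) ** (to_years / from_years)``; e.g. an annual death
    probability becomes the matching 6-month cycle probability with
    ``to_years = 0.5``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p}")
    if from_years <= 0 or to_years <= 0:
        raise ValueError("horizons must be positive")
    if p == 1.0:
        return 1.0
    return 1.0 - (1.0 - p) ** (to_years / from_years)


def apply_mortality(matrix: TransitionMatrix, cycle_death_prob: float) -> TransitionMatrix:
    """Layer a per-cycle death probability onto alive rows as a competing risk.

    Alive-destination mass in each alive row is scaled by
    ``1 - cycle_death_prob`` and the remainder goes to DEAD, so conditioning
    on survival recovers the original alive rows.
    """
    if not 0.0 <= cycle_death_prob <= 1.0:
        raise ValueError("cycle_death_prob must be in [0, 1]")
    probs = matrix.probs.copy()
    alive = list(ALIVE_STATES)
    probs[np.ix_(alive, alive)] *= 1.0 - cycle_death_prob
    probs[alive, WeightState.DEAD] = 1.0 - probs[np.ix_(alive, alive)].sum(axis=1)
    probs[WeightState.DEAD] = _DEAD_ROW
    return TransitionMatrix(probs, matrix.interval_months)


def calibrate_matrix(
    occ_from,
    occ_to,
    fixed: Mapping[tuple, float] | None = None,
    interval_months: float = 6.0,
) -> TransitionMatrix:
    """Minimum-movement alive-state matrix carrying one occupancy to another.

    The marginal constraint ``occ_from @ P = occ_to`` (plus any pinned
    entries, e.g. a published transition probability) leaves the 3x3 alive
    block underdetermined; this picks the feasible row-stochastic matrix
    closest to the identity in Frobenius norm — the least amount of state
    switching consistent with the observed margins.

    ``occ_from`` / ``occ_to`` are length-3 probability vectors over the alive
    states; ``fixed`` maps ``(origin, destination)`` alive-state pairs to
    pinned probabilities.
    """
    occ_from = np.asarray(occ_from, dtype=float)
    occ_to = np.asarray(occ_to, dtype=float)
    if occ_from.shape != (3,) or occ_to.shape != (3,):
        raise ValueError("occupancies must be length-3 vectors over alive states")
    for name, vec in (("occ_from", occ_from), ("occ_to", occ_to)):
        if abs(vec.sum() - 1.0) > 1e-6 or np.any(vec < 0):
            raise ValueError(f"{name} must be a probability vector, got {vec}")

    bounds = [(0.0, 1.0)] * 9
    for (i, j), value in (fixed or {}).items():
        if i not in ALIVE_STATES or j not in ALIVE_STATES:
            raise ValueError("fixed entries must be between alive states")
        bounds[int(i) * 3 + int(j)] = (value, value)

    def unpack(x):
        return x.reshape(3, 3)

    constraints = [
        {"type": "eq", "fun": lambda x: unpack(x).sum(axis=1) - 1.0},
        # two columns pin the marginal; the third is implied by row sums
        {"type": "eq", "fun": lambda x: occ_from @ unpack(x)[:, :2] - occ_to[:2]},
    ]
    x0 = np.eye(3).ravel()
    for idx, (lo, hi) in enumerate(bounds):
        x0[idx] = np.clip(x0[idx], lo, hi)
    result = optimize.minimize(
        lambda x: np.sum((unpack(x) - np.eye(3)) ** 2),
        x0,
        jac=lambda x: 2.0 * (x - np.eye(3).ravel()),
        bounds=bounds,
        constraints=constraints,
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    block = unpack(result.x)
    block = np.clip(block, 0.0, 1.0)
    block /= block.sum(axis=1, keepdims=True)
    residual = np.abs(occ_from @ block - occ_to).max()
    if residual > 1e-6:
        raise RuntimeError(
            f"calibration failed: marginal residual {residual:.2e} "
            f"(occ_from={occ_from}, occ_to={occ_to}, fixed={fixed})"
        )
    probs = np.zeros((N_STATES, N_STATES))
    probs[:3, :3] = block
    probs[WeightState.DEAD] = _DEAD_ROW
    return TransitionMatrix(probs, interval_months)


# ---------------------------------------------------------------------------
# serialization (long-format CSV: arm, from_month, to_month, from/to state)

def write_transitions(path, matrices: Mapping) -> None:
    """Write ``{arm: {(from_month, to_month): TransitionMatrix}}`` as long CSV."""
    rows = []
    for arm, by_interval in matrices.items():
        arm = Arm.parse(arm)
        for (from_month, to_month), matrix in by_interval.items():
            for i in WeightState:
                for j in WeightState:
                    rows.append(
                        {
                            "arm": arm.value,
                            "from_month": from_month,
                            "to_month": to_month,
                            "from_state": i.label,
                            "to_state": j.label,
                            "probability": matrix.entry(i, j),
                        }
                    )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_transitions(path) -> dict:
    """Inverse of :func:`write_transitions`."""
    frame = pd.read_csv(path)
    out: dict = {}
    grouped = frame.groupby(["arm", "from_month", "to_month"], sort=False)
    for (arm, from_month, to_month), group in grouped:
        probs = np.zeros((N_STATES, N_STATES))
        for row in group.itertuples():
            probs[
                WeightState.from_label(row.from_state),
                WeightState.from_label(row.to_state),
            ] = row.probability
        out.setdefault(Arm.parse(arm), {})[(from_month, to_month)] = TransitionMatrix(
            probs, float(to_month - from_month)
        )
    return out
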