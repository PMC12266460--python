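"""Synthetic participant-level trial data with the structure the model assumes.

The generator emulates a two-arm weight-maintenance trial: baseline weight and
age drawn from the trial's reported moments, weight-loss categories at the
month-16 and month-22 assessments drawn so that empirical occupancies match
the observed trial marginals, survey scores drawn from truncated normals with
state-conditional means, and zero-inflated right-skewed monthly out-of-pocket
costs with state-conditional means.  Month-16 and month-22 categories are
coupled through the same transition matrices the estimation module recovers,
so generator and estimator are mutually consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import datasets
from .states import ALIVE_STATES, Arm, Sex, WeightState
from .transitions import TransitionMatrix, categorize

ASSESSMENT_MONTHS = (0, 4, 16, 22)
SCORE_MONTHS = (0, 16, 22)

#: Percent-loss interval (lo, hi) sampled uniformly within each category.
#: The open >10% category is truncated at 25% loss; a tiny interior margin
#: keeps the category recoverable from the back-computed weights despite
#: floating-point round-trip error.
_CATEGORY_LOSS_BOUNDS = {
    WeightState.LOSS_LT5: (-0.05, 0.05 - 1e-9),
    WeightState.LOSS_5_10: (0.05 + 1e-9, 0.10 - 1e-9),
    WeightState.LOSS_GT10: (0.10 + 1e-9, 0.25),
}

CSV_COLUMNS = [
    "participant_id",
    "arm",
    "sex",
    "age_years",
    "weight_m0",
    "weight_m4",
    "weight_m16",
    "weight_m22",
    "htvas_m0",
    "htvas_m16",
    "htvas_m22",
    "sf36_m0",
    "sf36_m16",
    "sf36_m22",
    "rx_cost_monthly",
    "other_cost_monthly",
]


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant's longitudinal weights, scores, costs and assignment."""

    participant_id: str
    arm: Arm
    sex: Sex
    age_years: float
    weight_kg_by_month: dict  # month -> kg
    htvas_by_month: dict  # month -> score or None
    sf36gh_by_month: dict
    rx_cost_monthly_usd: float | None
    other_cost_monthly_usd: float | None

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise ValueError(f"{self.participant_id}: age must be positive")
        baseline = self.weight_kg_by_month.get(0)
        if baseline is None or baseline <= 0:
            raise ValueError(
                f"{self.participant_id}: baseline (month 0) weight must be "
                f"present and positive"
            )
        for month, weight in self.weight_kg_by_month.items():
            if weight is not None and weight <= 0:
                raise ValueError(
                    f"{self.participant_id}: weight at month {month} must be positive"
                )
        for name, scores in (
            ("htvas", self.htvas_by_month),
            ("sf36", self.sf36gh_by_month),
        ):
            for month, score in scores.items():
                if score is not None and not 0.0 <= score <= 100.0:
                    raise ValueError(
                        f"{self.participant_id}: {name} at month {month} must be "
                        f"in [0, 100], got {score}"
                    )
        for name, cost in (
            ("rx_cost_monthly_usd", self.rx_cost_monthly_usd),
            ("other_cost_monthly_usd", self.other_cost_monthly_usd),
        ):
            if cost is not None and cost < 0:
                raise ValueError(
                    f"{self.participant_id}: {name} must be >= 0, got {cost}"
                )

    def state_at(self, month: int) -> WeightState:
        return categorize(self.weight_kg_by_month[0], self.weight_kg_by_month[month])


def _default_n_per_arm() -> dict:
    return {Arm.EDUCATION_CONTROL: 153, Arm.INDIVIDUAL_COACHING: 149}


def _default_targets() -> dict:
    return {
        key: value[:3].copy() for key, value in datasets.load_occupancy_targets().items()
    }


def _default_utility_means() -> dict:
    econ = datasets.load_state_economics()
    return {s: (econ.utilities[s]["htvas"], econ.utilities[s]["sf36"]) for s in ALIVE_STATES}


def _default_cost_means() -> dict:
    econ = datasets.load_state_economics()
    return {
        s: (econ.monthly_costs[s]["rx"], econ.monthly_costs[s]["other"])
        for s in ALIVE_STATES
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort; defaults are the trial's moments.

    ``month4_occupancy`` (end of the active weight-loss phase, identical for
    both arms since phase 1 was a single shared program) was not reported and
    defaults to a plausible (0.30, 0.30, 0.40) split; it feeds only the trace,
    not the economic windows.
    """

    n_per_arm: dict = field(default_factory=_default_n_per_arm)
    seed: int = 0
    baseline_weight_mean_kg: float = 99.8
    baseline_weight_sd_kg: float = 14.6
    age_mean: float = 55.4
    age_sd: float = 10.3
    female_fraction: float = 0.827
    target_occupancy: dict = field(default_factory=_default_targets)
    month4_occupancy: tuple = (0.30, 0.30, 0.40)
    transition_matrices: dict | None = None  # arm -> month-16->22 TransitionMatrix
    utility_means: dict = field(default_factory=_default_utility_means)
    utility_sd: float = 15.0
    cost_means: dict = field(default_factory=_default_cost_means)
    cost_zero_prob: float = 0.2
    cost_cv: float = 1.0
    missing_rate: float = 0.05

    def __post_init__(self) -> None:
        self.n_per_arm = {Arm.parse(arm): n for arm, n in self.n_per_arm.items()}
        for arm, n in self.n_per_arm.items():
            if n <= 0:
                raise ValueError(f"n_per_arm[{arm}] must be positive, got {n}")
        self.target_occupancy = {
            (Arm.parse(arm), int(month)): vec
            for (arm, month), vec in self.target_occupancy.items()
        }
        for key, vec in self.target_occupancy.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (3,) or np.any(vec < 0):
                raise ValueError(f"target occupancy {key} must be 3 non-negative probs")
            if abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"target occupancy {key} must sum to 1, got {vec.sum()!r}"
                )
            self.target_occupancy[key] = vec
        m4 = np.asarray(self.month4_occupancy, dtype=float)
        if abs(m4.sum() - 1.0) > 1e-9 or np.any(m4 < 0):
            raise ValueError("month4_occupancy must be a probability vector")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        if not 0.0 <= self.cost_zero_prob < 1.0:
            raise ValueError("cost_zero_prob must be in [0, 1)")
        if self.cost_cv < 0:
            raise ValueError("cost_cv must be non-negative")
        if self.utility_sd < 0:
            raise ValueError("utility_sd must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        htvas = [self.utility_means[s][0] for s in ALIVE_STATES]
        sf36 = [self.utility_means[s][1] for s in ALIVE_STATES]
        if not (np.all(np.diff(htvas) > 0) and np.all(np.diff(sf36) > 0)):
            raise ValueError(
                "utility means must increase strictly with weight-loss category"
            )

    def matrix_for(self, arm: Arm) -> TransitionMatrix:
        if self.transition_matrices is not None and arm in self.transition_matrices:
            return self.transition_matrices[arm]
        return datasets.default_transition_matrix(arm)


def _truncated_normal(rng, mean, sd, lower, upper, size):
    """Vectorized truncated-normal draws; sd 0 degenerates to the mean."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    if sd == 0:
        return mean.copy()
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_costs(rng, means, zero_prob: float, cv: float):
    """Zero-inflated draws whose mixture mean equals the state mean.

    The positive part has mean ``mean / (1 - zero_prob)`` and coefficient of
    variation ``cv`` (gamma-shaped; cv 0 degenerates to a point mass).
    """
    means = np.asarray(means, dtype=float)
    positive_mean = np.where(means > 0, means / (1.0 - zero_prob), 0.0)
    if cv == 0:
        values = positive_mean.copy()
    else:
        shape = 1.0 / cv**2
        values = rng.gamma(shape, positive_mean / shape)
    if zero_prob > 0:
        values[rng.random(means.size) < zero_prob] = 0.0
    values[means == 0] = 0.0
    return values


def _draw_losses(rng, states):
    """Uniform percent loss within each drawn category's interval."""
    bounds = np.array([_CATEGORY_LOSS_BOUNDS[s] for s in ALIVE_STATES])
    lo, hi = bounds[states, 0], bounds[states, 1]
    return lo + rng.random(states.size) * (hi - lo)


def _sample_states(rng, probs, n: int):
    """Categorical draws; ``probs`` is either a vector or one row per draw."""
    probs = np.asarray(probs, dtype=float)
    if probs.ndim == 1:
        probs = np.broadcast_to(probs, (n, 3))
    cum = np.cumsum(probs / probs.sum(axis=1, keepdims=True), axis=1)
    return (rng.random(n)[:, None] >= cum).sum(axis=1)


def generate_cohort(config: GeneratorConfig) -> list:
    """Draw a full two-arm cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    records = []
    counter = 0
    m4 = np.asarray(config.month4_occupancy, dtype=float)
    for arm in sorted(config.n_per_arm, key=lambda a: Arm.parse(a).value):
        arm = Arm.parse(arm)
        n = config.n_per_arm[arm]
        occ16 = config.target_occupancy[(arm, 16)]
        matrix = config.matrix_for(arm)

        female = rng.random(n) < config.female_fraction
        age = _truncated_normal(rng, config.age_mean, config.age_sd, 18.0, 100.0, n)
        baseline = _truncated_normal(
            rng,
            config.baseline_weight_mean_kg,
            config.baseline_weight_sd_kg,
            40.0,
            200.0,
            n,
        )
        states = {
            4: _sample_states(rng, m4, n),
            16: _sample_states(rng, occ16, n),
        }
        states[22] = _sample_states(rng, matrix.probs[states[16], :3], n)
        states[0] = np.zeros(n, dtype=int)  # everyone at baseline weight
        weights = {0: baseline}
        for month in (4, 16, 22):
            weights[month] = baseline * (1.0 - _draw_losses(rng, states[month]))

        util_means = np.array([config.utility_means[s] for s in ALIVE_STATES])
        scores = {}
        for month in SCORE_MONTHS:
            for col, name in enumerate(("htvas", "sf36")):
                values = _truncated_normal(
                    rng, util_means[states[month], col], config.utility_sd,
                    0.0, 100.0, n,
                )
                missing = rng.random(n) < config.missing_rate
                scores[(name, month)] = (values, missing)

        cost_means = np.array([config.cost_means[s] for s in ALIVE_STATES])
        cost_values, cost_missing = {}, {}
        for col, name in enumerate(("rx", "other")):
            cost_values[name] = _draw_costs(
                rng, cost_means[states[16], col], config.cost_zero_prob, config.cost_cv
            )
            cost_missing[name] = rng.random(n) < config.missing_rate

        for i in range(n):
            counter += 1
            records.append(
                ParticipantRecord(
                    participant_id=f"P{counter:04d}",
                    arm=arm,
                    sex=Sex.FEMALE if female[i] else Sex.MALE,
                    age_years=float(age[i]),
                    weight_kg_by_month={
                        month: float(weights[month][i]) for month in ASSESSMENT_MONTHS
                    },
                    htvas_by_month={
                        month: None
                        if scores[("htvas", month)][1][i]
                        else float(scores[("htvas", month)][0][i])
                        for month in SCORE_MONTHS
                    },
                    sf36gh_by_month={
                        month: None
                        if scores[("sf36", month)][1][i]
                        else float(scores[("sf36", month)][0][i])
                        for month in SCORE_MONTHS
                    },
                    rx_cost_monthly_usd=None
                    if cost_missing["rx"][i]
                    else float(cost_values["rx"][i]),
                    other_cost_monthly_usd=None
                    if cost_missing["other"][i]
                    else float(cost_values["other"][i]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# CSV round-trip

def _to_cell(value):
    return "" if value is None else repr(float(value))


def write_cohort(records, path) -> None:
    """Lossless CSV dump; missing values become empty fields."""
    rows = []
    for rec in records:
        row = {
            "participant_id": rec.participant_id,
            "arm": rec.arm.value,
            "sex": rec.sex.value,
            "age_years": repr(float(rec.age_years)),
        }
        for month in ASSESSMENT_MONTHS:
            row[f"weight_m{month}"] = _to_cell(rec.weight_kg_by_month.get(month))
        for month in SCORE_MONTHS:
            row[f"htvas_m{month}"] = _to_cell(rec.htvas_by_month.get(month))
            row[f"sf36_m{month}"] = _to_cell(rec.sf36gh_by_month.get(month))
        row["rx_cost_monthly"] = _to_cell(rec.rx_cost_monthly_usd)
        row["other_cost_monthly"] = _to_cell(rec.other_cost_monthly_usd)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    frame.to_csv(path, index=False)


def _parse_cell(raw, row_idx: int, column: str, lower=None, upper=None):
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return None
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ValueError(
            f"row {row_idx}, column {column!r}: cannot parse {raw!r} as a number"
        ) from None
    if lower is not None and value < lower:
        raise ValueError(
            f"row {row_idx}, column {column!r}: value {value} below bound {lower}"
        )
    if upper is not None and value > upper:
        raise ValueError(
            f"row {row_idx}, column {column!r}: value {value} above bound "
            f"{upper} (scores must lie in [0, 100])"
        )
    return value


def read_cohort(path) -> list:
    """Read and validate a cohort CSV written by :func:`write_cohort`."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(CSV_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise ValueError(f"cohort file missing columns: {sorted(missing_cols)}")
    records = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        row = row._asdict()
        weights = {}
        for month in ASSESSMENT_MONTHS:
            value = _parse_cell(row[f"weight_m{month}"], idx, f"weight_m{month}")
            if value is not None:
                weights[month] = value
        htvas, sf36 = {}, {}
        for month in SCORE_MONTHS:
            htvas[month] = _parse_cell(
                row[f"htvas_m{month}"], idx, f"htvas_m{month}", 0.0, 100.0
            )
            sf36[month] = _parse_cell(
                row[f"sf36_m{month}"], idx, f"sf36_m{month}", 0.0, 100.0
            )
        try:
            records.append(
                ParticipantRecord(
                    participant_id=row["participant_id"],
                    arm=Arm.parse(row["arm"]),
                    sex=Sex(row["sex"]),
                    age_years=_parse_cell(row["age_years"], idx, "age_years") or 0.0,
                    weight_kg_by_month=weights,
                    htvas_by_month=htvas,
                    sf36gh_by_month=sf36,
                    rx_cost_monthly_usd=_parse_cell(
                        row["rx_cost_monthly"], idx, "rx_cost_monthly", 0.0
                    ),
                    other_cost_monthly_usd=_parse_cell(
                        row["other_cost_monthly"], idx, "other_cost_monthly", 0.0
                    ),
                )
            )
        except ValueError as err:
            raise ValueError(f"row {idx}: {err}") from err
    return records
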