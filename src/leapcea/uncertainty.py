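"""Probabilistic and one-way sensitivity analysis.

The PSA resamples the economic parameters — state-conditional utility means
from normals truncated to the 0-100 score range, and state-conditional
monthly out-of-pocket costs from zero-inflated gamma mixtures — and reruns
the accumulation and ICER stages per replication.  Sampled values are shared
by both arms within a replication, so incremental differences are driven by
state occupancy, not by independent parameter noise.  Transition
probabilities are held fixed by default.

The OWSA reruns the deterministic pipeline with one parameter moved at a
time (program costs and monthly cost components by +/-20%, the discount rate
to 1% and 5%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cea import decide, icer
from .economics import MEASURES, DiscountSpec, StateEconomics, round_cents
from .pipeline import BaseCase
from .states import ALIVE_STATES, Arm, WeightState

# ---------------------------------------------------------------------------
# parameter distributions


@dataclass(frozen=True)
class TruncNormalSpec:
    """Normal truncated to [lower, upper]; sd 0 degenerates to a point mass."""

    mean: float
    sd: float
    lower: float = 0.0
    upper: float = 100.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.upper <= self.lower:
            raise ValueError("upper must exceed lower")

    def rvs(self, rng) -> float:
        if self.sd == 0:
            return float(self.mean)
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return float(
            stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, random_state=rng)
        )


@dataclass(frozen=True)
class ZeroInflatedGammaSpec:
    """Point mass at zero with probability ``p_zero``, else gamma(shape, scale).

    The mixture mean is ``(1 - p_zero) * shape * scale``.  A degenerate
    positive part (zero spread, e.g. from fitting identical positives or a
    zero coefficient of variation) is represented exactly by ``point_mass``,
    in which case shape/scale are ignored and the mean is
    ``(1 - p_zero) * point_mass``.
    """

    p_zero: float
    shape: float
    scale: float
    point_mass: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_zero <= 1.0:
            raise ValueError("p_zero must be in [0, 1]")
        if self.point_mass is not None:
            if self.point_mass < 0:
                raise ValueError("point_mass must be non-negative")
        elif self.p_zero < 1.0 and (self.shape <= 0 or self.scale < 0):
            raise ValueError("shape must be positive and scale non-negative")

    @property
    def degenerate(self) -> bool:
        return self.point_mass is not None

    @property
    def mean(self) -> float:
        if self.p_zero == 1.0:
            return 0.0
        if self.point_mass is not None:
            return (1.0 - self.p_zero) * self.point_mass
        return (1.0 - self.p_zero) * self.shape * self.scale

    @classmethod
    def from_mean_cv(cls, mean: float, p_zero: float, cv: float) -> "ZeroInflatedGammaSpec":
        """Parameterize from the mixture mean and the positive part's CV."""
        if mean == 0:
            return cls(p_zero=1.0, shape=1.0, scale=0.0)
        positive_mean = mean / (1.0 - p_zero)
        if cv == 0:
            return cls(p_zero=p_zero, shape=1.0, scale=0.0, point_mass=positive_mean)
        shape = 1.0 / cv**2
        return cls(p_zero=p_zero, shape=shape, scale=positive_mean / shape)

    def rvs(self, rng) -> float:
        if self.p_zero > 0 and rng.random() < self.p_zero:
            return 0.0
        if self.p_zero == 1.0:
            return 0.0
        if self.point_mass is not None:
            return float(self.point_mass)
        return float(rng.gamma(self.shape, self.scale))


def fit_trunc_normal(samples, lower: float = 0.0, upper: float = 100.0) -> TruncNormalSpec:
    """Maximum-likelihood (mean, sd) of a normal truncated to [lower, upper]."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(samples < lower) or np.any(samples > upper):
        raise ValueError(
            f"samples must lie within the truncation bounds [{lower}, {upper}]"
        )
    if np.ptp(samples) == 0:
        return TruncNormalSpec(float(samples[0]), 0.0, lower, upper)

    def nll(params):
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        return -np.sum(stats.truncnorm.logpdf(samples, a, b, loc=mu, scale=sigma))

    x0 = np.array([samples.mean(), math.log(samples.std(ddof=0))])
    result = optimize.minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-8})
    mu, log_sigma = result.x
    return TruncNormalSpec(float(mu), float(math.exp(log_sigma)), lower, upper)


def fit_zi_gamma(samples) -> ZeroInflatedGammaSpec:
    """Fit the zero fraction exactly and the positive part by gamma MLE."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(samples < 0):
        raise ValueError("samples must be non-negative")
    positives = samples[samples > 0]
    p_zero = 1.0 - positives.size / samples.size
    if positives.size == 0:
        return ZeroInflatedGammaSpec(p_zero=1.0, shape=1.0, scale=0.0)
    if positives.size == 1 or np.ptp(positives) == 0:
        return ZeroInflatedGammaSpec(
            p_zero=p_zero, shape=1.0, scale=0.0, point_mass=float(positives[0])
        )
    shape, _, scale = stats.gamma.fit(positives, floc=0.0)
    return ZeroInflatedGammaSpec(p_zero=float(p_zero), shape=float(shape), scale=float(scale))


# ---------------------------------------------------------------------------
# PSA


@dataclass(frozen=True)
class PSASpecs:
    """Sampling distributions per economic parameter.

    ``utilities`` maps ``(state, measure)`` -> TruncNormalSpec;
    ``costs`` maps ``(state, component)`` -> ZeroInflatedGammaSpec with
    component in {"rx", "other"}.
    """

    utilities: dict
    costs: dict

    def validate(self) -> None:
        for state in ALIVE_STATES:
            for measure in MEASURES:
                if (state, measure) not in self.utilities:
                    raise ValueError(
                        f"missing utility spec for ({state.label}, {measure})"
                    )
            for component in ("rx", "other"):
                if (state, component) not in self.costs:
                    raise ValueError(
                        f"missing cost spec for ({state.label}, {component})"
                    )


def build_default_specs(
    econ: StateEconomics,
    utility_sd: float = 15.0,
    per_state_n: int = 100,
    cost_zero_prob: float = 0.2,
    cost_cv: float = 1.0,
) -> PSASpecs:
    """Default PSA calibration around the base-case state economics.

    Utility means are sampled at standard-error scale
    (``utility_sd / sqrt(per_state_n)``); monthly cost components keep their
    base-case means with a zero-inflated gamma spread.
    """
    se = utility_sd / math.sqrt(per_state_n) if per_state_n > 0 else utility_sd
    utilities = {
        (state, measure): TruncNormalSpec(econ.utility(state, measure), se)
        for state in ALIVE_STATES
        for measure in MEASURES
    }
    costs = {
        (state, component): ZeroInflatedGammaSpec.from_mean_cv(
            econ.monthly_costs[state][component], cost_zero_prob, cost_cv
        )
        for state in ALIVE_STATES
        for component in ("rx", "other")
    }
    return PSASpecs(utilities=utilities, costs=costs)


@dataclass(frozen=True)
class PSAResult:
    """Per-replication incrementals and the cost-effective fractions."""

    n_reps: int
    seed: int
    wtp_usd_per_qaly: float
    d_cost: np.ndarray
    d_qaly: dict  # measure -> array
    icers: dict  # measure -> list (float or dominance label)
    cost_effective: dict  # measure -> boolean array

    @property
    def fraction_cost_effective(self) -> dict:
        return {m: float(np.mean(flags)) for m, flags in self.cost_effective.items()}

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"rep": np.arange(self.n_reps), "d_cost": self.d_cost})
        for measure in MEASURES:
            frame[f"d_qaly_{measure}"] = self.d_qaly[measure]
            frame[f"icer_{measure}"] = self.icers[measure]
            frame[f"cost_effective_{measure}"] = self.cost_effective[measure]
        return frame


def _sample_economics(rng, specs: PSASpecs) -> StateEconomics:
    utilities = {}
    costs = {}
    for state in ALIVE_STATES:
        utilities[state] = {
            measure: specs.utilities[(state, measure)].rvs(rng) for measure in MEASURES
        }
        costs[state] = {
            component: specs.costs[(state, component)].rvs(rng)
            for component in ("rx", "other")
        }
    return StateEconomics(utilities, costs)


def run_psa(
    base: BaseCase,
    specs: PSASpecs,
    n_reps: int = 1000,
    seed: int = 0,
    wtp: float | None = None,
) -> PSAResult:
    """Monte-Carlo over the economic parameters; deterministic given ``seed``.

    Each replication draws one set of state utilities and state costs, shared
    by both arms, and reruns accumulation and the ICER comparison.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    specs.validate()
    wtp = wtp if wtp is not None else base.wtp_usd_per_qaly
    rng = np.random.default_rng(seed)
    d_cost = np.empty(n_reps)
    d_qaly = {m: np.empty(n_reps) for m in MEASURES}
    icers = {m: [] for m in MEASURES}
    flags = {m: np.empty(n_reps, dtype=bool) for m in MEASURES}
    for rep in range(n_reps):
        econ = _sample_economics(rng, specs)
        result = base.evaluate(econ=econ)
        d_cost[rep] = result.incremental_cost
        for measure in MEASURES:
            d_qaly[measure][rep] = result.incremental_qaly(measure)
            ratio = result.icer(measure)
            icers[measure].append(ratio)
            flags[measure][rep] = decide(ratio, wtp)
    return PSAResult(
        n_reps=n_reps,
        seed=seed,
        wtp_usd_per_qaly=wtp,
        d_cost=d_cost,
        d_qaly=d_qaly,
        icers=icers,
        cost_effective=flags,
    )


# ---------------------------------------------------------------------------
# OWSA


@dataclass(frozen=True)
class OWSAScenario:
    """One deterministic perturbation and its incremental results."""

    name: str
    parameter: str
    direction: str  # "base", "low" or "high"
    new_value: float | None
    d_cost: float
    d_qaly: dict  # measure -> incremental QALYs
    icers: dict  # measure -> ICER or label

    def to_row(self) -> dict:
        row = {
            "parameter": self.parameter,
            "direction": self.direction,
            "new_value": self.new_value,
            "d_cost": self.d_cost,
        }
        for measure in MEASURES:
            row[f"d_qaly_{measure}"] = self.d_qaly[measure]
            row[f"icer_{measure}"] = self.icers[measure]
        return row


def _scenario_from_result(name, parameter, direction, new_value, result) -> OWSAScenario:
    return OWSAScenario(
        name=name,
        parameter=parameter,
        direction=direction,
        new_value=new_value,
        d_cost=result.incremental_cost,
        d_qaly={m: result.incremental_qaly(m) for m in MEASURES},
        icers={m: result.icer(m) for m in MEASURES},
    )


def run_owsa(
    base: BaseCase,
    multiplier: float = 0.2,
    alt_discount_rates=(0.01, 0.05),
) -> list:
    """Base case plus the standard one-way scenarios.

    Scenarios: each arm's phase-2 program cost +/-``multiplier``, all-state
    monthly medication and other-healthcare costs +/-``multiplier``, and the
    discount rate replaced by each alternate.  Pure cost scenarios leave
    incremental QALYs untouched by construction.
    """
    scenarios = [
        _scenario_from_result("base", "base", "base", None, base.evaluate())
    ]

    for arm, tag in (
        (Arm.INDIVIDUAL_COACHING, "phase2_program_cost_individual"),
        (Arm.EDUCATION_CONTROL, "phase2_program_cost_education"),
    ):
        for direction, factor in (("high", 1.0 + multiplier), ("low", 1.0 - multiplier)):
            program = dict(base.program)
            program[arm] = base.program[arm].scaled(phase2=factor)
            scenarios.append(
                _scenario_from_result(
                    f"{tag}_{direction}",
                    tag,
                    direction,
                    program[arm].phase2_per_participant,
                    base.evaluate(program=program),
                )
            )

    for component, tag in (("rx", "rx_monthly_all_states"), ("other", "other_monthly_all_states")):
        for direction, factor in (("high", 1.0 + multiplier), ("low", 1.0 - multiplier)):
            kwargs = {component: factor}
            econ = base.econ.scaled_costs(**kwargs)
            new_value = round_cents(
                econ.monthly_costs[WeightState.LOSS_LT5][component]
            )
            scenarios.append(
                _scenario_from_result(
                    f"{tag}_{direction}", tag, direction, new_value,
                    base.evaluate(econ=econ),
                )
            )

    low, high = sorted(alt_discount_rates)
    for direction, rate in (("low", low), ("high", high)):
        discount = replace(base.discount, annual_rate=rate)
        scenarios.append(
            _scenario_from_result(
                f"discount_rate_{direction}", "annual_discount_rate", direction,
                rate, base.evaluate(discount=discount),
            )
        )
    return scenarios


def owsa_frame(scenarios) -> pd.DataFrame:
    """Tornado-ready table of scenario incrementals."""
    return pd.DataFrame([s.to_row() for s in scenarios])
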