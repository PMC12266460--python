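"""Run configuration: YAML parsing with packaged-fixture defaults.

Precedence is CLI flag > config file > built-in fixtures.  The cycle length
is fixed at 6 months; the horizon must reach the last trial assessment
(month 22) and extends in whole cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .pipeline import (
    DEFAULT_END_OF_TRIAL_WINDOW,
    DEFAULT_FIVE_YEAR_WINDOW,
    DEFAULT_HORIZON_MONTHS,
)

CYCLE_MONTHS = 6.0


@dataclass
class PSAConfig:
    n_reps: int = 1000
    seed: int = 7
    utility_sd: float = 15.0
    per_state_n: int = 100
    cost_zero_prob: float = 0.2
    cost_cv: float = 1.0


@dataclass
class OWSAConfig:
    multiplier: float = 0.2
    alt_discount_rates: tuple = (0.01, 0.05)


@dataclass
class SyntheticConfig:
    """Overrides forwarded to :class:`leapcea.synthetic_trial.GeneratorConfig`."""

    seed: int = 0
    overrides: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    cohort_path: str | None = None
    synthetic: SyntheticConfig | None = None
    annual_rate: float = 0.03
    wtp_usd_per_qaly: float = 150_000.0
    horizon_months: float = DEFAULT_HORIZON_MONTHS
    annual_mortality_prob: float | None = None  # None -> derived from fixtures
    end_of_trial_window: tuple = DEFAULT_END_OF_TRIAL_WINDOW
    five_year_window: tuple = DEFAULT_FIVE_YEAR_WINDOW
    half_cycle: bool = False
    psa: PSAConfig = field(default_factory=PSAConfig)
    owsa: OWSAConfig = field(default_factory=OWSAConfig)

    def __post_init__(self) -> None:
        if self.horizon_months < 22.0:
            raise ValueError("horizon must reach the last trial assessment (month 22)")
        if (self.horizon_months - 22.0) % CYCLE_MONTHS != 0:
            raise ValueError(
                "horizon past month 22 must be a whole number of 6-month cycles"
            )


def load_config(path: str | Path | None) -> RunConfig:
    """Build a RunConfig from a YAML file; missing keys keep defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    synthetic = None
    if "synthetic" in raw:
        block = dict(raw["synthetic"] or {})
        synthetic = SyntheticConfig(
            seed=block.pop("seed", 0), overrides=block
        )
    psa_block = raw.get("psa", {}) or {}
    owsa_block = raw.get("owsa", {}) or {}
    return RunConfig(
        cohort_path=raw.get("cohort_path"),
        synthetic=synthetic,
        annual_rate=raw.get("annual_rate", 0.03),
        wtp_usd_per_qaly=raw.get("wtp_usd_per_qaly", 150_000.0),
        horizon_months=raw.get("horizon_months", DEFAULT_HORIZON_MONTHS),
        annual_mortality_prob=raw.get("annual_mortality_prob"),
        end_of_trial_window=tuple(
            raw.get("end_of_trial_window", DEFAULT_END_OF_TRIAL_WINDOW)
        ),
        five_year_window=tuple(raw.get("five_year_window", DEFAULT_FIVE_YEAR_WINDOW)),
        half_cycle=raw.get("half_cycle", False),
        psa=PSAConfig(**psa_block),
        owsa=OWSAConfig(
            multiplier=owsa_block.get("multiplier", 0.2),
            alt_discount_rates=tuple(owsa_block.get("alt_discount_rates", (0.01, 0.05))),
        ),
    )
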