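"""Shared enumerations: weight-loss health states and trial arms.

The model tracks four mutually exclusive states defined by percent weight
reduction from baseline (month 0): limited/no loss (<5%), moderate loss
(5-10%), large loss (>10%), and a single absorbing state pooling death and
loss to follow-up.
"""

from __future__ import annotations

import enum


class WeightState(enum.IntEnum):
    """Health state by percent weight loss from baseline; DEAD is absorbing."""

    LOSS_LT5 = 0
    LOSS_5_10 = 1
    LOSS_GT10 = 2
    DEAD = 3

    @property
    def label(self) -> str:
        return _STATE_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "WeightState":
        try:
            return _LABEL_TO_STATE[label]
        except KeyError:
            raise ValueError(
                f"unknown state label {label!r}; expected one of "
                f"{sorted(_LABEL_TO_STATE)}"
            ) from None


ALIVE_STATES = (WeightState.LOSS_LT5, WeightState.LOSS_5_10, WeightState.LOSS_GT10)
N_STATES = 4

_STATE_LABELS = {
    WeightState.LOSS_LT5: "lt5",
    WeightState.LOSS_5_10: "m5_10",
    WeightState.LOSS_GT10: "gt10",
    WeightState.DEAD: "dead",
}
_LABEL_TO_STATE = {v: k for k, v in _STATE_LABELS.items()}


class Arm(str, enum.Enum):
    """Randomized maintenance-phase assignment."""

    EDUCATION_CONTROL = "education_control"
    INDIVIDUAL_COACHING = "individual_coaching"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def parse(cls, value: "str | Arm") -> "Arm":
        if isinstance(value, Arm):
            return value
        try:
            return cls(value)
        except ValueError:
            raise ValueError(
                f"unknown arm {value!r}; expected one of "
                f"{[a.value for a in cls]}"
            ) from None


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
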