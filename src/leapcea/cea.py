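"""Incremental cost-effectiveness: ICERs, dominance, net monetary benefit.

Comparisons are strictly pairwise (intervention vs. comparator).  The ICER
is reported as a dollars-per-QALY ratio when the intervention is both
costlier and more effective; otherwise a dominance label replaces it.
Cost-effectiveness at a willingness-to-pay threshold uses strict inequality.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .economics import MEASURES

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined (incremental effect ~ 0)"

_EFF_TOL = 1e-9


def icer(cost_i: float, cost_c: float, eff_i: float, eff_c: float):
    """Incremental cost-effectiveness ratio of intervention vs. comparator.

    Returns ``(cost_i - cost_c) / (eff_i - eff_c)`` when both increments are
    positive, the label ``"dominant"`` when the intervention is no costlier
    but more effective, ``"dominated"`` when it is no cheaper but less
    effective, and an undefined-ratio label when the effect difference is
    negligible.
    """
    values = (cost_i, cost_c, eff_i, eff_c)
    if any(math.isnan(v) or math.isinf(v) for v in values):
        raise ValueError(f"inputs must be finite, got {values}")
    d_cost = cost_i - cost_c
    d_eff = eff_i - eff_c
    if abs(d_eff) < _EFF_TOL:
        return UNDEFINED
    if d_eff > 0 and d_cost <= 0:
        return DOMINANT
    if d_eff < 0 and d_cost >= 0:
        return DOMINATED
    return d_cost / d_eff


def nmb(cost: float, eff: float, wtp: float) -> float:
    """Net monetary benefit ``eff * wtp - cost``."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return eff * wtp - cost


def decide(icer_or_label, wtp: float) -> bool:
    """Cost-effective iff dominant or ICER strictly below the threshold."""
    if icer_or_label == DOMINANT:
        return True
    if isinstance(icer_or_label, str):
        return False
    return icer_or_label < wtp


@dataclass(frozen=True)
class CEAResult:
    """Pairwise comparison of two arms over both QALY measures."""

    cost_intervention: float
    cost_control: float
    qalys_intervention: dict  # measure -> QALYs
    qalys_control: dict
    wtp_usd_per_qaly: float = 150_000.0

    @property
    def incremental_cost(self) -> float:
        return self.cost_intervention - self.cost_control

    def incremental_qaly(self, measure: str) -> float:
        return self.qalys_intervention[measure] - self.qalys_control[measure]

    def icer(self, measure: str):
        return icer(
            self.cost_intervention,
            self.cost_control,
            self.qalys_intervention[measure],
            self.qalys_control[measure],
        )

    def incremental_nmb(self, measure: str) -> float:
        return nmb(
            self.incremental_cost, self.incremental_qaly(measure), self.wtp_usd_per_qaly
        )

    def cost_effective(self, measure: str) -> bool:
        return decide(self.icer(measure), self.wtp_usd_per_qaly)

    def to_dict(self) -> dict:
        out = {
            "wtp_usd_per_qaly": self.wtp_usd_per_qaly,
            "cost_intervention": self.cost_intervention,
            "cost_control": self.cost_control,
            "incremental_cost": self.incremental_cost,
            "measures": {},
        }
        for measure in MEASURES:
            out["measures"][measure] = {
                "qaly_intervention": self.qalys_intervention[measure],
                "qaly_control": self.qalys_control[measure],
                "incremental_qaly": self.incremental_qaly(measure),
                "icer": self.icer(measure),
                "incremental_nmb": self.incremental_nmb(measure),
                "cost_effective": self.cost_effective(measure),
            }
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=2)
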