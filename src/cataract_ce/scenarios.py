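"""Paired evaluation of the no-surgery and surgery arms.

A scenario pairs the untreated disease course against the same course with a
surgery policy, on a shared horizon derived from the life expectancy at the
surgery age.  The pair yields the cost saving (comparator total minus
intervention total), the QALY gain and — when the intervention costs more
than it saves — the incremental cost-effectiveness ratio (ICER), which is
classified against the WHO-style GDP-per-capita corridors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    ArmResult,
    Conventions,
    DiseaseCourse,
    LifeTable,
    ModelParameters,
    PolicyError,
    SurgeryPolicy,
    evaluate_arm,
)

__all__ = [
    "COST_SAVING",
    "HIGHLY_COST_EFFECTIVE",
    "COST_EFFECTIVE",
    "NOT_COST_EFFECTIVE",
    "PairResult",
    "evaluate_pair",
    "classify",
    "corridor_scan",
    "SCAN_POLICIES",
]

COST_SAVING = "cost_saving"
HIGHLY_COST_EFFECTIVE = "highly_cost_effective"
COST_EFFECTIVE = "cost_effective"
NOT_COST_EFFECTIVE = "not_cost_effective"

#: The three surgery-timing policies scanned over onset ages.
SCAN_POLICIES = ("at_onset", "at_severe_start", "at_blind_start")


@dataclass(frozen=True)
class PairResult:
    """Outcome of comparing one surgery policy against no surgery."""

    arm_without: ArmResult
    arm_with: ArmResult
    cost_saving: float          # without-total minus with-total [USD]
    qaly_gain: float            # with-QALYs minus without-QALYs
    icer: Optional[float]       # USD per QALY; None when cost-saving or dominated
    dominated: bool             # costs more AND yields no QALY gain
    corridor: str


def classify(cost_saving: float, qaly_gain: float, icer: Optional[float], gdp: float) -> str:
    """Corridor label: cost-saving, else ICER against 1x / 2x GDP per capita."""
    if cost_saving > 0:
        return COST_SAVING
    if icer is None:
        return NOT_COST_EFFECTIVE
    if icer <= gdp:
        return HIGHLY_COST_EFFECTIVE
    if icer <= 2.0 * gdp:
        return COST_EFFECTIVE
    return NOT_COST_EFFECTIVE


def evaluate_pair(
    course: DiseaseCourse,
    policy: SurgeryPolicy,
    life_table: LifeTable,
    params: ModelParameters,
    conventions: Conventions = Conventions(),
) -> PairResult:
    """Evaluate both arms on the shared horizon set by the surgery age.

    The horizon is re-derived per policy (the life expectancy at the surgery
    age applies to operated and unoperated patient alike), so pairs under
    different timing policies are internally consistent but use different
    horizons.
    """
    s = policy.surgery_age_for(course, params)
    if s is None:
        raise PolicyError("evaluate_pair needs a policy with a surgery year")
    horizon_end = life_table.horizon_end(s)
    no_surgery = SurgeryPolicy("none")
    arm_wo = evaluate_arm(course, no_surgery, life_table, params, conventions, horizon_end)
    arm_w = evaluate_arm(course, policy, life_table, params, conventions, horizon_end)

    # Difference the yearly flows before discounting: years identical in both
    # arms cancel exactly, so parameters the comparison does not depend on
    # have bit-exact zero influence on the saving.
    t_wo, t_w = arm_wo.trajectory, arm_w.trajectory
    disc = (1.0 + params.r / 100.0) ** (-np.arange(len(t_wo), dtype=float))
    cost_flow_delta = sum(
        t_wo.flows(name) - t_w.flows(name)
        for name in ("treatment", "patient_loss", "caregiver_loss")
    )
    cost_saving = float(cost_flow_delta @ disc) + (arm_wo.npv_surgery - arm_w.npv_surgery)
    qaly_gain = float((t_w.flows("quality") - t_wo.flows("quality")) @ disc)
    icer = None
    dominated = False
    if cost_saving <= 0:
        if qaly_gain > 0:
            icer = -cost_saving / qaly_gain
        else:
            dominated = True
    corridor = classify(cost_saving, qaly_gain, icer, params.gdp)
    return PairResult(arm_wo, arm_w, cost_saving, qaly_gain, icer, dominated, corridor)


def _applicable(course: DiseaseCourse, surgery_age: int, life_table: LifeTable) -> bool:
    # A cell is applicable only if the unclamped life expectancy leaves at
    # least one whole modelled year after the surgery.
    raw = life_table.expected_death_age(surgery_age, clamp=False)
    return raw >= surgery_age + 1


def corridor_scan(
    life_table: LifeTable,
    params: ModelParameters,
    policies: Sequence[str] = SCAN_POLICIES,
    onset_ages: Iterable[int] = range(40, 100),
    conventions: Conventions = Conventions(),
) -> pd.DataFrame:
    """Grid of pair outcomes over onset ages x surgery-timing policies.

    Returns a rectangular DataFrame with one row per (onset age, policy);
    cells whose remaining life expectancy at the surgery age is below one
    modelled year are flagged ``applicable = False`` and carry NaN outcomes.
    """
    rows = []
    for a in onset_ages:
        course = DiseaseCourse(a)
        for mode in policies:
            policy = SurgeryPolicy(mode)
            s = policy.surgery_age_for(course, params)
            row = {
                "onset_age": a,
                "policy": mode,
                "surgery_age": s,
                "applicable": True,
                "cost_saving_usd": float("nan"),
                "qaly_gain": float("nan"),
                "icer_usd_per_qaly": float("nan"),
                "corridor": "",
            }
            if not _applicable(course, s, life_table):
                row["applicable"] = False
            else:
                pair = evaluate_pair(course, policy, life_table, params, conventions)
                row["cost_saving_usd"] = pair.cost_saving
                row["qaly_gain"] = pair.qaly_gain
                row["icer_usd_per_qaly"] = (
                    pair.icer if pair.icer is not None else float("nan")
                )
                row["corridor"] = pair.corridor
            rows.append(row)
    return pd.DataFrame(rows)
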