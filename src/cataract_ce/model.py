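"""Core lifetime-cost model for untreated and surgically treated cataract.

A patient develops cataract at an integer onset age ``a`` and progresses
through three visual-impairment stages on a yearly grid — mild/moderate
(``t_m`` years), severe (``t_s`` years), then blindness until death.  Each
year carries direct treatment cost, productivity loss of the patient (only
while below pension age) and productivity loss of a caregiver, plus a
quality-of-life weight.  Surgery, if performed, restores vision from the
surgery year onward: all disease cost flows stop and the post-operative
quality weight applies.

All flows fall at the *start* of each year (annuity-due convention) and are
discounted to the onset age at interest rate ``r`` percent per year; the
onset-age year therefore carries discount exponent 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ParameterError",
    "PolicyError",
    "Conventions",
    "ModelParameters",
    "LifeTable",
    "DiseaseCourse",
    "SurgeryPolicy",
    "YearRecord",
    "Trajectory",
    "ArmResult",
    "discount_weight",
    "build_trajectory",
    "npv_treatment",
    "npv_patient_productivity",
    "npv_caregiver",
    "npv_surgery",
    "npv_qalys",
    "evaluate_arm",
    "PATIENT_LOSS_GDP_FRACTIONS",
    "CAREGIVER_LOSS_GDP_FRACTIONS",
    "MILD",
    "SEVERE",
    "BLIND",
    "POST_OP",
]


class ParameterError(ValueError):
    """Raised when a model parameter violates its domain constraints."""


class PolicyError(ValueError):
    """Raised when a surgery policy is inconsistent with the disease course."""


# Stage labels used throughout.
MILD = "mild"
SEVERE = "severe"
BLIND = "blind"
POST_OP = "post_op"

# Productivity losses expressed as fractions of GDP per capita
# (mild, severe, blind).  Used when GDP itself is varied: the loss
# parameters are defined as these shares of GDP and move with it.
PATIENT_LOSS_GDP_FRACTIONS = (0.05, 0.30, 0.60)
CAREGIVER_LOSS_GDP_FRACTIONS = (0.00, 0.05, 0.25)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Conventions:
    """Switches for conventions the published results pin down only implicitly.

    include_blind_treatment
        If True, the blind stage accrues the blind-stage treatment cost; the
        default False reproduces the published treatment net values, which
        accrue treatment cost only in the mild and severe stages.
    surgery_discount_convention
        ``"calibrated"`` discounts the surgery cost with exponent 0 for
        surgery in the onset year and ``s - a - 1`` otherwise (this
        reproduces the published 193.38 and 630-threshold figures
        simultaneously); ``"literal"`` uses exponent ``s - a``.
    """

    include_blind_treatment: bool = False
    surgery_discount_convention: str = "calibrated"

    def __post_init__(self) -> None:
        if self.surgery_discount_convention not in ("calibrated", "literal"):
            raise ParameterError(
                "surgery_discount_convention must be 'calibrated' or 'literal', "
                f"got {self.surgery_discount_convention!r}"
            )


@dataclass(frozen=True)
class ModelParameters:
    """All scalar constants of the model, validated on construction.

    Currencies are USD per year unless noted; durations are whole years;
    quality weights are dimensionless in [0, 1].
    """

    ctm: float = 20.0        # treatment cost / year, mild stage
    cts: float = 20.0        # treatment cost / year, severe stage
    ctb: float = 20.0        # treatment cost / year, blind stage
    t_m: int = 10            # duration of mild stage [years]
    t_s: int = 5             # duration of severe stage [years]
    cpm: float = 55.0        # patient productivity loss / year, mild
    cps: float = 330.0       # patient productivity loss / year, severe
    cpb: float = 660.0       # patient productivity loss / year, blind
    ccm: float = 0.0         # caregiver productivity loss / year, mild
    ccs: float = 55.0        # caregiver productivity loss / year, severe
    ccb: float = 275.0       # caregiver productivity loss / year, blind
    gdp: float = 1100.0      # GDP per capita per year [USD]
    r: float = 5.0           # interest (discount) rate [% / year]
    pension_age: int = 60    # pension age P [years]
    cs: float = 300.0        # cost of one surgery [USD]
    qm: float = 0.7          # quality weight, mild
    qs: float = 0.6          # quality weight, severe
    qb: float = 0.5          # quality weight, blind
    qo: float = 0.9          # quality weight after successful surgery

    _CURRENCY_FIELDS = ("ctm", "cts", "ctb", "cpm", "cps", "cpb",
                        "ccm", "ccs", "ccb", "gdp", "cs")
    _QUALITY_FIELDS = ("qm", "qs", "qb", "qo")

    def __post_init__(self) -> None:
        for name in self._CURRENCY_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be a finite non-negative currency, got {v}")
        if not np.isfinite(self.r) or self.r <= -100:
            raise ParameterError(f"interest rate r must exceed -100%, got {self.r}")
        for name in ("t_m", "t_s"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ParameterError(f"{name} must be a non-negative whole number of years, got {v}")
            object.__setattr__(self, name, int(v))
        if int(self.pension_age) != self.pension_age or self.pension_age < 0:
            raise ParameterError(f"pension_age must be a non-negative whole number, got {self.pension_age}")
        object.__setattr__(self, "pension_age", int(self.pension_age))
        for name in self._QUALITY_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ParameterError(f"quality weight {name} must lie in [0, 1], got {v}")
        if self.qo < self.qb:
            raise ParameterError(
                f"post-operative quality qo={self.qo} must not be below blind-stage qb={self.qb}"
            )

    def with_gdp(self, gdp: float) -> "ModelParameters":
        """Return a copy with GDP set to ``gdp`` and all six productivity-loss
        parameters rescaled to their defining GDP fractions."""
        pm, ps, pb = PATIENT_LOSS_GDP_FRACTIONS
        cm, cs_, cb = CAREGIVER_LOSS_GDP_FRACTIONS
        return replace(
            self, gdp=gdp,
            cpm=pm * gdp, cps=ps * gdp, cpb=pb * gdp,
            ccm=cm * gdp, ccs=cs_ * gdp, ccb=cb * gdp,
        )


@dataclass(frozen=True)
class LifeTable:
    """Expected age at death as a piecewise-linear function of current age.

    Anchors are (age, expected_death_age) pairs; values between anchors are
    linearly interpolated, values outside the anchored range are linearly
    extrapolated from the two nearest anchors.  For model construction the
    result is clamped to at least ``age + 1`` so every patient has one whole
    year on the grid; applicability checks may inspect the unclamped value.
    """

    anchors: Tuple[Tuple[float, float], ...]

    def __init__(self, anchors: Iterable[Sequence[float]]):
        pts = tuple((float(a), float(d)) for a, d in anchors)
        if not pts:
            raise ParameterError("life table needs at least one anchor")
        ages = [a for a, _ in pts]
        deaths = [d for _, d in pts]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ParameterError("life-table anchor ages must be strictly increasing")
        if any(d <= a for a, d in pts):
            raise ParameterError("expected death age must exceed the anchor age")
        if any(d2 < d1 for d1, d2 in zip(deaths, deaths[1:])):
            raise ParameterError("expected death age must be non-decreasing in age")
        object.__setattr__(self, "anchors", pts)

    def expected_death_age(self, age: float, clamp: bool = True) -> float:
        ages = np.array([a for a, _ in self.anchors])
        deaths = np.array([d for _, d in self.anchors])
        if len(ages) == 1:
            val = float(deaths[0])
        elif age < ages[0]:
            slope = (deaths[1] - deaths[0]) / (ages[1] - ages[0])
            val = float(deaths[0] + slope * (age - ages[0]))
        elif age > ages[-1]:
            slope = (deaths[-1] - deaths[-2]) / (ages[-1] - ages[-2])
            val = float(deaths[-1] + slope * (age - ages[-1]))
        else:
            val = float(np.interp(age, ages, deaths))
        if clamp:
            val = max(val, age + 1.0)
        return val

    def horizon_end(self, age: float) -> int:
        """Exclusive model horizon: round(L(age)) with half rounded up,
        clamped to ``age + 1``; the last modelled year is ``horizon_end - 1``."""
        return max(_round_half_up(self.expected_death_age(age, clamp=True)),
                   int(math.floor(age)) + 1)


@dataclass(frozen=True)
class DiseaseCourse:
    """Onset age plus the stage schedule it implies under given durations."""

    onset_age: int

    def __post_init__(self) -> None:
        if int(self.onset_age) != self.onset_age:
            raise ParameterError(f"onset_age must be a whole year, got {self.onset_age}")
        object.__setattr__(self, "onset_age", int(self.onset_age))

    def stage_at(self, t: int, params: ModelParameters) -> str:
        """Disease stage in year ``t`` since onset (0-based), absent surgery."""
        if t < params.t_m:
            return MILD
        if t < params.t_m + params.t_s:
            return SEVERE
        return BLIND


_POLICY_MODES = ("none", "at_onset", "at_severe_start", "at_blind_start", "at_age")


@dataclass(frozen=True)
class SurgeryPolicy:
    """When (if ever) the cataract surgery is performed.

    The three named timing modes tie the surgery year to the stage schedule:
    at onset (s = a), at the first severe year (s = a + t_m) or at the first
    blind year (s = a + t_m + t_s).
    """

    mode: str = "none"
    surgery_age: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in _POLICY_MODES:
            raise PolicyError(f"unknown surgery policy mode {self.mode!r}")
        if self.mode == "at_age" and self.surgery_age is None:
            raise PolicyError("mode 'at_age' requires surgery_age")

    def surgery_age_for(self, course: DiseaseCourse, params: ModelParameters) -> Optional[int]:
        a = course.onset_age
        if self.mode == "none":
            return None
        if self.mode == "at_onset":
            s = a
        elif self.mode == "at_severe_start":
            s = a + params.t_m
        elif self.mode == "at_blind_start":
            s = a + params.t_m + params.t_s
        else:
            s = int(self.surgery_age)
        if s < a:
            raise PolicyError(f"surgery age {s} precedes onset age {a}")
        return s


@dataclass(frozen=True)
class YearRecord:
    age: int
    t: int                    # years since onset, 0-based
    state: str                # mild / severe / blind / post_op
    treatment: float
    patient_loss: float
    caregiver_loss: float
    quality: float
    pensionable: int          # beta_t: 1 while age < pension age


@dataclass(frozen=True)
class Trajectory:
    """Year-by-year schedule of one arm, onset through ``horizon_end - 1``."""

    onset_age: int
    horizon_end: int
    surgery_age: Optional[int]
    records: Tuple[YearRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def flows(self, name: str) -> np.ndarray:
        return np.array([getattr(rec, name) for rec in self.records], dtype=float)


def discount_weight(r: float, t_index: int) -> float:
    """Present-value factor (1 + r/100)^(-t) for a flow ``t_index`` whole
    years after the evaluation age; the evaluation-age year is undiscounted."""
    if r <= -100:
        raise ParameterError(f"interest rate r must exceed -100%, got {r}")
    if t_index < 0 or int(t_index) != t_index:
        raise ParameterError(f"t_index must be a non-negative integer, got {t_index}")
    return float((1.0 + r / 100.0) ** (-int(t_index)))


def _discount_vector(r: float, n: int) -> np.ndarray:
    if r <= -100:
        raise ParameterError(f"interest rate r must exceed -100%, got {r}")
    return (1.0 + r / 100.0) ** (-np.arange(n, dtype=float))


def build_trajectory(
    course: DiseaseCourse,
    policy: SurgeryPolicy,
    life_table: LifeTable,
    params: ModelParameters,
    conventions: Conventions = Conventions(),
    horizon_end: Optional[int] = None,
) -> Trajectory:
    """Lay out the yearly flow schedule of one arm.

    The horizon reference age is the surgery age for operated arms and the
    onset age otherwise; ``horizon_end`` may be supplied to force both arms
    of a comparison onto a shared horizon.
    """
    a = course.onset_age
    s = policy.surgery_age_for(course, params)
    if horizon_end is None:
        h = s if s is not None else a
        horizon_end = life_table.horizon_end(h)
    if horizon_end <= a:
        raise PolicyError(f"horizon end {horizon_end} leaves no modelled year after onset {a}")
    if s is not None and s >= horizon_end:
        raise PolicyError(f"surgery age {s} is at or beyond the horizon end {horizon_end}")

    ctb_flow = params.ctb if conventions.include_blind_treatment else 0.0
    treat = {MILD: params.ctm, SEVERE: params.cts, BLIND: ctb_flow}
    ploss = {MILD: params.cpm, SEVERE: params.cps, BLIND: params.cpb}
    closs = {MILD: params.ccm, SEVERE: params.ccs, BLIND: params.ccb}
    qual = {MILD: params.qm, SEVERE: params.qs, BLIND: params.qb}

    records = []
    for age in range(a, horizon_end):
        t = age - a
        beta = 1 if age < params.pension_age else 0
        if s is not None and age >= s:
            rec = YearRecord(age, t, POST_OP, 0.0, 0.0, 0.0, params.qo, beta)
        else:
            stage = course.stage_at(t, params)
            rec = YearRecord(
                age, t, stage,
                treat[stage],
                beta * ploss[stage],
                closs[stage],
                qual[stage],
                beta,
            )
        records.append(rec)
    return Trajectory(a, horizon_end, s, tuple(records))


def npv_treatment(traj: Trajectory, params: ModelParameters, r: Optional[float] = None) -> float:
    """Discounted treatment cost of the arm (CT), net value at the onset age."""
    r = params.r if r is None else r
    return float(traj.flows("treatment") @ _discount_vector(r, len(traj)))


def npv_patient_productivity(traj: Trajectory, params: ModelParameters, r: Optional[float] = None) -> float:
    """Discounted patient productivity loss (CP); only pre-pension years count."""
    r = params.r if r is None else r
    return float(traj.flows("patient_loss") @ _discount_vector(r, len(traj)))


def npv_caregiver(traj: Trajectory, params: ModelParameters, r: Optional[float] = None) -> float:
    """Discounted caregiver productivity loss (CC); no pension cut-off."""
    r = params.r if r is None else r
    return float(traj.flows("caregiver_loss") @ _discount_vector(r, len(traj)))


def npv_qalys(traj: Trajectory, params: ModelParameters, r: Optional[float] = None) -> float:
    """Discounted quality-adjusted life years of the arm (NQ)."""
    r = params.r if r is None else r
    return float(traj.flows("quality") @ _discount_vector(r, len(traj)))


def npv_surgery(
    course: DiseaseCourse,
    policy: SurgeryPolicy,
    params: ModelParameters,
    conventions: Conventions = Conventions(),
    r: Optional[float] = None,
) -> float:
    """Discounted surgery cost (NS).

    Under the calibrated convention the discount exponent is 0 for surgery in
    the onset year and ``s - a - 1`` otherwise; the literal convention uses
    ``s - a``.
    """
    r = params.r if r is None else r
    s = policy.surgery_age_for(course, params)
    if s is None:
        return 0.0
    d = s - course.onset_age
    if conventions.surgery_discount_convention == "calibrated" and d > 0:
        d -= 1
    return params.cs * discount_weight(r, d)


@dataclass(frozen=True)
class ArmResult:
    """Component net values of one arm, discounted to the onset age."""

    npv_treatment: float
    npv_patient_productivity: float
    npv_caregiver: float
    npv_surgery: float
    npv_total: float
    qalys: float
    trajectory: Trajectory = field(repr=False, compare=False, default=None)


def evaluate_arm(
    course: DiseaseCourse,
    policy: SurgeryPolicy,
    life_table: LifeTable,
    params: ModelParameters,
    conventions: Conventions = Conventions(),
    horizon_end: Optional[int] = None,
) -> ArmResult:
    """Compute all discounted components and their total for one arm."""
    traj = build_trajectory(course, policy, life_table, params, conventions, horizon_end)
    ct = npv_treatment(traj, params)
    cp = npv_patient_productivity(traj, params)
    cc = npv_caregiver(traj, params)
    ns = npv_surgery(course, policy, params, conventions)
    nq = npv_qalys(traj, params)
    return ArmResult(ct, cp, cc, ns, ct + cp + cc + ns, nq, traj)
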