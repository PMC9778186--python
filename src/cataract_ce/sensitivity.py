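"""Deterministic sensitivity machinery: tornado, thresholds, return on investment.

All three tools perturb a single *case* — an (onset age, surgery policy)
pair evaluated on a life table with a parameter set — one parameter at a
time:

* ``tornado`` swings every parameter by a fixed fraction (default +/-50%)
  and ranks them by the induced range of the cost saving;
* ``find_threshold`` solves for the parameter value at which the case stops
  being cost-saving (or stops clearing the 1x / 2x GDP cost-effectiveness
  bounds), by bisection for continuous parameters and integer scan for
  whole-year parameters;
* ``solve_roi`` finds the internal rate of return: the discount rate at
  which the cost saving is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import pandas as pd
from scipy.optimize import brentq

from .model import (
    Conventions,
    DiseaseCourse,
    LifeTable,
    ModelParameters,
    ParameterError,
    _round_half_up,
)
from .scenarios import PairResult, SurgeryPolicy, evaluate_pair

__all__ = [
    "CaseSpec",
    "TornadoRow",
    "ThresholdResult",
    "ROIResult",
    "tornado",
    "find_threshold",
    "threshold_table",
    "solve_roi",
    "TORNADO_PARAMETERS",
    "CRITERIA",
    "INTEGER_PARAMETERS",
    "CONTINUOUS_PARAMETERS",
]

# Parameters swung in the tornado, in the order they are perturbed.
TORNADO_PARAMETERS = (
    "ctm", "cts", "ctb", "t_m", "t_s", "gdp", "r",
    "cpm", "cps", "cpb", "ccm", "ccs", "ccb", "cs", "pension_age",
)

CRITERIA = ("cost_saving_zero", "icer_equals_gdp", "icer_equals_2gdp")

INTEGER_PARAMETERS = ("t_m", "t_s", "pension_age", "life_expectancy")
CONTINUOUS_PARAMETERS = (
    "cs", "gdp", "r", "ctm", "cts", "ctb",
    "cpm", "cps", "cpb", "ccm", "ccs", "ccb",
)

_CRITERION_MULTIPLE = {"icer_equals_gdp": 1.0, "icer_equals_2gdp": 2.0}


@dataclass(frozen=True)
class CaseSpec:
    """One (disease course, surgery policy) evaluation context."""

    course: DiseaseCourse
    policy: SurgeryPolicy
    life_table: LifeTable
    params: ModelParameters
    conventions: Conventions = Conventions()

    def evaluate(self) -> PairResult:
        return evaluate_pair(self.course, self.policy, self.life_table,
                             self.params, self.conventions)

    def surgery_age(self) -> int:
        return self.policy.surgery_age_for(self.course, self.params)

    def with_param(self, name: str, value: float) -> "CaseSpec":
        """Copy of the case with one parameter replaced.

        ``gdp`` rescales the six productivity-loss parameters along with it
        (they are defined as GDP shares); ``life_expectancy`` replaces the
        life table with one anchored at the surgery age.
        """
        if name == "gdp":
            return replace(self, params=self.params.with_gdp(value))
        if name == "life_expectancy":
            table = LifeTable([(self.surgery_age(), float(value))])
            return replace(self, life_table=table)
        if name in ("t_m", "t_s", "pension_age"):
            value = int(value)
        if not hasattr(self.params, name):
            raise ParameterError(f"unknown model parameter {name!r}")
        return replace(self, params=replace(self.params, **{name: value}))


@dataclass(frozen=True)
class TornadoRow:
    parameter: str
    low: float
    high: float
    saving_low: float
    saving_high: float
    impact_range: float


def tornado(case: CaseSpec, variation: float = 0.5,
            parameters: Sequence[str] = TORNADO_PARAMETERS) -> pd.DataFrame:
    """One-way sensitivity of the cost saving, rows sorted by impact range.

    Each parameter is evaluated at ``(1 - variation)`` and ``(1 + variation)``
    times its base value, all others held at base; whole-year durations are
    rounded to the nearest year, and the pension age moves by whole years
    (+/-5 at the default variation) instead of a fraction of itself.
    """
    if variation <= -1:
        raise ParameterError(f"variation must exceed -1, got {variation}")
    rows = []
    for name in parameters:
        base = getattr(case.params, name)
        if name == "pension_age":
            # +/-5 years at the default 50% variation, scaled proportionally
            delta = _round_half_up(10 * variation)
            low, high = base - delta, base + delta
        elif name in ("t_m", "t_s"):
            low = _round_half_up(base * (1 - variation))
            high = _round_half_up(base * (1 + variation))
        else:
            low = base * (1 - variation)
            high = base * (1 + variation)
        s_low = case.with_param(name, low).evaluate().cost_saving
        s_high = case.with_param(name, high).evaluate().cost_saving
        rows.append(TornadoRow(name, low, high, s_low, s_high,
                               abs(s_high - s_low)))
    rows.sort(key=lambda row: row.impact_range, reverse=True)
    return pd.DataFrame([row.__dict__ for row in rows])


@dataclass(frozen=True)
class ThresholdResult:
    parameter: str
    criterion: str
    threshold: Optional[float]      # None when the criterion is never left
    bracket: Tuple[float, float]
    residual: Optional[float]       # criterion function at the threshold [USD]

    @property
    def found(self) -> bool:
        return self.threshold is not None


def _criterion_residual(case: CaseSpec, criterion: str) -> float:
    """Signed distance from the criterion boundary, in USD.

    Negative while the criterion holds (cost-saving, or ICER within the GDP
    multiple), positive once it is left; zero at the boundary.
    """
    pair = case.evaluate()
    if criterion == "cost_saving_zero":
        return -pair.cost_saving
    k = _CRITERION_MULTIPLE[criterion]
    return (-pair.cost_saving) - k * case.params.gdp * pair.qaly_gain


def _default_bracket(case: CaseSpec, name: str, criterion: str) -> Tuple[float, float]:
    if name in CONTINUOUS_PARAMETERS:
        if name == "r":
            return (0.0, 1000.0)
        return (0.0, 1.0e6)
    # integer scans run from the base value toward the adverse direction
    if name == "life_expectancy":
        return (_base_life_expectancy(case), case.surgery_age() + 1)
    if name == "pension_age":
        return (getattr(case.params, name), 0)
    return (getattr(case.params, name), 60)       # t_m, t_s grow


def _base_life_expectancy(case: CaseSpec) -> int:
    return _round_half_up(case.life_table.expected_death_age(case.surgery_age()))


def find_threshold(case: CaseSpec, parameter: str,
                   criterion: str = "cost_saving_zero",
                   bracket: Optional[Tuple[float, float]] = None,
                   tol: float = 1e-6) -> ThresholdResult:
    """Parameter value at which the case leaves the criterion's corridor.

    Continuous parameters are bisected to ``|residual| < tol`` USD; whole-year
    parameters are scanned from the base value toward the adverse end of the
    bracket and the first failing integer is reported.  If the criterion
    holds over the whole bracket the result carries ``threshold = None``
    (a "no threshold" cell).
    """
    if criterion not in CRITERIA:
        raise ParameterError(f"unknown criterion {criterion!r}")
    if parameter not in INTEGER_PARAMETERS and parameter not in CONTINUOUS_PARAMETERS:
        raise ParameterError(f"unknown threshold parameter {parameter!r}")
    if bracket is None:
        bracket = _default_bracket(case, parameter, criterion)

    def residual(x: float) -> float:
        return _criterion_residual(case.with_param(parameter, x), criterion)

    if parameter in INTEGER_PARAMETERS:
        start, stop = int(bracket[0]), int(bracket[1])
        step = 1 if stop >= start else -1
        for x in range(start + step, stop + step, step):
            if residual(x) > 0:
                return ThresholdResult(parameter, criterion, float(x), bracket,
                                       residual(x))
        return ThresholdResult(parameter, criterion, None, bracket, None)

    lo, hi = float(bracket[0]), float(bracket[1])
    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo == 0.0:
        return ThresholdResult(parameter, criterion, lo, bracket, 0.0)
    if f_hi == 0.0:
        return ThresholdResult(parameter, criterion, hi, bracket, 0.0)
    if f_lo * f_hi > 0:
        return ThresholdResult(parameter, criterion, None, bracket, None)
    root = brentq(residual, lo, hi, xtol=min(tol * 1e-3, 1e-9))
    return ThresholdResult(parameter, criterion, float(root), bracket, residual(root))


_REPORT_STEP = {"cs": 10.0, "gdp": 10.0}


def threshold_table(case: CaseSpec,
                    parameters: Sequence[str] = (
                        "ctm", "cts", "ctb", "life_expectancy", "t_m", "t_s",
                        "gdp", "cpm", "cps", "cpb", "ccm", "ccs", "ccb",
                        "pension_age", "cs",
                    )) -> pd.DataFrame:
    """Threshold summary across all criteria.

    Monetary thresholds are additionally reported to the nearest 10 USD and
    whole-year ones as integers; the full-precision value is kept alongside.
    Cells where the criterion is never left within the default bracket show
    ``"-"``.
    """
    rows = []
    for name in parameters:
        row = {"parameter": name}
        for criterion in CRITERIA:
            res = find_threshold(case, name, criterion)
            raw = res.threshold
            if raw is None:
                reported = "-"
            elif name in INTEGER_PARAMETERS:
                reported = int(raw)
            else:
                step = _REPORT_STEP.get(name)
                reported = _round_half_up(raw / step) * step if step else round(raw, 2)
            row[criterion] = reported
            row[criterion + "_raw"] = raw
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ROIResult:
    """Internal rate of return of the surgery for one case.

    ``status`` is ``"solved"`` when a rate was found, ``"negative"`` when the
    case is not cost-saving even undiscounted, and ``"unbounded"`` when the
    saving never reaches zero on the bracket.
    """

    rate_percent: Optional[float]
    status: str
    residual: Optional[float] = None


def solve_roi(case: CaseSpec, bracket: Tuple[float, float] = (0.0, 200.0),
              tol: float = 1e-6) -> ROIResult:
    """Discount rate (percent) at which the cost saving vanishes."""

    def saving(r: float) -> float:
        return case.with_param("r", r).evaluate().cost_saving

    lo, hi = bracket
    s_lo = saving(lo)
    if s_lo <= 0:
        return ROIResult(None, "negative")
    s_hi = saving(hi)
    if s_hi > 0:
        return ROIResult(None, "unbounded")
    root = brentq(saving, lo, hi, xtol=min(tol * 1e-3, 1e-9))
    return ROIResult(float(root), "solved", saving(root))
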