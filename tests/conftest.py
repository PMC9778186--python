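"""Shared fixtures and independent numerical oracles.

The oracles here deliberately avoid the package's vectorized NPV path: the
closed-form annuity-due factor and a plain-Python year-by-year summation are
used to cross-check every discounted quantity.
"""

from __future__ import annotations

import pytest

from cataract_ce import (
    CaseSpec,
    DiseaseCourse,
    SurgeryPolicy,
    default_life_table,
    default_parameters,
)


def annuity_due(n: int, r: float) -> float:
    """Closed-form present value of a unit flow at the start of each of n years."""
    if n <= 0:
        return 0.0
    if r == 0:
        return float(n)
    v = 1.0 / (1.0 + r / 100.0)
    return (1.0 - v**n) / (1.0 - v)


def npv_brute(flows, r: float) -> float:
    """Year-by-year discounted sum, independent of the vectorized implementation."""
    return sum(f * (1.0 + r / 100.0) ** (-t) for t, f in enumerate(flows))


def segment_npv(segments, r: float) -> float:
    """Piecewise-constant-flow NPV from (start, stop, flow) segments via
    differences of annuity-due factors."""
    return sum(flow * (annuity_due(stop, r) - annuity_due(start, r))
               for start, stop, flow in segments)


@pytest.fixture
def params():
    return default_parameters()


@pytest.fixture
def life_table():
    return default_life_table()


@pytest.fixture
def baseline_case(params, life_table):
    """Onset at 50, surgery at the start of the severe stage (age 60)."""
    return CaseSpec(DiseaseCourse(50), SurgeryPolicy("at_severe_start"),
                    life_table, params)


@pytest.fixture
def onset60_case(params, life_table):
    """Onset at 60 with surgery in the onset year (the threshold case)."""
    return CaseSpec(DiseaseCourse(60), SurgeryPolicy("at_onset"),
                    life_table, params)
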