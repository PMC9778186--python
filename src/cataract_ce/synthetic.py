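"""Reference inputs and randomized, structurally valid synthetic inputs.

``default_parameters`` / ``default_life_table`` return the published
low-income-country baseline (a rural Tanzanian setting: 20 USD/year
treatment, 300 USD surgery, GDP p.c. 1100 USD, 5% discounting, quality
weights 0.7/0.6/0.5/0.9).  The random generators draw parameter sets and
life tables that satisfy every structural invariant of the model, for
property-based testing; they are fully determined by their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .model import LifeTable, ModelParameters, ParameterError

__all__ = [
    "default_parameters",
    "default_life_table",
    "default_inputs",
    "GeneratorConfig",
    "random_parameters",
    "random_life_table",
    "DEFAULT_LIFE_ANCHORS",
]

#: Life-expectancy anchors (age, expected age at death).  The 60-80 anchors
#: follow the published expectancy statements for the modelled population;
#: the 90/92 anchors extend the table so the oldest-old scenarios have a
#: defined one- and two-year horizon.  Ages outside the anchored range are
#: linearly extrapolated from the two nearest anchors.
DEFAULT_LIFE_ANCHORS: Tuple[Tuple[float, float], ...] = (
    (60.0, 77.0),
    (65.0, 78.8),
    (75.0, 82.5),
    (80.0, 85.0),
    (90.0, 92.0),
    (92.0, 93.0),
)


def default_parameters() -> ModelParameters:
    """The baseline parameter set (all ``ModelParameters`` defaults)."""
    return ModelParameters()


def default_life_table() -> LifeTable:
    """The baseline life table over the default anchors."""
    return LifeTable(DEFAULT_LIFE_ANCHORS)


def default_inputs() -> Tuple[ModelParameters, LifeTable]:
    """Baseline (parameters, life table) pair used by every worked example."""
    return default_parameters(), default_life_table()


@dataclass(frozen=True)
class GeneratorConfig:
    """Ranges and sizes for the random generators; the seed fixes everything.

    ``scale_low``/``scale_high`` bound each scalar parameter as multiples of
    its baseline value (overridable per field via ``ranges``).  Life tables
    get ``n_anchors`` anchors starting at ``anchor_start_age``, with the
    expected death age rising at a slope within ``slope_bounds`` (slopes
    below 1 keep remaining lifetime shrinking with age).
    """

    seed: int = 0
    scale_low: float = 0.25
    scale_high: float = 4.0
    ranges: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    n_anchors: int = 6
    anchor_start_age: float = 40.0
    anchor_age_step: Tuple[float, float] = (4.0, 14.0)
    first_margin: Tuple[float, float] = (2.0, 35.0)
    slope_bounds: Tuple[float, float] = (0.0, 0.95)
    onset_age_range: Tuple[int, int] = (40, 99)

    def __post_init__(self) -> None:
        if self.scale_low <= 0 or self.scale_high < self.scale_low:
            raise ParameterError("need 0 < scale_low <= scale_high")
        if self.n_anchors < 1:
            raise ParameterError("need at least one anchor")
        lo, hi = self.slope_bounds
        if not (0.0 <= lo <= hi < 1.0):
            raise ParameterError("slope bounds must satisfy 0 <= low <= high < 1")

    def range_for(self, name: str, base: float) -> Tuple[float, float]:
        if name in self.ranges:
            return self.ranges[name]
        return (self.scale_low * base, self.scale_high * base)


def _rng(config_or_seed) -> np.random.Generator:
    if isinstance(config_or_seed, np.random.Generator):
        return config_or_seed
    return np.random.default_rng(config_or_seed)


def random_parameters(config: GeneratorConfig = GeneratorConfig(),
                      rng: Optional[np.random.Generator] = None) -> ModelParameters:
    """Draw a valid parameter set.

    Currencies are uniform within the configured multiples of their baseline,
    durations and the pension age are uniform integers within theirs, and
    quality weights are drawn on a 0.01 grid with the post-operative weight
    at least the blind-stage weight.  Degenerate ranges (low = high = base)
    reproduce the baseline exactly.
    """
    rng = _rng(config.seed) if rng is None else rng
    base = default_parameters()
    values = {}
    for name in ModelParameters._CURRENCY_FIELDS + ("r",):
        lo, hi = config.range_for(name, getattr(base, name))
        if hi < lo:
            raise ParameterError(f"infeasible range for {name}: ({lo}, {hi})")
        values[name] = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    for name in ("t_m", "t_s", "pension_age"):
        lo, hi = config.range_for(name, getattr(base, name))
        lo_i, hi_i = int(np.ceil(lo)), int(np.floor(hi))
        if hi_i < lo_i:
            raise ParameterError(f"infeasible integer range for {name}: ({lo}, {hi})")
        values[name] = int(rng.integers(lo_i, hi_i + 1))
    # quality weights on a 0.01 grid; qo drawn at or above qb
    qm, qs = (int(rng.integers(0, 101)) / 100.0 for _ in range(2))
    qb = int(rng.integers(0, 101)) / 100.0
    qo = int(rng.integers(round(qb * 100), 101)) / 100.0
    values.update(qm=qm, qs=qs, qb=qb, qo=qo)
    return ModelParameters(**values)


def random_life_table(config: GeneratorConfig = GeneratorConfig(),
                      rng: Optional[np.random.Generator] = None) -> LifeTable:
    """Draw a structurally valid life table.

    Anchor ages increase by random steps; the first expected death age sits
    a random margin above the first anchor age, and subsequent anchors rise
    with a slope in ``slope_bounds`` so the expected death age is
    non-decreasing and remaining lifetime shrinks with age.
    """
    rng = _rng(config.seed) if rng is None else rng
    ages = [float(config.anchor_start_age)]
    for _ in range(config.n_anchors - 1):
        ages.append(ages[-1] + float(rng.uniform(*config.anchor_age_step)))
    deaths = [ages[0] + float(rng.uniform(*config.first_margin))]
    for prev_age, age in zip(ages, ages[1:]):
        slope = float(rng.uniform(*config.slope_bounds))
        deaths.append(deaths[-1] + slope * (age - prev_age))
    # the invariant L(anchor) > anchor may bind late in a flat table;
    # queries are clamped to age + 1 by LifeTable itself, but anchors
    # themselves must stay strictly above their age
    deaths = [max(d, a + 1.0) for a, d in zip(ages, deaths)]
    deaths = list(np.maximum.accumulate(deaths))
    return LifeTable(tuple(zip(ages, deaths)))
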