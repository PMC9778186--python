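# Methods

## The model

`cataract_ce` implements a deterministic, yearly-grid lifetime cost model of
cataract in a low-income setting.  A patient develops cataract at an integer
onset age *a* and, untreated, progresses through three WHO visual-acuity
stages: mild/moderate impairment for `t_m` years, severe impairment for
`t_s` years, and blindness until death.  Each modelled year carries four
flows:

* **treatment cost** (`ctm`, `cts`, `ctb` USD/year by stage),
* **patient productivity loss** (`cpm`, `cps`, `cpb`), counted only while
  the patient is below the pension age `P` (the indicator β_t = 1 iff
  age < P),
* **caregiver productivity loss** (`ccm`, `ccs`, `ccb`), with no pension
  cut-off, and
* a **quality-of-life weight** (`qm`, `qs`, `qb`).

A single successful surgery at age *s* ends the disease: from the surgery
year onward all three cost flows are zero and the post-operative quality
weight `qo` applies.  The surgery itself costs `cs` once.

All flows fall at the *start* of each year (annuity-due convention) and are
discounted to the onset age at rate *r* % per year, so the onset-year flow
is undiscounted.  The net value of a flow stream is

    NPV = Σ_t flow(t) · (1 + r/100)^(−t),   t = 0, 1, …, years since onset.

The horizon runs from the onset age to `round(L(h)) − 1` inclusive, where
`L` is the life-expectancy function (piecewise-linear between anchor points,
linearly extrapolated outside them) and the reference age *h* is the surgery
age when a surgery is modelled and the onset age otherwise.  Both arms of a
comparison share the horizon derived at the surgery age: the life expectancy
at the age of surgery applies to the operated and the unoperated patient
alike.  Halves round up.

A *pair* evaluation compares the no-surgery arm against a surgery arm under
one of three timing policies — at onset (s = a), at the first severe year
(s = a + t_m), at the first blind year (s = a + t_m + t_s) — or at an
explicit age.  Its outputs are

* **cost saving** = total without − total with (all four components),
* **QALY gain** = discounted QALYs with − without,
* **ICER** = (−cost saving) / QALY gain when the surgery costs more than it
  saves and gains quality, and
* a **corridor label**: cost-saving when the saving is positive; otherwise
  highly cost-effective when ICER ≤ GDP p.c., cost-effective when
  ICER ≤ 2·GDP p.c., else not cost-effective.  An arm that costs more and
  gains nothing is dominated and classified not cost-effective.

## Calibrated conventions

Two conventions are not fully determined by the published description and
are exposed as switches on `Conventions`:

* `include_blind_treatment` (default `False`).  The published component
  table is reproducible only if treatment cost accrues in the mild and
  severe stages; the default therefore zeroes the blind-stage treatment
  flow.  Setting the switch honours the literal three-stage treatment
  equation instead.
* `surgery_discount_convention` (default `"calibrated"`).  The calibrated
  exponent is 0 for surgery in the onset year and `s − a − 1` otherwise,
  which reproduces both the baseline's discounted operation cost and the
  onset-year threshold arithmetic simultaneously; `"literal"` uses `s − a`.

All runs through the CLI log the active conventions.

## Sensitivity tools

**Tornado.**  Each parameter in {ctm, cts, ctb, t_m, t_s, gdp, r, cpm, cps,
cpb, ccm, ccs, ccb, cs, pension_age} is set to (1 ± v) times its base value
(default v = 0.5) with all others at base, and the induced cost savings are
recorded; rows are sorted by |saving(high) − saving(low)|.  Three cases are
special: durations are rounded to whole years; the pension age moves by ±5
years at the default variation (scaled proportionally for other v); and the
GDP bar rescales the six productivity-loss parameters along with GDP, since
they are defined as GDP shares (patient 5/30/60 %, caregiver 0/5/25 % by
stage).  The individual loss bars move only the named parameter.

**Threshold search.**  For a chosen parameter, the value at which the case
leaves a corridor: cost-saving (saving = 0), highly cost-effective
(ICER = 1·GDP) or cost-effective (ICER = 2·GDP).  The criterion function is
the signed USD distance (−saving) − k·GDP·QALY-gain, which is continuous
across the cost-saving boundary.  Continuous parameters are solved by Brent
bisection to a residual below 10⁻⁶ USD within a bracket that must change
sign (otherwise a "no threshold" cell is reported — several parameters
genuinely cannot push the reference case out of its corridor).  Whole-year
parameters (durations, pension age, the life expectancy at the surgery age)
are scanned integer by integer in the adverse direction and the first
failing value is reported, matching how such thresholds are quoted in
practice (e.g. "not cost-saving once life expectancy falls to 73").
Monetary thresholds are presented to the nearest 10 USD with the raw value
retained alongside.

When GDP is the threshold parameter the productivity losses are rescaled
with it, as in the tornado.  The life-expectancy threshold replaces the life
table by one anchored at the surgery age, which is the only age the case
queries.

**Return on investment.**  The internal rate: the discount rate r at which
the cost saving is exactly zero, bisected on [0, 200] % to a residual below
10⁻⁶ USD.  Cases that are not cost-saving even undiscounted get a
`negative` marker; cases whose saving never reaches zero (e.g. a free
surgery) get `unbounded`.

**Corridor scan.**  The pair evaluation over onset ages 40–99 × the three
timing policies, emitted as a rectangular grid.  A cell is *not applicable*
when the unclamped life expectancy at the surgery age leaves less than one
whole modelled year — there is then no grid year in which restored vision
could be enjoyed.  (For modelled cells the life-table query is clamped to
age + 1 so every trajectory has at least one record.)

## Default inputs

`default_parameters()` is the rural low-income baseline: 20 USD/year
treatment in every stage, 10-year mild and 5-year severe stages, GDP p.c.
1100 USD, r = 5 %, patient losses 55/330/660 USD (5/30/60 % of GDP),
caregiver losses 0/55/275 USD (0/5/25 %), pension at 60, surgery 300 USD,
quality weights 0.7/0.6/0.5 and 0.9 after surgery.

`default_life_table()` anchors the expectancy function at (60, 77),
(65, 78.8), (75, 82.5), (80, 85), (90, 92) and (92, 93).  The 60–80 anchors
are the expectancy statements for the modelled population; the 90/92
anchors extend the table so the oldest-old scenarios have defined one- and
two-year horizons (they pin the 668.29 and 1400 USD/QALY figures).  Ages
below 60 extrapolate the first segment (slope 0.36) — a fixture policy,
replaceable by supplying other anchors.

## Synthetic inputs and what they do (not) show

`random_parameters` / `random_life_table` draw structurally valid inputs —
currencies uniform within 0.25–4× their baseline, whole-year durations,
quality weights on a 0.01 grid with `qo ≥ qb`, life tables with
non-decreasing expected death age whose remaining lifetime shrinks with age
(anchor slopes below 1) — deterministically from a seed.  They exercise the
model's invariants (additivity, closed-form equivalence, discount
monotonicity, corridor ordering) across a wide envelope; they do not emulate
any real population's epidemiology or demography, so passing property tests
demonstrates numerical and structural correctness, not external validity.

## Numerical choices

* Internal arithmetic is full double precision; 2-decimal currency/QALY
  rounding happens only at the presentation layer (CSV/stdout).  JSON output
  keeps full floats.
* Pair deltas (saving, QALY gain) are computed by differencing the yearly
  flows of the two arms *before* discounting.  Years identical in both arms
  cancel exactly, so a parameter the comparison does not depend on has
  bit-exact zero tornado range, and catastrophic cancellation between two
  large totals is avoided.  The difference from `total_without −
  total_with` is at machine-epsilon level.
* Brent's method is used for all continuous root finding (`xtol ≤ 1e−9`);
  results are bracket-independent whenever both brackets contain the same
  sign change.
* Ties: β_t = 1 strictly when age < pension age (onset at the pension age
  means zero patient productivity loss); horizon halves round up; integer
  threshold scans report the first failing value, not the last passing one.

## Problem sizes

Every quantity is computed on its natural problem size — trajectories of at
most ~100 yearly records, grids of 180 cells — so all analyses, the full
test suite and the reproduction script complete in seconds.

## Known limitations

* Deterministic cohort-of-one model: no stochastic survival, no
  probabilistic sensitivity analysis, no Markov/agent-based extension, and
  single (effectively unilateral, complication-free) surgery.
* The cost-effectiveness thresholds follow the GDP-multiple convention;
  the GDP comparator is not discounted over time and no equity weighting is
  applied.
* Exact corridor boundary ages depend on the full national life table; with
  the six default anchors they are reproducible only qualitatively.
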