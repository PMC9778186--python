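# cataract-ce

A deterministic lifetime cost-effectiveness model of cataract surgery in
low-income settings, for health economists and eye-care program planners
who need to answer: *at which onset ages and surgery timings is cataract
surgery cost-saving, and where it is not, what does a QALY cost?*

## The model

An untreated patient with onset age *a* progresses on a yearly grid through
mild/moderate impairment (`t_m` years), severe impairment (`t_s` years) and
blindness until death.  Each year carries treatment cost, patient
productivity loss (only below pension age `P`, indicator β_t) and caregiver
productivity loss, plus a quality-of-life weight.  A single surgery at age
*s* costs `CS` and ends all disease flows, restoring quality `Qo`.  Flows
fall at the start of each year and are discounted to the onset age:

    NPV = Σ_t flow(t) · (1 + r/100)^(−t)

The horizon runs to the (rounded) life expectancy at the surgery age, shared
by both arms.  Comparing the arms yields the **cost saving** (without-total
minus with-total), the **QALY gain**, and — where the surgery is not
cost-saving — the **ICER** = additional cost / QALY gain, classified as
highly cost-effective (≤ 1·GDP p.c.), cost-effective (≤ 2·GDP p.c.) or not
cost-effective.

On top of the pair evaluation the package provides a ±50 % tornado
analysis, parameter threshold search (bisection / integer scan for the
value at which a case leaves a corridor), an internal-rate-of-return solver
(the discount rate zeroing the saving) and the onset-age × surgery-timing
corridor grid.  See `docs/methods.md` for conventions and numerical
details.

## Worked example

Evaluate the baseline scenario — onset at 50, surgery at the start of the
severe stage (age 60), default low-income parameters:

```
$ cataract-ce evaluate --policy at_severe_start --onset-age 50
                   quantity without_surgery with_surgery
                  treatment          217.97       162.16
  productivity_loss_patient          445.93       445.93
productivity_loss_caregiver         1384.54         0.00
             cost_operation            0.00       193.38
                 total_cost         2048.45       801.47
       quality_of_life_qaly            9.59        12.22
                cost_saving             NaN      1246.98
               benefit_qaly             NaN         2.63
          icer_usd_per_qaly             NaN          NaN
                   corridor                  cost_saving
```

Without surgery the patient's discounted lifetime cost is 2048.45 USD —
dominated by the caregiver's opportunity cost during the 12 blind years —
against 801.47 USD with surgery: the operation *saves* 1246.98 USD while
gaining 2.63 discounted QALYs, so no ICER is needed.  The same library
calls are available in Python:

```python
from cataract_ce import DiseaseCourse, SurgeryPolicy, default_inputs, evaluate_pair
params, life_table = default_inputs()
pair = evaluate_pair(DiseaseCourse(50), SurgeryPolicy("at_severe_start"),
                     life_table, params)
pair.cost_saving   # 1246.98
```

Sensitivity tools work on a case (onset age + policy).  For a 60-year-old
operated in the onset year:

```
$ cataract-ce threshold --parameter cs --onset-age 60 --policy at_onset
parameter,criterion,threshold,...
cs,cost_saving_zero,629.73,...        # surgery stays cost-saving below ~630 USD

$ cataract-ce roi --onset-age 60
onset_age,policy,rate_percent,status
60,at_onset,12.73,solved              # saving stays positive up to a 12.73% rate
```

Other subcommands: `tornado` (one-way sensitivity ranking), `corridor`
(grid over onset 40–99 × three timing policies).  All accept `--config
FILE` (YAML parameters + life-table anchors, see
`cataract_ce.io.write_config`), `--set KEY=VALUE` overrides and
`--format csv|json`.

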