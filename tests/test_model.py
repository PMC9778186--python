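"""Unit and property tests for the core lifetime-cost model."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cataract_ce import (
    Conventions,
    DiseaseCourse,
    GeneratorConfig,
    LifeTable,
    ModelParameters,
    ParameterError,
    PolicyError,
    SurgeryPolicy,
    build_trajectory,
    discount_weight,
    evaluate_arm,
    npv_caregiver,
    npv_patient_productivity,
    npv_qalys,
    npv_surgery,
    npv_treatment,
    random_life_table,
    random_parameters,
)
from conftest import annuity_due, npv_brute, segment_npv

NO_SURGERY = SurgeryPolicy("none")


class TestDiscountWeight:
    @pytest.mark.parametrize(
        "r, t, expected",
        [(5, 0, 1.0), (5, 10, 1.05**-10), (0, 7, 1.0), (100, 1, 0.5)],
    )
    def test_matches_direct_power(self, r, t, expected):
        assert discount_weight(r, t) == pytest.approx(expected, rel=1e-12)

    def test_rejects_rate_at_or_below_minus_100(self):
        with pytest.raises(ParameterError):
            discount_weight(-100, 1)

    def test_rejects_negative_or_fractional_year(self):
        with pytest.raises(ParameterError):
            discount_weight(5, -1)
        with pytest.raises(ParameterError):
            discount_weight(5, 1.5)


class TestParameterValidation:
    @pytest.mark.parametrize(
        "bad",
        [dict(cs=-1), dict(gdp=-5), dict(r=-100), dict(qm=1.2), dict(qb=-0.1),
         dict(qo=0.4, qb=0.5), dict(t_m=-1), dict(t_m=2.5)],
    )
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ParameterError):
            ModelParameters(**bad)

    def test_gdp_rescaling_sets_loss_fractions(self, params):
        p = params.with_gdp(2200.0)
        assert (p.cpm, p.cps, p.cpb) == (110.0, 660.0, 1320.0)
        assert (p.ccm, p.ccs, p.ccb) == (0.0, 110.0, 550.0)


class TestLifeTable:
    def test_interpolates_between_anchors(self, life_table):
        assert life_table.expected_death_age(60) == 77.0
        assert life_table.expected_death_age(70) == pytest.approx(80.65)

    def test_extrapolates_below_first_anchor_segment(self, life_table):
        # slope of the (60,77)-(65,78.8) segment is 0.36
        assert life_table.expected_death_age(55) == pytest.approx(77 - 5 * 0.36)

    def test_clamps_to_one_remaining_year(self, life_table):
        # raw extrapolation above 92 has slope 0.5 and drops below age+1
        assert life_table.expected_death_age(95, clamp=False) == pytest.approx(94.5)
        assert life_table.expected_death_age(95) == 96.0

    @pytest.mark.parametrize(
        "anchors",
        [[], [(60, 60)], [(60, 77), (60, 78)], [(60, 77), (65, 76)]],
    )
    def test_invalid_anchor_sets_rejected(self, anchors):
        with pytest.raises(ParameterError):
            LifeTable(anchors)

    def test_horizon_end_rounds_half_up(self):
        assert LifeTable([(60, 77.0)]).horizon_end(60) == 77
        assert LifeTable([(60, 77.5)]).horizon_end(60) == 78
        assert LifeTable([(60, 77.4)]).horizon_end(60) == 77


class TestTrajectory:
    def test_baseline_stage_schedule(self, params, life_table):
        traj = build_trajectory(DiseaseCourse(50), NO_SURGERY, life_table,
                                params, horizon_end=77)
        states = [rec.state for rec in traj.records]
        assert len(traj) == 27
        assert states == ["mild"] * 10 + ["severe"] * 5 + ["blind"] * 12
        assert [rec.pensionable for rec in traj.records] == [1] * 10 + [0] * 17

    def test_late_onset_never_reaches_severe_stage(self, params, life_table):
        # onset at 80 with 5 remaining years stays mild throughout
        traj = build_trajectory(DiseaseCourse(80), NO_SURGERY, life_table, params)
        assert [rec.state for rec in traj.records] == ["mild"] * 5

    def test_post_operative_years_have_no_flows_and_restored_quality(
            self, params, life_table):
        traj = build_trajectory(DiseaseCourse(50), SurgeryPolicy("at_severe_start"),
                                life_table, params)
        post = [rec for rec in traj.records if rec.age >= 60]
        assert len(post) == 17
        assert all(rec.state == "post_op" for rec in post)
        assert all(rec.treatment == rec.patient_loss == rec.caregiver_loss == 0
                   for rec in post)
        assert all(rec.quality == params.qo for rec in post)

    def test_blind_treatment_flow_follows_convention(self, params, life_table):
        course = DiseaseCourse(50)
        default = build_trajectory(course, NO_SURGERY, life_table, params)
        assert default.records[-1].treatment == 0.0
        literal = build_trajectory(course, NO_SURGERY, life_table, params,
                                   Conventions(include_blind_treatment=True))
        assert literal.records[-1].treatment == params.ctb

    def test_invalid_policies_rejected(self, params, life_table):
        with pytest.raises(PolicyError):
            build_trajectory(DiseaseCourse(50), SurgeryPolicy("at_age", 45),
                             life_table, params)
        with pytest.raises(PolicyError):
            build_trajectory(DiseaseCourse(50), SurgeryPolicy("at_age", 95),
                             life_table, params, horizon_end=77)


class TestNetValues:
    """Each NPV operation against the closed-form annuity-due oracle."""

    def test_treatment_both_arms(self, params, life_table):
        course = DiseaseCourse(50)
        wo = build_trajectory(course, NO_SURGERY, life_table, params, horizon_end=77)
        w = build_trajectory(course, SurgeryPolicy("at_severe_start"),
                             life_table, params, horizon_end=77)
        assert npv_treatment(wo, params) == pytest.approx(217.97, abs=5e-3)
        assert npv_treatment(w, params) == pytest.approx(162.16, abs=5e-3)
        assert npv_treatment(wo, params) == pytest.approx(
            20 * annuity_due(15, 5), rel=1e-12)

    def test_treatment_with_blind_stage_included(self, params, life_table):
        traj = build_trajectory(DiseaseCourse(50), NO_SURGERY, life_table, params,
                                Conventions(include_blind_treatment=True),
                                horizon_end=77)
        assert npv_treatment(traj, params) == pytest.approx(
            20 * annuity_due(27, 5), rel=1e-12)
        assert npv_treatment(traj, params) == pytest.approx(307.50, abs=5e-3)

    def test_patient_productivity_stops_at_pension(self, params, life_table):
        course = DiseaseCourse(50)
        traj = build_trajectory(course, NO_SURGERY, life_table, params, horizon_end=77)
        assert npv_patient_productivity(traj, params) == pytest.approx(
            55 * annuity_due(10, 5), rel=1e-12)
        late = build_trajectory(DiseaseCourse(60), NO_SURGERY, life_table, params)
        assert npv_patient_productivity(late, params) == 0.0

    def test_partial_pre_pension_window(self, params, life_table):
        # onset 55, pension 60: exactly 5 pre-pension mild years accrue
        traj = build_trajectory(DiseaseCourse(55), NO_SURGERY, life_table, params)
        expected = params.cpm * annuity_due(5, params.r)
        assert npv_patient_productivity(traj, params) == pytest.approx(expected, rel=1e-12)
        brute = npv_brute([rec.patient_loss for rec in traj.records], params.r)
        assert npv_patient_productivity(traj, params) == pytest.approx(brute, rel=1e-12)

    def test_caregiver_piecewise_segments(self, params, life_table):
        traj = build_trajectory(DiseaseCourse(50), NO_SURGERY, life_table, params,
                                horizon_end=77)
        expected = segment_npv([(10, 15, 55.0), (15, 27, 275.0)], 5)
        assert npv_caregiver(traj, params) == pytest.approx(expected, rel=1e-12)
        assert npv_caregiver(traj, params) == pytest.approx(1384.54, abs=5e-3)
        zero = dataclasses.replace(params, ccm=0, ccs=0, ccb=0)
        traj0 = build_trajectory(DiseaseCourse(50), NO_SURGERY, life_table, zero,
                                 horizon_end=77)
        assert npv_caregiver(traj0, zero) == 0.0

    def test_surgery_discount_conventions(self, params, life_table):
        course = DiseaseCourse(50)
        policy = SurgeryPolicy("at_severe_start")
        assert npv_surgery(course, policy, params) == pytest.approx(
            300 * 1.05**-9, rel=1e-12)
        assert npv_surgery(course, policy, params) == pytest.approx(193.38, abs=5e-3)
        literal = Conventions(surgery_discount_convention="literal")
        assert npv_surgery(course, policy, params, literal) == pytest.approx(
            300 * 1.05**-10, rel=1e-12)
        # onset-year surgery is undiscounted under either convention
        at_onset = SurgeryPolicy("at_onset")
        assert npv_surgery(course, at_onset, params) == 300.0
        assert npv_surgery(course, at_onset, params, literal) == 300.0
        assert npv_surgery(course, NO_SURGERY, params) == 0.0
        free = dataclasses.replace(params, cs=0)
        assert npv_surgery(course, policy, free) == 0.0

    def test_qalys_both_arms(self, params, life_table):
        course = DiseaseCourse(50)
        wo = build_trajectory(course, NO_SURGERY, life_table, params, horizon_end=77)
        w = build_trajectory(course, SurgeryPolicy("at_severe_start"),
                             life_table, params, horizon_end=77)
        expected_wo = segment_npv([(0, 10, 0.7), (10, 15, 0.6), (15, 27, 0.5)], 5)
        assert npv_qalys(wo, params) == pytest.approx(expected_wo, rel=1e-12)
        assert npv_qalys(wo, params) == pytest.approx(9.59, abs=5e-3)
        assert npv_qalys(w, params) == pytest.approx(12.22, abs=5e-3)

    def test_full_health_zero_rate_counts_years(self, life_table):
        p = ModelParameters(r=0, qm=1, qs=1, qb=1, qo=1)
        traj = build_trajectory(DiseaseCourse(50), NO_SURGERY, life_table, p,
                                horizon_end=77)
        assert npv_qalys(traj, p) == pytest.approx(27.0, rel=1e-12)


def _draw_inputs(seed):
    rng = np.random.default_rng(seed)
    cfg = GeneratorConfig(seed=seed)
    params = random_parameters(cfg, rng)
    table = random_life_table(cfg, rng)
    onset = int(rng.integers(40, 100))
    return params, table, onset


@settings(max_examples=60, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_arm_properties_on_random_inputs(seed):
    """Additivity, brute-force oracle equivalence, zero-rate limit and QALY
    bounds hold for randomly generated parameter sets and life tables."""
    params, table, onset = _draw_inputs(seed)
    course = DiseaseCourse(onset)
    arm = evaluate_arm(course, NO_SURGERY, table, params)
    comp_sum = (arm.npv_treatment + arm.npv_patient_productivity
                + arm.npv_caregiver + arm.npv_surgery)
    assert arm.npv_total == pytest.approx(comp_sum, rel=1e-9, abs=1e-12)
    assert arm.npv_total >= 0 and arm.qalys >= 0

    traj = arm.trajectory
    for name, fn in [("treatment", npv_treatment),
                     ("patient_loss", npv_patient_productivity),
                     ("caregiver_loss", npv_caregiver),
                     ("quality", npv_qalys)]:
        brute = npv_brute([getattr(rec, name) for rec in traj.records], params.r)
        assert fn(traj, params) == pytest.approx(brute, rel=1e-9, abs=1e-12)

    n = len(traj)
    assert arm.qalys <= annuity_due(n, params.r) + 1e-9

    zero_rate = dataclasses.replace(params, r=0)
    arm0 = evaluate_arm(course, NO_SURGERY, table, zero_rate)
    undiscounted = sum(rec.treatment + rec.patient_loss + rec.caregiver_loss
                      for rec in arm0.trajectory.records)
    assert arm0.npv_total == pytest.approx(undiscounted, rel=1e-9, abs=1e-9)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**31 - 1),
       r_pair=st.tuples(st.floats(0, 50), st.floats(0, 50)))
def test_npvs_non_increasing_in_discount_rate(seed, r_pair):
    params, table, onset = _draw_inputs(seed)
    r_lo, r_hi = sorted(r_pair)
    course = DiseaseCourse(onset)
    lo = evaluate_arm(course, NO_SURGERY, table,
                      dataclasses.replace(params, r=r_lo))
    hi = evaluate_arm(course, NO_SURGERY, table,
                      dataclasses.replace(params, r=r_hi))
    for attr in ("npv_treatment", "npv_patient_productivity",
                 "npv_caregiver", "npv_total", "qalys"):
        assert getattr(hi, attr) <= getattr(lo, attr) + 1e-9
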