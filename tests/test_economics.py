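"""Microcosting, discounting, ICER/NMB arithmetic, accounting identities on
the published base-case table, and result-file round trips."""

import math

import numpy as np
import pytest

from screencea.economics import (
    ConsistencyError,
    PhaseError,
    assemble_cea,
    build_phase_schedule,
    compute_icer,
    compute_nmb,
    diagnostic_cost_at_diagnosis,
    discount_factor,
    fp_workup_cost,
    load_published_basecase,
    phase_cost,
    published_incrementals,
    read_results,
    write_results,
)
from screencea.params import EconSettings
from screencea.engine import run_cea


# ---------------------------------------------------------------------------
# phase costs
# ---------------------------------------------------------------------------


def test_phase_cost_single_item_products(smoking_params):
    """Unit-cost x utilization worked examples: lobectomy-class surgery at
    45.1% for stage I post-diagnosis, chest x-ray at 57.5% for stage IV
    post-progression."""
    c = smoking_params.costs
    assert 0.451 * 9310 == pytest.approx(4198.81)
    surgery_part = c.unit_costs["surgery"] * c.utilization["surgery"]["postdiagnosis"]["I"]
    assert surgery_part == pytest.approx(4198.81, abs=1e-9)
    xray_part = c.unit_costs["chest_xray"] * c.utilization["chest_xray"]["postprogression"]["IV"]
    assert xray_part == pytest.approx(13.80, abs=1e-9)


def test_phase_cost_zero_utilization(smoking_params):
    p = smoking_params.copy()
    for iv in p.costs.utilization:
        for ph in p.costs.utilization[iv]:
            for s in p.costs.utilization[iv][ph]:
                p.costs.utilization[iv][ph][s] = 0.0
    assert phase_cost("I", "postdiagnosis", p.costs) == 0.0
    assert phase_cost("IV", "postprogression", p.costs) == 0.0


def test_phase_cost_unknown_stage_or_phase(smoking_params):
    with pytest.raises(PhaseError):
        phase_cost("V", "ongoing", smoking_params.costs)
    with pytest.raises(PhaseError):
        phase_cost("I", "terminal", smoking_params.costs)


def test_diagnostic_bundle_matches_published_scenario_anchor(smoking_params):
    """The stage-I diagnostics/imaging bundle sums to $1,672 - the published
    half-cost scenario prints $836."""
    assert diagnostic_cost_at_diagnosis("I", smoking_params.costs) == pytest.approx(1672.0, abs=0.1)


def test_ongoing_cost_matches_published_scenario_anchors(smoking_params):
    """Per-cycle ongoing costs reproduce the published half-cost scenario
    anchors: stage I $486 (half $243), stage IV $822 (half $411)."""
    sched = build_phase_schedule(smoking_params.costs)
    assert sched.ongoing_per_cycle["I"] == pytest.approx(486.0, abs=1.0)
    assert sched.ongoing_per_cycle["IV"] == pytest.approx(822.0, abs=4.0)


def test_pharma_costs_scale_with_phase_duration(smoking_params):
    """Per-30-day drug costs multiply by the 6-month phase duration."""
    p = smoking_params.copy()
    c = p.costs
    full = phase_cost("IV", "postdiagnosis", c)
    for iv in c.pharmaceuticals:
        for ph in c.utilization.get(iv, {}):
            for s in c.utilization[iv][ph]:
                c.utilization[iv][ph][s] = 0.0
    nonpharma = phase_cost("IV", "postdiagnosis", c)
    pharma_month = sum(
        smoking_params.costs.unit_costs[iv]
        * smoking_params.costs.utilization[iv]["postdiagnosis"]["IV"]
        for iv in smoking_params.costs.pharmaceuticals
    )
    assert full - nonpharma == pytest.approx(6.0 * pharma_month, rel=1e-12)


def test_fp_workup_bundle(smoking_params):
    c = smoking_params.costs
    expected = 0.40 * 507 + 0.50 * 1331 + 0.401 * 601
    assert fp_workup_cost(c) == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# discounting / ICER / NMB
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "t,rate,expected",
    [(0.0, 0.035, 1.0), (1.0, 0.035, 1 / 1.035), (7.0, 0.0, 1.0), (2.0, 0.035, 1.035 ** -2)],
)
def test_discount_factor(t, rate, expected):
    assert discount_factor(t, rate) == pytest.approx(expected, abs=1e-12)


def test_icer_published_worked_examples():
    assert compute_icer(330955103, 23436).rounded == 14122
    assert compute_icer(96708179, 10063).rounded == 9610
    assert compute_icer(96708179, 13299).rounded == 7272
    assert compute_icer(0, 5.0).rounded == 0


def test_icer_undefined_and_dominance():
    u = compute_icer(100.0, 0.0)
    assert u.undefined and u.raw is None
    d = compute_icer(-100.0, 5.0)
    assert d.dominant and d.raw == -20.0
    dd = compute_icer(100.0, -5.0)
    assert dd.dominated


def test_nmb_arithmetic():
    assert compute_nmb(0, 24302, 0) == 0
    assert compute_nmb(10, 24302, 100000) == pytest.approx(143020)
    nmb = compute_nmb(23436, 24302, 330955103)
    assert nmb == pytest.approx(238587630, rel=1e-4)  # printed value has unrounded internals


# ---------------------------------------------------------------------------
# published-table accounting identities
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def published():
    return published_incrementals()


def test_published_icers_reproduced_from_arm_differences(published):
    assert published["smoking"].icer_per_qaly.rounded == 14122
    assert published["nonsmoking"].icer_per_qaly.rounded == 9610
    assert published["nonsmoking"].icer_per_lyg.rounded == 7272


def test_published_incremental_counts(published):
    s = published["smoking"]
    assert s.incr_diagnoses == 1017
    assert s.deaths_averted == 1580
    assert s.stage_iv_averted == 4544
    assert published["nonsmoking"].incr_diagnoses == 1238


def test_published_decomposition_close(published):
    """Printed cost categories sum to the printed totals up to their
    last-digit rounding."""
    for cohort in ("smoking", "nonsmoking"):
        for arm in ("screening", "no_screening"):
            a = getattr(published[cohort], arm)
            parts = a.screening_cost + a.diagnostic_cost + a.treatment_cost
            assert abs(parts - a.total_cost) <= 1.0


# ---------------------------------------------------------------------------
# assembly and result I/O
# ---------------------------------------------------------------------------


def test_assemble_identical_arms_gives_zero_and_undefined_icer(base_cea):
    arm = base_cea["smoking"].screening
    r = assemble_cea(arm, arm, EconSettings(), "smoking")
    assert r.incr_cost == 0 and r.incr_qaly == 0
    assert r.icer_per_qaly.undefined


def test_assemble_rejects_mismatched_cohorts(base_cea):
    import copy

    a = base_cea["smoking"].screening
    b = copy.deepcopy(base_cea["smoking"].no_screening)
    b.n_cohort = a.n_cohort + 1
    with pytest.raises(ConsistencyError):
        assemble_cea(a, b, EconSettings())


def test_dominance_flag_set_when_cheaper_and_better(base_cea):
    import copy

    better = copy.deepcopy(base_cea["smoking"].screening)
    worse = copy.deepcopy(base_cea["smoking"].no_screening)
    better.total_cost = worse.total_cost - 1000.0
    better.qaly_disc = worse.qaly_disc + 10.0
    r = assemble_cea(better, worse, EconSettings())
    assert r.icer_per_qaly.dominant


def test_model_cost_decomposition_exact(base_cea):
    for res in base_cea.values():
        for arm in (res.screening, res.no_screening):
            parts = arm.screening_cost + arm.diagnostic_cost + arm.treatment_cost
            assert parts == pytest.approx(arm.total_cost, abs=1e-6)
            assert arm.treatment_cost == pytest.approx(
                math.fsum(arm.treatment_cost_by_stage.values()), abs=1e-6
            )


def test_nmb_sign_consistent_with_icer(base_cea):
    for res in base_cea.values():
        assert res.incr_qaly > 0
        for wtp, nmb in ((res.wtp_low, res.nmb_low), (res.wtp_high, res.nmb_high)):
            assert (nmb > 0) == (res.icer_per_qaly.raw < wtp)


def test_discounting_reduces_totals(base_cea):
    for res in base_cea.values():
        for arm in (res.screening, res.no_screening):
            assert arm.ly_disc < arm.ly_undisc
            assert arm.qaly_disc < arm.qaly_undisc


def test_write_read_roundtrip_bitexact(tmp_path, base_cea):
    path = tmp_path / "cea.csv"
    write_results(base_cea["smoking"], path)
    back = read_results(path)
    assert back == base_cea["smoking"]
    # writing the re-read result reproduces the file bytes
    path2 = tmp_path / "cea2.csv"
    write_results(back, path2)
    assert path.read_bytes() == path2.read_bytes()


def test_written_icer_equals_computed_ratio(tmp_path, base_cea):
    res = base_cea["nonsmoking"]
    path = tmp_path / "cea.csv"
    write_results(res, path)
    back = read_results(path)
    assert back.icer_per_qaly.raw == res.incr_cost / res.incr_qaly


def test_write_results_zero_incrementals(tmp_path, base_cea):
    arm = base_cea["smoking"].screening
    r = assemble_cea(arm, arm, EconSettings(), "smoking")
    path = tmp_path / "zero.csv"
    write_results(r, path)
    back = read_results(path)
    assert back.incr_cost == 0.0 and back.icer_per_qaly.undefined
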