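"""Hazard calibration, exact transition matrices, Markov engine vs the
continuous-time closed form, and incidence calibration."""

import math

import numpy as np
import pytest

from screencea.disease import (
    CalibrationError,
    CalibratedHazards,
    base_transition_matrix,
    build_transition_matrix,
    calibrate_hazards,
    calibrate_incidence,
    calibrate_stage,
    expand_chain_matrix,
    implied_targets,
    life_years,
    os_two_compartment,
    run_arm,
)
from screencea.params import STAGES, SurvivalTargets
from screencea.screening import run_screening_program
from screencea.disease import run_markov


def test_progression_rate_closed_form(smoking_params):
    """Stage IV: a = -ln(0.3829) per year."""
    a, b = calibrate_stage(0.3829, 0.0482)
    assert a == pytest.approx(-math.log(0.3829), abs=1e-12)
    assert a == pytest.approx(0.9600, abs=1e-4)
    assert os_two_compartment(5.0, a, b) == pytest.approx(0.0482, abs=1e-8)


def test_calibration_no_event_limit():
    a, b = calibrate_stage(1.0 - 1e-13, 1.0 - 1e-13)
    assert a == 0.0 and b == 0.0


def test_calibration_parameter_recovery():
    """Simulate anchors from known (a*, b*), recalibrate, recover."""
    for a_true, b_true in [(0.3, 0.5), (0.9, 1.2), (0.05, 0.02), (0.7, 0.7)]:
        pfs = math.exp(-a_true)
        os5 = os_two_compartment(5.0, a_true, b_true)
        a, b = calibrate_stage(pfs, os5)
        assert a == pytest.approx(a_true, abs=1e-6)
        assert b == pytest.approx(b_true, abs=1e-6)


def test_calibration_infeasible_target_names_stage():
    # with 1-y PFS 0.99 the achievable 5-y OS lies above the b->inf floor
    # exp(-5a) ~ 0.951; a target of 0.5 sits below it, hence unattainable
    # even with instant post-progression death
    bad = SurvivalTargets(
        os5y_by_stage={"I": 0.5, "II": 0.3772, "III": 0.1536, "IV": 0.0482},
        pfs1y_by_stage={"I": 0.99, "II": 0.7203, "III": 0.4915, "IV": 0.3829},
    )
    with pytest.raises(CalibrationError, match="stage I"):
        calibrate_hazards(bad)
    clipped = calibrate_hazards(bad, clip=True)
    assert clipped.lambda_death_postprogression["I"] >= 100


def test_calibration_idempotent_fixed_point(smoking_params):
    h1 = calibrate_hazards(smoking_params.survival)
    h2 = calibrate_hazards(implied_targets(h1))
    for s in STAGES:
        assert h2.lambda_progression[s] == pytest.approx(h1.lambda_progression[s], abs=1e-6)
        assert h2.lambda_death_postprogression[s] == pytest.approx(
            h1.lambda_death_postprogression[s], abs=1e-6
        )


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------


def test_zero_hazards_give_identity():
    M = base_transition_matrix(0.0, 0.0, 0.0, 0.25)
    assert np.allclose(M, np.eye(4), atol=1e-15)


def test_single_cause_exit_probability():
    """lambda = ln2 / year over a 3-month cycle: exit 1 - 2^(-1/4)."""
    M = base_transition_matrix(0.0, math.log(2.0), 0.0, 0.25)
    assert M[1, 2] == pytest.approx(1.0 - 2.0 ** (-0.25), abs=1e-12)


def test_rows_stochastic_for_random_hazards():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        a, b, mu = rng.uniform(0.0, 3.0, size=3)
        M = base_transition_matrix(a, b, mu, 0.25)
        assert np.all(M >= -1e-15)
        assert np.abs(M.sum(axis=1) - 1.0).max() < 1e-12
        # dead states absorbing; no post -> pre transition
        assert M[1, 0] == 0.0 and M[2, 2] == 1.0 and M[3, 3] == 1.0


def test_build_transition_matrix_uses_life_table(smoking_params, smoking_hazards):
    M = build_transition_matrix(
        smoking_hazards, "I", 70.0, smoking_params.life_table, 3.0
    )
    mu = smoking_params.life_table.annual_hazard(70.0)
    a = smoking_hazards.lambda_progression["I"]
    assert M[0, 0] == pytest.approx(math.exp(-(a + mu) * 0.25), abs=1e-15)
    # ages beyond the table reuse the terminal hazard
    M_hi = build_transition_matrix(smoking_hazards, "I", 130.0, smoking_params.life_table, 3.0)
    M_term = build_transition_matrix(smoking_hazards, "I", 100.0, smoking_params.life_table, 3.0)
    assert np.allclose(M_hi, M_term, atol=1e-15)


def test_matrix_matches_continuous_generator_exactly():
    """The one-cycle matrix must equal expm(Q dt) of the continuous
    three-state generator (incl. the within-cycle progress-then-die path)."""
    from scipy.linalg import expm

    rng = np.random.default_rng(11)
    for _ in range(50):
        a, b, mu = rng.uniform(0.0, 2.5, size=3)
        Q = np.array(
            [
                [-(a + mu), a, 0.0, mu],
                [0.0, -(b + mu), b, mu],
                [0.0, 0.0, 0.0, 0.0],
                [0.0, 0.0, 0.0, 0.0],
            ]
        )
        assert np.allclose(base_transition_matrix(a, b, mu, 0.25), expm(Q * 0.25), atol=1e-12)


# ---------------------------------------------------------------------------
# Markov engine
# ---------------------------------------------------------------------------


def _simulate_stage(h: CalibratedHazards, stage: str, n_cycles: int) -> np.ndarray:
    """Occupancy of one diagnosed person with no background mortality."""
    P = expand_chain_matrix(
        base_transition_matrix(
            h.lambda_progression[stage], h.lambda_death_postprogression[stage], 0.0, 0.25
        )
    )
    v = np.zeros(8)
    v[0] = 1.0
    out = [v]
    for _ in range(n_cycles):
        v = v @ P
        out.append(v)
    return np.array(out)


def test_markov_reproduces_calibration_targets(smoking_params, smoking_hazards):
    """Calibrate, simulate with no background mortality: 5-y OS and 1-y
    PFS at the cycle boundaries reproduce the printed anchors to 1e-6."""
    for s in STAGES:
        occ = _simulate_stage(smoking_hazards, s, 20)
        os5 = occ[20, :6].sum()
        pfs1 = occ[4, :3].sum()
        assert os5 == pytest.approx(smoking_params.survival.os5y_by_stage[s], abs=1e-6)
        assert pfs1 == pytest.approx(smoking_params.survival.pfs1y_by_stage[s], abs=1e-6)


def test_markov_matches_two_compartment_closed_form():
    """100 random hazard sets: chain occupancy at every cycle boundary
    equals the analytic two-compartment solution."""
    rng = np.random.default_rng(3)
    for _ in range(100):
        a, b = rng.uniform(0.01, 2.0, size=2)
        h = CalibratedHazards({"I": a, "II": a, "III": a, "IV": a},
                              {"I": b, "II": b, "III": b, "IV": b})
        occ = _simulate_stage(h, "I", 40)
        for k in (1, 4, 10, 20, 40):
            t = 0.25 * k
            surv = occ[k, :6].sum()
            pre = occ[k, :3].sum()
            assert surv == pytest.approx(os_two_compartment(t, a, b), abs=1e-10)
            assert pre == pytest.approx(math.exp(-a * t), abs=1e-10)


def test_pure_death_cohort_halves_in_four_cycles():
    h = CalibratedHazards(
        {s: 0.0 for s in STAGES}, {s: 0.0 for s in STAGES}
    )
    # model a pure-death compartment via the post-progression state
    P = base_transition_matrix(0.0, math.log(2.0), 0.0, 0.25)
    v = np.array([0.0, 1.0, 0.0, 0.0])
    for _ in range(4):
        v = v @ P
    assert v[1] == pytest.approx(0.5, abs=1e-9)


def test_markov_constant_with_zero_hazards(smoking_params):
    h = CalibratedHazards({s: 0.0 for s in STAGES}, {s: 0.0 for s in STAGES})
    p = smoking_params.copy()
    p.life_table = type(p.life_table)(
        ages=p.life_table.ages, qx=tuple(1e-15 for _ in p.life_table.qx)
    )
    prog = run_screening_program(p, 1000.0, 0.0, arm="none", n_cycles=40)
    trace = run_markov(p, h, prog)
    assert trace.undiagnosed[0] == pytest.approx(1000.0)
    assert trace.undiagnosed[-1] == pytest.approx(1000.0, abs=1e-6)


def test_cohort_mass_conserved_each_cycle(smoking_params, smoking_hazards):
    n0 = 112023.0
    h = calibrate_incidence(18680.0, n0, smoking_params)
    for arm in ("screening", "none"):
        trace = run_arm(smoking_params, smoking_hazards, h, n0, arm)
        for t in range(trace.n_cycles + 1):
            assert trace.total_mass(t) == pytest.approx(n0, abs=1e-6)
            assert trace.occupancy[t].min() >= -1e-12


# ---------------------------------------------------------------------------
# incidence calibration
# ---------------------------------------------------------------------------


def test_calibrate_incidence_zero_target(smoking_params):
    assert calibrate_incidence(0.0, 1000.0, smoking_params) == 0.0


def test_calibrate_incidence_recovers_known_hazard(smoking_params):
    """Self-consistency: run the no-screening model at a known hazard, use
    its diagnosis total as the target, recover the hazard."""
    h_true = 1.7e-3
    prog = run_screening_program(smoking_params, 1000.0, h_true, arm="none")
    target = prog.clinical_detected.sum()
    h = calibrate_incidence(target, 1000.0, smoking_params)
    assert h == pytest.approx(h_true, abs=1e-8)


def test_calibrate_incidence_fixture_target_monotone(smoking_params):
    h1 = calibrate_incidence(18680.0, 112023.0, smoking_params)
    h2 = calibrate_incidence(25000.0, 112023.0, smoking_params)
    assert 0.0 < h1 < h2 < 1.0


def test_calibrate_incidence_unattainable(smoking_params):
    with pytest.raises(CalibrationError):
        calibrate_incidence(-5.0, 100.0, smoking_params)
    with pytest.raises(CalibrationError):
        calibrate_incidence(200.0, 100.0, smoking_params)


# ---------------------------------------------------------------------------
# life years
# ---------------------------------------------------------------------------


def _immortal_trace(smoking_params, n_cycles):
    p = smoking_params.copy()
    p.life_table = type(p.life_table)(
        ages=p.life_table.ages, qx=tuple(1e-300 for _ in p.life_table.qx)
    )
    h = CalibratedHazards({s: 0.0 for s in STAGES}, {s: 0.0 for s in STAGES})
    prog = run_screening_program(p, 1.0, 0.0, arm="none", n_cycles=n_cycles)
    return run_markov(p, h, prog)


def test_life_years_immortal_cohort(smoking_params):
    trace = _immortal_trace(smoking_params, 40)
    undisc, disc = life_years(trace, 0.0)
    assert undisc == pytest.approx(10.0, abs=1e-9)
    assert disc == pytest.approx(10.0, abs=1e-9)


def test_life_years_discounted_annuity_oracle(smoking_params):
    """Discounted LY of an immortal person equals the closed-form geometric
    series sum((1.035)^(-t_k) * dt)."""
    trace = _immortal_trace(smoking_params, 40)
    _, disc = life_years(trace, 0.035)
    expected = sum(1.035 ** (-0.25 * k) * 0.25 for k in range(40))
    assert disc == pytest.approx(expected, abs=1e-9)
    # half-cycle correction discounts at cycle midpoints
    _, disc_hcc = life_years(trace, 0.035, half_cycle_correction=True)
    expected_hcc = sum(1.035 ** (-0.25 * (k + 0.5)) * 0.25 for k in range(40))
    assert disc_hcc == pytest.approx(expected_hcc, abs=1e-9)


def test_life_years_empty_cohort(smoking_params):
    p = smoking_params.copy()
    h = CalibratedHazards({s: 0.0 for s in STAGES}, {s: 0.0 for s in STAGES})
    prog = run_screening_program(p, 0.0, 0.0, arm="none", n_cycles=20)
    trace = run_markov(p, h, prog)
    assert life_years(trace, 0.035) == (0.0, 0.0)
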