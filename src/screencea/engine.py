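"""End-to-end orchestration: size the arm, calibrate hazards and the
incidence rate, run both arms of the Markov model, and assemble the
cost-effectiveness result."""

from __future__ import annotations

from dataclasses import dataclass, field

from . import funnel
from .disease import (
    CalibratedHazards,
    calibrate_hazards,
    calibrate_incidence,
    run_arm,
)
from .economics import (
    ArmResult,
    CEAResult,
    PhaseCostSchedule,
    accumulate,
    assemble_cea,
    build_phase_schedule,
)
from .params import ModelParameters


@dataclass
class RunOptions:
    """Engine-level knobs that sit outside the parameter pack."""

    horizon_years: float | None = None      # None = lifetime (to age 100)
    bg_multiplier: float = 1.0              # background-mortality scaling
    #: multiplicative scalings of cost bundles, e.g. {"diagnostic": {"I": 0.5}}
    cost_scales: dict[str, dict[str, float]] = field(default_factory=dict)
    #: clip infeasible survival anchors to the model boundary instead of
    #: raising (sensitivity analyses only)
    calibration_clip: bool = False


def arm_size(params: ModelParameters) -> int:
    """Screened persons for this cohort (eligibility x uptake, half-even
    rounding at each published milestone)."""
    epi = params.epidemiology
    if params.cohort_label == "smoking":
        eligible = funnel.eligible_smokers(
            int(epi.eligible_current_smokers), int(epi.eligible_ex_smokers)
        )
    else:
        eligible = funnel.eligible_nonsmokers(
            int(epi.nonsmoking_pool), epi.nonsmoker_high_risk_fraction
        )
    return funnel.screened_population(eligible, epi.uptake)


def _scaled_schedule(params: ModelParameters, options: RunOptions) -> PhaseCostSchedule:
    sched = build_phase_schedule(params.costs, params.econ.cycle_length_months)
    maps = {
        "diagnostic": sched.diagnostic_at_diagnosis,
        "postdiagnosis": sched.postdiagnosis_bundle,
        "ongoing": sched.ongoing_per_cycle,
        "postprogression": sched.postprogression_bundle,
    }
    for bundle, scales in options.cost_scales.items():
        if bundle not in maps:
            raise KeyError(f"unknown cost bundle {bundle!r}")
        for stage, f in scales.items():
            maps[bundle][stage] = maps[bundle][stage] * f
    return sched


def run_cea(
    params: ModelParameters,
    options: RunOptions | None = None,
    *,
    hazards: CalibratedHazards | None = None,
) -> CEAResult:
    """Base-case (or overridden) cost-effectiveness analysis for one cohort.

    The stage-specific hazards are calibrated to the pack's survival
    anchors; the per-cycle diagnosis hazard is calibrated so the
    no-screening arm reproduces the pack's lifetime-diagnoses anchor as a
    fraction of its reference arm size (so results per person - and the
    ICER - are invariant to uptake).
    """
    options = options or RunOptions()
    n0 = arm_size(params)
    if hazards is None:
        hazards = calibrate_hazards(params.survival, clip=options.calibration_clip)
    epi = params.epidemiology
    h_cycle = calibrate_incidence(
        epi.target_diagnoses / epi.target_arm_size * n0,
        n0,
        params,
        bg_multiplier=options.bg_multiplier,
    )
    sched = _scaled_schedule(params, options)
    arms: dict[str, ArmResult] = {}
    for arm_name in ("screening", "none"):
        trace = run_arm(
            params,
            hazards,
            h_cycle,
            n0,
            arm_name,
            horizon_years=options.horizon_years,
            bg_multiplier=options.bg_multiplier,
        )
        arms[arm_name] = accumulate(
            trace, sched, params.utilities, params.econ, params.costs,
            label=f"{params.cohort_label}:{arm_name}",
        )
    return assemble_cea(arms["screening"], arms["none"], params.econ, params.cohort_label)
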