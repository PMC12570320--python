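"""Three-state disease natural history: hazard calibration to the printed
survival anchors, exact per-cycle transition matrices with competing
background mortality, and the cohort Markov engine.

Survival follows a two-compartment constant-hazard (exponential) model per
stage at diagnosis: pre-progression patients progress at rate ``a`` and
post-progression patients die of lung cancer at rate ``b`` (pre-progression
cancer death is zero; all pre-progression deaths are background).  The two
printed anchors per stage - 1-year progression/disease-free survival and
5-year overall survival - exactly identify ``(a, b)``:

    PFS(t) = exp(-a t)
    OS(t)  = exp(-a t) + a * (exp(-a t) - exp(-b t)) / (b - a)

``a`` is closed-form; ``b`` is found by bracketed root-finding on OS(5y).

Per-cycle transition matrices are the exact one-cycle solution of the
continuous-time generator with the age-specific background hazard added as
a competing risk (including the within-cycle progress-then-die path), so
the 3-month chain reproduces the continuous closed form at cycle
boundaries to machine precision and simulation recovers the calibration
targets exactly.  Rows are completed by residual so they sum to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .params import LifeTable, ModelParameters, STAGES, SCREEN_STAGES, SurvivalTargets
from .screening import ScreeningProgramTrace, run_screening_program

#: expanded chain states; pd0/pd1 are the two post-diagnosis cycles and
#: pp0/pp1 the two post-progression cycles (cost-phase bookkeeping only -
#: clinically they are the pre-/post-progression states)
CHAIN_STATES = ("pd0", "pd1", "pre", "pp0", "pp1", "pp", "dead_lc", "dead_other")
LIVING = (0, 1, 2, 3, 4, 5)
PREPROG = (0, 1, 2)
POSTPROG = (3, 4, 5)
I_DLC, I_DO = 6, 7


class CalibrationError(ValueError):
    pass


@dataclass
class CalibratedHazards:
    """Per-stage annual event rates; ``lambda_death_preprogression`` is zero
    by construction (no pre-progression cancer-death anchor exists)."""

    lambda_progression: dict[str, float]
    lambda_death_postprogression: dict[str, float]
    lambda_death_preprogression: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.lambda_death_preprogression:
            self.lambda_death_preprogression = {s: 0.0 for s in self.lambda_progression}


def os_two_compartment(t: float, a: float, b: float) -> float:
    """Closed-form overall survival of the progress-then-die model."""
    if a <= 0.0:
        return 1.0
    if abs(b - a) < 1e-12 * max(1.0, a):
        return math.exp(-a * t) * (1.0 + a * t)
    return math.exp(-a * t) + a * (math.exp(-a * t) - math.exp(-b * t)) / (b - a)


def calibrate_stage(pfs1y: float, os5y: float, *, clip: bool = False) -> tuple[float, float]:
    """Solve (a, b) from the two survival anchors for one stage.

    ``clip=True`` (used by sensitivity analyses, whose +/-20% perturbations
    can push the anchors outside the exponential model's feasible set)
    returns the boundary solution nearest the target instead of raising.
    """
    if not (0.0 < pfs1y < 1.0) or not (0.0 < os5y < 1.0):
        raise CalibrationError("survival anchors must lie in (0, 1)")
    a = -math.log(pfs1y)
    if a < 1e-12:
        return 0.0, 0.0
    floor = math.exp(-5.0 * a)  # OS at b -> inf: death immediately on progression
    if os5y <= floor:
        if clip:
            return a, 1e3  # effectively instant post-progression death
        raise CalibrationError(
            f"5-y OS target {os5y} unattainable: even instant post-progression "
            f"death gives {floor:.4g} with 1-y PFS {pfs1y}"
        )
    f = lambda b: os_two_compartment(5.0, a, b) - os5y
    if f(0.0) <= 0.0:  # OS target >= 1 at b = 0: no post-progression mortality
        return a, 0.0
    hi = 1.0
    while f(hi) > 0.0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover
            raise CalibrationError("no bracket for post-progression death rate")
    b = brentq(f, 0.0, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
    assert abs(os_two_compartment(5.0, a, b) - os5y) < 1e-8
    return a, float(b)


def calibrate_hazards(targets: SurvivalTargets, *, clip: bool = False) -> CalibratedHazards:
    prog, death = {}, {}
    for s in STAGES:
        try:
            a, b = calibrate_stage(targets.pfs1y_by_stage[s], targets.os5y_by_stage[s], clip=clip)
        except CalibrationError as e:
            raise CalibrationError(f"stage {s}: {e}") from e
        prog[s] = a
        death[s] = b
    return CalibratedHazards(lambda_progression=prog, lambda_death_postprogression=death)


def implied_targets(h: CalibratedHazards) -> SurvivalTargets:
    """Survival anchors implied by a hazard set (calibration inverse)."""
    return SurvivalTargets(
        os5y_by_stage={
            s: os_two_compartment(5.0, h.lambda_progression[s], h.lambda_death_postprogression[s])
            for s in h.lambda_progression
        },
        pfs1y_by_stage={s: math.exp(-h.lambda_progression[s]) for s in h.lambda_progression},
    )


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------


def _intexp(x: float, dt: float) -> float:
    """integral_0^dt exp(-x s) ds, stable at x = 0."""
    if x * dt < 1e-10:
        return dt * (1.0 - 0.5 * x * dt)
    return -math.expm1(-x * dt) / x


def base_transition_matrix(a: float, b: float, mu: float, dt: float) -> np.ndarray:
    """Exact one-cycle 4x4 matrix over (pre, post, dead_lc, dead_other).

    ``a``: progression rate, ``b``: post-progression cancer death rate,
    ``mu``: background all-cause hazard, all per year; ``dt`` years.
    """
    alpha = a + mu
    beta = b + mu
    e_a = math.exp(-alpha * dt)
    e_b = math.exp(-beta * dt)
    if abs(beta - alpha) > 1e-9 * max(1.0, alpha, beta):
        p_pre_pp = a * (e_a - e_b) / (beta - alpha)
        p_pre_dlc = a * b * (_intexp(alpha, dt) - _intexp(beta, dt)) / (beta - alpha)
    else:
        p_pre_pp = a * dt * e_a
        # d/dx of -intexp at x = alpha
        p_pre_dlc = a * b * (_intexp(alpha, dt) * dt - dt * dt * e_a) / max(alpha * dt, 1e-30) \
            if alpha > 0 else 0.0
    p_pp_dlc = b * _intexp(beta, dt)
    M = np.zeros((4, 4))
    M[0, 0] = e_a
    M[0, 1] = p_pre_pp
    M[0, 2] = p_pre_dlc
    M[0, 3] = 1.0 - e_a - p_pre_pp - p_pre_dlc
    M[1, 1] = e_b
    M[1, 2] = p_pp_dlc
    M[1, 3] = 1.0 - e_b - p_pp_dlc
    M[2, 2] = 1.0
    M[3, 3] = 1.0
    return M


def build_transition_matrix(
    h: CalibratedHazards,
    stage: str,
    age: float,
    lt: LifeTable,
    cycle_length_months: float,
    bg_multiplier: float = 1.0,
) -> np.ndarray:
    """Row-stochastic 4x4 matrix (pre, post, dead_lc, dead_other) for one
    stage, one cycle, one age.  Ages beyond the table reuse the terminal
    hazard (never extrapolated)."""
    if stage not in h.lambda_progression:
        raise KeyError(f"unknown stage {stage!r}")
    mu = bg_multiplier * lt.annual_hazard(age)
    return base_transition_matrix(
        h.lambda_progression[stage],
        h.lambda_death_postprogression[stage],
        mu,
        cycle_length_months / 12.0,
    )


def expand_chain_matrix(M: np.ndarray) -> np.ndarray:
    """Lift the 4x4 clinical matrix onto the 8-state phase-tracking chain."""
    P = np.zeros((8, 8))
    for i, nxt in ((0, 1), (1, 2), (2, 2)):  # pd0 -> pd1 -> pre -> pre
        P[i, nxt] = M[0, 0]
        P[i, 3] = M[0, 1]      # progression enters pp0
        P[i, I_DLC] = M[0, 2]
        P[i, I_DO] = M[0, 3]
    for i, nxt in ((3, 4), (4, 5), (5, 5)):  # pp0 -> pp1 -> pp -> pp
        P[i, nxt] = M[1, 1]
        P[i, I_DLC] = M[1, 2]
        P[i, I_DO] = M[1, 3]
    P[I_DLC, I_DLC] = 1.0
    P[I_DO, I_DO] = 1.0
    return P


# ---------------------------------------------------------------------------
# cohort trace and Markov engine
# ---------------------------------------------------------------------------

MODES = ("screen", "clinical")


@dataclass
class CohortTrace:
    """Per-cycle expected state occupancy for one arm.

    ``occupancy[t, i_stage, i_mode, i_state]`` covers the diagnosed strata
    (stage at diagnosis x detection mode x chain state); the undiagnosed
    and carcinoma-in-situ strata are carried separately.  Mass is conserved
    every cycle: living + dead across all strata equals the initial cohort.
    """

    entry_age: float
    cycle_years: float
    cohort_n: float
    occupancy: np.ndarray            # [T+1, 4, 2, 8]
    undiagnosed: np.ndarray          # [T+1]
    undiagnosed_dead: np.ndarray     # [T+1] cumulative
    stage0_alive: np.ndarray         # [T+1]
    stage0_dead: np.ndarray          # [T+1] cumulative
    new_diagnoses: np.ndarray        # [T, 4, 2]
    new_stage0: np.ndarray           # [T]
    program: ScreeningProgramTrace

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def age_at(self, t: int) -> float:
        return self.entry_age + t * self.cycle_years

    def total_mass(self, t: int) -> float:
        return float(
            self.occupancy[t].sum()
            + self.undiagnosed[t]
            + self.undiagnosed_dead[t]
            + self.stage0_alive[t]
            + self.stage0_dead[t]
        )

    def living(self, t: int) -> float:
        return float(
            self.occupancy[t, :, :, LIVING].sum() + self.undiagnosed[t] + self.stage0_alive[t]
        )

    def diagnoses_by_stage(self) -> dict[str, float]:
        out = {s: float(self.new_diagnoses[:, i, :].sum()) for i, s in enumerate(STAGES)}
        out["0"] = float(self.new_stage0.sum())
        return out

    def lc_deaths_by_stage(self, t: int | None = None) -> dict[str, float]:
        t = self.n_cycles if t is None else t
        return {s: float(self.occupancy[t, i, :, I_DLC].sum()) for i, s in enumerate(STAGES)}


def run_markov(
    params: ModelParameters,
    hazards: CalibratedHazards,
    program: ScreeningProgramTrace,
    *,
    bg_multiplier: float = 1.0,
) -> CohortTrace:
    """Iterate the cohort over the program's horizon.

    New diagnoses from the screening event stream enter the first
    post-diagnosis state of their (stage, detection-mode) stratum in their
    diagnosis cycle; the undiagnosed stratum's background mortality and
    depletion were already applied by the screening program.
    """
    T = program.n_cycles
    dt = params.econ.cycle_years
    entry = params.epidemiology.mean_entry_age
    lt = params.life_table

    # cache expanded matrices per (stage, integer age)
    cache: dict[tuple[str, int], np.ndarray] = {}

    def chain_matrix(stage: str, age: float) -> np.ndarray:
        key = (stage, int(math.floor(age)))
        if key not in cache:
            cache[key] = expand_chain_matrix(
                build_transition_matrix(hazards, stage, age, lt, params.econ.cycle_length_months, bg_multiplier)
            )
        return cache[key]

    occ = np.zeros((T + 1, len(STAGES), len(MODES), 8))
    new_dx = np.zeros((T, len(STAGES), len(MODES)))
    new_s0 = np.zeros(T)
    s0_alive = np.zeros(T + 1)
    s0_dead = np.zeros(T + 1)

    i_s0 = SCREEN_STAGES.index("0")
    s0 = 0.0
    s0_dead_cum = 0.0
    for t in range(T):
        age = entry + t * dt
        # inflows at cycle t: entrants are counted in cycle-t occupancy
        # (matching the program's post-event undiagnosed convention), then
        # everyone transitions into cycle t+1
        for i, s in enumerate(STAGES):
            j = SCREEN_STAGES.index(s)
            new_dx[t, i, 0] = program.screen_detected[t, j]
            new_dx[t, i, 1] = program.clinical_detected[t, i]
        new_s0[t] = program.screen_detected[t, i_s0]
        s0_dead[t] = s0_dead_cum
        s0 += new_s0[t]
        s0_alive[t] = s0
        occ[t, :, 0, 0] += new_dx[t, :, 0]
        occ[t, :, 1, 0] += new_dx[t, :, 1]
        for i, s in enumerate(STAGES):
            P = chain_matrix(s, age)
            occ[t + 1, i] = occ[t, i] @ P
        mu = bg_multiplier * lt.annual_hazard(age)
        surv = math.exp(-mu * dt)
        s0_dead_cum += s0 * (1.0 - surv)
        s0 *= surv
    s0_alive[T] = s0
    s0_dead[T] = s0_dead_cum

    return CohortTrace(
        entry_age=entry,
        cycle_years=dt,
        cohort_n=program.cohort_n,
        occupancy=occ,
        undiagnosed=program.undiagnosed.copy(),
        undiagnosed_dead=program.undiagnosed_deaths.copy(),
        stage0_alive=s0_alive,
        stage0_dead=s0_dead,
        new_diagnoses=new_dx,
        new_stage0=new_s0,
        program=program,
    )


def run_arm(
    params: ModelParameters,
    hazards: CalibratedHazards,
    incidence_hazard: float,
    cohort_n: float,
    arm: str,
    *,
    horizon_years: float | None = None,
    bg_multiplier: float = 1.0,
) -> CohortTrace:
    """Screening program + Markov chain for one arm over one horizon."""
    dt = params.econ.cycle_years
    entry = params.epidemiology.mean_entry_age
    lifetime = (100.0 - entry) / dt
    n_cycles = int(math.ceil(lifetime if horizon_years is None else min(lifetime, horizon_years / dt)))
    program = run_screening_program(
        params, cohort_n, incidence_hazard, arm=arm, n_cycles=n_cycles, bg_multiplier=bg_multiplier
    )
    return run_markov(params, hazards, program, bg_multiplier=bg_multiplier)


# ---------------------------------------------------------------------------
# incidence calibration
# ---------------------------------------------------------------------------


def _lifetime_diagnoses(h: float, mus_cycle_surv: np.ndarray) -> float:
    """Total diagnoses in the no-screening undiagnosed recursion, per person."""
    u = 1.0
    total = 0.0
    for surv in mus_cycle_surv:
        d = u * h
        total += d
        u = (u - d) * surv
    return total


def calibrate_incidence(
    target_lifetime_diagnoses: float,
    cohort_n: float,
    params: ModelParameters,
    *,
    bg_multiplier: float = 1.0,
) -> float:
    """Constant per-cycle diagnosis hazard such that the no-screening arm
    accumulates the target lifetime diagnoses (within 0.1 person)."""
    if target_lifetime_diagnoses == 0.0:
        return 0.0
    if not (0.0 < target_lifetime_diagnoses < cohort_n):
        raise CalibrationError("target must lie strictly between 0 and the cohort size")
    dt = params.econ.cycle_years
    entry = params.epidemiology.mean_entry_age
    T = int(math.ceil((100.0 - entry) / dt))
    ages = entry + dt * np.arange(T)
    survs = np.exp(
        -bg_multiplier * dt * np.array([params.life_table.annual_hazard(a) for a in ages])
    )
    frac = target_lifetime_diagnoses / cohort_n
    f = lambda h: _lifetime_diagnoses(h, survs) - frac
    if f(1.0 - 1e-12) < 0:
        raise CalibrationError("target diagnoses unattainable within the horizon")
    h = brentq(f, 0.0, 1.0 - 1e-12, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    assert abs(_lifetime_diagnoses(h, survs) * cohort_n - target_lifetime_diagnoses) < 0.1
    return float(h)


# ---------------------------------------------------------------------------
# life years
# ---------------------------------------------------------------------------


def life_years(
    trace: CohortTrace,
    discount_rate: float = 0.0,
    *,
    half_cycle_correction: bool = False,
) -> tuple[float, float]:
    """(undiscounted, discounted) life years over the trace horizon.

    Occupancy of living states accrues ``dt`` years per cycle; with the
    half-cycle correction, accruals use the mean of start- and end-of-cycle
    occupancy discounted at the cycle midpoint, otherwise start-of-cycle
    occupancy discounted at the cycle start.
    """
    dt = trace.cycle_years
    T = trace.n_cycles
    living = np.array([trace.living(t) for t in range(T + 1)])
    if half_cycle_correction:
        accrual = 0.5 * (living[:-1] + living[1:])
        times = (np.arange(T) + 0.5) * dt
    else:
        accrual = living[:-1]
        times = np.arange(T) * dt
    disc = (1.0 + discount_rate) ** (-times)
    return float(accrual.sum() * dt), float((accrual * disc).sum() * dt)
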