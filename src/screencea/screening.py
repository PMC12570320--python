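"""Screening decision trees: expected scan counts, false positives,
screen-detected cancers by stage, and interval cancers, per round.

The model is expected-value: a cohort of n screenees is pushed through the
branch probabilities of the scan-outcome table, so every output count is
exactly linear in n.  A regular scan splits negative / indeterminate /
positive; indeterminate results get one recall LDCT resolving negative or
positive; pooled negatives split true/false negative and pooled positives
split true/false positive; true positives carry the screen-detected stage
distribution.  False negatives present clinically in the same cycle at the
clinical-presentation stage distribution (the tree assigns no latency).

Screening rounds are annual (every 4 cycles at the 3-month cycle length),
round 1 at cycle 0.  Round 1 uses the first-round table; every later round
uses the subsequent-round table scaled by adherence.  Cancers arising in
cycles without a scheduled screen present clinically via a constant
per-cycle diagnosis hazard shared with the no-screening arm (calibrated by
the disease model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ModelParameters, ScanOutcomeTable, STAGES, SCREEN_STAGES
from .funnel import DomainError


@dataclass
class ScreenRoundResult:
    round_index: int
    scans_performed: float          # regular + recall scans
    scans_recall: float
    n_negative: float               # true negatives (remain undiagnosed)
    n_false_negative: float
    n_positive_referrals: float
    n_true_positive: float
    n_false_positive: float
    detected_by_stage: dict[str, float]
    cohort_remaining: float

    def as_row(self) -> dict:
        row = {
            "round": self.round_index,
            "scans": self.scans_performed,
            "recall_scans": self.scans_recall,
            "true_negative": self.n_negative,
            "false_negative": self.n_false_negative,
            "positive_referrals": self.n_positive_referrals,
            "true_positive": self.n_true_positive,
            "false_positive": self.n_false_positive,
            "cohort_remaining": self.cohort_remaining,
        }
        for s in SCREEN_STAGES:
            row[f"detected_stage_{s}"] = self.detected_by_stage.get(s, 0.0)
        return row


@dataclass
class ScreeningProgramTrace:
    """Per-cycle event stream for one arm, consumed by the Markov engine."""

    n_cycles: int
    cohort_n: float
    rounds: list[ScreenRoundResult]
    #: expected new screen-detected diagnoses [cycle, screen-stage]
    screen_detected: np.ndarray
    #: expected new clinically presenting diagnoses [cycle, stage I-IV]
    #: (interval cancers plus same-cycle false negatives)
    clinical_detected: np.ndarray
    interval_cancers: np.ndarray     # [cycle, stage I-IV], interval component only
    false_positives: np.ndarray      # [cycle]
    scans_regular: np.ndarray        # [cycle]
    scans_recall: np.ndarray         # [cycle]
    attendees: np.ndarray            # [cycle]
    #: alive and undiagnosed during cycle t (after that cycle's screening /
    #: presentation events, before its background mortality); final entry is
    #: the end-of-horizon count
    undiagnosed: np.ndarray          # [cycle+1]
    #: cumulative background deaths through the start of cycle t
    undiagnosed_deaths: np.ndarray   # [cycle+1]
    #: per-cycle background survival factor exp(-mu(age_t) * dt)
    bg_survival: np.ndarray          # [cycle]

    @property
    def total_ldct_scans(self) -> float:
        return float(self.scans_regular.sum() + self.scans_recall.sum())

    def interval_cancers_by_cycle(self) -> dict[int, dict[str, float]]:
        out = {}
        for t in range(self.n_cycles):
            if self.interval_cancers[t].sum() > 0:
                out[t] = dict(zip(STAGES, self.interval_cancers[t]))
        return out


def classify_round(cohort_n: float, table: ScanOutcomeTable, round_index: int = 1) -> ScreenRoundResult:
    """Expected outcome counts for one screening round of ``cohort_n``."""
    if cohort_n < 0:
        raise DomainError("cohort_n must be nonnegative")
    n = float(cohort_n)
    n_indet = n * table.p_regular_indeterminate
    pooled_neg = n * table.p_pooled_negative
    pooled_pos = n * table.p_pooled_positive
    tn = pooled_neg * table.p_true_negative
    fn = pooled_neg * table.p_false_negative
    tp = pooled_pos * table.p_true_positive
    fp = pooled_pos * table.p_false_positive
    detected = {s: tp * p for s, p in table.stage_distribution.items()}
    return ScreenRoundResult(
        round_index=round_index,
        scans_performed=n + n_indet,
        scans_recall=n_indet,
        n_negative=tn,
        n_false_negative=fn,
        n_positive_referrals=pooled_pos,
        n_true_positive=tp,
        n_false_positive=fp,
        detected_by_stage=detected,
        cohort_remaining=n - tp - fn,
    )


def screen_cycles(params: ModelParameters) -> dict[int, int]:
    """Mapping cycle -> round index for the configured program (annual
    rounds = every 4 cycles of 3 months, round 1 at cycle 0)."""
    cycles_per_round = max(1, int(round(12.0 / params.econ.cycle_length_months)))
    return {r * cycles_per_round: r + 1 for r in range(params.econ.n_screen_rounds)}


def interval_incidence(
    cohort_undiagnosed: float,
    per_cycle_hazard: float,
    clinical_stage_distribution: dict[str, float],
) -> dict[str, float]:
    """Expected interval/clinical diagnoses in one cycle, by stage."""
    if not (0.0 <= per_cycle_hazard <= 1.0):
        raise DomainError("per-cycle hazard must be in [0, 1]")
    total = math.fsum(clinical_stage_distribution.values())
    if abs(total - 1.0) > 1e-9:
        raise DomainError(f"clinical stage distribution sums to {total!r}")
    d = cohort_undiagnosed * per_cycle_hazard
    return {s: d * p for s, p in clinical_stage_distribution.items()}


def screen_sensitivity(table: ScanOutcomeTable) -> float:
    """Fraction of cancers surfacing in a screen cycle that the screen
    detects, implied by the tree's true-positive and false-negative arms."""
    tp = table.p_pooled_positive * table.p_true_positive
    fn = table.p_pooled_negative * table.p_false_negative
    return tp / (tp + fn) if tp + fn > 0 else 0.0


def invasive_stage_distribution(table: ScanOutcomeTable) -> dict[str, float]:
    """Screen-detected stage mix over invasive stages I-IV (stage 0
    renormalized out; in-situ detections are handled as a separate,
    prevalence-driven flow)."""
    inv = {s: table.stage_distribution.get(s, 0.0) for s in STAGES}
    tot = math.fsum(inv.values())
    return {s: v / tot for s, v in inv.items()} if tot > 0 else inv


def run_screening_program(
    params: ModelParameters,
    cohort_n: float,
    incidence_hazard: float,
    *,
    arm: str = "screening",
    n_cycles: int | None = None,
    bg_multiplier: float = 1.0,
) -> ScreeningProgramTrace:
    """Forward dynamics of the undiagnosed cohort for one arm.

    One per-cycle diagnosis hazard generates cancers in both arms; what
    screening changes is the *stage at diagnosis* (and the resource use):
    cancers arising in a cycle containing a scheduled screen are detected
    at the screen-detected stage distribution (a fraction given by the
    tree's implied sensitivity; the rest present clinically the same
    cycle), while cancers in other cycles - and everything in the
    no-screening arm - present clinically at the clinical-presentation
    stage distribution.  Carcinoma-in-situ (stage 0) detections are
    prevalence-driven from the tree's true-positive arm and move healthy
    pool members into the post-resection stratum.  Scan counts, recalls and
    false positives come from the decision tree on the attendees.  The
    cohort is depleted by detections, presentations and background
    mortality.  ``arm='none'`` runs the program with no screens.
    """
    if arm not in ("screening", "none"):
        raise DomainError(f"unknown arm {arm!r}")
    epi = params.epidemiology
    dt = params.econ.cycle_years
    if n_cycles is None:
        n_cycles = int(math.ceil((100.0 - epi.mean_entry_age) / dt))
    plan = screen_cycles(params) if arm == "screening" else {}
    clin_dist = np.array([epi.clinical_stage_distribution[s] for s in STAGES])

    screen_det = np.zeros((n_cycles, len(SCREEN_STAGES)))
    clin_det = np.zeros((n_cycles, len(STAGES)))
    interval = np.zeros((n_cycles, len(STAGES)))
    fps = np.zeros(n_cycles)
    scans_reg = np.zeros(n_cycles)
    scans_rec = np.zeros(n_cycles)
    attend = np.zeros(n_cycles)
    undiag = np.zeros(n_cycles + 1)
    undiag_dead = np.zeros(n_cycles + 1)
    bg_surv = np.zeros(n_cycles)
    rounds: list[ScreenRoundResult] = []

    u = float(cohort_n)
    dead = 0.0
    for t in range(n_cycles):
        age = epi.mean_entry_age + t * dt
        undiag_dead[t] = dead
        if t in plan:
            r = plan[t]
            frac = 1.0 if r == 1 else epi.adherence_round2plus
            att = u * frac
            table = params.scan_tables["first" if r == 1 else "subsequent"]
            res = classify_round(att, table, r)
            rounds.append(res)
            attend[t] = att
            scans_reg[t] = att
            scans_rec[t] = res.scans_recall
            fps[t] = res.n_false_positive
            # cancers arising this cycle among attendees: stage-shifted if
            # the screen catches them, clinical presentation if missed
            d_att = att * incidence_hazard
            sens = screen_sensitivity(table)
            inv_dist = invasive_stage_distribution(table)
            for i, s in enumerate(STAGES):
                screen_det[t, SCREEN_STAGES.index(s)] += d_att * sens * inv_dist[s]
            clin_det[t] += d_att * (1.0 - sens) * clin_dist
            # in-situ detections: prevalence-driven from the tree's
            # true-positive arm, drawn from the healthy pool
            d_s0 = res.n_true_positive * table.stage_distribution.get("0", 0.0)
            screen_det[t, SCREEN_STAGES.index("0")] += d_s0
            # non-attendees face the interval hazard as usual
            skip = u * (1.0 - frac)
            d_int = skip * incidence_hazard
            interval[t] += d_int * clin_dist
            clin_det[t] += d_int * clin_dist
            u = u - d_att - d_s0 - d_int
        else:
            d_int = u * incidence_hazard
            interval[t] += d_int * clin_dist
            clin_det[t] += d_int * clin_dist
            u -= d_int
        undiag[t] = u  # alive-undiagnosed during cycle t, post-events
        mu = bg_multiplier * params.life_table.annual_hazard(age)
        surv = math.exp(-mu * dt)
        bg_surv[t] = surv
        dead += u * (1.0 - surv)
        u *= surv
    undiag[n_cycles] = u
    undiag_dead[n_cycles] = dead

    return ScreeningProgramTrace(
        n_cycles=n_cycles,
        cohort_n=float(cohort_n),
        rounds=rounds,
        screen_detected=screen_det,
        clinical_detected=clin_det,
        interval_cancers=interval,
        false_positives=fps,
        scans_regular=scans_reg,
        scans_recall=scans_rec,
        attendees=attend,
        undiagnosed=undiag,
        undiagnosed_deaths=undiag_dead,
        bg_survival=bg_surv,
    )


def stage0_pathway(
    n_stage0: float, costs, n_cycles: int, cycle_years: float
) -> tuple[np.ndarray, None]:
    """Per-cycle cost stream for carcinoma-in-situ detections.

    One resection at diagnosis (cycle 0 of the stream) plus the configured
    surveillance-scan schedule; occupants follow general-population survival
    and utility thereafter (applied by the engine, which scales this stream
    by survival).  Returns (expected cost by cycle for ``n_stage0`` persons,
    None) - the utility stream is the general-population norm by
    construction, applied by the engine with the cohort's current age.
    """
    stream = np.zeros(n_cycles)
    if n_stage0 < 0:
        raise DomainError("n_stage0 must be nonnegative")
    if n_stage0 == 0:
        return stream, None
    stream[0] += costs.unit_costs[costs.stage0_surgery]
    for month, scan in costs.stage0_surveillance_schedule:
        cyc = int(round(month / (cycle_years * 12.0)))
        if cyc < n_cycles:
            stream[cyc] += costs.unit_costs[scan]
    return stream * float(n_stage0), None
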