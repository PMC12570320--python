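"""Money and QALYs: microcosted phase costs, utilities, discounting,
per-arm totals, incrementals, ICER and net monetary benefit.

Cost phases follow the microcosting grid: a post-diagnosis bundle covering
the first 6 months (2 cycles) after diagnosis, a per-cycle ongoing cost
until progression, a post-progression bundle covering the first 6 months
(2 cycles) after progression, and the ongoing rate as maintenance
thereafter.  Pharmaceutical unit costs are per 30 days of therapy and scale
with the phase duration in months; all other items are one-off within
their phase.  Six-month bundles are split evenly across their two cycles
for discounting.  Diagnostic costs at diagnosis are the diagnostics/imaging
rows of the post-diagnosis column; in the screening arm the diagnostic
category additionally carries recall LDCTs and false-positive work-ups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import yaml

from .params import CostTable, EconSettings, STAGES, UtilitySet, fixture_path
from .disease import CohortTrace, LIVING, PREPROG, POSTPROG


class PhaseError(ValueError):
    pass


class ConsistencyError(ValueError):
    pass


def discount_factor(t_years: float, rate: float) -> float:
    """(1 + rate)^(-t); rate is per year."""
    if rate < 0 or t_years < 0:
        raise ValueError("rate and time must be nonnegative")
    return (1.0 + rate) ** (-t_years)


def phase_cost(stage: str, phase: str, costs: CostTable, cycle_months: float = 3.0) -> float:
    """Expected cost of one phase for one patient of the given stage.

    For the 6-month post-diagnosis / post-progression phases this is the
    full bundle; for the open-ended ongoing phase it is the per-cycle cost.
    """
    if stage not in STAGES:
        raise PhaseError(f"unknown stage {stage!r}")
    if phase not in ("postdiagnosis", "ongoing", "postprogression"):
        raise PhaseError(f"unknown phase {phase!r}")
    months = costs.phase_durations.get(phase, cycle_months)
    total = 0.0
    for iv, phases in costs.utilization.items():
        util = phases.get(phase, {}).get(stage, 0.0)
        if util == 0.0:
            continue
        unit = costs.unit_costs[iv]
        if iv in costs.pharmaceuticals:
            total += util * unit * months  # per-30-day dosing over the phase
        else:
            total += util * unit
    return total


def diagnostic_cost_at_diagnosis(stage: str, costs: CostTable) -> float:
    """Diagnostics-and-imaging work-up cost booked at diagnosis."""
    if stage not in STAGES:
        raise PhaseError(f"unknown stage {stage!r}")
    return math.fsum(
        costs.unit_costs[iv] * costs.utilization[iv]["postdiagnosis"].get(stage, 0.0)
        for iv in costs.diagnostic_interventions
    )


def fp_workup_cost(costs: CostTable) -> float:
    """Cost of one false-positive work-up (configurable bundle)."""
    return math.fsum(costs.unit_costs[iv] * frac for iv, frac in costs.fp_workup_bundle.items())


@dataclass
class PhaseCostSchedule:
    """Per-stage cost inputs for the accumulator (all USD)."""

    diagnostic_at_diagnosis: dict[str, float]
    postdiagnosis_bundle: dict[str, float]   # treatment part, excl. diagnostics
    ongoing_per_cycle: dict[str, float]
    postprogression_bundle: dict[str, float]


def build_phase_schedule(costs: CostTable, cycle_months: float = 3.0) -> PhaseCostSchedule:
    diag, pd, on, pp = {}, {}, {}, {}
    for s in STAGES:
        diag[s] = diagnostic_cost_at_diagnosis(s, costs)
        pd[s] = phase_cost(s, "postdiagnosis", costs, cycle_months) - diag[s]
        on[s] = phase_cost(s, "ongoing", costs, cycle_months)
        pp[s] = phase_cost(s, "postprogression", costs, cycle_months)
    return PhaseCostSchedule(
        diagnostic_at_diagnosis=diag,
        postdiagnosis_bundle=pd,
        ongoing_per_cycle=on,
        postprogression_bundle=pp,
    )


# ---------------------------------------------------------------------------
# arm accumulation
# ---------------------------------------------------------------------------

_STAGE_KEYS = STAGES + ("0",)


@dataclass
class ArmResult:
    """Discounted totals for one arm (undiscounted LY/QALY carried too)."""

    label: str
    n_cohort: float
    n_cycles: int
    screening_cost: float = 0.0
    diagnostic_cost: float = 0.0
    treatment_cost_by_stage: dict[str, float] = field(default_factory=dict)
    treatment_cost: float = 0.0
    total_cost: float = 0.0
    ly_disc: float = 0.0
    ly_undisc: float = 0.0
    qaly_disc: float = 0.0
    qaly_undisc: float = 0.0
    ly_by_stage: dict[str, float] = field(default_factory=dict)
    qaly_by_stage: dict[str, float] = field(default_factory=dict)
    ly_lc_free: float = 0.0
    qaly_lc_free: float = 0.0
    diagnoses_by_stage: dict[str, float] = field(default_factory=dict)
    diagnoses_total: float = 0.0      # stages I-IV (stage 0 kept separate)
    diagnoses_stage0: float = 0.0
    deaths_by_stage: dict[str, float] = field(default_factory=dict)
    deaths_total: float = 0.0
    total_ldct_scans: float = 0.0


def accumulate(
    trace: CohortTrace,
    schedule: PhaseCostSchedule,
    utilities: UtilitySet,
    econ: EconSettings,
    costs: CostTable,
    *,
    label: str,
) -> ArmResult:
    """Turn a cohort trace into discounted costs, LY and QALYs."""
    dt = trace.cycle_years
    T = trace.n_cycles
    hcc = econ.half_cycle_correction
    t_event = np.arange(T) * dt                      # one-off events: cycle start
    t_accr = (np.arange(T) + (0.5 if hcc else 0.0)) * dt
    dc_event = (1.0 + econ.discount_rate_costs) ** (-t_event)
    dh_accr = (1.0 + econ.discount_rate_health) ** (-t_accr)
    dh_event = (1.0 + econ.discount_rate_health) ** (-t_event)

    prog = trace.program
    occ = trace.occupancy  # [T+1, stage, mode, state]

    # per-cycle state costs [stage, state]
    n_stage = len(STAGES)
    state_cost = np.zeros((n_stage, 8))
    u_state = np.zeros((n_stage, 8))
    for i, s in enumerate(STAGES):
        state_cost[i, 0] = state_cost[i, 1] = schedule.postdiagnosis_bundle[s] / 2.0
        state_cost[i, 2] = schedule.ongoing_per_cycle[s]
        state_cost[i, 3] = state_cost[i, 4] = schedule.postprogression_bundle[s] / 2.0
        state_cost[i, 5] = schedule.ongoing_per_cycle[s]  # maintenance
        u_state[i, list(PREPROG)] = utilities.preprogression_by_stage[s]
        u_state[i, list(POSTPROG)] = utilities.postprogression_by_stage[s]

    occ_t = occ[:-1].sum(axis=2)  # [T, stage, state] start-of-cycle incl. entrants

    # --- costs ------------------------------------------------------------
    screening_cost = float((prog.scans_regular * costs.ldct_cost * dc_event).sum())

    diag_bundle = np.array([schedule.diagnostic_at_diagnosis[s] for s in STAGES])
    new_dx = trace.new_diagnoses.sum(axis=2)  # [T, stage]
    diagnostic = float((new_dx @ diag_bundle * dc_event).sum())
    diagnostic += float((prog.scans_recall * costs.ldct_cost * dc_event).sum())
    diagnostic += float((prog.false_positives * fp_workup_cost(costs) * dc_event).sum())

    treat_by_stage: dict[str, float] = {}
    for i, s in enumerate(STAGES):
        per_cycle = occ_t[:, i, :] @ state_cost[i]
        treat_by_stage[s] = float((per_cycle * dc_event).sum())

    # carcinoma in situ: resection at detection plus surveillance scans,
    # scaled by general-population survival from detection
    s0_cost = 0.0
    if trace.new_stage0.sum() > 0:
        cum = np.concatenate([[1.0], np.cumprod(prog.bg_survival)])
        surgery = costs.unit_costs[costs.stage0_surgery]
        for te in np.nonzero(trace.new_stage0)[0]:
            n = trace.new_stage0[te]
            s0_cost += n * surgery * dc_event[te]
            for month, scan in costs.stage0_surveillance_schedule:
                tc = te + int(round(month / (dt * 12.0)))
                if tc < T:
                    alive = cum[tc] / cum[te]
                    s0_cost += n * alive * costs.unit_costs[scan] * dc_event[tc]
    treat_by_stage["0"] = float(s0_cost)
    treatment = math.fsum(treat_by_stage.values())
    total = screening_cost + diagnostic + treatment

    # --- health outcomes ---------------------------------------------------
    lcfree_alive = trace.undiagnosed[:-1] + trace.stage0_alive[:-1]
    if hcc:
        lcfree_accr = 0.5 * (lcfree_alive + trace.undiagnosed[1:] + trace.stage0_alive[1:])
    else:
        lcfree_accr = lcfree_alive
    ages = trace.entry_age + np.arange(T) * dt
    u_gp = np.array([utilities.general_population_utility(a) for a in ages])

    ly_by_stage, qaly_by_stage = {}, {}
    living_idx = list(LIVING)
    for i, s in enumerate(STAGES):
        o = occ[:, i, :, :][:, :, living_idx].sum(axis=(1, 2))  # [T+1]
        accr = 0.5 * (o[:-1] + o[1:]) if hcc else o[:-1]
        ly_by_stage[s] = float((accr * dh_accr).sum() * dt)
        ou = np.einsum("tms,s->t", occ[:-1, i, :, :], u_state[i])
        if hcc:
            ou_next = np.einsum("tms,s->t", occ[1:, i, :, :], u_state[i])
            ou = 0.5 * (ou + ou_next)
        qaly_by_stage[s] = float((ou * dh_accr).sum() * dt)
    ly_lc_free = float((lcfree_accr * dh_accr).sum() * dt)
    qaly_lc_free = float((lcfree_accr * u_gp * dh_accr).sum() * dt)
    # screening disutility: one-off decrement per attended screen
    qaly_lc_free -= float(
        utilities.screening_disutility * (prog.attendees * dh_event).sum()
    )

    ly_disc = math.fsum(ly_by_stage.values()) + ly_lc_free
    qaly_disc = math.fsum(qaly_by_stage.values()) + qaly_lc_free

    # undiscounted totals
    living_all = np.array([trace.living(t) for t in range(T + 1)])
    accr_all = 0.5 * (living_all[:-1] + living_all[1:]) if hcc else living_all[:-1]
    ly_undisc = float(accr_all.sum() * dt)
    qaly_undisc = 0.0
    for i, s in enumerate(STAGES):
        ou = np.einsum("tms,s->t", occ[:-1, i, :, :], u_state[i])
        qaly_undisc += float(ou.sum() * dt)
    qaly_undisc += float((lcfree_alive * u_gp).sum() * dt)
    qaly_undisc -= float(utilities.screening_disutility * prog.attendees.sum())

    dx_by_stage = trace.diagnoses_by_stage()
    deaths = trace.lc_deaths_by_stage()

    return ArmResult(
        label=label,
        n_cohort=trace.cohort_n,
        n_cycles=T,
        screening_cost=screening_cost,
        diagnostic_cost=diagnostic,
        treatment_cost_by_stage=treat_by_stage,
        treatment_cost=treatment,
        total_cost=total,
        ly_disc=ly_disc,
        ly_undisc=ly_undisc,
        qaly_disc=qaly_disc,
        qaly_undisc=qaly_undisc,
        ly_by_stage=ly_by_stage,
        qaly_by_stage=qaly_by_stage,
        ly_lc_free=ly_lc_free,
        qaly_lc_free=qaly_lc_free,
        diagnoses_by_stage={s: dx_by_stage[s] for s in STAGES},
        diagnoses_total=math.fsum(dx_by_stage[s] for s in STAGES),
        diagnoses_stage0=dx_by_stage["0"],
        deaths_by_stage=deaths,
        deaths_total=math.fsum(deaths.values()),
        total_ldct_scans=prog.total_ldct_scans,
    )


# ---------------------------------------------------------------------------
# ICER / NMB / assembly
# ---------------------------------------------------------------------------


@dataclass
class IcerValue:
    raw: float | None
    rounded: int | None
    undefined: bool = False
    dominant: bool = False
    dominated: bool = False


def compute_icer(incr_cost: float, incr_effect: float) -> IcerValue:
    """Incremental cost per incremental effect; dominance flagged, zero
    effect yields an undefined signal rather than a number."""
    if incr_effect == 0.0:
        return IcerValue(raw=None, rounded=None, undefined=True)
    raw = incr_cost / incr_effect
    return IcerValue(
        raw=raw,
        rounded=int(round(raw)),
        dominant=(incr_cost < 0.0 and incr_effect > 0.0),
        dominated=(incr_cost > 0.0 and incr_effect < 0.0),
    )


def compute_nmb(qalys: float, wtp: float, incr_cost: float) -> float:
    """Net monetary benefit: health gain x willingness-to-pay - cost."""
    return qalys * wtp - incr_cost


@dataclass
class CEAResult:
    cohort_label: str
    screening: ArmResult
    no_screening: ArmResult
    incr_cost: float
    incr_qaly: float
    incr_ly: float
    incr_diagnoses: float
    incr_diagnoses_by_stage: dict[str, float]
    deaths_averted: float
    stage_iv_averted: float
    icer_per_qaly: IcerValue
    icer_per_lyg: IcerValue
    nmb_low: float
    nmb_high: float
    wtp_low: float
    wtp_high: float

    def to_dict(self) -> dict:
        return {
            "cohort_label": self.cohort_label,
            "screening": asdict(self.screening),
            "no_screening": asdict(self.no_screening),
            "incr_cost": self.incr_cost,
            "incr_qaly": self.incr_qaly,
            "incr_ly": self.incr_ly,
            "incr_diagnoses": self.incr_diagnoses,
            "incr_diagnoses_by_stage": dict(self.incr_diagnoses_by_stage),
            "deaths_averted": self.deaths_averted,
            "stage_iv_averted": self.stage_iv_averted,
            "icer_per_qaly": asdict(self.icer_per_qaly),
            "icer_per_lyg": asdict(self.icer_per_lyg),
            "nmb_low": self.nmb_low,
            "nmb_high": self.nmb_high,
            "wtp_low": self.wtp_low,
            "wtp_high": self.wtp_high,
        }


def assemble_cea(
    arm_screening: ArmResult,
    arm_none: ArmResult,
    econ: EconSettings,
    cohort_label: str = "",
) -> CEAResult:
    """Fill incrementals, ICERs and the NMB range from two arm blocks."""
    if arm_screening.n_cohort != arm_none.n_cohort:
        raise ConsistencyError(
            f"arms sized {arm_screening.n_cohort} vs {arm_none.n_cohort}: must match"
        )
    if arm_screening.n_cycles != arm_none.n_cycles:
        raise ConsistencyError("arms must share the same horizon")
    d_cost = arm_screening.total_cost - arm_none.total_cost
    d_qaly = arm_screening.qaly_disc - arm_none.qaly_disc
    d_ly = arm_screening.ly_disc - arm_none.ly_disc
    d_dx = arm_screening.diagnoses_total - arm_none.diagnoses_total
    d_dx_stage = {
        s: arm_screening.diagnoses_by_stage.get(s, 0.0) - arm_none.diagnoses_by_stage.get(s, 0.0)
        for s in STAGES
    }
    return CEAResult(
        cohort_label=cohort_label,
        screening=arm_screening,
        no_screening=arm_none,
        incr_cost=d_cost,
        incr_qaly=d_qaly,
        incr_ly=d_ly,
        incr_diagnoses=d_dx,
        incr_diagnoses_by_stage=d_dx_stage,
        deaths_averted=arm_none.deaths_total - arm_screening.deaths_total,
        stage_iv_averted=arm_none.diagnoses_by_stage.get("IV", 0.0)
        - arm_screening.diagnoses_by_stage.get("IV", 0.0),
        icer_per_qaly=compute_icer(d_cost, d_qaly),
        icer_per_lyg=compute_icer(d_cost, d_ly),
        nmb_low=compute_nmb(d_qaly, econ.wtp_low, d_cost),
        nmb_high=compute_nmb(d_qaly, econ.wtp_high, d_cost),
        wtp_low=econ.wtp_low,
        wtp_high=econ.wtp_high,
    )


# ---------------------------------------------------------------------------
# result I/O (delimited, bit-for-bit round-trip via repr floats)
# ---------------------------------------------------------------------------

_ARM_SCALARS = (
    "n_cohort", "n_cycles", "screening_cost", "diagnostic_cost", "treatment_cost",
    "total_cost", "ly_disc", "ly_undisc", "qaly_disc", "qaly_undisc",
    "ly_lc_free", "qaly_lc_free", "diagnoses_total", "diagnoses_stage0",
    "deaths_total", "total_ldct_scans",
)
_ARM_MAPS = (
    "treatment_cost_by_stage", "ly_by_stage", "qaly_by_stage",
    "diagnoses_by_stage", "deaths_by_stage",
)
_INC_SCALARS = (
    "incr_cost", "incr_qaly", "incr_ly", "incr_diagnoses", "deaths_averted",
    "stage_iv_averted", "nmb_low", "nmb_high", "wtp_low", "wtp_high",
)


def write_results(result: CEAResult, path: str | Path) -> None:
    """Column-stable CSV; floats written with repr so a re-read reproduces
    every number bit-for-bit."""
    rows: list[tuple[str, str, str, str]] = [("section", "field", "key", "value")]

    def put(section: str, fieldname: str, key: str, value) -> None:
        rows.append((section, fieldname, key, repr(value) if value is not None else ""))

    put("meta", "cohort_label", "", result.cohort_label)
    for arm_name, arm in (("screening", result.screening), ("no_screening", result.no_screening)):
        put(arm_name, "label", "", arm.label)
        for f in _ARM_SCALARS:
            put(arm_name, f, "", getattr(arm, f))
        for f in _ARM_MAPS:
            for k in sorted(getattr(arm, f)):
                put(arm_name, f, k, getattr(arm, f)[k])
    for f in _INC_SCALARS:
        put("incremental", f, "", getattr(result, f))
    for k in sorted(result.incr_diagnoses_by_stage):
        put("incremental", "incr_diagnoses_by_stage", k, result.incr_diagnoses_by_stage[k])
    for name, icer in (("icer_per_qaly", result.icer_per_qaly), ("icer_per_lyg", result.icer_per_lyg)):
        put("incremental", name, "raw", icer.raw)
        put("incremental", name, "rounded", icer.rounded)
        put("incremental", name, "undefined", icer.undefined)
        put("incremental", name, "dominant", icer.dominant)
        put("incremental", name, "dominated", icer.dominated)
    Path(path).write_text("\n".join(",".join(r) for r in rows) + "\n")


def read_results(path: str | Path) -> CEAResult:
    """Inverse of :func:`write_results`."""
    lines = Path(path).read_text().strip().splitlines()
    data: dict[tuple[str, str, str], str] = {}
    for line in lines[1:]:
        section, fieldname, key, value = line.split(",", 3)
        data[(section, fieldname, key)] = value

    def lit(v: str):
        if v == "":
            return None
        if v in ("True", "False"):
            return v == "True"
        try:
            return int(v)
        except ValueError:
            try:
                return float(v)
            except ValueError:
                return v.strip("'\"")

    def read_arm(name: str) -> ArmResult:
        kw = {f: lit(data[(name, f, "")]) for f in _ARM_SCALARS}
        for f in _ARM_MAPS:
            kw[f] = {
                k: lit(v)
                for (sec, fn, k), v in data.items()
                if sec == name and fn == f and k != ""
            }
        return ArmResult(label=lit(data[(name, "label", "")]) or name, **kw)

    def read_icer(name: str) -> IcerValue:
        return IcerValue(
            raw=lit(data[("incremental", name, "raw")]),
            rounded=lit(data[("incremental", name, "rounded")]),
            undefined=lit(data[("incremental", name, "undefined")]),
            dominant=lit(data[("incremental", name, "dominant")]),
            dominated=lit(data[("incremental", name, "dominated")]),
        )

    inc = {f: lit(data[("incremental", f, "")]) for f in _INC_SCALARS}
    return CEAResult(
        cohort_label=lit(data[("meta", "cohort_label", "")]) or "",
        screening=read_arm("screening"),
        no_screening=read_arm("no_screening"),
        incr_diagnoses_by_stage={
            k: lit(v)
            for (sec, fn, k), v in data.items()
            if sec == "incremental" and fn == "incr_diagnoses_by_stage" and k != ""
        },
        icer_per_qaly=read_icer("icer_per_qaly"),
        icer_per_lyg=read_icer("icer_per_lyg"),
        **inc,
    )


# ---------------------------------------------------------------------------
# published base-case arm blocks (printed results table)
# ---------------------------------------------------------------------------


def load_published_basecase() -> dict[str, dict[str, ArmResult]]:
    """The source study's printed per-arm base-case totals, as ArmResult
    blocks (discounted fields; printed totals kept verbatim - they embed
    the publication's own rounding).  Incrementals are always recomputed."""
    raw = yaml.safe_load(fixture_path("published_basecase.yaml").read_text())
    out: dict[str, dict[str, ArmResult]] = {}
    for cohort, arms in raw.items():
        out[cohort] = {}
        for arm_name, d in arms.items():
            out[cohort][arm_name] = ArmResult(
                label=f"{cohort}:{arm_name}",
                n_cohort=float("nan"),
                n_cycles=-1,
                screening_cost=float(d.get("screening_cost", 0.0)),
                diagnostic_cost=float(d["diagnostic_cost"]),
                treatment_cost_by_stage={str(k): float(v) for k, v in d["treatment_cost_by_stage"].items()},
                treatment_cost=float(d["treatment_cost"]),
                total_cost=float(d["total_cost"]),
                ly_disc=float(d["ly_total"]),
                qaly_disc=float(d["qaly_total"]),
                ly_by_stage={str(k): float(v) for k, v in d["ly_by_stage"].items()},
                qaly_by_stage={str(k): float(v) for k, v in d["qaly_by_stage"].items()},
                ly_lc_free=float(d["ly_lc_free"]),
                qaly_lc_free=float(d["qaly_lc_free"]),
                diagnoses_by_stage={str(k): float(v) for k, v in d["diagnoses_by_stage"].items()},
                diagnoses_total=float(d["diagnoses_total"]),
                diagnoses_stage0=float(d.get("diagnoses_stage0", 0.0)),
                deaths_by_stage={str(k): float(v) for k, v in d["deaths_by_stage"].items()},
                deaths_total=float(d["deaths_total"]),
            )
    return out


def published_incrementals(econ: EconSettings | None = None) -> dict[str, CEAResult]:
    """Incremental accounting over the printed arm blocks (the identity
    checks: published incrementals are differences of published arms)."""
    econ = econ or EconSettings()
    pub = load_published_basecase()
    out = {}
    for cohort, arms in pub.items():
        s, n = arms["screening"], arms["no_screening"]
        s.n_cohort = n.n_cohort = 0.0
        s.n_cycles = n.n_cycles = 0
        out[cohort] = assemble_cea(s, n, econ, cohort_label=cohort)
    return out
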