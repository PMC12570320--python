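"""Parameter data model, validation, and config I/O.

The model is driven entirely by a structured parameter pack: screening
decision-tree probabilities, cohort epidemiology, stage-specific survival
anchors, utilities, a microcosting grid (unit cost x utilization per stage
per phase), and the economic evaluation settings.  All probabilities are
stored as decimals (0.465, not 46.5%) to avoid percent/fraction ambiguity.

Packs are human-editable YAML; a cohort file may list ``include`` files
(resolved relative to itself) whose sections are merged underneath it, so
the two cohorts can share one cost/utility/survival block.
"""

from __future__ import annotations

import copy
import hashlib
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

STAGES = ("I", "II", "III", "IV")
#: stages a screen-detected tumour may carry ("0" = carcinoma in situ,
#: observed only in the risk-factor cohort's trial)
SCREEN_STAGES = ("0",) + STAGES
PHASES = ("postdiagnosis", "ongoing", "postprogression")
SIMPLEX_TOL = 1e-9
#: printed-percentage rounding slack accepted (and repaired) at load time
PRINT_TOL = 5e-4


class ConfigError(ValueError):
    """Raised when a parameter pack cannot be loaded or fails validation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ScanOutcomeTable:
    """One screening round's decision-tree probabilities.

    A regular scan splits negative/indeterminate/positive; indeterminate
    results receive a recall scan that resolves negative/positive; pooled
    negatives split true-negative/false-negative and pooled positives split
    true-positive/false-positive; true positives carry the screen-detected
    stage distribution.  A single-pass table degenerates to
    ``p_regular_indeterminate = 0``.
    """

    p_regular_negative: float
    p_regular_indeterminate: float
    p_regular_positive: float
    p_indeterminate_negative: float
    p_indeterminate_positive: float
    p_true_negative: float
    p_false_negative: float
    p_true_positive: float
    p_false_positive: float
    stage_distribution: dict[str, float]

    @property
    def p_pooled_positive(self) -> float:
        """Probability a screenee ends up referred positive."""
        return self.p_regular_positive + self.p_regular_indeterminate * self.p_indeterminate_positive

    @property
    def p_pooled_negative(self) -> float:
        return self.p_regular_negative + self.p_regular_indeterminate * self.p_indeterminate_negative


@dataclass
class EpidemiologyParams:
    total_population: float
    age_band_fraction: float
    smoker_fractions: dict[str, float]
    nonsmoker_high_risk_fraction: float
    annual_lc_incidence: float
    clinical_stage_distribution: dict[str, float]
    mean_entry_age: float
    uptake: float
    adherence_round2plus: float
    eligible_current_smokers: float = 0.0
    eligible_ex_smokers: float = 0.0
    nonsmoking_pool: float = 0.0
    #: lifetime diagnoses calibration anchor: `target_diagnoses` expected
    #: among a no-screening cohort of `target_arm_size` persons
    target_diagnoses: float = 0.0
    target_arm_size: float = 0.0


@dataclass
class SurvivalTargets:
    os5y_by_stage: dict[str, float]
    pfs1y_by_stage: dict[str, float]


@dataclass
class GeneralPopulationUtility:
    """Age-dependent EQ-5D norm via a quadratic age regression.

    u(age) = intercept + male_coef*male_fraction + age_coef*age + age2_coef*age^2,
    clipped to [0, 1].
    """

    intercept: float = 0.9508566
    male_coef: float = 0.0212126
    male_fraction: float = 0.456
    age_coef: float = -0.0002587
    age2_coef: float = -0.0000332

    def __call__(self, age: float) -> float:
        u = (
            self.intercept
            + self.male_coef * self.male_fraction
            + self.age_coef * age
            + self.age2_coef * age * age
        )
        return min(1.0, max(0.0, u))


@dataclass
class UtilitySet:
    preprogression_by_stage: dict[str, float]
    postprogression_by_stage: dict[str, float]
    general_population: GeneralPopulationUtility = field(default_factory=GeneralPopulationUtility)
    screening_disutility: float = 0.0

    def general_population_utility(self, age: float) -> float:
        return self.general_population(age)


@dataclass
class CostTable:
    """Microcosting inputs.

    ``unit_costs`` are USD (2023).  ``utilization[intervention][phase][stage]``
    is the fraction of patients of that stage receiving the intervention
    during that phase.  Pharmaceutical unit costs are per 30 days of therapy
    and scale with phase duration; everything else is one-off within a phase
    (per cycle for the open-ended ongoing phase).
    """

    unit_costs: dict[str, float]
    utilization: dict[str, dict[str, dict[str, float]]]
    ldct_cost: float
    pharmaceuticals: tuple[str, ...]
    diagnostic_interventions: tuple[str, ...]
    phase_durations: dict[str, float]  # months
    stage0_surgery: str
    stage0_surveillance_schedule: tuple[tuple[float, str], ...]
    fp_workup_bundle: dict[str, float]


@dataclass
class EconSettings:
    discount_rate_costs: float = 0.035
    discount_rate_health: float = 0.035
    cycle_length_months: float = 3.0
    horizon: float | str = "lifetime"
    wtp_low: float = 24302.0
    wtp_high: float = 40202.0
    n_screen_rounds: int = 1
    half_cycle_correction: bool = False

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_months / 12.0


@dataclass
class LifeTable:
    """All-cause mortality: rows of (integer age, annual death probability).

    Ages are consecutive; lookups beyond the last row reuse the terminal
    hazard rather than extrapolating.
    """

    ages: tuple[int, ...]
    qx: tuple[float, ...]

    def annual_q(self, age: float) -> float:
        a = int(math.floor(age))
        if a <= self.ages[0]:
            return self.qx[0]
        if a >= self.ages[-1]:
            return self.qx[-1]
        return self.qx[a - self.ages[0]]

    def annual_hazard(self, age: float) -> float:
        q = min(self.annual_q(age), 1.0 - 1e-12)
        return -math.log1p(-q)


@dataclass
class ModelParameters:
    cohort_label: str
    scan_tables: dict[str, ScanOutcomeTable]
    epidemiology: EpidemiologyParams
    survival: SurvivalTargets
    utilities: UtilitySet
    costs: CostTable
    econ: EconSettings
    life_table: LifeTable
    psa_spec: dict[str, dict[str, float | str]] = field(default_factory=dict)

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _check_simplex(violations: list[str], name: str, values: Sequence[float], tol: float = SIMPLEX_TOL) -> None:
    s = math.fsum(values)
    if abs(s - 1.0) > tol:
        violations.append(f"{name}: components sum to {s!r}, expected 1 within {tol}")
    for v in values:
        if not (-tol <= v <= 1 + tol):
            violations.append(f"{name}: component {v!r} outside [0, 1]")


def _check_unit(violations: list[str], name: str, v: float) -> None:
    if not (0.0 <= v <= 1.0):
        violations.append(f"{name}: value {v!r} outside [0, 1]")


def validate_scan_table(t: ScanOutcomeTable, name: str = "scan_table") -> list[str]:
    out: list[str] = []
    _check_simplex(out, f"{name}.regular", (t.p_regular_negative, t.p_regular_indeterminate, t.p_regular_positive))
    _check_simplex(out, f"{name}.recall", (t.p_indeterminate_negative, t.p_indeterminate_positive))
    _check_simplex(out, f"{name}.negatives(TN+FN)", (t.p_true_negative, t.p_false_negative))
    _check_simplex(out, f"{name}.positives(TP+FP)", (t.p_true_positive, t.p_false_positive))
    _check_simplex(out, f"{name}.stage_distribution", list(t.stage_distribution.values()))
    for s in t.stage_distribution:
        if s not in SCREEN_STAGES:
            out.append(f"{name}.stage_distribution: unknown stage {s!r}")
    return out


def validate_parameters(p: ModelParameters) -> list[str]:
    """Return a list of invariant violations (empty list == valid)."""
    out: list[str] = []
    if p.cohort_label not in ("smoking", "nonsmoking"):
        out.append(f"cohort_label: {p.cohort_label!r} not in {{smoking, nonsmoking}}")
    for key, tab in p.scan_tables.items():
        out.extend(validate_scan_table(tab, f"scan_tables[{key}]"))
        if "0" in tab.stage_distribution and tab.stage_distribution["0"] > 0 and p.cohort_label == "smoking":
            out.append(f"scan_tables[{key}]: stage 0 only permitted for the single-pass (risk-factor) table")
    epi = p.epidemiology
    _check_simplex(out, "epidemiology.clinical_stage_distribution", list(epi.clinical_stage_distribution.values()))
    for s in epi.clinical_stage_distribution:
        if s not in STAGES:
            out.append(f"epidemiology.clinical_stage_distribution: unknown stage {s!r}")
    _check_unit(out, "epidemiology.uptake", epi.uptake)
    _check_unit(out, "epidemiology.adherence_round2plus", epi.adherence_round2plus)
    for fname in ("total_population", "annual_lc_incidence", "eligible_current_smokers",
                  "eligible_ex_smokers", "nonsmoking_pool", "target_diagnoses", "target_arm_size"):
        if getattr(epi, fname) < 0:
            out.append(f"epidemiology.{fname}: negative count")
    _check_unit(out, "epidemiology.nonsmoker_high_risk_fraction", epi.nonsmoker_high_risk_fraction)
    for s in STAGES:
        for label, m in (("os5y", p.survival.os5y_by_stage), ("pfs1y", p.survival.pfs1y_by_stage)):
            v = m.get(s)
            if v is None:
                out.append(f"survival.{label}_by_stage: missing stage {s}")
            elif not (0.0 < v < 1.0):
                out.append(f"survival.{label}_by_stage[{s}]: {v!r} outside (0, 1)")
    os5 = p.survival.os5y_by_stage
    if all(s in os5 for s in STAGES):
        if not (os5["I"] >= os5["II"] >= os5["III"] >= os5["IV"]):
            out.append("survival.os5y_by_stage: stage ordering I >= II >= III >= IV violated")
    for s in STAGES:
        _check_unit(out, f"utilities.preprogression_by_stage[{s}]", p.utilities.preprogression_by_stage[s])
        _check_unit(out, f"utilities.postprogression_by_stage[{s}]", p.utilities.postprogression_by_stage[s])
    if p.utilities.screening_disutility < 0:
        out.append("utilities.screening_disutility: negative decrement")
    for name, c in p.costs.unit_costs.items():
        if c < 0:
            out.append(f"costs.unit_costs[{name}]: negative cost")
    if p.costs.ldct_cost < 0:
        out.append("costs.ldct_cost: negative cost")
    for iv, phases in p.costs.utilization.items():
        if iv not in p.costs.unit_costs:
            out.append(f"costs.utilization[{iv}]: no matching unit cost")
        for ph, stages in phases.items():
            if ph not in PHASES:
                out.append(f"costs.utilization[{iv}]: unknown phase {ph!r}")
            for s, frac in stages.items():
                _check_unit(out, f"costs.utilization[{iv}][{ph}][{s}]", frac)
    for ph in ("postdiagnosis", "postprogression"):
        if p.costs.phase_durations.get(ph, -1) <= 0:
            out.append(f"costs.phase_durations[{ph}]: must be a positive number of months")
    for iv, frac in p.costs.fp_workup_bundle.items():
        if iv not in p.costs.unit_costs:
            out.append(f"costs.fp_workup_bundle[{iv}]: no matching unit cost")
        _check_unit(out, f"costs.fp_workup_bundle[{iv}]", frac)
    econ = p.econ
    if econ.discount_rate_costs < 0 or econ.discount_rate_health < 0:
        out.append("econ: discount rates must be >= 0")
    if econ.cycle_length_months <= 0:
        out.append("econ.cycle_length_months: must be > 0")
    if econ.wtp_low > econ.wtp_high:
        out.append("econ: wtp_low > wtp_high")
    if econ.n_screen_rounds < 1:
        out.append("econ.n_screen_rounds: must be >= 1")
    lt = p.life_table
    if list(lt.ages) != list(range(lt.ages[0], lt.ages[0] + len(lt.ages))):
        out.append("life_table: ages must increase strictly by 1")
    for a, q in zip(lt.ages, lt.qx):
        if not (0.0 < q <= 1.0):
            out.append(f"life_table: q({a}) = {q!r} outside (0, 1]")
    if lt.ages[-1] < 100:
        out.append("life_table: must cover ages up to 100")
    return out


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _req(d: Mapping, key: str, ctx: str):
    if key not in d:
        raise ConfigError(f"missing key {ctx}.{key}")
    return d[key]


def _num(d: Mapping, key: str, ctx: str) -> float:
    v = _req(d, key, ctx)
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise ConfigError(f"malformed number at {ctx}.{key}: {v!r}")
    return float(v)


def _renorm(values: dict[str, float], ctx: str) -> dict[str, float]:
    """Repair printed-percentage rounding: renormalize a simplex block whose
    raw sum is within PRINT_TOL of 1; anything further off is an error."""
    s = math.fsum(values.values())
    if abs(s - 1.0) > PRINT_TOL:
        raise ConfigError(f"{ctx}: probabilities sum to {s!r}, expected 1 within {PRINT_TOL}")
    if abs(s - 1.0) < 1e-12:  # already normalized: keep bit-identical (round-trip)
        return dict(values)
    return {k: v / s for k, v in values.items()}


def _pair_renorm(a: float, b: float, ctx: str) -> tuple[float, float]:
    d = _renorm({"a": a, "b": b}, ctx)
    return d["a"], d["b"]


def _parse_scan_table(d: Mapping, ctx: str) -> ScanOutcomeTable:
    reg = _req(d, "regular", ctx)
    rec = _req(d, "recall", ctx)
    neg = _req(d, "negatives", ctx)
    pos = _req(d, "positives", ctx)
    regular = _renorm(
        {
            "negative": _num(reg, "negative", f"{ctx}.regular"),
            "indeterminate": _num(reg, "indeterminate", f"{ctx}.regular"),
            "positive": _num(reg, "positive", f"{ctx}.regular"),
        },
        f"{ctx}.regular",
    )
    rn, rp = _pair_renorm(_num(rec, "negative", f"{ctx}.recall"), _num(rec, "positive", f"{ctx}.recall"), f"{ctx}.recall")
    tn, fn = _pair_renorm(
        _num(neg, "true_negative", f"{ctx}.negatives"), _num(neg, "false_negative", f"{ctx}.negatives"), f"{ctx}.negatives"
    )
    tp, fp = _pair_renorm(
        _num(pos, "true_positive", f"{ctx}.positives"), _num(pos, "false_positive", f"{ctx}.positives"), f"{ctx}.positives"
    )
    sd_raw = {str(k): float(v) for k, v in _req(d, "stage_distribution", ctx).items()}
    return ScanOutcomeTable(
        p_regular_negative=regular["negative"],
        p_regular_indeterminate=regular["indeterminate"],
        p_regular_positive=regular["positive"],
        p_indeterminate_negative=rn,
        p_indeterminate_positive=rp,
        p_true_negative=tn,
        p_false_negative=fn,
        p_true_positive=tp,
        p_false_positive=fp,
        stage_distribution=_renorm(sd_raw, f"{ctx}.stage_distribution"),
    )


def load_life_table(path: Path) -> LifeTable:
    ages: list[int] = []
    qx: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("age"):
            continue
        a, q = line.split(",")
        ages.append(int(a))
        qx.append(float(q))
    if not ages:
        raise ConfigError(f"life table {path} is empty")
    return LifeTable(ages=tuple(ages), qx=tuple(qx))


def _load_raw(path: Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:  # pragma: no cover - exercised via malformed file test
        raise ConfigError(f"cannot parse {path}: {e}") from e
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    merged: dict = {}
    for inc in raw.pop("include", []) or []:
        merged = _merge(merged, _load_raw(path.parent / inc))
    merged = _merge(merged, raw)
    merged.setdefault("_base_dir", str(path.parent))
    return merged


def _params_from_raw(raw: dict) -> ModelParameters:
    base_dir = Path(raw.get("_base_dir", "."))
    label = _req(raw, "cohort_label", "<root>")

    tables = {
        key: _parse_scan_table(val, f"scan_tables.{key}")
        for key, val in _req(raw, "scan_tables", "<root>").items()
    }

    e = _req(raw, "epidemiology", "<root>")
    epi = EpidemiologyParams(
        total_population=_num(e, "total_population", "epidemiology"),
        age_band_fraction=_num(e, "age_band_fraction", "epidemiology"),
        smoker_fractions={k: float(v) for k, v in e.get("smoker_fractions", {}).items()},
        nonsmoker_high_risk_fraction=float(e.get("nonsmoker_high_risk_fraction", 0.10)),
        annual_lc_incidence=_num(e, "annual_lc_incidence", "epidemiology"),
        clinical_stage_distribution=_renorm(
            {str(k): float(v) for k, v in _req(e, "clinical_stage_distribution", "epidemiology").items()},
            "epidemiology.clinical_stage_distribution",
        ),
        mean_entry_age=_num(e, "mean_entry_age", "epidemiology"),
        uptake=_num(e, "uptake", "epidemiology"),
        adherence_round2plus=_num(e, "adherence_round2plus", "epidemiology"),
        eligible_current_smokers=float(e.get("eligible_current_smokers", 0.0)),
        eligible_ex_smokers=float(e.get("eligible_ex_smokers", 0.0)),
        nonsmoking_pool=float(e.get("nonsmoking_pool", 0.0)),
        target_diagnoses=float(e.get("target_diagnoses", 0.0)),
        target_arm_size=float(e.get("target_arm_size", 0.0)),
    )

    s = _req(raw, "survival", "<root>")
    surv = SurvivalTargets(
        os5y_by_stage={str(k): float(v) for k, v in _req(s, "os5y_by_stage", "survival").items()},
        pfs1y_by_stage={str(k): float(v) for k, v in _req(s, "pfs1y_by_stage", "survival").items()},
    )

    u = _req(raw, "utilities", "<root>")
    gp = u.get("general_population", {})
    util = UtilitySet(
        preprogression_by_stage={str(k): float(v) for k, v in _req(u, "preprogression_by_stage", "utilities").items()},
        postprogression_by_stage={str(k): float(v) for k, v in _req(u, "postprogression_by_stage", "utilities").items()},
        general_population=GeneralPopulationUtility(
            intercept=float(gp.get("intercept", 0.9508566)),
            male_coef=float(gp.get("male_coef", 0.0212126)),
            male_fraction=float(gp.get("male_fraction", 0.456)),
            age_coef=float(gp.get("age_coef", -0.0002587)),
            age2_coef=float(gp.get("age2_coef", -0.0000332)),
        ),
        screening_disutility=float(u.get("screening_disutility", 0.0)),
    )

    c = _req(raw, "costs", "<root>")
    unit_costs = {str(k): float(v) for k, v in _req(c, "unit_costs", "costs").items()}
    utilization = {
        str(iv): {str(ph): {str(st): float(f) for st, f in stages.items()} for ph, stages in phases.items()}
        for iv, phases in _req(c, "utilization", "costs").items()
    }
    costs = CostTable(
        unit_costs=unit_costs,
        utilization=utilization,
        ldct_cost=_num(c, "ldct_cost", "costs"),
        pharmaceuticals=tuple(c.get("pharmaceuticals", ())),
        diagnostic_interventions=tuple(c.get("diagnostic_interventions", ())),
        phase_durations={str(k): float(v) for k, v in _req(c, "phase_durations", "costs").items()},
        stage0_surgery=str(c.get("stage0_surgery", "surgery")),
        stage0_surveillance_schedule=tuple(
            (float(m), str(iv)) for m, iv in c.get("stage0_surveillance_schedule", ())
        ),
        fp_workup_bundle={str(k): float(v) for k, v in c.get("fp_workup_bundle", {}).items()},
    )

    ec = raw.get("econ", {})
    econ = EconSettings(
        discount_rate_costs=float(ec.get("discount_rate_costs", 0.035)),
        discount_rate_health=float(ec.get("discount_rate_health", 0.035)),
        cycle_length_months=float(ec.get("cycle_length_months", 3.0)),
        horizon=ec.get("horizon", "lifetime"),
        wtp_low=float(ec.get("wtp_low", 24302.0)),
        wtp_high=float(ec.get("wtp_high", 40202.0)),
        n_screen_rounds=int(ec.get("n_screen_rounds", 1)),
        half_cycle_correction=bool(ec.get("half_cycle_correction", False)),
    )

    lt_raw = _req(raw, "life_table", "<root>")
    if isinstance(lt_raw, str):
        lt = load_life_table(base_dir / lt_raw)
    else:
        lt = LifeTable(
            ages=tuple(int(a) for a, _ in lt_raw), qx=tuple(float(q) for _, q in lt_raw)
        )

    psa_spec = {str(k): dict(v) for k, v in raw.get("psa_spec", {}).items()}

    params = ModelParameters(
        cohort_label=str(label),
        scan_tables=tables,
        epidemiology=epi,
        survival=surv,
        utilities=util,
        costs=costs,
        econ=econ,
        life_table=lt,
        psa_spec=psa_spec,
    )
    violations = validate_parameters(params)
    if violations:
        raise ConfigError("invalid parameter pack:\n  " + "\n  ".join(violations))
    return params


def load_parameters(path: str | Path) -> ModelParameters:
    """Load and validate a parameter pack from a YAML config file."""
    return _params_from_raw(_load_raw(Path(path)))


def fixture_path(name: str) -> Path:
    """Path to a packaged fixture file (e.g. ``smoking.yaml``)."""
    return Path(str(resources.files("screencea") / "fixtures" / name))


def load_fixture(cohort: str) -> ModelParameters:
    """Load a packaged cohort pack: ``smoking`` or ``nonsmoking``."""
    if cohort not in ("smoking", "nonsmoking"):
        raise ConfigError(f"unknown cohort {cohort!r}")
    return load_parameters(fixture_path(f"{cohort}.yaml"))


def config_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# writing packs back out (round-trip support)
# ---------------------------------------------------------------------------


def _scan_table_to_raw(t: ScanOutcomeTable) -> dict:
    return {
        "regular": {
            "negative": t.p_regular_negative,
            "indeterminate": t.p_regular_indeterminate,
            "positive": t.p_regular_positive,
        },
        "recall": {"negative": t.p_indeterminate_negative, "positive": t.p_indeterminate_positive},
        "negatives": {"true_negative": t.p_true_negative, "false_negative": t.p_false_negative},
        "positives": {"true_positive": t.p_true_positive, "false_positive": t.p_false_positive},
        "stage_distribution": dict(t.stage_distribution),
    }


def write_parameters(p: ModelParameters, path: str | Path) -> None:
    """Serialize a pack to one self-contained YAML file (load round-trips)."""
    epi = asdict(p.epidemiology)
    raw = {
        "cohort_label": p.cohort_label,
        "scan_tables": {k: _scan_table_to_raw(t) for k, t in p.scan_tables.items()},
        "epidemiology": epi,
        "survival": asdict(p.survival),
        "utilities": {
            "preprogression_by_stage": dict(p.utilities.preprogression_by_stage),
            "postprogression_by_stage": dict(p.utilities.postprogression_by_stage),
            "general_population": asdict(p.utilities.general_population),
            "screening_disutility": p.utilities.screening_disutility,
        },
        "costs": {
            "unit_costs": dict(p.costs.unit_costs),
            "utilization": {iv: {ph: dict(st) for ph, st in phs.items()} for iv, phs in p.costs.utilization.items()},
            "ldct_cost": p.costs.ldct_cost,
            "pharmaceuticals": list(p.costs.pharmaceuticals),
            "diagnostic_interventions": list(p.costs.diagnostic_interventions),
            "phase_durations": dict(p.costs.phase_durations),
            "stage0_surgery": p.costs.stage0_surgery,
            "stage0_surveillance_schedule": [[m, iv] for m, iv in p.costs.stage0_surveillance_schedule],
            "fp_workup_bundle": dict(p.costs.fp_workup_bundle),
        },
        "econ": {
            "discount_rate_costs": p.econ.discount_rate_costs,
            "discount_rate_health": p.econ.discount_rate_health,
            "cycle_length_months": p.econ.cycle_length_months,
            "horizon": p.econ.horizon,
            "wtp_low": p.econ.wtp_low,
            "wtp_high": p.econ.wtp_high,
            "n_screen_rounds": p.econ.n_screen_rounds,
            "half_cycle_correction": p.econ.half_cycle_correction,
        },
        "life_table": [[a, q] for a, q in zip(p.life_table.ages, p.life_table.qx)],
        "psa_spec": {k: dict(v) for k, v in p.psa_spec.items()},
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))
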