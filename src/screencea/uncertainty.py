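"""Sensitivity machinery: one-way deterministic analysis with tornado
ranking, probabilistic sensitivity analysis with the stated distribution
families (Dirichlet for multinomial outcome tables, Beta for utilities and
proportions, Gamma for costs and counts), cost-effectiveness acceptability
curves, and the scenario grid.

PSA sampling is moment-matched (means equal the base case) and uses
counter-based substreams - one child seed per iteration - so results are
bit-reproducible for a fixed root seed regardless of evaluation order.
A global ``dispersion_scale`` multiplies every group's spread; zero gives
exact point-mass sampling (every draw is the base case).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import CEAResult
from .engine import RunOptions, run_cea
from .params import ConfigError, ModelParameters, STAGES
from .synthetic import gen_scan_table


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

_PARAM_OVERRIDES = frozenset({
    "uptake", "adherence_round2plus", "mean_entry_age", "target_diagnoses",
    "discount_rate_costs", "discount_rate_health", "screening_disutility",
    "ldct_cost", "unit_costs", "survival_targets", "n_screen_rounds",
})
_OPTION_OVERRIDES = frozenset({
    "horizon_years", "bg_mortality_multiplier", "cost_scales",
})


@dataclass
class ScenarioSpec:
    """Named set of parameter overrides for a what-if run."""

    name: str
    overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = set(self.overrides) - _PARAM_OVERRIDES - _OPTION_OVERRIDES
        if unknown:
            raise ConfigError(f"scenario {self.name!r}: unknown overrides {sorted(unknown)}")


def apply_overrides(params: ModelParameters, spec: ScenarioSpec) -> tuple[ModelParameters, RunOptions]:
    spec.validate()
    p = params.copy()
    opts = RunOptions(calibration_clip=True)
    ov = spec.overrides
    epi, econ = p.epidemiology, p.econ
    if "uptake" in ov:
        epi.uptake = float(ov["uptake"])
    if "adherence_round2plus" in ov:
        epi.adherence_round2plus = float(ov["adherence_round2plus"])
    if "mean_entry_age" in ov:
        epi.mean_entry_age = float(ov["mean_entry_age"])
    if "target_diagnoses" in ov:
        epi.target_diagnoses = float(ov["target_diagnoses"])
    if "discount_rate_costs" in ov:
        econ.discount_rate_costs = float(ov["discount_rate_costs"])
    if "discount_rate_health" in ov:
        econ.discount_rate_health = float(ov["discount_rate_health"])
    if "n_screen_rounds" in ov:
        econ.n_screen_rounds = int(ov["n_screen_rounds"])
    if "screening_disutility" in ov:
        p.utilities.screening_disutility = float(ov["screening_disutility"])
    if "ldct_cost" in ov:
        p.costs.ldct_cost = float(ov["ldct_cost"])
    for name, value in ov.get("unit_costs", {}).items():
        if name not in p.costs.unit_costs:
            raise ConfigError(f"scenario {spec.name!r}: unknown unit cost {name!r}")
        p.costs.unit_costs[name] = float(value)
    st = ov.get("survival_targets", {})
    for s, v in st.get("os5y_by_stage", {}).items():
        p.survival.os5y_by_stage[str(s)] = float(v)
    for s, v in st.get("pfs1y_by_stage", {}).items():
        p.survival.pfs1y_by_stage[str(s)] = float(v)
    if "horizon_years" in ov:
        opts.horizon_years = float(ov["horizon_years"])
    if "bg_mortality_multiplier" in ov:
        opts.bg_multiplier = float(ov["bg_mortality_multiplier"])
    if "cost_scales" in ov:
        opts.cost_scales = {k: dict(v) for k, v in ov["cost_scales"].items()}
    return p, opts


def run_scenario(spec: ScenarioSpec, params: ModelParameters) -> CEAResult:
    p, opts = apply_overrides(params, spec)
    return run_cea(p, opts)


# EGFR-weight variants of early-stage disease-free survival: blended 1-y DFS
# using approximate trial-arm anchors (EGFR-mutant on adjuvant TKI ~0.90,
# EGFR-wild-type ~0.70); the base-case anchor corresponds to neither weight.
_PFS_EGFR = {"10": 0.10 * 0.90 + 0.90 * 0.70, "25": 0.25 * 0.90 + 0.75 * 0.70}

#: the packaged what-if grid (one spec per published scenario row)
SCENARIO_GRID: tuple[ScenarioSpec, ...] = (
    ScenarioSpec("base_case"),
    ScenarioSpec("uptake_25pct", {"uptake": 0.25}),
    ScenarioSpec("uptake_75pct", {"uptake": 0.75}),
    ScenarioSpec("horizon_5y", {"horizon_years": 5}),
    ScenarioSpec("horizon_10y", {"horizon_years": 10}),
    ScenarioSpec("horizon_15y", {"horizon_years": 15}),
    ScenarioSpec("discount_0pct", {"discount_rate_costs": 0.0, "discount_rate_health": 0.0}),
    ScenarioSpec("discount_6pct", {"discount_rate_costs": 0.06, "discount_rate_health": 0.06}),
    ScenarioSpec("screening_disutility", {"screening_disutility": 0.0024}),
    ScenarioSpec("background_mortality_x2", {"bg_mortality_multiplier": 2.0}),
    ScenarioSpec(
        "dfs_egfr_weight_10_90",
        {"survival_targets": {"pfs1y_by_stage": {"I": _PFS_EGFR["10"], "II": _PFS_EGFR["10"]}}},
    ),
    ScenarioSpec(
        "dfs_egfr_weight_25_75",
        {"survival_targets": {"pfs1y_by_stage": {"I": _PFS_EGFR["25"], "II": _PFS_EGFR["25"]}}},
    ),
    # stage-level 5-y OS in the spirit of the IASLC staging-project clinical
    # stages (approximate plug-in values)
    ScenarioSpec(
        "iaslc_survival",
        {"survival_targets": {"os5y_by_stage": {"I": 0.60, "II": 0.42, "III": 0.22, "IV": 0.06}}},
    ),
    ScenarioSpec("ldct_cost_191", {"ldct_cost": 191.0}),
    ScenarioSpec("ldct_cost_127", {"ldct_cost": 127.0}),
    ScenarioSpec("ldct_cost_63", {"ldct_cost": 63.0}),
    ScenarioSpec("half_diagnostic_cost_stage_I", {"cost_scales": {"diagnostic": {"I": 0.5}}}),
    ScenarioSpec("half_diagnostic_cost_stage_IV", {"cost_scales": {"diagnostic": {"IV": 0.5}}}),
    ScenarioSpec("half_ongoing_cost_stage_I", {"cost_scales": {"ongoing": {"I": 0.5}}}),
    ScenarioSpec("half_ongoing_cost_stage_IV", {"cost_scales": {"ongoing": {"IV": 0.5}}}),
)


def run_scenario_grid(params: ModelParameters, grid=SCENARIO_GRID) -> pd.DataFrame:
    rows = []
    for spec in grid:
        r = run_scenario(spec, params)
        rows.append(
            {
                "scenario": spec.name,
                "icer_per_qaly": r.icer_per_qaly.raw,
                "icer_per_lyg": r.icer_per_lyg.raw,
                "incr_cost": r.incr_cost,
                "incr_qaly": r.incr_qaly,
                "qaly_gained_per_diagnosis": (
                    r.incr_qaly / r.screening.diagnoses_total if r.screening.diagnoses_total else math.nan
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-way sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class TornadoEntry:
    parameter_name: str
    icer_low: float      # ICER at the downward perturbation
    icer_high: float     # ICER at the upward perturbation
    range_width: float


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def _owsa_parameters(params: ModelParameters):
    """(name, setter(p, factor)) pairs: every Table-style scalar plus one
    aggregate cost multiplier per microcosting block."""

    entries = []

    def scalar(name, get, set_, probability=False):
        base = get(params)

        def apply(p: ModelParameters, factor: float) -> None:
            v = base * factor
            set_(p, _clamp01(v) if probability else v)

        entries.append((name, apply))

    scalar("uptake", lambda p: p.epidemiology.uptake,
           lambda p, v: setattr(p.epidemiology, "uptake", v), probability=True)
    scalar("adherence_round2plus", lambda p: p.epidemiology.adherence_round2plus,
           lambda p, v: setattr(p.epidemiology, "adherence_round2plus", v), probability=True)
    scalar("lifetime_lc_incidence", lambda p: p.epidemiology.target_diagnoses,
           lambda p, v: setattr(p.epidemiology, "target_diagnoses", v))
    scalar("ldct_unit_cost", lambda p: p.costs.ldct_cost,
           lambda p, v: setattr(p.costs, "ldct_cost", v))
    scalar("discount_rate_costs", lambda p: p.econ.discount_rate_costs,
           lambda p, v: setattr(p.econ, "discount_rate_costs", v))
    scalar("discount_rate_health", lambda p: p.econ.discount_rate_health,
           lambda p, v: setattr(p.econ, "discount_rate_health", v))
    for s in STAGES:
        scalar(f"utility_preprogression_{s}",
               lambda p, s=s: p.utilities.preprogression_by_stage[s],
               lambda p, v, s=s: p.utilities.preprogression_by_stage.__setitem__(s, v),
               probability=True)
        scalar(f"utility_postprogression_{s}",
               lambda p, s=s: p.utilities.postprogression_by_stage[s],
               lambda p, v, s=s: p.utilities.postprogression_by_stage.__setitem__(s, v),
               probability=True)
        scalar(f"os5y_{s}",
               lambda p, s=s: p.survival.os5y_by_stage[s],
               lambda p, v, s=s: p.survival.os5y_by_stage.__setitem__(s, min(v, 1.0 - 1e-9)),
               probability=True)
        scalar(f"pfs1y_{s}",
               lambda p, s=s: p.survival.pfs1y_by_stage[s],
               lambda p, v, s=s: p.survival.pfs1y_by_stage.__setitem__(s, min(v, 1.0 - 1e-9)),
               probability=True)

    blocks = {
        "diagnostics_imaging_costs": list(params.costs.diagnostic_interventions),
        "surgery_costs": [params.costs.stage0_surgery],
        "radiotherapy_costs": ["intracranial_rt", "sabr", "palliative_rt"],
        "systemic_therapy_costs": list(params.costs.pharmaceuticals),
    }

    for block, names in blocks.items():
        names = [n for n in names if n in params.costs.unit_costs]

        def apply(p: ModelParameters, factor: float, names=tuple(names)) -> None:
            for n in names:
                p.costs.unit_costs[n] *= factor

        entries.append((block, apply))
    return entries


def owsa(params: ModelParameters, fraction: float = 0.20) -> list[TornadoEntry]:
    """Deterministic +/-``fraction`` perturbation of each scalar parameter,
    full model re-run, entries ranked by ICER range (ties by name)."""
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    entries = []
    for name, apply in _owsa_parameters(params):
        icers = {}
        for tag, factor in (("low", 1.0 - fraction), ("high", 1.0 + fraction)):
            p = params.copy()
            apply(p, factor)
            r = run_cea(p, RunOptions(calibration_clip=True))
            icers[tag] = r.icer_per_qaly.raw if r.icer_per_qaly.raw is not None else math.nan
        width = abs(icers["high"] - icers["low"])
        entries.append(
            TornadoEntry(name, icers["low"], icers["high"], 0.0 if math.isnan(width) else width)
        )
    entries.sort(key=lambda e: (-e.range_width, e.parameter_name))
    return entries


def tornado_report(entries: list[TornadoEntry], png_path=None, base_icer: float | None = None) -> pd.DataFrame:
    """Ranked tornado table; optionally also a horizontal-bar figure."""
    if not entries:
        raise ValueError("no tornado entries")
    ordered = sorted(entries, key=lambda e: (-e.range_width, e.parameter_name))
    df = pd.DataFrame(
        [
            {
                "parameter": e.parameter_name,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "range_width": e.range_width,
            }
            for e in ordered
        ]
    )
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        top = ordered[:15][::-1]
        fig, ax = plt.subplots(figsize=(8, 0.4 * len(top) + 1.5))
        for i, e in enumerate(top):
            lo, hi = sorted((e.icer_low, e.icer_high))
            ax.barh(i, hi - lo, left=lo, color="#4878b0")
        ax.set_yticks(range(len(top)))
        ax.set_yticklabels([e.parameter_name for e in top], fontsize=8)
        if base_icer is not None:
            ax.axvline(base_icer, color="k", lw=1, ls="--", label="base case")
            ax.legend(fontsize=8)
        ax.set_xlabel("ICER (US$/QALY)")
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
    return df


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PSAResult:
    draws: np.ndarray        # [n, 2]: (incr_cost, incr_qaly)
    icers: np.ndarray        # [n]
    mean_icer: float         # mean of per-draw ICERs
    icer_of_means: float     # mean(dC) / mean(dQ)
    seed: int
    n_iterations: int


def _beta_moment(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd <= 0.0 or mean <= 0.0 or mean >= 1.0:
        return mean
    bound = mean * (1.0 - mean)
    var = min(sd * sd, 0.81 * bound)
    nu = bound / var - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def _gamma_moment(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd <= 0.0 or mean <= 0.0:
        return mean
    shape = (mean / sd) ** 2
    return float(rng.gamma(shape, sd * sd / mean))


def sample_parameters(
    params: ModelParameters, rng: np.random.Generator, dispersion_scale: float = 1.0
) -> ModelParameters:
    """One joint draw of the uncertain parameter groups, moment-matched to
    the base case per ``params.psa_spec``.  ``dispersion_scale = 0`` returns
    an exact copy (point-mass sampling)."""
    p = params.copy()
    if dispersion_scale == 0.0:
        return p
    spec = p.psa_spec

    conc = float(spec.get("scan_tables", {}).get("concentration", 1000.0)) / dispersion_scale
    p.scan_tables = {k: gen_scan_table(None, conc, t, rng=rng) for k, t in p.scan_tables.items()}

    conc_c = float(spec.get("clinical_stage_distribution", {}).get("concentration", 1000.0)) / dispersion_scale
    dist = p.epidemiology.clinical_stage_distribution
    alphas = np.array([dist[s] for s in STAGES]) * conc_c
    draw = np.array([rng.gamma(a, 1.0) if a > 0 else 0.0 for a in alphas])
    p.epidemiology.clinical_stage_distribution = dict(zip(STAGES, draw / draw.sum()))

    se_u = float(spec.get("utilities", {}).get("rel_se", 0.10)) * dispersion_scale
    for m in (p.utilities.preprogression_by_stage, p.utilities.postprogression_by_stage):
        for s in m:
            m[s] = _beta_moment(rng, m[s], se_u * m[s])

    se_c = float(spec.get("unit_costs", {}).get("rel_se", 0.10)) * dispersion_scale
    for k in p.costs.unit_costs:
        p.costs.unit_costs[k] = _gamma_moment(rng, p.costs.unit_costs[k], se_c * p.costs.unit_costs[k])
    p.costs.ldct_cost = _gamma_moment(rng, p.costs.ldct_cost, se_c * p.costs.ldct_cost)

    se_p = float(spec.get("uptake", {}).get("rel_se", 0.10)) * dispersion_scale
    p.epidemiology.uptake = _beta_moment(rng, p.epidemiology.uptake, se_p * p.epidemiology.uptake)
    se_a = float(spec.get("adherence", {}).get("rel_se", 0.10)) * dispersion_scale
    p.epidemiology.adherence_round2plus = _beta_moment(
        rng, p.epidemiology.adherence_round2plus, se_a * p.epidemiology.adherence_round2plus
    )

    se_i = float(spec.get("incidence", {}).get("rel_se", 0.10)) * dispersion_scale
    p.epidemiology.target_diagnoses = _gamma_moment(
        rng, p.epidemiology.target_diagnoses, se_i * p.epidemiology.target_diagnoses
    )
    return p


def psa(
    params: ModelParameters,
    n_iterations: int,
    seed: int,
    *,
    dispersion_scale: float = 1.0,
) -> PSAResult:
    """Probabilistic sensitivity analysis: ``n_iterations`` joint parameter
    draws, full two-arm re-run each, deterministic under a fixed seed."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if dispersion_scale < 0:
        raise ConfigError("dispersion_scale must be nonnegative")
    from .disease import calibrate_hazards

    hazards = calibrate_hazards(params.survival)  # survival anchors not sampled
    draws = np.empty((n_iterations, 2))
    icers = np.empty(n_iterations)
    for i in range(n_iterations):
        rng = np.random.default_rng([int(seed), i])
        p = sample_parameters(params, rng, dispersion_scale)
        r = run_cea(p, RunOptions(calibration_clip=True), hazards=hazards)
        draws[i] = (r.incr_cost, r.incr_qaly)
        icers[i] = r.icer_per_qaly.raw if r.icer_per_qaly.raw is not None else math.nan
    dq = draws[:, 1].mean()
    return PSAResult(
        draws=draws,
        icers=icers,
        mean_icer=float(np.nanmean(icers)),
        icer_of_means=float(draws[:, 0].mean() / dq) if dq != 0 else math.nan,
        seed=int(seed),
        n_iterations=n_iterations,
    )


def ceac(result: PSAResult, wtp_grid) -> dict[float, float]:
    """Probability cost-effective at each willingness-to-pay grid point:
    the fraction of draws with positive net monetary benefit."""
    if result.n_iterations == 0:
        raise ValueError("empty PSA result")
    out = {}
    dc, dq = result.draws[:, 0], result.draws[:, 1]
    for w in wtp_grid:
        out[float(w)] = float(np.mean(dq * w - dc > 0.0))
    return out
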