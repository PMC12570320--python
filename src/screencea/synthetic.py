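"""Synthetic inputs with the statistical structure the analysis assumes.

Real Hong Kong life-table values are not part of the parameter pack, so a
Gompertz-Makeham stand-in is generated here (and shipped as the packaged
``life_table_synthetic.csv``): the simplest adult-mortality law with an
age-increasing hazard, with defaults tuned so life expectancy at age 58 is
about 27 years.  The module also draws Dirichlet-perturbed scan-outcome
tables and fully valid jittered cohort packs for fast end-to-end testing.
No demographic accuracy for Hong Kong is claimed.
"""

from __future__ import annotations

import math

import numpy as np

from .params import (
    LifeTable,
    ModelParameters,
    ScanOutcomeTable,
    load_fixture,
    validate_parameters,
)

# Gompertz-Makeham defaults: annual hazard mu(x) = a + b * c**x
DEFAULT_MAKEHAM_A = 4.0e-4
DEFAULT_GOMPERTZ_B = 2.0e-5
DEFAULT_GOMPERTZ_C = 1.10


class LifeTableParameterError(ValueError):
    pass


def gen_life_table(
    seed: int | None = None,
    makeham_a: float = DEFAULT_MAKEHAM_A,
    gompertz_b: float = DEFAULT_GOMPERTZ_B,
    gompertz_c: float = DEFAULT_GOMPERTZ_C,
    age_min: int = 40,
    age_max: int = 100,
    jitter_sd: float = 0.0,
) -> LifeTable:
    """Annual death probabilities q(x) = 1 - exp(-(a + b*c**x)).

    Deterministic given parameters; ``seed``/``jitter_sd`` produce lognormal
    hazard-jittered variants for robustness tests.
    """
    if makeham_a < 0 or gompertz_b < 0 or gompertz_c <= 0:
        raise LifeTableParameterError("hazard parameters must be nonnegative (c > 0)")
    ages = np.arange(age_min, age_max + 1)
    hazard = makeham_a + gompertz_b * gompertz_c ** ages.astype(float)
    if jitter_sd > 0.0:
        rng = np.random.default_rng(seed)
        hazard = hazard * np.exp(rng.normal(0.0, jitter_sd, size=hazard.shape))
    qx = -np.expm1(-hazard)
    if np.any(qx >= 1.0):
        first = int(ages[np.argmax(qx >= 1.0)])
        if first < age_max:
            raise LifeTableParameterError(f"q(x) reaches 1 at age {first}, before the terminal row")
        qx = np.minimum(qx, 1.0)
    if np.any(qx <= 0.0):
        raise LifeTableParameterError("death probabilities must be positive")
    return LifeTable(ages=tuple(int(a) for a in ages), qx=tuple(float(q) for q in qx))


def life_expectancy(lt: LifeTable, age: int) -> float:
    """Curtate-plus-half life expectancy implied by the table (terminal
    hazard reused beyond the last row)."""
    alive = 1.0
    total = 0.0
    a = age
    while alive > 1e-12 and a < 130:
        q = lt.annual_q(a)
        total += alive * (1.0 - q / 2.0)
        alive *= 1.0 - q
        a += 1
    return total


def write_life_table_csv(lt: LifeTable, path) -> None:
    lines = ["age,annual_death_probability"]
    lines += [f"{a},{q!r}" for a, q in zip(lt.ages, lt.qx)]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _dirichlet(rng: np.random.Generator, probs: list[float], concentration: float) -> list[float]:
    """Dirichlet draw centered on ``probs``; zero components stay zero."""
    alphas = np.asarray(probs) * concentration
    draws = np.array([rng.gamma(a, 1.0) if a > 0 else 0.0 for a in alphas])
    if draws.sum() <= 0:
        return [float(p) for p in probs]
    return [float(x) for x in draws / draws.sum()]


def gen_scan_table(
    seed: int | None,
    concentration: float,
    template: ScanOutcomeTable,
    rng: np.random.Generator | None = None,
) -> ScanOutcomeTable:
    """Sample each simplex block of a scan table from a Dirichlet centered
    on the template.  ``concentration -> inf`` returns the template."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    reg = _dirichlet(rng, [template.p_regular_negative, template.p_regular_indeterminate, template.p_regular_positive], concentration)
    rec = _dirichlet(rng, [template.p_indeterminate_negative, template.p_indeterminate_positive], concentration)
    neg = _dirichlet(rng, [template.p_true_negative, template.p_false_negative], concentration)
    pos = _dirichlet(rng, [template.p_true_positive, template.p_false_positive], concentration)
    stages = list(template.stage_distribution)
    sd = _dirichlet(rng, [template.stage_distribution[s] for s in stages], concentration)
    return ScanOutcomeTable(
        p_regular_negative=reg[0],
        p_regular_indeterminate=reg[1],
        p_regular_positive=reg[2],
        p_indeterminate_negative=rec[0],
        p_indeterminate_positive=rec[1],
        p_true_negative=neg[0],
        p_false_negative=neg[1],
        p_true_positive=pos[0],
        p_false_positive=pos[1],
        stage_distribution=dict(zip(stages, sd)),
    )


def gen_cohort_fixture(seed: int, scale: float = 1000.0, cohort: str = "smoking") -> ModelParameters:
    """A fully valid, small jittered parameter pack for fast end-to-end runs.

    Starts from the packaged cohort pack, perturbs the scan tables
    (Dirichlet), survival targets, utilities and unit costs, swaps in a
    jittered synthetic life table, and rescales the cohort to ``scale``
    persons.  Deterministic given ``seed``.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    rng = np.random.default_rng([int(seed), 2023])
    p = load_fixture(cohort)

    p.scan_tables = {
        key: gen_scan_table(None, 2000.0, tab, rng=rng) for key, tab in p.scan_tables.items()
    }

    # survival targets: jitter on the log-hazard scale, preserving the
    # stage ordering of 5-y OS and pfs >= os feasibility
    os5, pfs1 = {}, {}
    for s in ("I", "II", "III", "IV"):
        f = math.exp(rng.normal(0.0, 0.05))
        os5[s] = p.survival.os5y_by_stage[s] ** f
        pfs1[s] = p.survival.pfs1y_by_stage[s] ** f
    order = sorted(os5.values(), reverse=True)
    p.survival.os5y_by_stage = dict(zip(("I", "II", "III", "IV"), order))
    p.survival.pfs1y_by_stage = pfs1

    for s in p.utilities.preprogression_by_stage:
        u = p.utilities.preprogression_by_stage[s] * math.exp(rng.normal(0.0, 0.03))
        p.utilities.preprogression_by_stage[s] = min(1.0, u)
    for s in p.utilities.postprogression_by_stage:
        u = p.utilities.postprogression_by_stage[s] * math.exp(rng.normal(0.0, 0.03))
        p.utilities.postprogression_by_stage[s] = min(1.0, u)

    for k in p.costs.unit_costs:
        p.costs.unit_costs[k] *= math.exp(rng.normal(0.0, 0.10))
    p.costs.ldct_cost *= math.exp(rng.normal(0.0, 0.10))

    p.life_table = gen_life_table(seed=int(rng.integers(0, 2**31 - 1)), jitter_sd=0.05)

    epi = p.epidemiology
    frac = epi.target_diagnoses / epi.target_arm_size if epi.target_arm_size else 0.15
    epi.eligible_current_smokers = scale / max(epi.uptake, 1e-9)
    epi.eligible_ex_smokers = 0.0
    epi.nonsmoking_pool = scale / max(epi.uptake * epi.nonsmoker_high_risk_fraction, 1e-9)
    epi.target_arm_size = scale
    epi.target_diagnoses = scale * frac * math.exp(rng.normal(0.0, 0.05))

    assert validate_parameters(p) == [], "synthetic pack must validate"
    return p
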