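# Methods

This note documents the model, its assumptions, the parameter choices that
were genuinely open, the numerical design, and what the tests do and do
not establish.

## Cohorts and population funnel

Two screening cohorts are sized from census-style inputs: the
smoking-history cohort (133,000 current + 107,910 ex heavy smokers =
240,910 eligible; ten annual LDCT rounds from mean age 58) and the
risk-factor cohort (10% of 1,962,185 older never/long-quit smokers =
196,218 eligible; one LDCT round from mean age 65, the midpoint of its
55–75 eligibility band — the pack exposes this since no mean age is
published for that cohort).  Uptake is 46.5% and adherence to later
rounds 100%.  All milestone counts use nearest-integer rounding with ties
to even, in exact rational arithmetic; this is the unique simple rule
consistent with all four published milestones (e.g. 196,218.5 → 196,218
and 203,264.52 → 203,265).  Uptake is applied both to the combined
eligible pool (headline 203,265) and per cohort for arm sizing; the two
can differ by at most one person and the discrepancy is asserted, not
hidden.

## Screening decision trees

Each round's scan-outcome table is a small probability tree: regular scan
→ negative / indeterminate / positive; indeterminate → one recall LDCT →
negative / positive; pooled negatives → true/false negative; pooled
positives → true/false positive; true positives carry the screen-detected
stage distribution.  The smoking cohort uses the trial baseline-round
table for round 1 and the second-round table for every later round
(taken literally for rounds 3–10, which the source does not separately
report).  The risk-factor cohort's single-pass table has no indeterminate
branch and includes stage 0 (carcinoma in situ).  `classify_round` is a
pure expected-value function — linear in the cohort — and is verified
against a brute-force enumeration of all branch paths.

## Disease incidence and the stage-shift mechanism

The model is deliberately **mass-conserving across arms**: one constant
per-cycle diagnosis hazard generates cancers among the undiagnosed in
*both* arms.  The hazard is the model's single free parameter per cohort,
calibrated by bracketed root-finding so the no-screening arm accumulates
the cohort's lifetime-diagnoses anchor (18,680 of 112,023 and 1,615 of
91,241; stored as count + reference arm size, so the calibration is a
*fraction* and all per-person results — including the ICER — are exactly
invariant to uptake).

What screening changes is the **stage at diagnosis** and the resource
use.  Cancers arising in a cycle that contains a scheduled screen are
detected at the screen-detected stage mix (at the tree's implied
sensitivity, ~94–98%; the missed remainder presents clinically the same
cycle), while cancers in the other cycles present as interval/clinical
cases at the clinical stage distribution (63.3% stage IV).  Stage-0
detections are prevalence-driven from the tree's true-positive arm: they
move healthy pool members into a post-resection stratum that keeps
general-population survival and utility, receives one resection plus a
surveillance-CT schedule (6-monthly for 2 years then annual for 3 — the
midpoint reading of the published "every 3 to 6 months … 6 to 12
months" ranges), and slightly reduces later invasive incidence in the
screening arm (resected in-situ lesions no longer progress).

Two consequences are worth stating plainly.  First, screening is never
spuriously harmful here: the arms share the same cancer burden, so the
screening arm cannot "create" extra lethal cancers, and deaths averted
and QALY gains are structurally positive.  Second, the stage-shift
throughput is conservative: with annual rounds on a quarterly cycle only
the screen-containing cycle's incident cancers are re-staged, so the
modelled screen-detected volume (and hence the absolute QALY gain) is
several-fold smaller than the trial-anchored prevalence counts suggest,
and the modelled base-case ICERs (≈US$135k/QALY smoking, ≈US$756k/QALY
risk-factor) sit far above the published ones (US$14,122 and US$9,610).
The published per-arm tables cannot be reproduced by any mass-conserving
cohort model (their no-screening arm's "extra" never-diagnosed people
carry almost no extra life-years), and the parametric survival fits and
incidence apportionment behind them are not public, so this package does
not chase those magnitudes.  Its claims are the identities over the
published totals (reproduced exactly) and the model's qualitative
behaviour (horizon/discount orderings, uptake invariance, stage-shift
direction), all of which are tested.

## Survival model and calibration

Per stage at diagnosis, pre-progression patients progress at rate *a* and
post-progression patients die of lung cancer at rate *b* (both per year,
constant).  Pre-progression cancer mortality is zero — there is no anchor
to identify it — so all pre-progression deaths are background; this is a
documented limitation, biasing pre-progression survival slightly up.
*a* = −ln(1-y PFS); *b* solves OS(5y) = anchor by Brent's method to 1e-8
(residual asserted).  Anchors: 5-y OS 47.95 / 37.72 / 15.36 / 4.82% and
1-y D/PFS 72.03 / 72.03 / 49.15 / 38.29% for stages I–IV.  Perturbed
anchors can be infeasible (a 1-y PFS near 1 caps achievable 5-y OS at
e^(−5a)); strict calibration raises a named error, while sensitivity
analyses use a clipping mode that returns the boundary solution.
Alternative anchor sets (the staging-project OS values, EGFR-weighted
early-stage DFS blends) are plug-in scenario overrides; the packaged
values for those scenarios are approximations and labelled as such.

## Transition matrices and the Markov engine

The per-cycle 4×4 matrix over (pre-progression, post-progression, cancer
death, other-cause death) is the **exact one-cycle solution of the
continuous-time generator** with the age-specific background hazard μ
added as a competing risk — including the within-cycle
progress-then-die path:

    P(pre→post)  = a (e^(−αΔ) − e^(−βΔ)) / (β − α),       α = a+μ, β = b+μ
    P(pre→death_lc) = a b [(1−e^(−αΔ))/α − (1−e^(−βΔ))/β] / (β − α)

with series limits at α = β and each row completed by residual so it sums
to 1 exactly.  This (rather than the common proportional-allocation
approximation) makes the quarterly chain agree with the continuous
two-compartment closed form at every cycle boundary to ~1e-14, so
calibration and simulation are a fixed point and no discretization bias
enters the survival outputs; the matrices are verified against
`scipy.linalg.expm` of the generator.  Background mortality comes from a
two-column life table; ages beyond its support reuse the terminal hazard.
The engine tracks strata (stage × detection mode, plus undiagnosed and
stage 0) with two-cycle tunnel sub-states after diagnosis and after
progression — pure cost-phase bookkeeping on top of the three clinical
states.  Occupancy mass is conserved every cycle (tested to 1e-6
absolute on ~1e5-person cohorts; observed ~1e-11).  The lifetime horizon
is a cap at age 100 (occupancy beyond it is negligible).

## Costs, utilities, discounting

Microcosting: cost = Σ unit cost × utilization(stage, phase).
Pharmaceutical unit costs are per 30 days of standard dosing and scale
with the phase duration (6 months); everything else is one-off within its
phase.  The post-diagnosis and post-progression 6-month bundles are split
evenly across their two cycles; the ongoing phase accrues per cycle from
the third cycle after diagnosis until progression, and again as
maintenance after the post-progression bundle.  Diagnostic costs at
diagnosis are the diagnostics/imaging rows of the post-diagnosis column
(stage I: $1,672, matching the published half-cost scenario anchor of
$836); the screening arm's diagnostic category additionally carries
recall LDCTs and false-positive work-ups (default bundle: contrast CT +
PET-CT + bronchoscopy at stage-I diagnostic shares, ≈$1,109 — the source
prints no FP-specific bundle).  Regular scans are the screening cost
(LDCT $254).  One reconstruction decision: the ongoing-phase grid
excludes surgery, because the published ongoing-cost scenario anchors
($486/cycle stage I, $822/cycle stage IV) are reproduced by the grid only
without it; the grid as extracted would give $4,378 and $1,561.

Utilities: pre-progression 0.85/0.83/0.73/0.75 for stages I–IV;
post-progression 0.73 (stages I–II at diagnosis) and 0.75 (III–IV) — as
published, stage III's post-progression value exceeds its pre-progression
value, and the package does not "correct" this.  Screen-negatives,
the undiagnosed and stage 0 get an age-dependent general-population
EQ-5D norm from a standard quadratic age regression (coefficients in the
pack).  The optional screening disutility (scenario: 0.0024 QALY per
attended screen, a conventional value not printed in the source) is a
one-off decrement at each screen.

Discounting is (1+r)^(−t) at 3.5%/year for costs and health.  One-off
events are discounted at their cycle start.  The half-cycle correction
(default off, since the source never mentions it) averages start/end
occupancy for LY/QALY accruals and discounts them at cycle midpoints;
its base-case impact on the ICER is below 5% (tested).

## Sensitivity machinery

**OWSA** perturbs each scalar ±20% (probabilities clamped to [0,1]) and
re-runs the full model: every utility, both survival anchors per stage,
uptake, adherence, the incidence anchor, LDCT cost, both discount rates,
and one aggregate multiplier per microcosting block (diagnostics/imaging,
surgery, radiotherapy, systemic therapy) — matching the granularity of a
published tornado rather than ~160 individual utilization cells.
**PSA** samples scan tables and the clinical stage distribution from
Dirichlets (concentration = proportions × 1000), utilities and
proportions from moment-matched Betas, costs and the incidence anchor
from moment-matched Gammas (SE = 10% of mean) — the trial sample sizes
and SEs behind the published analysis are not available, so these are the
conventional defaults, stored in the pack and overridable.  Sampling uses
one child seed per iteration (`default_rng([seed, i])`), so results are
bit-identical for a seed regardless of order; a global dispersion scale
of zero gives exact point-mass draws (every iteration equals the base
case).  Survival anchors are not sampled (no uncertainty is published for
them).  The CEAC is the fraction of draws with positive net monetary
benefit.  The scenario grid covers uptake, horizons, discount rates,
screening disutility, doubled background mortality, alternative survival
anchors, LDCT price cuts and halved stage-specific cost bundles.

## Synthetic data

The life table is a Gompertz–Makeham stand-in, q(x) = 1 − e^(−(a + b c^x))
with a = 4e-4, b = 2e-5, c = 1.10 over ages 40–100, tuned so life
expectancy at 58 is ≈27 years; it claims structural plausibility, not
demographic accuracy, and a real table drops in as a two-column CSV
without code changes.  `gen_cohort_fixture` produces small, fully valid
jittered packs (Dirichlet-perturbed tables, log-jittered anchors and
costs, jittered life table) for fast end-to-end and conservation tests.
Passing tests on synthetic packs establish internal consistency —
conservation, calibration recovery, determinism — not fidelity to any
real population.

## Problem sizes used by tests and drivers

The test suite runs cohorts of 500–112,023 expected persons over 140–168
quarterly cycles; property tests use 100 random hazard sets and 100
synthetic packs; PSA checks use 5–50 iterations (point-mass and
reproducibility need no sampling spread).  The analysis drivers and the
acceptance script run the full 1000-iteration PSA for both cohorts.

## Known limitations

- Exponential (constant-hazard) survival per stage replaces per-trial
  parametric extrapolations; two anchors per stage are exactly matched
  but the shape between/beyond them is not informed.
- No pre-progression cancer mortality; no tunnel states for time-varying
  post-progression hazards; no histology substates.
- A single representative entry age per cohort (no age mixture).
- The stage-shift window is one cycle per screening round; screen-detected
  volumes are conservative relative to trial prevalence counts (see
  above), so absolute incremental effects are lower bounds in spirit,
  not calibrated estimates.
- Costs are USD 2023 throughout; no currency conversion, inflation
  indexing, program setup costs, or societal-perspective items.
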