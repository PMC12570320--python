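# screencea

Cost-effectiveness analysis of low-dose CT (LDCT) lung cancer screening
for two Hong Kong high-risk cohorts: people selected on **smoking
history** (heavy current/ex smokers aged 50–74, ten annual screening
rounds) and people selected on **risk factors other than smoking**
(never/long-quit smokers aged 55–75 with family history, passive-smoke or
cooking-fume exposure, or chronic lung disease — a single screening
round).  It is written for health-economics practitioners who want a
tested, fully reproducible implementation of this style of screening
model: every input is a plain-text parameter pack, every step is a
library function, and the headline numbers are recomputed from scratch by
one script.

## The model

A **decision tree** converts a screened cohort into expected scan counts,
recall scans, false positives and screen-detected cancers by stage.  A
regular scan splits negative / indeterminate / positive; indeterminate
scans get one recall LDCT; pooled negatives split true/false negative and
pooled positives split true/false positive; true positives carry the
screen-detected stage distribution (64.9–77.4% stage I, versus 17.3% at
clinical presentation — the *stage shift* that drives the health gain).

Diagnosed patients enter a **cohort state-transition Markov model** with
three health states — pre-progression, post-progression, death — on a
3-month cycle, with death split by cause for accounting.  Survival per
stage at diagnosis is a two-compartment constant-hazard model,

    PFS(t) = e^(−a t),    OS(t) = e^(−a t) + a (e^(−a t) − e^(−b t)) / (b − a),

whose two free rates per stage (progression *a*, post-progression cancer
death *b*) are exactly identified by the stage's 1-year
disease/progression-free survival and 5-year overall survival anchors.
Background all-cause mortality from a life table enters as a competing
risk; the per-cycle transition matrices are the exact one-cycle solution
of the continuous-time generator, so the quarterly chain reproduces the
continuous closed form at cycle boundaries to machine precision.

Cancer arises in both arms via one calibrated per-cycle diagnosis hazard;
screening re-stages the cancers surfacing in screen cycles from the
clinical to the screen-detected stage mix (and adds scan, recall and
false-positive work-up costs).  Costs are **microcosted** (unit cost ×
stage- and phase-specific utilization; drugs per 30 days of therapy),
utilities are stage- and progression-specific EQ-5D values, and both
costs and QALYs are discounted at 3.5%/year over a lifetime horizon.
Outputs are incremental costs, life-years, QALYs, the **ICER**
(incremental cost per QALY or per life-year gained) and **net monetary
benefit** at the willingness-to-pay range US$24,302–40,202/QALY, plus
one-way (±20%, tornado), probabilistic (Dirichlet/Beta/Gamma, 1000
draws) and scenario analyses.

## Worked example

```python
from screencea import load_fixture, run_cea
from screencea.economics import published_incrementals

# accounting identities over the published per-arm totals
pub = published_incrementals()
print(pub["smoking"].icer_per_qaly.rounded,      # 14122  (US$/QALY)
      pub["nonsmoking"].icer_per_qaly.rounded,   # 9610
      pub["smoking"].incr_diagnoses,             # 1017.0
      pub["smoking"].deaths_averted)             # 1580.0

# full model, smoking-history cohort (112,023 screened at 46.5% uptake)
r = run_cea(load_fixture("smoking"))
print(round(r.incr_qaly, 1))          # 1952.3   incremental QALYs
print(round(r.incr_cost))             # 262776235  incremental cost, US$
print(r.icer_per_qaly.rounded)        # 134596   US$/QALY
print(round(r.stage_iv_averted))      # 965      stage-IV diagnoses averted
```

The first block recomputes the published tables' internal arithmetic —
incremental counts, ICERs and NMB are identities over the printed per-arm
totals, and the package reproduces them exactly.  The second block is the
package's own end-to-end estimate.  Its stage-shift throughput (cancers
arising in the one cycle per year that contains a screen) is deliberately
conservative and mass-conserving, so its ICERs are higher than the
published ones; the scenario orderings (horizon, discounting, uptake
invariance, LDCT price) all match.  See `docs/methods.md` for exactly
what is and is not comparable.

The same numbers are available from the shell:

```bash
screen-cea funnel                  # 240,910 / 196,218 / 437,128 / 203,265
screen-cea run --cohort smoking    # full three-column results table
screen-cea owsa --cohort smoking   # tornado table + figure
screen-cea psa --cohort smoking --iterations 1000 --seed 7
screen-cea scenarios --cohort nonsmoking
```

## Analysis pipeline

The study is organised as numbered drivers over the library, each writing
its tables under `results/`:

| script | what it does |
| --- | --- |
| `analysis/01_population_funnel.py` | eligibility & uptake milestones |
| `analysis/02_screening_outcomes.py` | per-round decision-tree outcomes |
| `analysis/03_survival_calibration.py` | hazard calibration + residuals |
| `analysis/04_base_case.py` | two-arm CEA for both cohorts |
| `analysis/05_sensitivity.py` | OWSA/tornado, 1000-draw PSA, CEAC |
| `analysis/06_scenarios.py` | the what-if grid |

## Layout

```
src/screencea/
  params.py       parameter data model, validation, YAML packs
  fixtures/       cohort packs, shared cost/utility block, synthetic
                  life table, published per-arm base-case totals
  funnel.py       cohort sizing arithmetic
  screening.py    decision trees and the screening program
  disease.py      hazard calibration, transition matrices, Markov engine
  economics.py    phase costs, discounting, ICER/NMB, result I/O
  engine.py       end-to-end orchestration
  uncertainty.py  OWSA, PSA, CEAC, scenario grid
  synthetic.py    life-table and synthetic-pack generators
  cli.py          `screen-cea` command-line interface
  reporting.py    results tables and run manifests
```
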