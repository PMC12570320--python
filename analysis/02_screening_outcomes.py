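#!/usr/bin/env python
"""Step 2 - decision-tree screening outcomes per round.

Pushes each screened cohort through its scan-outcome tree: 10 annual
rounds for the smoking-history cohort (baseline-round probabilities for
round 1, second-round probabilities thereafter), a single round for the
risk-factor cohort.  Reports expected scans, recalls, true/false
positives and screen-detected stage mix per round, plus the interval
cancers implied by the calibrated diagnosis hazard.
Writes results/screening_rounds_<cohort>.csv.
"""

from pathlib import Path

import pandas as pd

from screencea.disease import calibrate_incidence
from screencea.engine import arm_size
from screencea.params import load_fixture
from screencea.screening import run_screening_program

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    for cohort in ("smoking", "nonsmoking"):
        p = load_fixture(cohort)
        n0 = arm_size(p)
        h = calibrate_incidence(
            p.epidemiology.target_diagnoses / p.epidemiology.target_arm_size * n0, n0, p
        )
        trace = run_screening_program(p, n0, h)
        df = pd.DataFrame([r.as_row() for r in trace.rounds])
        path = OUT / f"screening_rounds_{cohort}.csv"
        df.to_csv(path, index=False)
        print(f"== {cohort}: {n0:,} screened, {len(trace.rounds)} round(s), "
              f"{trace.total_ldct_scans:,.0f} LDCT scans, "
              f"{trace.false_positives.sum():,.0f} false positives, "
              f"{trace.interval_cancers.sum():,.0f} interval cancers")
        print(df.to_string(index=False, float_format=lambda v: f"{v:,.1f}"))
        print(f"wrote {path}\n")


if __name__ == "__main__":
    main()
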