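#!/usr/bin/env python
"""Step 3 - calibrate the disease natural history.

Solves the per-stage exponential hazards (progression rate a, post-
progression cancer death rate b) so that the two-compartment model hits
the stage-specific anchors: 1-y disease/progression-free survival and 5-y
overall survival.  Then verifies by simulating the 3-month Markov chain
with no background mortality and reading the anchors back (residuals are
at machine precision), and calibrates the per-cycle clinical diagnosis
hazard to each cohort's lifetime-diagnoses anchor.
Writes results/calibrated_hazards.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from screencea.disease import (
    base_transition_matrix,
    calibrate_hazards,
    calibrate_incidence,
    expand_chain_matrix,
)
from screencea.engine import arm_size
from screencea.params import STAGES, load_fixture

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    p = load_fixture("smoking")
    h = calibrate_hazards(p.survival)
    rows = []
    for s in STAGES:
        P = expand_chain_matrix(
            base_transition_matrix(
                h.lambda_progression[s], h.lambda_death_postprogression[s], 0.0, 0.25
            )
        )
        v = np.zeros(8)
        v[0] = 1.0
        traj = [v.copy()]
        for _ in range(20):
            v = v @ P
            traj.append(v.copy())
        rows.append(
            {
                "stage": s,
                "lambda_progression_per_year": h.lambda_progression[s],
                "lambda_death_postprogression_per_year": h.lambda_death_postprogression[s],
                "target_pfs1y": p.survival.pfs1y_by_stage[s],
                "simulated_pfs1y": traj[4][:3].sum(),
                "target_os5y": p.survival.os5y_by_stage[s],
                "simulated_os5y": traj[20][:6].sum(),
            }
        )
    df = pd.DataFrame(rows)
    df["os5y_residual"] = df["simulated_os5y"] - df["target_os5y"]
    print(df.to_string(index=False))
    df.to_csv(OUT / "calibrated_hazards.csv", index=False)
    print(f"\nmax |residual| = {df['os5y_residual'].abs().max():.2e}")

    for cohort in ("smoking", "nonsmoking"):
        q = load_fixture(cohort)
        n0 = arm_size(q)
        hc = calibrate_incidence(
            q.epidemiology.target_diagnoses / q.epidemiology.target_arm_size * n0, n0, q
        )
        print(f"{cohort}: per-cycle clinical diagnosis hazard = {hc:.6g} "
              f"(lifetime diagnoses anchor {q.epidemiology.target_diagnoses:,.0f} "
              f"of {q.epidemiology.target_arm_size:,.0f})")
    print(f"wrote {OUT/'calibrated_hazards.csv'}")


if __name__ == "__main__":
    main()
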