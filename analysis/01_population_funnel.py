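#!/usr/bin/env python
"""Step 1 - size the two screening cohorts.

From the census inputs (7.33M population; 133,000 current + 107,910
ex heavy smokers; 1,962,185 older never/long-quit smokers of whom 10% are
high-risk) this reproduces the eligibility funnel: 240,910 smoking-history
eligibles (3.29% of the population), 196,218 risk-factor eligibles (2.68%),
437,128 in total, and 203,265 screened at 46.5% uptake.
Writes results/funnel.json and results/funnel.csv.
"""

import json
from pathlib import Path

import pandas as pd

from screencea.funnel import fixture_funnel
from screencea.params import load_fixture

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    f = fixture_funnel(load_fixture("smoking"), load_fixture("nonsmoking"))
    print("Population funnel")
    df = pd.Series(f.to_dict()["screened_by_cohort"], name="screened").to_frame()
    print(json.dumps(f.to_dict(), indent=2))
    (OUT / "funnel.json").write_text(json.dumps(f.to_dict(), indent=2) + "\n")
    rows = f.to_dict()
    flat = {k: v for k, v in rows.items() if not isinstance(v, dict)}
    for k, v in rows["screened_by_cohort"].items():
        flat[f"screened_{k}"] = v
    for k, v in rows["eligible_share_of_population"].items():
        flat[f"share_{k}_pct"] = v
    pd.Series(flat).to_csv(OUT / "funnel.csv", header=False)
    print(f"\nwrote {OUT/'funnel.json'} and {OUT/'funnel.csv'}")


if __name__ == "__main__":
    main()
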