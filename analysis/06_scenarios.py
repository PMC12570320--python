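#!/usr/bin/env python
"""Step 6 - the scenario grid.

Re-runs the full model under the packaged what-if grid: uptake 25%/75%,
5/10/15-year horizons, 0%/6% discounting, a screening disutility,
doubled background mortality, alternative survival-anchor sets, LDCT
price cuts, and halved stage-specific diagnostic/ongoing cost bundles.
The qualitative pattern matches the published grid: the ICER is invariant
to uptake, falls with longer horizons, lower discounting and cheaper
LDCT, and rises with heavier discounting.
Writes results/scenarios_<cohort>.csv.
"""

from pathlib import Path

from screencea.params import load_fixture
from screencea.uncertainty import SCENARIO_GRID, run_scenario_grid

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    for cohort in ("smoking", "nonsmoking"):
        p = load_fixture(cohort)
        df = run_scenario_grid(p, SCENARIO_GRID)
        path = OUT / f"scenarios_{cohort}.csv"
        df.to_csv(path, index=False)
        print(f"== {cohort}")
        print(df.to_string(index=False, float_format=lambda v: f"{v:,.2f}"))
        print(f"wrote {path}\n")


if __name__ == "__main__":
    main()
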