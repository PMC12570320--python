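#!/usr/bin/env python
"""Step 5 - one-way and probabilistic sensitivity analyses.

OWSA perturbs every scalar input +/-20% and ranks the ICER ranges
(tornado); the dominant drivers are the lifetime lung-cancer incidence,
the LDCT unit cost, and the stage-I survival/utility inputs.  PSA draws
1000 joint parameter sets (Dirichlet outcome tables, Beta utilities and
proportions, Gamma costs and counts; moment-matched, counter-seeded) and
reports the mean ICER, CE-plane scatter and CEAC.
Writes results/owsa_<cohort>.csv, tornado_<cohort>.png,
psa_<cohort>.csv, ceac_<cohort>.csv, ce_plane_<cohort>.png.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from screencea.engine import run_cea
from screencea.params import load_fixture
from screencea.uncertainty import ceac, owsa, psa, tornado_report

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260926
N_ITER = 1000


def main():
    OUT.mkdir(exist_ok=True)
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for cohort in ("smoking", "nonsmoking"):
        p = load_fixture(cohort)
        base = run_cea(p)
        print(f"== {cohort}: base ICER {base.icer_per_qaly.raw:,.0f} US$/QALY")

        entries = owsa(p, 0.20)
        df = tornado_report(entries, png_path=OUT / f"tornado_{cohort}.png",
                            base_icer=base.icer_per_qaly.raw)
        df.to_csv(OUT / f"owsa_{cohort}.csv", index=False)
        print("top ICER drivers (+/-20%):")
        print(df.head(6).to_string(index=False, float_format=lambda v: f"{v:,.0f}"))

        res = psa(p, N_ITER, seed=SEED)
        draws = pd.DataFrame(res.draws, columns=["incr_cost", "incr_qaly"])
        draws["icer"] = res.icers
        draws.to_csv(OUT / f"psa_{cohort}.csv", index=False)
        grid = np.linspace(0.0, 3.0 * base.icer_per_qaly.raw, 61)
        cc = ceac(res, grid)
        pd.DataFrame(sorted(cc.items()), columns=["wtp", "prob_cost_effective"]).to_csv(
            OUT / f"ceac_{cohort}.csv", index=False
        )
        print(f"PSA ({N_ITER} draws, seed {SEED}): mean ICER {res.mean_icer:,.0f}, "
              f"ICER of means {res.icer_of_means:,.0f}")

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(draws["incr_qaly"], draws["incr_cost"] / 1e6, s=4, alpha=0.4)
        ax.set_xlabel("incremental QALYs")
        ax.set_ylabel("incremental cost (US$ millions)")
        ax.set_title(f"CE plane - {cohort} cohort")
        fig.tight_layout()
        fig.savefig(OUT / f"ce_plane_{cohort}.png", dpi=150)
        plt.close(fig)
        print()


if __name__ == "__main__":
    main()
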