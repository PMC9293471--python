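#!/usr/bin/env python
"""Stage the drought by soil water content and contrast the genotypes.

Joins the per-record gm estimates (step 03) with lysimetric RSWC, assigns the
well-watered / moderate / severe stages, and summarizes An, gsw, gm, WUEi and
the CO2 drawdowns per stage and genotype with Welch t contrasts.
"""

from pathlib import Path

import pandas as pd

from mesocond.io import PotWeights, compute_rswc
from mesocond.pipeline import assign_stage, summarize

ROOT = Path(__file__).resolve().parent.parent / "results"
STUDY = ROOT / "synthetic_study"


def main() -> None:
    est = pd.read_csv(ROOT / "gm_estimates.csv")
    pots = pd.read_csv(STUDY / "pot_weights.csv")
    pots["rswc"] = [compute_rswc(PotWeights(r.PW, r.DW, r.t0W)) for r in pots.itertuples()]
    df = est.merge(pots[["plant_id", "day", "rswc"]], on=["plant_id", "day"])
    df["stage"] = df["rswc"].map(assign_stage)
    usable = df[df.reliable]

    out = summarize(usable)
    out.to_csv(ROOT / "stage_summaries.csv", index=False)
    gm = out[out.variable == "gm"].pivot(index="stage", columns="genotype", values="mean")
    wue = out[out.variable == "wue_i"].pivot(index="stage", columns="genotype", values="mean")
    print("mean gm by stage (mol m-2 s-1):")
    print(gm.round(3).to_string())
    print("\nmean WUEi by stage (umol CO2 / mol H2O):")
    print(wue.round(1).to_string())
    print(f"\nwrote {ROOT / 'stage_summaries.csv'}")


if __name__ == "__main__":
    main()
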