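#!/usr/bin/env python
"""Establish the per-genotype estimation constants.

From each genotype's 1% O2 response curve and low-Ci protocol this step
estimates the fluorescence calibration (k, b, alpha*beta), day respiration Rd
and the intercellular compensation point Ci*, and resolves Gamma* by the
completed Ci* + Rd/gm fixed point.  These constants feed every later gm
estimate.
"""

import json
from pathlib import Path

from mesocond import fluorescence, laisk as lk, variable_j as vj
from mesocond.io import identity_column_map, read_gasex_table
from mesocond.simulate import laisk_curves_from_records

ROOT = Path(__file__).resolve().parent.parent / "results"
STUDY = ROOT / "synthetic_study"


def main() -> None:
    cal_recs = read_gasex_table(STUDY / "calibration.csv", identity_column_map())
    laisk_recs = read_gasex_table(STUDY / "laisk.csv", identity_column_map())
    survey = read_gasex_table(STUDY / "survey.csv", identity_column_map())

    out = {}
    for geno in sorted({r.genotype for r in cal_recs}):
        res = lk.estimate_laisk(laisk_curves_from_records(
            [r for r in laisk_recs if r.genotype == geno]))
        cal = fluorescence.calibrate([r for r in cal_recs if r.genotype == geno], res.Rd)
        day0 = [r for r in survey if r.genotype == geno and r.day == 0]
        _, resolved = vj.estimate_gm_chain(day0, cal, res, gamma_star_mode="iterative")
        out[geno] = {
            "k": cal.k, "b": cal.b, "alpha_beta": cal.alpha_beta, "r2": cal.r2,
            "Rd": res.Rd, "Ci_star": res.Ci_star, "gamma_star": resolved.gamma_star,
        }
        print(f"{geno}: k={cal.k:.3f} b={cal.b:.4f} alpha*beta={cal.alpha_beta:.3f} "
              f"Rd={res.Rd:.3f} Ci*={res.Ci_star:.2f} Gamma*={resolved.gamma_star:.2f}")

    path = ROOT / "calibration_constants.json"
    path.write_text(json.dumps(out, indent=2))
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
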