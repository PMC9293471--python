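#!/usr/bin/env python
"""Convert A-Ci response curves to A-Cc and fit the FvCB model per genotype.

Simulates one full CO2-response curve per genotype at its well-watered truth
(the same protocol as the study's instrument sequence), converts it to A-Cc
with the curve-level gm, and fits Vcmax and Jmax with Rd fixed to the Laisk
estimate, reporting 25 degC-normalized values.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from mesocond import fluorescence as fl, fvcb, variable_j as vj
from mesocond.simulate import simulate_co2_response

import importlib.util

ROOT = Path(__file__).resolve().parent.parent / "results"
_spec = importlib.util.spec_from_file_location(
    "sim_step", Path(__file__).with_name("01_simulate_study.py"))
_step1 = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_step1)


def main() -> None:
    consts = json.loads((ROOT / "calibration_constants.json").read_text())
    rows = []
    for geno, params in _step1.GENOTYPES.items():
        c = consts[geno]
        cal = fl.CalibrationResult(k=c["k"], b=c["b"], alpha_beta=c["alpha_beta"],
                                   n_used=12, r2=c["r2"])
        curve = simulate_co2_response(
            dataclasses.replace(params, sigma_A=0.0, sigma_phi=0.0))
        ests = vj.estimate_curve(curve, cal, c["Rd"], c["gamma_star"])
        gm_curve = vj.curve_gm(ests, curve)
        an = np.array([r.An for r in curve])
        ci = np.array([vj.correct_ci(r) for r in curve])
        cc = fvcb.aci_to_acc(an, ci, gm_curve)
        fit = fvcb.fit_fvcb(cc, an, Rd=c["Rd"])
        rows.append({"genotype": geno, "gm_curve": gm_curve, "Vcmax": fit.Vcmax,
                     "Jmax": fit.Jmax, "Vcmax25": fit.Vcmax25, "Jmax25": fit.Jmax25,
                     "Amax": fit.Amax, "rmse": fit.rmse,
                     "transition_Cc": fit.transition_Cc})
        print(f"{geno}: gm={gm_curve:.3f}  Vcmax={fit.Vcmax:.1f}  Jmax(at 1500)="
              f"{fit.Jmax:.1f}  Amax={fit.Amax:.1f}  rmse={fit.rmse:.3g}")
    pd.DataFrame(rows).to_csv(ROOT / "fvcb_fits.csv", index=False)
    print(f"wrote {ROOT / 'fvcb_fits.csv'}")


if __name__ == "__main__":
    main()
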