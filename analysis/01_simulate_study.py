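#!/usr/bin/env python
"""Generate the synthetic drought study used by the downstream analysis steps.

Two genotypes emulate the wild-type / d1 contrast: the mutant-like genotype
carries 40% higher mesophyll conductance, 20% higher stomatal conductance and
~10% higher photosynthetic capacity.  Five plants per genotype dry down over
three weeks; daily survey points at ambient CO2 plus per-genotype calibration
(1% O2) and low-Ci (Laisk) protocols are written as CSV fixtures together
with the ground truth.
"""

from pathlib import Path

from mesocond.simulate import StudyDesign, TruthParams, simulate_study, write_study

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic_study"

GENOTYPES = {
    "WT": TruthParams(gm_true=0.30, gsw_true=0.30, Vcmax_true=100, Jmax_true=180,
                      sigma_A=0.3, sigma_phi=0.005),
    "d1": TruthParams(gm_true=0.42, gsw_true=0.36, Vcmax_true=110, Jmax_true=195,
                      sigma_A=0.3, sigma_phi=0.005),
}


def main() -> None:
    bundle = simulate_study(GENOTYPES, StudyDesign(), seed=2021)
    paths = write_study(bundle, OUT)
    n = len(bundle["survey"])
    print(f"wrote {n} survey records for {len(GENOTYPES)} genotypes to {OUT}")
    for name, path in paths.items():
        print(f"  {name:12s} {path.name}")


if __name__ == "__main__":
    main()
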