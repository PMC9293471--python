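"""Forward simulation of gas-exchange + fluorescence data with known truth.

The simulator embodies the measurement model the estimators assume, so every
estimator in the package can be validated by parameter recovery:

* CO2-response points solve the coupled supply/demand system
  An = FvCB(Cc), Cc = Ci - An/gm, Ci = Ca - An/gsc by bracketed
  root-finding, and set the fluorescence-visible electron transport rate
  from the electron budget J = (An + Rd)(4Cc + 8Gamma*)/(Cc - Gamma*), so
  the variable-J inversion is exact on noise-free data.
* Under non-photorespiratory conditions (O2 <= 2%) photorespiration is
  treated as fully suppressed (Gamma* -> 0, J = 4(An + Rd)): CO2 fixation is
  the only electron sink, which is exactly the linearity the fluorescence
  calibration assumes.
* Low-Ci responses for the Laisk analysis are generated as an exactly linear
  pencil of lines through (Ci*, -Rd) whose slopes grow with irradiance, the
  geometry the intersection method assumes.  (A full FvCB solve is measurably
  curved over any practical low-Ci window; see the methods note.)
* Transpiration fields are constructed so the cuticular Ci correction is an
  exact inverse: Wi - Wa is fixed at 0.02 mol mol-1 and
  El = (gsw + 2*Ec)*(Wi - Wa).
* Fluorescence: Fm' is fixed at 2000 instrument units and Ft = Fm'*(1 -
  PhiPSII); only the ratio enters any downstream equation.

Gaussian measurement noise (sigma_A on An, sigma_phi on PhiPSII, sigma_gsw
on gsw) is added after the exact forward solve; the instrument-reported Ci
is recomputed from the noisy fluxes, as a real analyzer would.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .constants import KineticConstants
from .fvcb import fvcb_assimilation, kinetics_at
from .io import GasExchangeRecord
from .variable_j import DEFAULT_EC

#: the instrument CO2-reference sequence of the study protocol (umol mol-1)
STUDY_CA_SEQUENCE = (400, 300, 200, 150, 100, 50, 400, 600, 800, 1000, 1200, 1600)

#: irradiances of the low-Ci (Laisk) protocol (umol m-2 s-1)
LAISK_PPFDS = (100.0, 200.0, 400.0)

#: O2 fraction at or below which photorespiration is treated as suppressed
NONPHOTORESP_O2 = 0.02

#: fixed fluorescence scale (instrument units)
FM_PRIME = 2000.0

#: fixed leaf-air water vapor gradient (mol mol-1)
WI = 0.030
WA = 0.010


class SimulationInfeasibleError(RuntimeError):
    pass


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth leaf parameters and noise levels for forward simulation."""

    gm_true: float = 0.30
    gsw_true: float = 0.30
    Vcmax_true: float = 100.0
    Jmax_true: float = 180.0
    Rd_true: float = 1.0
    gamma_star_true: float = 42.75
    alpha_beta_true: float = 0.45
    #: curvature of the electron-transport light response
    theta_j: float = 0.7
    sigma_A: float = 0.0
    sigma_phi: float = 0.0
    sigma_gsw: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gm_true", "gsw_true", "Vcmax_true", "Jmax_true",
                     "gamma_star_true", "alpha_beta_true", "theta_j"):
            if getattr(self, name) <= 0:
                raise ValueError(f"TruthParams.{name} must be positive")
        if self.Rd_true < 0:
            raise ValueError("Rd_true must be non-negative")
        for name in ("sigma_A", "sigma_phi", "sigma_gsw"):
            if getattr(self, name) < 0:
                raise ValueError(f"TruthParams.{name} must be non-negative")

    @property
    def gsc_true(self) -> float:
        """Stomatal conductance to CO2, gsw/1.6."""
        return self.gsw_true / 1.6

    @property
    def ci_star_true(self) -> float:
        """Intercellular compensation point implied by Gamma* = Ci* + Rd/gm."""
        return self.gamma_star_true - self.Rd_true / self.gm_true


def j_light(PPFD: float, params: TruthParams) -> float:
    """Potential electron transport from the non-rectangular hyperbola light response."""
    a = params.alpha_beta_true * PPFD
    jm, th = params.Jmax_true, params.theta_j
    disc = (a + jm) ** 2 - 4.0 * th * a * jm
    return (a + jm - math.sqrt(disc)) / (2.0 * th)


def _gamma_star_at(params: TruthParams, o2_frac: float) -> float:
    if o2_frac <= NONPHOTORESP_O2:
        return 0.0
    return params.gamma_star_true * (o2_frac / 0.21)


def simulate_point(
    Ca: float,
    PPFD: float,
    o2_frac: float,
    params: TruthParams,
    rng: np.random.Generator | None = None,
    tleaf_c: float = 25.0,
    Ec: float = DEFAULT_EC,
    **labels,
) -> GasExchangeRecord:
    """Simulate one steady-state observation at the given chamber conditions.

    Solves An = FvCB(Cc(An)) with the CO2 supply chain Ci = Ca - An/gsc,
    Cc = Ci - An/gm by Brent root-finding (residual below 1e-10), then builds
    an instrument-consistent record (noise applied afterwards).
    """
    rng = rng or np.random.default_rng(params.seed)
    gs = _gamma_star_at(params, o2_frac)
    kin = KineticConstants().with_o2_fraction(o2_frac)
    km = kinetics_at(tleaf_c, kin)["Km"]
    jpot = j_light(PPFD, params)
    supply_res = 1.0 / params.gsc_true + 1.0 / params.gm_true

    def demand(an: float) -> float:
        cc = max(Ca - an * supply_res, 1e-9)
        return fvcb_assimilation(cc, params.Vcmax_true, jpot, params.Rd_true, gs, km)

    lo = -params.Rd_true - 2.0
    hi = min(params.Vcmax_true, jpot / 4.0)
    if (demand(lo) - lo) * (demand(hi) - hi) > 0:
        raise SimulationInfeasibleError(
            f"no root bracketed for Ca={Ca}, PPFD={PPFD}, O2={o2_frac}: "
            f"h(lo)={demand(lo) - lo:.3g}, h(hi)={demand(hi) - hi:.3g}"
        )
    an = brentq(lambda a: demand(a) - a, lo, hi, xtol=1e-12, rtol=1e-15)
    ci = Ca - an / params.gsc_true
    cc = ci - an / params.gm_true

    gross = an + params.Rd_true
    if o2_frac <= NONPHOTORESP_O2:
        j_actual = 4.0 * gross
    else:
        j_actual = gross * (4.0 * cc + 8.0 * gs) / (cc - gs)
    phi = j_actual / (params.alpha_beta_true * PPFD)

    an_obs = an + params.sigma_A * rng.standard_normal() if params.sigma_A else an
    phi_obs = phi + params.sigma_phi * rng.standard_normal() if params.sigma_phi else phi
    phi_obs = min(max(phi_obs, 1e-6), 0.999)
    gsw_obs = params.gsw_true + params.sigma_gsw * rng.standard_normal() if params.sigma_gsw else params.gsw_true
    gsw_obs = max(gsw_obs, 1e-4)

    ci_obs = Ca - 1.6 * an_obs / gsw_obs
    el = (gsw_obs + 2.0 * Ec) * (WI - WA)
    return GasExchangeRecord(
        An=an_obs, Ca=Ca, Ci_raw=ci_obs, gsw=gsw_obs, El=el, Wi=WI, Wa=WA,
        PPFD=PPFD, Tleaf_C=tleaf_c, O2_frac=o2_frac,
        Ft=FM_PRIME * (1.0 - phi_obs), Fm_prime=FM_PRIME, **labels,
    )


def simulate_co2_response(
    params: TruthParams,
    ca_steps=STUDY_CA_SEQUENCE,
    PPFD: float = 1500.0,
    o2_frac: float = 0.21,
    rng: np.random.Generator | None = None,
    **labels,
) -> list[GasExchangeRecord]:
    """Simulate a CO2 response curve over the study's Ca sequence."""
    rng = rng or np.random.default_rng(params.seed)
    return [simulate_point(ca, PPFD, o2_frac, params, rng=rng, **labels) for ca in ca_steps]


def simulate_calibration_curve(
    params: TruthParams,
    ca_steps=STUDY_CA_SEQUENCE,
    PPFD: float = 1500.0,
    rng: np.random.Generator | None = None,
    **labels,
) -> list[GasExchangeRecord]:
    """The 1% O2 response curve used to calibrate the fluorescence J."""
    return simulate_co2_response(params, ca_steps=ca_steps, PPFD=PPFD,
                                 o2_frac=0.01, rng=rng, **labels)


#: default Ci grid of a low-Ci (Laisk) curve (umol mol-1)
LAISK_CI_GRID = (50.0, 70.0, 90.0, 110.0, 130.0, 150.0)

#: slope of a low-Ci response per unit electron transport
#: (umol CO2 m-2 s-1 per umol mol-1 per umol e- m-2 s-1)
LAISK_SLOPE_PER_J = 5e-4


def simulate_laisk_curves(
    params: TruthParams,
    ppfds=LAISK_PPFDS,
    ci_grid=LAISK_CI_GRID,
    rng: np.random.Generator | None = None,
    slope_per_j: float = LAISK_SLOPE_PER_J,
    **labels,
) -> list[GasExchangeRecord]:
    """Low-Ci curves at several irradiances intersecting exactly at (Ci*, -Rd).

    Each curve is An = -Rd + s(PPFD)*(Ci - Ci*) with s proportional to the
    light-limited electron transport rate, so slopes increase with PPFD.
    """
    rng = rng or np.random.default_rng(params.seed)
    records = []
    for ppfd in ppfds:
        j = j_light(ppfd, params)
        slope = slope_per_j * j
        for ci in ci_grid:
            an = -params.Rd_true + slope * (ci - params.ci_star_true)
            an_obs = an + params.sigma_A * rng.standard_normal() if params.sigma_A else an
            ca = ci + 1.6 * an_obs / params.gsw_true
            phi = j / (params.alpha_beta_true * ppfd)
            el = (params.gsw_true + 2.0 * DEFAULT_EC) * (WI - WA)
            records.append(GasExchangeRecord(
                An=an_obs, Ca=ca, Ci_raw=ci, gsw=params.gsw_true, El=el,
                Wi=WI, Wa=WA, PPFD=ppfd, Tleaf_C=25.0, O2_frac=0.21,
                Ft=FM_PRIME * (1.0 - phi), Fm_prime=FM_PRIME,
                curve_id=f"laisk_{int(ppfd)}", **labels,
            ))
    return records


def laisk_curves_from_records(records) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Group low-Ci records by PPFD into (PPFD, Ci, An) triples for the Laisk fit."""
    by_ppfd: dict[float, list] = {}
    for r in records:
        by_ppfd.setdefault(r.PPFD, []).append(r)
    return [
        (ppfd, np.array([r.Ci_raw for r in rs]), np.array([r.An for r in rs]))
        for ppfd, rs in sorted(by_ppfd.items())
    ]


# ---------------------------------------------------------------------------
# study-level simulation


@dataclass(frozen=True)
class StudyDesign:
    """Layout of a simulated drought study."""

    n_plants: int = 5
    n_days: int = 21
    survey_ca: float = 400.0
    survey_ppfd: float = 1500.0
    #: e-folding time of the soil drying curve (days)
    drying_tau: float = 8.0
    #: RSWC (%) below which gsw declines linearly toward its floor
    gsw_breakpoint: float = 60.0
    gsw_floor: float = 0.05
    #: pot dry weight and day-0 weight (kg)
    pot_dw: float = 3.0
    pot_t0w: float = 10.0
    #: dedicated calibration/Laisk protocol curves are long steady-state
    #: averages; by default they carry no snapshot noise (surveys do)
    protocol_noise_free: bool = True


def rswc_trajectory(day: int, design: StudyDesign, jitter: float = 1.0) -> float:
    """Exponential soil drying from 100% RSWC, with a per-pot jitter factor."""
    return 100.0 * math.exp(-day * jitter / design.drying_tau)


def _drought_scaling(rswc: float, design: StudyDesign) -> tuple[float, float]:
    # stomata close roughly linearly below the breakpoint; gm declines more gently
    gsw_fac = min(1.0, max(rswc / design.gsw_breakpoint, design.gsw_floor))
    gm_fac = min(1.0, max(rswc / 50.0, 0.25) ** 0.5)
    return gsw_fac, gm_fac


def simulate_study(
    genotype_params: dict[str, TruthParams],
    design: StudyDesign | None = None,
    genotype_anatomy: dict | None = None,
    seed: int = 0,
) -> dict:
    """Simulate a full drought study: daily surveys, calibration and Laisk curves,
    pot weights and genotype-mean anatomy, plus the ground truth.

    Returns a dict with record lists (``survey``, ``calibration``, ``laisk``),
    a ``pot_weights`` table, an ``anatomy`` table and a ``truth`` dict.
    """
    from .anatomy import RICE_T65_WT, RICE_T65_D1

    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    if genotype_anatomy is None:
        keys = list(genotype_params)
        genotype_anatomy = {keys[0]: RICE_T65_WT}
        if len(keys) > 1:
            genotype_anatomy[keys[1]] = RICE_T65_D1

    survey, calibration, laisk_recs, pot_rows = [], [], [], []
    truth_rows = []
    for geno, params in genotype_params.items():
        protocol_params = (replace(params, sigma_A=0.0, sigma_phi=0.0, sigma_gsw=0.0)
                           if design.protocol_noise_free else params)
        calibration.extend(simulate_calibration_curve(
            protocol_params, rng=rng, genotype=geno, plant_id=f"{geno}_1", day=0,
            curve_id=f"{geno}_cal"))
        laisk_recs.extend(simulate_laisk_curves(
            protocol_params, rng=rng, genotype=geno, plant_id=f"{geno}_1", day=0))
        for plant in range(1, design.n_plants + 1):
            jitter = 1.0 + 0.05 * rng.standard_normal()
            for day in range(design.n_days):
                rswc = rswc_trajectory(day, design, jitter=jitter)
                gsw_fac, gm_fac = _drought_scaling(rswc, design)
                day_params = replace(params, gsw_true=params.gsw_true * gsw_fac,
                                     gm_true=params.gm_true * gm_fac)
                rec = simulate_point(
                    design.survey_ca, design.survey_ppfd, 0.21, day_params, rng=rng,
                    genotype=geno, plant_id=f"{geno}_{plant}", day=day,
                    curve_id=f"{geno}_{plant}_d{day}")
                survey.append(rec)
                pot_rows.append({
                    "genotype": geno, "plant_id": f"{geno}_{plant}", "day": day,
                    "PW": design.pot_dw + rswc / 100.0 * (design.pot_t0w - design.pot_dw),
                    "DW": design.pot_dw, "t0W": design.pot_t0w,
                })
                truth_rows.append({"genotype": geno, "plant_id": f"{geno}_{plant}",
                                   "day": day, "rswc": rswc,
                                   "gm_true": day_params.gm_true,
                                   "gsw_true": day_params.gsw_true})
    anatomy_rows = [
        {"genotype": g, **{k: v for k, v in asdict(a).items() if k != "genotype"}}
        for g, a in genotype_anatomy.items()
    ]
    return {
        "survey": survey,
        "calibration": calibration,
        "laisk": laisk_recs,
        "pot_weights": pot_rows,
        "anatomy": anatomy_rows,
        "truth": {
            "genotypes": {g: asdict(p) for g, p in genotype_params.items()},
            "design": asdict(design),
            "seed": seed,
            "per_record": truth_rows,
        },
    }


def write_study(bundle: dict, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated study bundle as the CSV/JSON fixture set."""
    import pandas as pd

    from .io import write_gasex_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("survey", "calibration", "laisk"):
        paths[name] = outdir / f"{name}.csv"
        write_gasex_table(bundle[name], paths[name])
    for name in ("pot_weights", "anatomy"):
        paths[name] = outdir / f"{name}.csv"
        pd.DataFrame(bundle[name]).to_csv(paths[name], index=False)
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(bundle["truth"], indent=2))
    return paths
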