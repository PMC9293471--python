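"""One-dimensional anatomical model of mesophyll conductance.

CO2 travels from the substomatal cavity through the intercellular air space
(gas phase) and then, in the liquid phase, across the cell wall, plasma
membrane, cytosol, chloroplast envelope and stroma in series.  Gas-phase
conductance is g_ias = Da*f_ias/(dL_ias*tau) with dL_ias half the mesophyll
thickness; each liquid component has per-surface conductance
g_i = Dw*rf_i*p_i/dL_i (membranes get fixed permeabilities).  Per leaf area,
wall and plasma-membrane resistances are divided by the mesophyll surface Sm
and the intracellular components by the chloroplast surface Sc; their sum
inverts to g_liq, and the composite is

    gm = 1 / (1/g_ias + (R*Tk/H) / g_liq)

converted from m s-1 to mol m-2 s-1 with the molar density of air.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import DiffusionConstants

log = logging.getLogger("mesocond.anatomy")

#: curvature correction factor for ellipsoidal mesophyll cell shape
CURVATURE_FACTOR = 1.42

#: liquid-phase components in diffusion order
LIQUID_COMPONENTS = ("cw", "pl", "cyt", "env", "st")


@dataclass(frozen=True)
class AnatomyMeasurements:
    """Traced leaf-anatomy traits (thicknesses in um, surfaces in m2 m-2)."""

    Tleaf: float
    Sm: float
    Sc: float
    Tcw: float
    Tcyt: float
    Tchl: float
    f_ias: float = 0.3
    LMA: float | None = None
    Lchl: float | None = None
    genotype: str = ""

    def __post_init__(self) -> None:
        for name in ("Tleaf", "Sm", "Sc", "Tcw", "Tcyt", "Tchl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"AnatomyMeasurements.{name} must be positive")
        if self.Sc > self.Sm:
            raise ValueError("Sc cannot exceed Sm")
        if not 0.0 < self.f_ias < 1.0:
            raise ValueError("f_ias must lie in (0, 1)")


@dataclass(frozen=True)
class AnatomicalGmResult:
    """Component conductances/resistances and the composite modeled gm."""

    #: gas-phase conductance, m s-1 and mol m-2 s-1
    g_ias: float
    g_ias_mol: float
    #: per-surface liquid component conductances (m s-1), keyed by component
    g_components: dict
    #: per-leaf-area component resistances (s m-1), keyed by component
    r_components_leaf: dict
    #: composite liquid-phase conductance per leaf area (m s-1)
    g_liq: float
    #: composite modeled mesophyll conductance, m s-1 and mol m-2 s-1
    gm_model_ms: float
    gm_model: float


#: genotype-mean leaf anatomy of well-watered rice cv. Taichung 65 wild type
#: and its d1 (RGA1-null) mutant, from traced light/TEM cross sections
RICE_T65_WT = AnatomyMeasurements(
    Tleaf=68.5, LMA=62.9, Sm=17.5, Sc=13.9, Tcw=0.128, Tcyt=0.05,
    Lchl=4.3, Tchl=2.6, genotype="WT",
)
RICE_T65_D1 = AnatomyMeasurements(
    Tleaf=74.9, LMA=66.5, Sm=22.5, Sc=19.5, Tcw=0.106, Tcyt=0.03,
    Lchl=4.6, Tchl=1.48, genotype="d1",
)


def surface_per_area(l: float, W: float) -> float:
    """Exposed surface per leaf area, S = (l/W)*1.42, from a traced perimeter.

    ``l`` is the total traced perimeter facing the intercellular air space and
    ``W`` the analyzed cross-section width (same units); 1.42 corrects for the
    ellipsoidal cell shape.
    """
    if W <= 0:
        raise ValueError("section width W must be positive")
    if l <= 0:
        raise ValueError("perimeter l must be positive")
    return (l / W) * CURVATURE_FACTOR


def ias_fraction(S_ias: float, S_mes: float) -> float:
    """Intercellular-air-space fraction from cross-sectional areas, Sias/(Smes + Sias)."""
    if S_ias < 0 or S_mes < 0:
        raise ValueError("areas must be non-negative")
    if S_ias == 0 and S_mes == 0:
        raise ValueError("at least one area must be positive")
    return S_ias / (S_mes + S_ias)


def gas_phase_conductance(const: DiffusionConstants, f_ias: float, Tleaf_um: float) -> tuple[float, float]:
    """Gas-phase conductance g_ias = Da*f_ias/(dL_ias*tau), in m s-1 and mol m-2 s-1.

    The effective gas path dL_ias is taken as half the leaf thickness (the
    available proxy for mesophyll thickness).
    """
    if not 0.0 < f_ias < 1.0:
        raise ValueError("f_ias must lie in (0, 1)")
    if Tleaf_um <= 0:
        raise ValueError("Tleaf must be positive")
    dL = 0.5 * Tleaf_um * 1e-6
    g = const.Da * f_ias / (dL * const.tau)
    return g, g * const.molar_density


def liquid_component_conductance(Dw: float, rf: float, p: float, dL_m: float) -> float:
    """Per-surface liquid conductance g_i = Dw*rf*p/dL (all SI, result m s-1)."""
    if dL_m <= 0:
        raise ValueError("diffusion path length must be positive")
    return Dw * rf * p / dL_m


def component_conductances(anat: AnatomyMeasurements, const: DiffusionConstants) -> dict[str, float]:
    """Per-surface conductances (m s-1) of the five serial liquid components.

    Path lengths: dL_cw = Tcw, dL_cyt = Tcyt, dL_st = Tchl/2; membranes carry
    fixed permeabilities.
    """
    return {
        "cw": liquid_component_conductance(const.Dw, const.rf_cw, const.p_cw, anat.Tcw * 1e-6),
        "pl": const.g_pl,
        "cyt": liquid_component_conductance(const.Dw, const.rf_cyt, const.p_cyt, anat.Tcyt * 1e-6),
        "env": const.g_env,
        "st": liquid_component_conductance(const.Dw, const.rf_st, const.p_st, 0.5 * anat.Tchl * 1e-6),
    }


def _exposure(anat: AnatomyMeasurements) -> dict[str, float]:
    # wall and plasma membrane scale with the mesophyll surface, the
    # intracellular components with the chloroplast surface
    return {"cw": anat.Sm, "pl": anat.Sm, "cyt": anat.Sc, "env": anat.Sc, "st": anat.Sc}


def compose_gm(anat: AnatomyMeasurements, const: DiffusionConstants | None = None) -> AnatomicalGmResult:
    """Compose gas and liquid phases into the modeled mesophyll conductance."""
    const = const or DiffusionConstants()
    g = component_conductances(anat, const)
    expo = _exposure(anat)
    for name, gi in g.items():
        if gi <= 0:
            raise ValueError(f"non-positive conductance for component {name!r}")
    r_leaf = {name: 1.0 / (g[name] * expo[name]) for name in LIQUID_COMPONENTS}
    r_liq_total = sum(r_leaf.values())
    g_liq = 1.0 / r_liq_total
    g_ias, g_ias_mol = gas_phase_conductance(const, anat.f_ias, anat.Tleaf)
    gm_ms = 1.0 / (1.0 / g_ias + const.henry_factor / g_liq)
    return AnatomicalGmResult(
        g_ias=g_ias,
        g_ias_mol=g_ias_mol,
        g_components=g,
        r_components_leaf=r_leaf,
        g_liq=g_liq,
        gm_model_ms=gm_ms,
        gm_model=gm_ms * const.molar_density,
    )


def liquid_resistance_total(result: AnatomicalGmResult) -> float:
    """Total per-leaf-area liquid-phase resistance (s m-1)."""
    return sum(result.r_components_leaf.values())


def resistance_shares(result: AnatomicalGmResult) -> dict[str, float]:
    """Fractional share of each component in the liquid-phase resistance (sums to 1)."""
    total = liquid_resistance_total(result)
    return {k: v / total for k, v in result.r_components_leaf.items()}


def compare_genotypes(result_a: AnatomicalGmResult, result_b: AnatomicalGmResult) -> dict:
    """Percent reduction of B's resistances relative to A's, 100*(1 - r_B/r_A).

    Both per-surface (independent of Sm/Sc) and per-leaf-area views are
    reported for each component, plus the per-leaf-area liquid-phase total.
    """
    out = {
        "per_surface": {
            name: 100.0 * (1.0 - result_a.g_components[name] / result_b.g_components[name])
            for name in LIQUID_COMPONENTS
        },
        "per_leaf_area": {
            name: 100.0 * (1.0 - result_b.r_components_leaf[name] / result_a.r_components_leaf[name])
            for name in LIQUID_COMPONENTS
        },
        "liquid_total_per_leaf_area": 100.0 * (
            1.0 - liquid_resistance_total(result_b) / liquid_resistance_total(result_a)
        ),
    }
    return out
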