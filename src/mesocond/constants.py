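"""Physical and kinetic constants used across the package.

All diffusion constants follow the one-dimensional serial-resistance model of
leaf-internal CO2 transfer; kinetic constants default to the Bernacchi
parameterization of Rubisco kinetics and the photorespiratory compensation
point, expressed as mole fractions at 25 degC with simple-Arrhenius activation
energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

#: Universal gas constant (J mol-1 K-1).
R_GAS = 8.314

#: Standard atmospheric pressure (Pa).
P_ATM = 101325.0

#: Reference temperature for kinetic normalization (K).
T_REF = 298.15


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetics and photorespiration constants.

    Mole-fraction units: Kc and Gamma* in umol mol-1, Ko and O in mmol mol-1.
    Activation energies in J mol-1 (simple Arrhenius).
    """

    Kc25: float = 404.9
    Ko25: float = 278.4
    gamma_star25: float = 42.75
    Ea_Kc: float = 79430.0
    Ea_Ko: float = 36380.0
    Ea_gamma_star: float = 37830.0
    Ea_Vcmax: float = 65330.0
    Ea_Jmax: float = 43540.0
    #: oxygen mole fraction (mmol mol-1) at 21% O2
    O: float = 210.0

    def __post_init__(self) -> None:
        for name in ("Kc25", "Ko25", "gamma_star25", "O"):
            if getattr(self, name) <= 0:
                raise ValueError(f"KineticConstants.{name} must be positive")

    def with_o2_fraction(self, o2_frac: float) -> "KineticConstants":
        """Return a copy with the oxygen mole fraction set from a fraction (0.21 -> 210)."""
        return replace(self, O=1000.0 * o2_frac)


@dataclass(frozen=True)
class DiffusionConstants:
    """Constants of the one-dimensional anatomical CO2 diffusion model.

    Component conductances are per unit of exposed surface in m s-1; the
    Henry's-law constant H converts liquid-phase conductance to its gas-phase
    equivalent via the dimensionless factor R*Tk/H.
    """

    #: CO2 diffusivity in air at 25 degC (m2 s-1)
    Da: float = 1.51e-4
    #: CO2 diffusivity in water at 25 degC (m2 s-1)
    Dw: float = 1.79e-9
    #: tortuosity of the gas-phase diffusion path (dimensionless)
    tau: float = 1.57
    #: effective porosity of cell wall / cytosol / stroma (m3 m-3)
    p_cw: float = 0.3
    p_cyt: float = 1.0
    p_st: float = 1.0
    #: diffusivity-reduction factors for solutes and macromolecules
    rf_cw: float = 1.0
    rf_cyt: float = 0.3
    rf_st: float = 0.3
    #: plasma-membrane and chloroplast-envelope permeabilities (m s-1)
    g_pl: float = 0.0035
    g_env: float = 0.0035
    #: gas constant (Pa m3 mol-1 K-1) and absolute temperature (K)
    R: float = R_GAS
    Tk: float = T_REF
    #: Henry's law constant for CO2 at 25 degC (Pa m3 mol-1)
    H: float = 2941.0
    #: ambient pressure (Pa), for m s-1 -> mol m-2 s-1 conversion
    pressure: float = P_ATM

    def __post_init__(self) -> None:
        for name in ("Da", "Dw", "tau", "g_pl", "g_env", "R", "Tk", "H", "pressure"):
            if getattr(self, name) <= 0:
                raise ValueError(f"DiffusionConstants.{name} must be positive")
        for name in ("p_cw", "p_cyt", "p_st", "rf_cw", "rf_cyt", "rf_st"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"DiffusionConstants.{name} must lie in (0, 1]")

    @property
    def molar_density(self) -> float:
        """Molar density of air (mol m-3), P/(R*Tk)."""
        return self.pressure / (self.R * self.Tk)

    @property
    def henry_factor(self) -> float:
        """Dimensionless gas/liquid partition factor R*Tk/H."""
        return self.R * self.Tk / self.H
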