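"""FvCB photosynthesis model: A-Cc conversion, fitting, temperature normalization.

The Farquhar-von Caemmerer-Berry model describes net assimilation as the
minimum of the Rubisco-limited and RuBP-regeneration-limited rates,

    Ac = Vcmax * (Cc - Gamma*) / (Cc + Kc * (1 + O/Ko))
    Aj = J     * (Cc - Gamma*) / (4*Cc + 8*Gamma*)
    An = min(Ac, Aj) - Rd

with Cc the chloroplastic CO2 mole fraction obtained from A-Ci curves via
Cc = Ci - An/gm.  Vcmax and J (Jmax at saturating light) are fitted by
least squares with Rd fixed to its Laisk estimate by default, and normalized
to 25 degC with a simple Arrhenius factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import lmfit

from .constants import KineticConstants, R_GAS, T_REF

log = logging.getLogger("mesocond.fvcb")


@dataclass(frozen=True)
class FvCBFit:
    """Fitted FvCB parameters at leaf temperature and normalized to 25 degC."""

    Vcmax: float
    Jmax: float
    Vcmax25: float
    Jmax25: float
    Amax: float
    Rd_used: float
    rmse: float
    transition_Cc: float
    jmax_identifiable: bool = True
    vcmax_identifiable: bool = True

    def __post_init__(self) -> None:
        if self.Vcmax <= 0 or self.Jmax <= 0:
            raise ValueError("Vcmax and Jmax must be positive")
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")


def arrhenius_scale(tleaf_c: float, Ea: float) -> float:
    """exp(Ea*(Tk - 298.15)/(298.15*R*Tk)): the forward Arrhenius factor from 25 degC."""
    tk = np.asarray(tleaf_c, dtype=float) + 273.15
    out = np.exp(Ea * (tk - T_REF) / (T_REF * R_GAS * tk))
    return float(out) if out.ndim == 0 else out


def normalize_25(value, tleaf_c: float, Ea: float):
    """Scale a rate measured at leaf temperature to its 25 degC equivalent."""
    tl = np.asarray(tleaf_c, dtype=float)
    if np.any((tl < 0) | (tl > 50)):
        log.warning("leaf temperature %s degC outside the physical 0-50 range", tleaf_c)
    return value / arrhenius_scale(tleaf_c, Ea)


def denormalize_25(value25, tleaf_c: float, Ea: float):
    """Inverse of :func:`normalize_25`."""
    return value25 * arrhenius_scale(tleaf_c, Ea)


def kinetics_at(tleaf_c: float, kin: KineticConstants | None = None) -> dict[str, float]:
    """Kc, Ko, Gamma* and the effective Michaelis constant Km at leaf temperature."""
    kin = kin or KineticConstants()
    Kc = kin.Kc25 * arrhenius_scale(tleaf_c, kin.Ea_Kc)
    Ko = kin.Ko25 * arrhenius_scale(tleaf_c, kin.Ea_Ko)
    gs = kin.gamma_star25 * arrhenius_scale(tleaf_c, kin.Ea_gamma_star)
    return {"Kc": Kc, "Ko": Ko, "gamma_star": gs, "Km": Kc * (1.0 + kin.O / Ko), "O": kin.O}


def aci_to_acc(An, Ci, gm):
    """Convert A-Ci points to A-Cc via Fick's law, Cc = Ci - An/gm.

    ``gm`` may be a scalar (curve-level conductance) or per-point array; an
    infinite gm leaves Cc = Ci.
    """
    An = np.asarray(An, dtype=float)
    Ci = np.asarray(Ci, dtype=float)
    gm_arr = np.broadcast_to(np.asarray(gm, dtype=float), An.shape).copy()
    if np.any(~np.isfinite(gm_arr) & (gm_arr < 0)) or np.any(np.isnan(gm_arr)):
        bad = np.flatnonzero(~np.isfinite(gm_arr) | np.isnan(gm_arr))
        raise ValueError(f"missing gm at points {bad.tolist()}")
    with np.errstate(invalid="ignore"):
        drawdown = np.where(np.isinf(gm_arr), 0.0, An / gm_arr)
    return Ci - drawdown


def fvcb_assimilation(Cc, Vcmax: float, J: float, Rd: float,
                      gamma_star: float, Km: float):
    """Net assimilation An = min(Ac, Aj) - Rd at chloroplastic CO2 ``Cc``."""
    Cc = np.asarray(Cc, dtype=float)
    if np.any(Cc < 0):
        raise ValueError("Cc must be non-negative")
    Ac = Vcmax * (Cc - gamma_star) / (Cc + Km)
    Aj = J * (Cc - gamma_star) / (4.0 * Cc + 8.0 * gamma_star)
    out = np.minimum(Ac, Aj) - Rd
    return float(out) if out.ndim == 0 else out


def transition_cc(Vcmax: float, J: float, gamma_star: float, Km: float) -> float:
    """Cc where Ac = Aj: (J*Km - 8*Gamma**Vcmax) / (4*Vcmax - J).

    Returns +inf when the curve is Rubisco-limited everywhere (J >= 4*Vcmax
    or a non-physical crossover below Gamma*).
    """
    denom = 4.0 * Vcmax - J
    if denom <= 0:
        return np.inf
    cc = (J * Km - 8.0 * gamma_star * Vcmax) / denom
    return cc if cc > gamma_star else np.inf


def fit_fvcb(
    Cc,
    An,
    Rd: float,
    tleaf_c: float = 25.0,
    kinetics: KineticConstants | None = None,
    fit_rd: bool = False,
) -> FvCBFit:
    """Least-squares fit of Vcmax and J (reported as Jmax) to an A-Cc curve.

    Rd is fixed to the supplied (Laisk) estimate unless ``fit_rd`` is true.
    Kinetic constants are evaluated at ``tleaf_c``; the fitted rates are also
    reported normalized to 25 degC.  Curves whose points all sit in one
    limitation region leave the other parameter weakly identified; this is
    flagged rather than failed.
    """
    Cc = np.asarray(Cc, dtype=float)
    An = np.asarray(An, dtype=float)
    if Cc.size < 5:
        log.warning("only %d points: FvCB fit should span both limitation regions", Cc.size)
    kin = kinetics or KineticConstants()
    kt = kinetics_at(tleaf_c, kin)

    params = lmfit.Parameters()
    params.add("Vcmax", value=80.0, min=1e-3)
    params.add("J", value=1.7 * 80.0, min=1e-3)
    params.add("Rd", value=Rd, min=0.0, vary=fit_rd)

    def residual(p):
        return fvcb_assimilation(Cc, p["Vcmax"].value, p["J"].value,
                                 p["Rd"].value, kt["gamma_star"], kt["Km"]) - An

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise RuntimeError(f"FvCB fit did not converge: {result.message}")
    vcmax = float(result.params["Vcmax"].value)
    j = float(result.params["J"].value)
    rd_used = float(result.params["Rd"].value)
    rmse = float(np.sqrt(np.mean(residual(result.params) ** 2)))
    tcc = transition_cc(vcmax, j, kt["gamma_star"], kt["Km"])
    jmax_ok = bool(np.any(Cc > tcc)) if np.isfinite(tcc) else False
    vcmax_ok = bool(np.any(Cc < tcc))
    if not jmax_ok:
        log.warning("no points above the transition Cc: Jmax weakly identified")
    if not vcmax_ok:
        log.warning("no points below the transition Cc: Vcmax weakly identified")
    return FvCBFit(
        Vcmax=vcmax,
        Jmax=j,
        Vcmax25=normalize_25(vcmax, tleaf_c, kin.Ea_Vcmax),
        Jmax25=normalize_25(j, tleaf_c, kin.Ea_Jmax),
        Amax=float(An[np.argmax(Cc)]),
        Rd_used=rd_used,
        rmse=rmse,
        transition_Cc=float(tcc),
        jmax_identifiable=jmax_ok,
        vcmax_identifiable=vcmax_ok,
    )
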