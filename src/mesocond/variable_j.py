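"""Variable-J estimation of chloroplastic CO2 and mesophyll conductance.

The Harley variable-J method infers the chloroplastic CO2 mole fraction from
the fluorescence-calibrated electron transport rate,

    Cc = Gamma* * (J + 8*(An + Rd)) / (J - 4*(An + Rd))

and mesophyll conductance from Fick's law, gm = An / (Ci - Cc), after the
intercellular CO2 has been corrected for cuticular water loss (Boyer): the
instrument's total water conductance El/(Wi - Wa) includes a cuticular part
2*Ec that carries no CO2, so the stomatal-only conductance is
g' = El/(Wi - Wa) - 2*Ec and Ci = Ca - 1.6*An/g'.

The method is singular where J approaches 4*(An + Rd); estimates are kept
only inside a sensitivity window on dCc/dAn and with a margin on the
denominator, and are otherwise retained but flagged unreliable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import laisk as laisk_mod
from .fluorescence import CalibrationResult, j_calibrated, phi_psii
from .io import GasExchangeRecord

log = logging.getLogger("mesocond.variable_j")

#: cuticular transpiration constant, per leaf surface (mol H2O m-2 s-1 per unit
#: mole-fraction gradient); two surfaces contribute 2*Ec
DEFAULT_EC = 0.005

#: classic variable-J sensitivity window on dCc/dAn
SENSITIVITY_WINDOW = (10.0, 50.0)

#: minimum denominator margin, J - 4*(An+Rd) > margin * J
J_MARGIN = 0.05


class CorrectionInfeasibleError(ValueError):
    """Cuticular correction would produce a non-positive stomatal conductance."""


class NonPhysicalRegimeError(ValueError):
    """J <= 4*(An + Rd): the variable-J denominator is non-positive."""


@dataclass
class GmEstimate:
    """Per-record variable-J estimate with derived quantities and quality flags."""

    Ci_corr: float
    Cc: float
    gm: float | None
    J_used: float
    gsc: float
    wue_i: float
    drawdown_surface: float
    drawdown_mesophyll: float
    reliable: bool
    sensitivity: float


def correct_ci(rec: GasExchangeRecord, Ec: float = DEFAULT_EC, mode: str = "boyer") -> float:
    """Cuticle-corrected intercellular CO2 mole fraction (umol mol-1).

    ``mode='off'`` returns the instrument Ci unchanged.  If the corrected
    water conductance is non-positive the correction is infeasible; the
    instrument Ci is retained with a warning by raising
    :class:`CorrectionInfeasibleError` for the caller to handle.
    """
    if mode == "off":
        return rec.Ci_raw
    if not rec.Wi > rec.Wa:
        raise ValueError("requires Wi > Wa")
    if rec.El <= 0:
        raise ValueError("requires El > 0")
    g_tw = rec.El / (rec.Wi - rec.Wa)
    g_prime = g_tw - 2.0 * Ec
    if g_prime <= 0:
        raise CorrectionInfeasibleError(
            f"corrected conductance {g_prime:.4g} <= 0 (El={rec.El}, Wi-Wa={rec.Wi - rec.Wa})"
        )
    return rec.Ca - 1.6 * rec.An / g_prime


def chloroplastic_cc(An: float, Rd: float, J: float, gamma_star: float) -> float:
    """Harley variable-J chloroplastic CO2, Gamma*(J + 8(An+Rd))/(J - 4(An+Rd))."""
    gross = An + Rd
    denom = J - 4.0 * gross
    if denom <= 0:
        raise NonPhysicalRegimeError(
            f"J={J:.3g} <= 4*(An+Rd)={4 * gross:.3g}: variable-J denominator non-positive"
        )
    return gamma_star * (J + 8.0 * gross) / denom


def cc_sensitivity(An: float, Rd: float, J: float, gamma_star: float) -> float:
    """dCc/dAn = 12*J*Gamma* / (J - 4*(An+Rd))^2, the classic reliability measure."""
    denom = J - 4.0 * (An + Rd)
    return 12.0 * J * gamma_star / denom**2


def gm_variable_j(
    rec: GasExchangeRecord,
    Rd: float,
    J: float,
    gamma_star: float,
    Ec: float = DEFAULT_EC,
    ci_mode: str = "boyer",
    sensitivity_window: tuple[float, float] = SENSITIVITY_WINDOW,
    j_margin: float = J_MARGIN,
) -> GmEstimate:
    """Full per-record variable-J estimate.

    Never silently drops a record: singular or out-of-window estimates are
    returned with ``reliable=False`` (and ``gm=None`` where Cc = Ci).
    """
    try:
        ci = correct_ci(rec, Ec=Ec, mode=ci_mode)
    except CorrectionInfeasibleError as exc:
        log.warning("cuticular correction infeasible (%s); using instrument Ci", exc)
        ci = rec.Ci_raw
    gsc = rec.gsw / 1.6
    wue_i = rec.An / rec.gsw if rec.gsw > 0 else math.nan

    reliable = True
    try:
        cc = chloroplastic_cc(rec.An, Rd, J, gamma_star)
        sens = cc_sensitivity(rec.An, Rd, J, gamma_star)
    except NonPhysicalRegimeError:
        return GmEstimate(
            Ci_corr=ci, Cc=math.nan, gm=None, J_used=J, gsc=gsc, wue_i=wue_i,
            drawdown_surface=rec.Ca - ci, drawdown_mesophyll=math.nan,
            reliable=False, sensitivity=math.inf,
        )
    if not sensitivity_window[0] <= sens <= sensitivity_window[1]:
        reliable = False
    if not J - 4.0 * (rec.An + Rd) > j_margin * J:
        reliable = False

    if math.isclose(ci, cc, rel_tol=0.0, abs_tol=1e-12):
        log.warning("Ci equals Cc: infinite-gm signal, gm reported missing")
        gm = None
        reliable = False
    else:
        gm = rec.An / (ci - cc)
        if gm <= 0:
            reliable = False
    return GmEstimate(
        Ci_corr=ci, Cc=cc, gm=gm, J_used=J, gsc=gsc, wue_i=wue_i,
        drawdown_surface=rec.Ca - ci, drawdown_mesophyll=ci - cc,
        reliable=reliable, sensitivity=sens,
    )


def estimate_curve(
    records: Sequence[GasExchangeRecord],
    cal: CalibrationResult,
    Rd: float,
    gamma_star: float,
    Ec: float = DEFAULT_EC,
    ci_mode: str = "boyer",
) -> list[GmEstimate]:
    """Variable-J estimates for every fluorescence record of one response curve."""
    out = []
    for rec in records:
        if not rec.has_fluorescence:
            raise ValueError("gm estimation requires fluorescence fields on every record")
        j = j_calibrated(phi_psii(rec.Ft, rec.Fm_prime), rec.PPFD, cal)
        out.append(gm_variable_j(rec, Rd, j, gamma_star, Ec=Ec, ci_mode=ci_mode))
    return out


def curve_gm(estimates: Sequence[GmEstimate], records: Sequence[GasExchangeRecord],
             ca_ref: float = 400.0) -> float:
    """The curve-level gm: mean of reliable estimates at CO2 steps near ``ca_ref``.

    The measurement protocol visits the reference step twice (before and after
    the low-CO2 excursion); both visits are averaged.  Falls back to the
    median of all reliable estimates when no reliable point sits within 10%
    of the reference step.
    """
    reliable = [(e, r) for e, r in zip(estimates, records) if e.reliable and e.gm is not None]
    if not reliable:
        raise ValueError("no reliable gm estimates on this curve")
    near = [e.gm for e, r in reliable if abs(r.Ca - ca_ref) <= 0.1 * ca_ref]
    if near:
        return float(np.mean(near))
    return float(np.median([e.gm for e, _ in reliable]))


def robust_curve_gm(estimates: Sequence[GmEstimate]) -> float:
    """Median gm over the reliable steps of one response curve.

    The robust curve-level summary for noisy data: unreliable steps (near the
    variable-J singularity or outside the sensitivity window) are excluded and
    the median damps the heavy-tailed noise amplification of the remaining
    ones.  Identical to any single reliable estimate on noise-free data.
    """
    vals = [e.gm for e in estimates if e.reliable and e.gm is not None]
    if not vals:
        raise ValueError("no reliable gm estimates on this curve")
    return float(np.median(vals))


def estimate_gm_chain(
    records: Sequence[GasExchangeRecord],
    cal: CalibrationResult,
    laisk_result: "laisk_mod.LaiskResult",
    gamma_star_mode: str = "ci_star_as_gamma_star",
    Ec: float = DEFAULT_EC,
    ci_mode: str = "boyer",
    ca_ref: float = 400.0,
) -> tuple[list[GmEstimate], "laisk_mod.LaiskResult"]:
    """Estimate gm for a response curve, resolving Gamma* per the chosen mode.

    With ``gamma_star_mode='iterative'`` the Gamma* = Ci* + Rd/gm conversion is
    completed by a damped fixed point in which each trial Gamma* re-estimates
    the curve-level gm; the conventional shortcut Gamma* = Ci* is the default.
    """
    if gamma_star_mode == "iterative":
        def gm_of(gs: float) -> float:
            est = estimate_curve(records, cal, laisk_result.Rd, gs, Ec=Ec, ci_mode=ci_mode)
            return curve_gm(est, records, ca_ref=ca_ref)

        resolved = laisk_mod.gamma_star(laisk_result, gm=gm_of, mode="iterative")
    else:
        resolved = laisk_mod.gamma_star(laisk_result, mode=gamma_star_mode)
    estimates = estimate_curve(records, cal, laisk_result.Rd, resolved.gamma_star,
                               Ec=Ec, ci_mode=ci_mode)
    return estimates, resolved


def gm_vs_gsc_regression(df: pd.DataFrame, min_points: int = 3) -> pd.DataFrame:
    """Per-genotype OLS of gm on gsc with 95% confidence intervals on the slope.

    ``df`` needs columns ``genotype``, ``gm``, ``gsc`` (reliable estimates
    only); genotypes with fewer than ``min_points`` points are skipped with a
    warning.
    """
    rows = []
    for geno, grp in df.groupby("genotype"):
        grp = grp.dropna(subset=["gm", "gsc"])
        if len(grp) < min_points:
            log.warning("genotype %s skipped: only %d points", geno, len(grp))
            continue
        fit = sm.OLS(grp["gm"].to_numpy(), sm.add_constant(grp["gsc"].to_numpy())).fit()
        lo, hi = fit.conf_int(alpha=0.05)[1]
        rows.append({
            "genotype": geno, "n": len(grp),
            "slope": float(fit.params[1]), "intercept": float(fit.params[0]),
            "slope_ci_low": float(lo), "slope_ci_high": float(hi),
            "slope_se": float(fit.bse[1]), "r2": float(fit.rsquared),
        })
    return pd.DataFrame(rows)
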