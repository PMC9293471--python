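"""Quantum yields and fluorescence calibration of electron transport rate.

The operating quantum yield of PSII, PhiPSII = (Fm' - Ft)/Fm' (Genty), is
regressed against the apparent quantum yield of CO2 fixation,
PhiCO2 = (An + Rd)/PPFD, measured under non-photorespiratory conditions
(1% O2) where CO2 fixation is the only electron sink.  The slope k and
intercept b of that regression calibrate the fluorescence-based electron
transport rate used at 21% O2:

    Jcal = 4 * (PhiPSII - b) / k * PPFD

which reduces to J = PhiPSII * PPFD * alpha * beta (leaf absorbance alpha
times PSII partitioning beta) when b = 0 and k = 4/(alpha*beta).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .io import GasExchangeRecord

log = logging.getLogger("mesocond.fluorescence")


class MeasurementError(ValueError):
    """A fluorescence or flux value outside its physical domain."""


class InsufficientDataError(ValueError):
    """Too few points survive filtering to fit."""


@dataclass(frozen=True)
class CalibrationResult:
    """Slope/intercept of the PhiPSII-vs-PhiCO2 line and the implied alpha*beta."""

    k: float
    b: float
    alpha_beta: float
    n_used: int
    r2: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("calibration slope k must be positive")
        if not 0.0 <= self.b < 0.5:
            raise ValueError("calibration intercept b must lie in [0, 0.5)")
        if self.n_used < 3:
            raise ValueError("calibration requires at least 3 points")


def phi_psii(Ft: float, Fm_prime: float) -> float:
    """Operating quantum yield of PSII, (Fm' - Ft)/Fm'."""
    Ft = np.asarray(Ft, dtype=float)
    Fm_prime = np.asarray(Fm_prime, dtype=float)
    if np.any(Ft <= 0) or np.any(Fm_prime <= Ft):
        raise MeasurementError("requires Fm_prime > Ft > 0")
    out = (Fm_prime - Ft) / Fm_prime
    return float(out) if out.ndim == 0 else out


def phi_co2(An: float, Rd: float, PPFD: float) -> float:
    """Apparent quantum yield of CO2 fixation, (An + Rd)/PPFD."""
    An = np.asarray(An, dtype=float)
    PPFD = np.asarray(PPFD, dtype=float)
    if Rd < 0:
        raise MeasurementError("Rd must be non-negative")
    if np.any(PPFD <= 0):
        raise MeasurementError("PPFD must be positive")
    out = (An + Rd) / PPFD
    return float(out) if out.ndim == 0 else out


def calibrate(
    records: Sequence[GasExchangeRecord],
    Rd: float,
    phi_co2_max: float = 0.05,
    phi_psii_max: float = 0.5,
) -> CalibrationResult:
    """OLS of PhiPSII on PhiCO2 over the linear region of a 1% O2 response curve.

    Points are restricted to PhiCO2 < ``phi_co2_max`` and PhiPSII <
    ``phi_psii_max``, the region where the PSII-to-CO2 electron budget is
    linear.  Returns slope k, intercept b and the implied alpha*beta = 4/k.
    """
    recs = [r for r in records if r.has_fluorescence]
    if len(recs) < 3:
        raise InsufficientDataError("need at least 3 fluorescence records at low O2")
    for r in recs:
        if r.O2_frac > 0.05:
            log.warning("calibration record at O2_frac=%.3f is not non-photorespiratory", r.O2_frac)
    y = np.array([phi_psii(r.Ft, r.Fm_prime) for r in recs])
    x = np.array([phi_co2(r.An, Rd, r.PPFD) for r in recs])
    keep = (x < phi_co2_max) & (y < phi_psii_max)
    if keep.sum() < 3:
        raise InsufficientDataError(
            f"only {int(keep.sum())} points inside the linear region "
            f"(PhiCO2 < {phi_co2_max}, PhiPSII < {phi_psii_max})"
        )
    x, y = x[keep], y[keep]
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    b, k = float(fit.params[0]), float(fit.params[1])
    return CalibrationResult(k=k, b=max(b, 0.0), alpha_beta=4.0 / k, n_used=int(keep.sum()), r2=float(fit.rsquared))


def j_calibrated(phi_psii_value, PPFD, cal: CalibrationResult):
    """Calibrated electron transport rate Jcal = 4*(PhiPSII - b)/k * PPFD.

    Non-positive results are non-physical; callers flag and exclude them.
    """
    phi = np.asarray(phi_psii_value, dtype=float)
    ppfd = np.asarray(PPFD, dtype=float)
    if np.any(ppfd < 0):
        raise MeasurementError("PPFD must be non-negative")
    out = 4.0 * (phi - cal.b) / cal.k * ppfd
    if np.any(out <= 0):
        log.warning("non-physical Jcal <= 0 encountered; flag and exclude downstream")
    return float(out) if out.ndim == 0 else out
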