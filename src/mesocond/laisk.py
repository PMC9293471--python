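"""Laisk estimation of day respiration Rd and the intercellular compensation point Ci*.

Low-Ci A-Ci responses measured at several irradiances are each fitted with a
straight line; because electron transport is light-limited there, the lines
fan out with PPFD but share the common point (Ci*, -Rd).  The mean of the
three pairwise intersections gives Ci* (x) and Rd (y = -Rd).  The apparent
chloroplastic compensation point follows from Gamma* = Ci* + Rd/gm; because
gm is unknown before the variable-J step, Ci* itself is the usual stand-in
(mode ``ci_star_as_gamma_star``), with a Bernacchi-constant mode and a
completed fixed-point mode (``iterative``) also available.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace, field
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm

from .constants import KineticConstants
from .fvcb import arrhenius_scale

log = logging.getLogger("mesocond.laisk")

#: default upper edge of the low-Ci fitting window (umol mol-1)
DEFAULT_CI_WINDOW = 150.0

MODES = ("ci_star_as_gamma_star", "bernacchi_constant", "iterative")


class InsufficientDataError(ValueError):
    pass


class DegenerateGeometryError(ValueError):
    """Two response lines are parallel; their intersection is undefined."""


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, last: float):
        super().__init__(msg)
        self.last = last


@dataclass(frozen=True)
class LaiskResult:
    """Rd (stored positive), Ci*, and the Gamma* implied by the chosen mode."""

    Rd: float
    Ci_star: float
    gamma_star: float
    mode: str
    intersections: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.Rd < 0:
            raise ValueError("Rd must be non-negative (sign convention: stored positive)")
        if self.Ci_star <= 0:
            raise ValueError("Ci_star must be positive")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


def fit_low_ci_lines(
    curves: Sequence[tuple[float, np.ndarray, np.ndarray]],
    ci_max: float = DEFAULT_CI_WINDOW,
) -> list[tuple[float, float]]:
    """OLS line (slope, intercept) per low-Ci curve.

    ``curves`` is a sequence of (PPFD, Ci, An) triples; only points with
    Ci <= ``ci_max`` enter each fit.  PPFD levels must be distinct, and the
    fitted slopes should increase with PPFD (a warning is emitted if not).
    """
    ppfds = [c[0] for c in curves]
    if len(set(ppfds)) != len(ppfds):
        raise ValueError("PPFD levels of the low-Ci curves must be strictly distinct")
    lines = []
    for ppfd, ci, an in curves:
        ci = np.asarray(ci, dtype=float)
        an = np.asarray(an, dtype=float)
        keep = ci <= ci_max
        if keep.sum() < 3:
            raise InsufficientDataError(
                f"curve at PPFD={ppfd} has only {int(keep.sum())} points with Ci <= {ci_max}"
            )
        fit = sm.OLS(an[keep], sm.add_constant(ci[keep])).fit()
        lines.append((float(fit.params[1]), float(fit.params[0])))
    order = np.argsort(ppfds)
    slopes_by_light = np.array([lines[i][0] for i in order])
    if not np.all(np.diff(slopes_by_light) > 0):
        log.warning("low-Ci slopes do not increase with PPFD: %s", slopes_by_light)
    return lines


def intersect_and_average(lines: Sequence[tuple[float, float]]) -> LaiskResult:
    """Average the pairwise intersections of the fitted lines into (Ci*, Rd).

    Each pair (m_i, b_i), (m_j, b_j) intersects at x = (b_j - b_i)/(m_i - m_j);
    Ci* is the mean x and Rd the negated mean y over all pairs.
    """
    pts = []
    for (i, (mi, bi)), (j, (mj, bj)) in itertools.combinations(enumerate(lines), 2):
        if np.isclose(mi, mj, rtol=0.0, atol=1e-12):
            raise DegenerateGeometryError(f"lines {i} and {j} are parallel (slope {mi})")
        x = (bj - bi) / (mi - mj)
        pts.append((x, mi * x + bi))
    xs, ys = zip(*pts)
    return LaiskResult(
        Rd=-float(np.mean(ys)),
        Ci_star=float(np.mean(xs)),
        gamma_star=float(np.mean(xs)),
        mode="ci_star_as_gamma_star",
        intersections=tuple(pts),
    )


def gamma_star(
    result: LaiskResult,
    gm: float | Callable[[float], float] | None = None,
    mode: str = "ci_star_as_gamma_star",
    kinetics: KineticConstants | None = None,
    tleaf_c: float = 25.0,
    tol: float = 0.01,
    max_iter: int = 50,
    damping: float = 0.5,
) -> LaiskResult:
    """Resolve Gamma* from a Laisk result under the chosen convention.

    * ``ci_star_as_gamma_star`` -- Gamma* = Ci* (the incomplete conversion).
    * ``bernacchi_constant`` -- Gamma* from the Bernacchi temperature function
      at ``tleaf_c``, ignoring the Laisk intersection.
    * ``iterative`` -- completes Gamma* = Ci* + Rd/gm by damped fixed point;
      ``gm`` is either a fixed conductance or a callable gm(Gamma*) that
      re-estimates gm for a trial Gamma* (closing the variable-J loop).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "ci_star_as_gamma_star":
        return replace(result, gamma_star=result.Ci_star, mode=mode)
    if mode == "bernacchi_constant":
        kin = kinetics or KineticConstants()
        gs = kin.gamma_star25 * arrhenius_scale(tleaf_c, kin.Ea_gamma_star)
        return replace(result, gamma_star=float(gs), mode=mode)
    if gm is None:
        raise ValueError("iterative mode requires gm (a value or a callable)")
    gm_of = gm if callable(gm) else (lambda _gs: gm)
    gs = result.Ci_star
    for _ in range(max_iter):
        target = result.Ci_star + result.Rd / gm_of(gs)
        new = gs + damping * (target - gs)
        if abs(new - gs) < tol:
            return replace(result, gamma_star=float(new), mode="iterative")
        gs = new
    raise ConvergenceError(f"Gamma* fixed point did not converge in {max_iter} iterations", gs)


def estimate_laisk(
    curves: Sequence[tuple[float, np.ndarray, np.ndarray]],
    ci_max: float = DEFAULT_CI_WINDOW,
) -> LaiskResult:
    """Fit, intersect and average in one call (Gamma* left at the Ci* convention)."""
    return intersect_and_average(fit_low_ci_lines(curves, ci_max=ci_max))
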