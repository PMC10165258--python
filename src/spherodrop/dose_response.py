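"""Four-parameter logistic (Hill) dose–response fitting and IC50 extraction.

The model on the log-concentration axis is

    V(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)

so the fitted IC50 is the midpoint of the sigmoid: V(ic50) = (top+bottom)/2.
Fits run per spheroid point (not per-level means), with multi-start
initialisation over a hill × ic50 grid and bound-constrained least squares.
Zero-concentration controls do not sit on the log axis; they are
summarised separately and can pin the fitted top to their mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["DoseResponseFit", "FlatResponseError", "fit_sigmoid",
           "predict_viability", "control_summary"]

HILL_STARTS = (0.5, 1.0, 2.0, 4.0)
N_IC50_STARTS = 5


class FlatResponseError(ValueError):
    """The response carries no dose dependence: the IC50 is undefined."""


@dataclass
class DoseResponseFit:
    top: float
    bottom: float
    ic50: float
    hill: float
    ssr: float
    n: int
    converged: bool
    pinned_top: float | None = None
    units: str = "uM"

    def as_row(self) -> dict:
        return {"ic50_uM": self.ic50, "hill": self.hill, "top": self.top,
                "bottom": self.bottom, "ssr": self.ssr, "n": self.n,
                "converged": self.converged}


def _model(logc: np.ndarray, top: float, bottom: float,
           log_ic50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))


def fit_sigmoid(
    concentrations,
    viabilities,
    pin_top: float | None = None,
    flat_span: float = 0.05,
    max_hill: float = 10.0,
) -> DoseResponseFit:
    """Least-squares 4PL fit of viability vs concentration.

    Requires >= 4 distinct positive concentrations.  ``pin_top`` fixes the
    top plateau (typically to the mean control viability).  A response
    whose span is below ``flat_span`` raises :class:`FlatResponseError`
    ("response flat, IC50 undefined").  Multi-start: hill in
    {0.5, 1, 2, 4} × 5 log-spaced ic50 grid points across the data range;
    the best sum of squared residuals wins, ties going to the smaller hill.
    """
    conc = np.asarray(concentrations, dtype=np.float64)
    viab = np.asarray(viabilities, dtype=np.float64)
    if conc.shape != viab.shape:
        raise ValueError("concentrations and viabilities differ in length")
    keep = conc > 0
    conc, viab = conc[keep], viab[keep]
    if np.unique(conc).size < 4:
        raise ValueError("need >= 4 distinct positive concentrations")
    if np.any((viab < -1e-9) | (viab > 1.0 + 1e-9)):
        raise ValueError("viabilities must lie in [0, 1]")
    if float(np.ptp(viab)) < flat_span:
        raise FlatResponseError("response flat, IC50 undefined")

    logc = np.log10(conc)
    lo_c, hi_c = logc.min(), logc.max()
    ic50_bounds = (lo_c - 2.0, hi_c + 2.0)          # conc/100 .. conc*100

    if pin_top is None:
        def residuals(p):
            return _model(logc, p[0], p[1], p[2], p[3]) - viab
        lower = [0.0, 0.0, ic50_bounds[0], 1e-3]
        upper = [1.1, 1.0, ic50_bounds[1], max_hill]

        def pack(top0, bottom0, lic0, hill0):
            return [top0, bottom0, lic0, hill0]
    else:
        def residuals(p):
            return _model(logc, pin_top, p[0], p[1], p[2]) - viab
        lower = [0.0, ic50_bounds[0], 1e-3]
        upper = [min(1.0, pin_top), ic50_bounds[1], max_hill]

        def pack(top0, bottom0, lic0, hill0):
            return [min(bottom0, pin_top), lic0, hill0]

    top0 = float(np.clip(viab.max(), 0.05, 1.1))
    bottom0 = float(np.clip(viab.min(), 0.0, 1.0))
    best = None
    best_key = (np.inf, np.inf)
    for hill0 in HILL_STARTS:
        for lic0 in np.linspace(lo_c, hi_c, N_IC50_STARTS):
            x0 = np.clip(pack(top0, bottom0, lic0, hill0), lower, upper)
            try:
                sol = least_squares(residuals, x0, bounds=(lower, upper),
                                    xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except Exception:
                continue
            ssr = float(np.sum(sol.fun**2))
            hill_fit = float(sol.x[-1])
            if ssr < best_key[0] - 1e-12 or (
                abs(ssr - best_key[0]) <= 1e-12 and hill_fit < best_key[1]
            ):
                best, best_key = sol, (ssr, hill_fit)
    if best is None:
        return DoseResponseFit(np.nan, np.nan, np.nan, np.nan, np.inf,
                               conc.size, False, pin_top)
    if pin_top is None:
        top, bottom, lic, hill = best.x
    else:
        top = pin_top
        bottom, lic, hill = best.x
    return DoseResponseFit(float(top), float(bottom), float(10.0**lic),
                           float(hill), best_key[0], int(conc.size),
                           bool(best.success), pin_top)


def predict_viability(fit: DoseResponseFit, concentration) -> np.ndarray | float:
    """Evaluate the fitted curve; c = ic50 returns exactly (top+bottom)/2."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    c = np.asarray(concentration, dtype=np.float64)
    out = np.where(
        c == 0.0,
        fit.top,
        fit.bottom + (fit.top - fit.bottom)
        / (1.0 + np.power(np.where(c > 0, c, 1.0) / fit.ic50, fit.hill)),
    )
    return float(out) if out.ndim == 0 else out


def control_summary(control_viabilities) -> dict:
    """Summary of zero-concentration controls (kept off the log axis)."""
    v = np.asarray(control_viabilities, dtype=np.float64)
    if v.size == 0:
        return {"n": 0, "mean": np.nan, "sd": np.nan}
    return {"n": int(v.size), "mean": float(v.mean()), "sd": float(v.std())}
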