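"""Four-parameter logistic (4PL) concentration-response fitting.

The model on log10 concentration is

    y(x) = bottom + (top - bottom) / (1 + 10^(h * (log10 x50 - log10 x)))

for rising (agonist) curves, where x50 is the EC50 and h > 0 the Hill
slope; antagonist curves use the mirrored, declining orientation and x50 is
then the IC50.  Fits are unweighted least squares with deterministic,
data-derived initialization (response extremes for the asymptotes, the
concentration nearest half-maximum for x50, Hill slope 1), so a given
dataset always yields the same fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import DataError, DomainError, InsufficientDataError

AGONIST = "AGONIST"
ANTAGONIST = "ANTAGONIST"


def four_pl(conc, bottom, top, x50, hill, direction=AGONIST):
    """Evaluate the 4PL curve at molar concentrations ``conc``."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc <= 0):
        raise DomainError("concentrations must be positive")
    logx = np.log10(conc)
    sign = 1.0 if direction == AGONIST else -1.0
    return bottom + (top - bottom) / (1.0 + 10.0 ** (sign * hill * (np.log10(x50) - logx)))


@dataclass
class FourPLFit:
    bottom: float
    top: float
    ec50: float          # IC50 when direction == ANTAGONIST
    hill: float
    se_ec50: float
    converged: bool
    residual_ss: float
    direction: str = AGONIST
    extrapolated: bool = False
    message: str = ""

    def predict(self, conc) -> np.ndarray:
        return four_pl(conc, self.bottom, self.top, self.ec50, self.hill, self.direction)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("bottom", "top", "ec50", "hill", "se_ec50", "converged",
                 "residual_ss", "direction", "extrapolated", "message")}


def fit_4pl(conc, response, direction: str = AGONIST) -> FourPLFit:
    """Least-squares 4PL fit; returns a flagged (non-converged) fit rather
    than raising when the data carry no sigmoid (e.g. constant response).

    Requires >= 5 distinct positive concentrations; replicates are fitted as
    individual points (unweighted).  ``se_ec50`` is a delta-method standard
    error propagated from the fitted log10 x50.
    """
    if direction not in (AGONIST, ANTAGONIST):
        raise DataError(f"unknown direction {direction!r}")
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if conc.shape != response.shape:
        raise DataError("conc and response must have equal length")
    if np.any(conc <= 0):
        raise DomainError("concentrations must be positive")
    distinct = np.unique(conc)
    if distinct.size < 5:
        raise InsufficientDataError("4PL needs >= 5 distinct concentrations")

    logx = np.log10(conc)
    sign = 1.0 if direction == AGONIST else -1.0

    # deterministic initialization from data quantiles
    means = {c: response[conc == c].mean() for c in distinct}
    mean_resp = np.array([means[c] for c in distinct])
    lo, hi = float(mean_resp.min()), float(mean_resp.max())
    span = hi - lo
    if span == 0:
        return FourPLFit(lo, hi, float(np.median(distinct)), 1.0, np.inf, False,
                         float(((response - response.mean()) ** 2).sum()),
                         direction, False, "constant response: no sigmoid to fit")
    half = (lo + hi) / 2.0
    x50_0 = float(distinct[np.argmin(np.abs(mean_resp - half))])

    def model(lx, bottom, top, log_x50, hill):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (sign * hill * (log_x50 - lx)))

    p0 = [lo, hi, np.log10(x50_0), 1.0]
    lmin, lmax = logx.min(), logx.max()
    bounds = ([lo - 2 * span, lo - 2 * span, lmin - 3.0, 1e-3],
              [hi + 2 * span, hi + 2 * span, lmax + 3.0, 10.0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(model, logx, response, p0=p0, bounds=bounds,
                                   maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return FourPLFit(lo, hi, x50_0, 1.0, np.inf, False,
                         float(((response - response.mean()) ** 2).sum()),
                         direction, False, f"fit failed: {exc}")

    bottom, top, log_x50, hill = (float(v) for v in popt)
    x50 = 10.0 ** log_x50
    resid = response - model(logx, *popt)
    rss = float((resid ** 2).sum())
    se_log = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.inf
    se_x50 = x50 * np.log(10.0) * se_log
    # canonical orientation: top is the upper asymptote
    if top < bottom:
        bottom, top = top, bottom
    extrapolated = not (distinct.min() <= x50 <= distinct.max())
    converged = bool(np.isfinite(x50) and (top - bottom) > 1e-12)
    return FourPLFit(bottom, top, x50, hill, se_x50, converged, rss,
                     direction, extrapolated)


def ec90_from_fit(fit: FourPLFit) -> float:
    """Concentration producing 90% of the fitted span: EC50 * 9^(1/hill)."""
    if not fit.converged:
        raise DataError("EC90 requested from a non-converged fit")
    if fit.hill <= 0:
        raise DomainError("EC90 needs a positive Hill slope")
    return float(fit.ec50 * 9.0 ** (1.0 / fit.hill))


def ic50_table(fits: list[FourPLFit]) -> dict[str, float]:
    """Average IC50 (mean, SD, n) across repeated fits, e.g. per-time-point
    reads of the same antagonist; non-converged fits are excluded with a
    warning."""
    usable = [f for f in fits if f.converged]
    dropped = len(fits) - len(usable)
    if dropped:
        warnings.warn(f"excluded {dropped} non-converged fit(s) from IC50 averaging")
    if len(usable) < 2:
        raise InsufficientDataError("IC50 averaging needs >= 2 converged fits")
    vals = np.array([f.ec50 for f in usable])
    return {"mean_ic50": float(vals.mean()),
            "sd_ic50": float(vals.std(ddof=1)),
            "n_fits": len(usable)}
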