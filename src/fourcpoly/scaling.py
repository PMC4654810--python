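"""Log-log smoothing-spline fits of contact-probability decay.

Contact probabilities fall off with genomic separation roughly as a power law
P ~ s^nu over intermediate scales (the fit is typically linear in log-log
space from ~10 kb to ~10 Mb).  A smoothing spline, rather than a straight
line, is fitted so that departures from scaling at short range (measurement
resolution) and long range (nuclear confinement, poor signal) do not bias the
local slope.  The spline smoothing parameter is chosen by generalized
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline, make_smoothing_spline

__all__ = ["LogLogSplineFit", "fit_loglog", "FitError"]


class FitError(RuntimeError):
    """Raised when a decay fit is not identifiable from the data given."""


@dataclass
class LogLogSplineFit:
    """A smooth function log F(log s) with analytic derivative.

    ``slope(s)`` is the local scaling exponent at separation ``s`` (bp):
    d log F / d log s, evaluated analytically from the spline.
    """

    spline: BSpline
    derivative: BSpline
    log_s_min: float
    log_s_max: float
    n_points: int
    label: str = ""

    def predict_log(self, s) -> np.ndarray:
        return self.spline(np.log(np.asarray(s, dtype=float)))

    def __call__(self, s) -> np.ndarray:
        """Fitted F at separation s (bp), on the original scale."""
        return np.exp(self.predict_log(s))

    def slope(self, s) -> np.ndarray:
        """Local log-log slope (scaling exponent) at separation s."""
        return self.derivative(np.log(np.asarray(s, dtype=float)))

    def in_support(self, s) -> np.ndarray:
        ls = np.log(np.asarray(s, dtype=float))
        return (ls >= self.log_s_min) & (ls <= self.log_s_max)


def fit_loglog(separations, values, fit_range=(1e4, 1e7), min_points: int = 30,
               min_decades: float = 1.0, label: str = "") -> LogLogSplineFit:
    """Fit log(values) against log(separations) with a GCV smoothing spline.

    Only strictly positive values at separations inside ``fit_range`` enter
    the fit.  Duplicate separations (e.g. the two fragments flanking a
    viewpoint at equal distance) are averaged in log space before fitting.

    Raises :class:`FitError` when fewer than ``min_points`` usable points
    remain or when they span less than ``min_decades`` decades.
    """
    s = np.asarray(separations, dtype=float)
    f = np.asarray(values, dtype=float)
    lo, hi = fit_range
    mask = np.isfinite(s) & np.isfinite(f) & (f > 0) & (s >= lo) & (s <= hi)
    s, f = s[mask], f[mask]
    who = f" for {label}" if label else ""
    if s.size < min_points:
        raise FitError(
            f"log-log fit{who}: only {s.size} positive points in "
            f"[{lo:g}, {hi:g}] bp (need >= {min_points})")
    x = np.log(s)
    y = np.log(f)
    order = np.argsort(x)
    x, y = x[order], y[order]
    # collapse duplicate abscissae to their mean log value
    ux, inverse = np.unique(x, return_inverse=True)
    if ux.size < x.size:
        uy = np.bincount(inverse, weights=y) / np.bincount(inverse)
        x, y = ux, uy
    if x.size < 4:
        raise FitError(f"log-log fit{who}: fewer than 4 distinct separations")
    if (x[-1] - x[0]) < min_decades * np.log(10):
        raise FitError(
            f"log-log fit{who}: separations span {(x[-1]-x[0])/np.log(10):.2f} "
            f"decades (need >= {min_decades})")
    spline = make_smoothing_spline(x, y)  # lambda by generalized CV
    return LogLogSplineFit(spline=spline, derivative=spline.derivative(),
                           log_s_min=float(x[0]), log_s_max=float(x[-1]),
                           n_points=int(x.size), label=label)
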