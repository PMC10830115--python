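"""Grassberger-Procaccia correlation-dimension estimation.

The correlation integral C(r) is the fraction of point pairs within
distance r of each other,

    C(r) = (2 / N(N-1)) * sum_{i<j} H(r - ||x_i - x_j||),

with H the Heaviside step (H(0) = 1: boundary pairs count).  For a point
cloud sampled from a d-dimensional set, C(r) ~ r^alpha with alpha equal to
the intrinsic dimension, so alpha is read off as the least-squares slope
of log C(r) against log r.  The fit is restricted to radii whose C values
fall between the 20th and 80th percentile of the evaluated C values, which
avoids both the noise-dominated small-r regime and the saturating large-r
regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist


@dataclass
class CorrelationIntegral:
    radii: np.ndarray
    c: np.ndarray
    n_points: int
    alpha: float | None = None
    fit_r2: float | None = None
    n_fit: int | None = None

    @property
    def n_pairs(self) -> int:
        return self.n_points * (self.n_points - 1) // 2


def correlation_integral(points: np.ndarray, radii: np.ndarray) -> CorrelationIntegral:
    """Evaluate C(r) at the given radii (boundary pairs count, H(0)=1)."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 2:
        raise ValueError("need >= 2 points in a 2-D array")
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    d = np.sort(pdist(points))
    if d[-1] == 0:
        raise ValueError("zero-diameter cloud")
    counts = np.searchsorted(d, radii, side="right")
    return CorrelationIntegral(radii=radii, c=counts / len(d), n_points=len(points))


def estimate_dimension(
    points: np.ndarray,
    n_radii: int = 50,
    fit_percentiles: tuple[float, float] = (20.0, 80.0),
) -> CorrelationIntegral:
    """Estimate intrinsic dimension alpha from the log-log slope of C(r).

    Radii are log-spaced between the smallest nonzero and the largest
    pairwise distance.
    """
    points = np.asarray(points, dtype=float)
    d = pdist(points)
    d_pos = d[d > 0]
    if len(d_pos) == 0:
        raise ValueError("zero-diameter cloud")
    radii = np.geomspace(d_pos.min(), d_pos.max(), n_radii)
    ci = correlation_integral(points, radii)

    lo, hi = np.percentile(ci.c, fit_percentiles)
    mask = (ci.c >= lo) & (ci.c <= hi) & (ci.c > 0)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 radii in the percentile fit band")
    logr = np.log(radii[mask])
    logc = np.log(ci.c[mask])
    slope, intercept = np.polyfit(logr, logc, 1)
    resid = logc - (slope * logr + intercept)
    ss_tot = np.sum((logc - logc.mean()) ** 2)
    ci.alpha = float(slope)
    ci.fit_r2 = float(1 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    ci.n_fit = int(mask.sum())
    return ci
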