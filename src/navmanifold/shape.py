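"""D2 shape-distribution signatures, feature models and PV correlations.

The D2 signature of a point cloud is the histogram of all pairwise
distances, min-max normalized to [0, 1], binned into 1200 bins, Gaussian
smoothed (sigma = 10 bins) and renormalized to sum 1.  Because of the
min-max normalization it is invariant to rigid motions and global
rescaling, which makes it a convenient signature for matching a neural
manifold against idealized geometric models (sphere, planar figure-8,
bent figure-8).  Dissimilarity between two signatures is the L1 distance
between their bin probabilities (range [0, 2]).

Bimodality of the raw normalized-distance sample is quantified by the
coefficient

    b = (g^2 + 1) / (k + 3 (n-1)^2 / ((n-2)(n-3)))

with g the sample skewness and k the sample excess kurtosis; b tends to
5/9 for a uniform sample and 1/3 for a normal one, and larger values
suggest bimodality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.distance import pdist
from scipy.stats import kurtosis, skew

from .maze import TMazeGeometry
from .session import BehaviorSeries, BinnedActivity
from .topology import density_filter

N_BINS = 1200
SMOOTH_SIGMA_BINS = 10.0
ARM_REWARD_U = (0.60, 0.90)  # arm + reward segment used for arm-tuning correlations


@dataclass
class ShapeDistribution:
    probs: np.ndarray      # 1200 bin probabilities, sum 1
    b: float               # bimodality coefficient of the distance sample
    n_points: int

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(N_BINS) + 0.5) / N_BINS


@dataclass
class FeatureModel:
    kind: str              # sphere | figure8 | bent_figure8
    points: np.ndarray
    params: dict


def bimodality_coefficient(sample: np.ndarray) -> float:
    sample = np.asarray(sample, dtype=float)
    n = len(sample)
    if n < 4:
        raise ValueError("need >= 4 samples")
    g = skew(sample, bias=False)
    k = kurtosis(sample, fisher=True, bias=False)
    return float((g**2 + 1) / (k + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def d2_distribution(points: np.ndarray, apply_density_filter: bool = True) -> ShapeDistribution:
    """D2 shape signature of a point cloud (density-filtered first by default)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 10:
        raise ValueError("need >= 10 points")
    if apply_density_filter:
        points = density_filter(points)
    d = pdist(points)
    lo, hi = d.min(), d.max()
    if hi == lo:
        raise ValueError("all pairwise distances equal; shape signature undefined")
    dn = (d - lo) / (hi - lo)
    hist, _ = np.histogram(dn, bins=N_BINS, range=(0.0, 1.0))
    probs = gaussian_filter1d(hist.astype(float), SMOOTH_SIGMA_BINS, mode="reflect")
    probs /= probs.sum()
    return ShapeDistribution(probs=probs, b=bimodality_coefficient(dn), n_points=len(points))


def dissimilarity(p: ShapeDistribution | np.ndarray, q: ShapeDistribution | np.ndarray) -> float:
    """L1 distance between two bin-probability signatures; symmetric, in [0, 2]."""
    pa = p.probs if isinstance(p, ShapeDistribution) else np.asarray(p, float)
    qa = q.probs if isinstance(q, ShapeDistribution) else np.asarray(q, float)
    if pa.shape != qa.shape:
        raise ValueError("signatures have different bin counts")
    return float(np.abs(pa - qa).sum())


# ---------------------------------------------------------------------------
# feature models


def _torus_points(n, center, ring_radius, tube_radius, normal_axis, rng):
    """Uniform sample of a torus surface (rejection-corrected in the tube angle)."""
    pts = np.empty((n, 3))
    m = 0
    while m < n:
        k = 2 * (n - m) + 16
        phi = rng.uniform(0, 2 * np.pi, k)       # around the ring
        theta = rng.uniform(0, 2 * np.pi, k)     # around the tube
        accept = rng.uniform(0, 1, k) < (ring_radius + tube_radius * np.cos(theta)) / (
            ring_radius + tube_radius
        )
        phi, theta = phi[accept], theta[accept]
        k = min(len(phi), n - m)
        r = ring_radius + tube_radius * np.cos(theta[:k])
        local = np.column_stack([r * np.cos(phi[:k]), r * np.sin(phi[:k]),
                                 tube_radius * np.sin(theta[:k])])
        pts[m:m + k] = local
        m += k
    if normal_axis == "y":  # rotate ring plane from xy to xz (normal z -> y)
        pts = pts[:, [0, 2, 1]] * np.array([1.0, 1.0, -1.0])
    return pts + np.asarray(center)


def make_feature_model(
    kind: str, n: int = 2000, seed: int = 0, tube_ratio: float = 0.3
) -> FeatureModel:
    """Sample an idealized manifold model.

    sphere: uniform on the unit sphere surface.  figure8: two congruent
    torus surfaces whose center-circle planes coincide, tangent at one
    point.  bent_figure8: the same two tori with a 90 degree dihedral
    angle between the center-circle planes.
    """
    rng = np.random.default_rng(seed)
    if kind == "sphere":
        v = rng.standard_normal((n, 3))
        pts = v / np.linalg.norm(v, axis=1, keepdims=True)
        return FeatureModel(kind=kind, points=pts, params={"n": n, "radius": 1.0})
    if kind in ("figure8", "bent_figure8"):
        ring, tube = 1.0, tube_ratio
        sep = ring + tube  # centers at +-sep: outer rims touch at the origin
        half = n // 2
        p1 = _torus_points(half, (-sep, 0.0, 0.0), ring, tube, "z", rng)
        axis2 = "z" if kind == "figure8" else "y"
        p2 = _torus_points(n - half, (sep, 0.0, 0.0), ring, tube, axis2, rng)
        return FeatureModel(
            kind=kind, points=np.vstack([p1, p2]),
            params={"n": n, "tube_ratio": tube_ratio, "dihedral_deg": 0 if kind == "figure8" else 90},
        )
    raise ValueError(f"unknown feature model {kind!r}")


# ---------------------------------------------------------------------------
# population-vector correlations


def _rate_maps(binned: BinnedActivity, behavior: BehaviorSeries, turn: str, n_u: int):
    f = behavior.frame
    mask = (f["turn"].to_numpy() == turn) & np.isfinite(f["u"].to_numpy())
    u = f["u"].to_numpy()[mask]
    rates = binned.rates[mask]
    which = np.clip((u * n_u).astype(int), 0, n_u - 1)
    maps = np.full((binned.n_units, n_u), np.nan)
    for k in range(n_u):
        sel = which == k
        if np.any(sel):
            maps[:, k] = rates[sel].mean(axis=0)
    return maps


def pv_correlation(
    binned: BinnedActivity,
    behavior: BehaviorSeries,
    n_position_bins: int = 50,
    geometry: TMazeGeometry | None = None,
) -> pd.DataFrame:
    """Left-vs-right population-vector and per-neuron arm-tuning correlations.

    Returns a frame of per-position PV correlations (column ``pv_r``) and
    attaches per-neuron arm-tuning correlations (restricted to the
    arm+reward segment u in [0.60, 0.90]) as ``.attrs['arm_r']``.
    """
    maps_l = _rate_maps(binned, behavior, "L", n_position_bins)
    maps_r = _rate_maps(binned, behavior, "R", n_position_bins)
    centers = (np.arange(n_position_bins) + 0.5) / n_position_bins

    pv_r = np.full(n_position_bins, np.nan)
    for k in range(n_position_bins):
        a, b = maps_l[:, k], maps_r[:, k]
        if np.any(np.isnan(a)) or np.any(np.isnan(b)) or a.std() == 0 or b.std() == 0:
            continue
        pv_r[k] = np.corrcoef(a, b)[0, 1]

    arm = (centers >= ARM_REWARD_U[0]) & (centers < ARM_REWARD_U[1])
    arm_r = np.full(binned.n_units, np.nan)
    for i in range(binned.n_units):
        a, b = maps_l[i, arm], maps_r[i, arm]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() >= 3 and a[ok].std() > 0 and b[ok].std() > 0:
            arm_r[i] = np.corrcoef(a[ok], b[ok])[0, 1]

    out = pd.DataFrame({"u": centers, "pv_r": pv_r})
    out.attrs["arm_r"] = arm_r
    return out
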