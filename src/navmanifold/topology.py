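"""Topological characterization of embedded manifolds.

Pipeline: density-filter the 3-D embedded point cloud (drop sparse
outliers), compute Vietoris-Rips persistence barcodes up to H2, and call a
hole robust when its lifetime exceeds the 99.9th percentile of a null
distribution built by circularly shifting every unit's spike train and
re-running the entire bin -> sqrt -> smooth -> embed -> filter ->
persistence pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._persistence import rips_persistence
from .embed import embed
from .session import BinnedActivity, SpikeTable, bin_activity, circular_shift_spikes


@dataclass
class PersistenceResult:
    bars: dict                     # q -> (m, 2) array of (birth, death)
    maxdim: int
    thresh: float | None = None
    null_threshold: dict = field(default_factory=dict)   # q -> lifetime threshold
    robust_counts: dict = field(default_factory=dict)    # q -> int
    n_points: int = 0

    def lifetimes(self, q: int) -> np.ndarray:
        b = self.bars.get(q, np.empty((0, 2)))
        return b[:, 1] - b[:, 0] if len(b) else np.empty(0)


def density_filter(points: np.ndarray) -> np.ndarray:
    """Drop points in sparse neighborhoods.

    The neighborhood radius is the 1st percentile of all pairwise
    distances; points whose neighbor count within that radius falls below
    the 20th percentile of the count distribution are excluded.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 10:
        raise ValueError("need >= 10 points")
    d = squareform(pdist(points))
    radius = np.percentile(d[np.triu_indices(len(points), k=1)], 1.0)
    counts = (d <= radius).sum(axis=1) - 1
    cutoff = np.percentile(counts, 20.0)
    keep = counts >= cutoff
    if not np.any(keep):
        raise ValueError("density filter removed all points")
    return points[keep]


def maxmin_subsample(points: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Greedy farthest-point (maxmin) landmark selection."""
    points = np.asarray(points, dtype=float)
    if n >= len(points):
        return points
    rng = np.random.default_rng(seed)
    idx = [int(rng.integers(len(points)))]
    mind = np.linalg.norm(points - points[idx[0]], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(mind))
        idx.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(points - points[nxt], axis=1))
    return points[np.sort(idx)]


def persistence_barcodes(
    points: np.ndarray,
    maxdim: int = 2,
    thresh: float | None = None,
    n_landmarks: int | None = None,
    seed: int = 0,
) -> PersistenceResult:
    """Vietoris-Rips barcodes of a (filtered) point cloud.

    ``n_landmarks`` optionally reduces the cloud by maxmin subsampling
    first, which keeps the simplex enumeration tractable at maxdim 2.
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise ValueError("empty point cloud")
    if n_landmarks is not None:
        points = maxmin_subsample(points, n_landmarks, seed=seed)
    bars = rips_persistence(points, maxdim=maxdim, thresh=thresh)
    return PersistenceResult(bars=bars, maxdim=maxdim, thresh=thresh, n_points=len(points))


def dominant_count(result: PersistenceResult, q: int, gap: float = 4.0) -> int:
    """Number of bars whose lifetime is within ``gap`` of the longest bar.

    Counts bars with lifetime >= max_lifetime / gap, i.e. the leading group
    separated from shorter (noise or fine-structure) bars.
    """
    lt = result.lifetimes(q)
    if len(lt) == 0:
        return 0
    return int(np.sum(lt >= lt.max() / gap))


@dataclass
class TopologyParams:
    bin_s: float = 0.512
    smooth_sigma_bins: float = 2.0
    d: int = 3
    n_neighbors: int = 20
    maxdim: int = 2
    n_landmarks: int = 64


def manifold_point_cloud(
    spikes: SpikeTable, interval: tuple[float, float], params: TopologyParams
) -> np.ndarray:
    """Spikes -> bins -> sqrt -> smooth -> Isomap -> density filter."""
    binned: BinnedActivity = bin_activity(
        spikes, interval, bin_s=params.bin_s, sqrt=True,
        smooth_sigma_bins=params.smooth_sigma_bins,
    )
    emb = embed(binned, method="isomap", d=params.d, n_neighbors=params.n_neighbors)
    return density_filter(emb.coords)


def robust_holes(
    spikes: SpikeTable,
    interval: tuple[float, float],
    params: TopologyParams | None = None,
    n_shuffle: int = 50,
    pct: float = 99.9,
    seed: int = 0,
    min_holes: int = 100,
) -> PersistenceResult:
    """Observed barcodes plus a spike-level circular-shift null.

    Each shuffle independently circularly shifts every unit's spike train
    by a uniform offset and re-runs the full pipeline; per-dimension null
    lifetimes are pooled across shuffles and the robustness threshold is
    their ``pct`` percentile.  The essential H0 component is always robust.
    """
    if n_shuffle < 2:
        raise ValueError("need at least 2 shuffles")
    params = params or TopologyParams()
    rng = np.random.default_rng(seed)

    cloud = manifold_point_cloud(spikes, interval, params)
    observed = persistence_barcodes(
        cloud, maxdim=params.maxdim, n_landmarks=params.n_landmarks, seed=seed
    )

    null: dict[int, list] = {q: [] for q in range(params.maxdim + 1)}
    for _ in range(n_shuffle):
        shuffled = circular_shift_spikes(spikes, interval, rng)
        sh_cloud = manifold_point_cloud(shuffled, interval, params)
        sh = persistence_barcodes(
            sh_cloud, maxdim=params.maxdim, n_landmarks=params.n_landmarks, seed=seed
        )
        for q in null:
            null[q].extend(sh.lifetimes(q).tolist())

    for q in range(params.maxdim + 1):
        pooled = np.asarray(null[q])
        if len(pooled) < min_holes:
            warnings.warn(
                f"null for H{q} pooled only {len(pooled)} holes (<{min_holes})",
                stacklevel=2,
            )
        thr = np.percentile(pooled, pct) if len(pooled) else np.inf
        observed.null_threshold[q] = float(thr)
        lt = observed.lifetimes(q)
        count = int(np.sum(lt > thr))
        if q == 0 and count == 0 and len(lt):
            count = 1  # the single essential component is always a real feature
        observed.robust_counts[q] = count
    return observed
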