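"""Isomap and PCA embeddings of binned population activity.

Isomap follows the classical recipe: a k-nearest-neighbor graph on the
point cloud (k = 20 by default), geodesic distances by shortest paths on
that graph, then classical metric scaling of the geodesic distance matrix
into d dimensions.  If the neighbor graph is disconnected, k is doubled
until it connects.  The eigen-sign ambiguity of classical scaling is fixed
by orienting every axis so its largest-magnitude coordinate is positive,
which makes embeddings reproducible; all downstream geometry metrics are
rotation-invariant anyway.

Joint embeddings place awake task bins (512 ms) and ripple event bins
(76.8 ms) in one space by embedding the concatenated rows and z-scoring
the coordinates per axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.sparse.linalg import eigsh
from sklearn.neighbors import kneighbors_graph

from .session import BinnedActivity


@dataclass
class Embedding:
    coords: np.ndarray           # n x d
    method: str                  # isomap | pca
    n_neighbors: int | None = None
    awake_mask: np.ndarray | None = None  # True for awake rows in joint embeddings
    zscored: bool = False

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    @property
    def awake_coords(self) -> np.ndarray:
        return self.coords[self.awake_mask] if self.awake_mask is not None else self.coords

    @property
    def event_coords(self) -> np.ndarray:
        if self.awake_mask is None:
            raise ValueError("not a joint embedding")
        return self.coords[~self.awake_mask]


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def isomap_coords(x: np.ndarray, d: int, n_neighbors: int = 20) -> np.ndarray:
    """Geodesic (shortest-path) classical scaling of a point cloud."""
    n = len(x)
    if d >= x.shape[1]:
        raise ValueError("embedding dimension must be below the ambient dimension")
    k = min(n_neighbors, n - 1)
    if k < 1:
        raise ValueError("need n_neighbors >= 1")
    while True:
        g = kneighbors_graph(x, n_neighbors=k, mode="distance")
        g.data[g.data == 0] = 1e-12  # duplicate points: keep the edge explicit
        g = g.maximum(g.T)
        n_comp, _ = connected_components(g, directed=False)
        if n_comp == 1:
            break
        k = min(2 * k, n - 1)
        warnings.warn(f"k-NN graph disconnected; doubled neighbors to k={k}", stacklevel=2)
        if k == n - 1:
            break
    geo = shortest_path(g, method="D", directed=False)
    g2 = geo**2
    b = -0.5 * (g2 - g2.mean(axis=0) - g2.mean(axis=1)[:, None] + g2.mean())
    v0 = np.full(n, 1.0 / np.sqrt(n))  # fixed start vector for determinism
    vals, vecs = eigsh(b, k=d, which="LA", tol=0, v0=v0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs * np.sqrt(np.clip(vals, 0, None))
    return _fix_signs(coords)


def pca_coords(x: np.ndarray, d: int) -> np.ndarray:
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    return _fix_signs(u[:, :d] * s[:d])


def embed(
    activity: BinnedActivity | np.ndarray,
    method: str = "isomap",
    d: int = 3,
    n_neighbors: int = 20,
) -> Embedding:
    """Embed a T x N activity matrix (or BinnedActivity) into d dimensions."""
    x = activity.rates if isinstance(activity, BinnedActivity) else np.asarray(activity, float)
    if method == "isomap":
        coords = isomap_coords(x, d, n_neighbors)
    elif method == "pca":
        coords = pca_coords(x, d)
    else:
        raise ValueError(f"unknown method {method!r}")
    return Embedding(coords=coords, method=method, n_neighbors=n_neighbors)


def joint_embed(
    awake: BinnedActivity,
    events: BinnedActivity,
    method: str = "isomap",
    d: int = 3,
    n_neighbors: int = 20,
) -> Embedding:
    """Embed awake and event bins in one space; coordinates are z-scored per axis."""
    if list(awake.unit_ids) != list(events.unit_ids):
        raise ValueError("awake and event matrices must share the same unit set")
    if awake.ledger.sqrt != events.ledger.sqrt:
        raise ValueError("awake and event matrices must share the sqrt transform")
    x = np.vstack([awake.rates, events.rates])
    emb = embed(x, method=method, d=d, n_neighbors=n_neighbors)
    coords = (emb.coords - emb.coords.mean(axis=0)) / emb.coords.std(axis=0)
    mask = np.zeros(len(x), dtype=bool)
    mask[: awake.n_bins] = True
    return Embedding(coords=coords, method=method, n_neighbors=n_neighbors,
                     awake_mask=mask, zscored=True)
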