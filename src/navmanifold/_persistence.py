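"""Vietoris-Rips persistent homology over Z/2 (components, rings, cavities).

Small, self-contained implementation of the standard boundary-matrix
reduction, sufficient for point clouds of up to a few hundred points at
maxdim 1 and ~100 points at maxdim 2:

* filtration threshold defaults to the enclosing radius
  min_i max_j d(i, j), beyond which the complex is a cone and all homology
  dies, so no bar is lost by truncating there (essential bars are capped
  at the threshold);
* H0 via Kruskal-style union-find on the sorted edges;
* H1/H2 via column reduction of the dimension-(q+1) boundary matrix with
  the twist (clearing) optimization, processing dimensions top-down;
* columns are stored as Python integers used as bitsets (XOR = Z/2 sum,
  highest set bit = pivot), which keeps the inner loop in C.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform


def enclosing_radius(dist: np.ndarray) -> float:
    """min over points of the max distance to any other point."""
    return float(np.min(np.max(dist, axis=1)))


def _sorted_edges(dist: np.ndarray, thresh: float):
    n = len(dist)
    iu, ju = np.triu_indices(n, k=1)
    d = dist[iu, ju]
    keep = d <= thresh
    iu, ju, d = iu[keep], ju[keep], d[keep]
    order = np.lexsort((ju, iu, d))
    return iu[order], ju[order], d[order]


def _triangles(dist: np.ndarray, thresh: float):
    """All i<j<k with diameter <= thresh, sorted by (diameter, lex)."""
    n = len(dist)
    adj = dist <= thresh
    np.fill_diagonal(adj, False)
    tri_i, tri_j, tri_k, tri_d = [], [], [], []
    idx = np.arange(n)
    for i in range(n - 2):
        nbr_i = np.flatnonzero(adj[i] & (idx > i))
        for a, j in enumerate(nbr_i):
            ks = nbr_i[a + 1:][adj[j, nbr_i[a + 1:]]]
            if len(ks) == 0:
                continue
            tri_i.append(np.full(len(ks), i))
            tri_j.append(np.full(len(ks), j))
            tri_k.append(ks)
            tri_d.append(np.maximum(dist[i, j], np.maximum(dist[i, ks], dist[j, ks])))
    if not tri_i:
        return (np.empty(0, int),) * 3 + (np.empty(0),)
    ti = np.concatenate(tri_i)
    tj = np.concatenate(tri_j)
    tk = np.concatenate(tri_k)
    td = np.concatenate(tri_d)
    order = np.lexsort((tk, tj, ti, td))
    return ti[order], tj[order], tk[order], td[order]


def _tetrahedra(dist: np.ndarray, thresh: float, tri):
    """Extend threshold triangles by common higher-index neighbors."""
    ti, tj, tk, _ = tri
    n = len(dist)
    adj = dist <= thresh
    np.fill_diagonal(adj, False)
    idx = np.arange(n)
    qi, qj, qk, ql, qd = [], [], [], [], []
    for i, j, k in zip(ti, tj, tk):
        ls = np.flatnonzero(adj[i] & adj[j] & adj[k] & (idx > k))
        if len(ls) == 0:
            continue
        qi.append(np.full(len(ls), i))
        qj.append(np.full(len(ls), j))
        qk.append(np.full(len(ls), k))
        ql.append(ls)
        d3 = np.maximum(dist[i, j], np.maximum(dist[i, k], dist[j, k]))
        qd.append(np.maximum(d3, np.maximum(dist[i, ls], np.maximum(dist[j, ls], dist[k, ls]))))
    if not qi:
        return (np.empty(0, int),) * 4 + (np.empty(0),)
    arrs = [np.concatenate(x) for x in (qi, qj, qk, ql, qd)]
    order = np.lexsort((arrs[3], arrs[2], arrs[1], arrs[0], arrs[4]))
    return tuple(a[order] for a in arrs)


def _reduce(columns: list[int], skip: np.ndarray | None = None) -> dict[int, int]:
    """Z/2 column reduction; returns pivot-row -> column-index map.

    ``columns`` are bitset integers over face indices (in filtration order).
    Columns listed in ``skip`` are cleared (known to reduce to zero).
    """
    pivots: dict[int, int] = {}
    for j, col in enumerate(columns):
        if skip is not None and skip[j]:
            continue
        while col:
            low = col.bit_length() - 1
            other = pivots.get(low)
            if other is None:
                pivots[low] = j
                columns[j] = col
                break
            col ^= columns[other]
        else:
            columns[j] = 0
    return pivots


def rips_persistence(
    points_or_dist: np.ndarray,
    maxdim: int = 2,
    thresh: float | None = None,
    metric_input: bool = False,
) -> dict[int, np.ndarray]:
    """Persistence diagrams {q: array of (birth, death)} for q = 0..maxdim.

    Essential classes (alive at the threshold) are reported with death
    equal to the threshold; with the default enclosing-radius threshold
    this is exact for H0's single surviving component and a no-loss cap
    for higher dimensions.  Zero-lifetime bars are omitted.
    """
    x = np.asarray(points_or_dist, dtype=float)
    if metric_input:
        dist = x if x.ndim == 2 else squareform(x)
    else:
        from scipy.spatial.distance import pdist

        dist = squareform(pdist(x))
    n = len(dist)
    if n == 0:
        raise ValueError("empty point cloud")
    if thresh is None:
        thresh = enclosing_radius(dist)

    ei, ej, ed = _sorted_edges(dist, thresh)

    # --- H0: union-find over sorted edges ---
    parent = np.arange(n)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    h0 = []
    edge_positive = np.zeros(len(ed), dtype=bool)  # edges that create a 1-cycle
    for m in range(len(ed)):
        ra, rb = find(ei[m]), find(ej[m])
        if ra == rb:
            edge_positive[m] = True
        else:
            parent[ra] = rb
            if ed[m] > 0:
                h0.append((0.0, ed[m]))
    n_comp = len({find(i) for i in range(n)})
    h0.extend([(0.0, thresh)] * n_comp)  # essential component(s), capped
    diagrams = {0: np.array(h0) if h0 else np.empty((0, 2))}
    if maxdim < 1:
        return diagrams

    tri = _triangles(dist, thresh)
    ti, tj, tk, td = tri
    edge_index = {(int(a), int(b)): m for m, (a, b) in enumerate(zip(ei, ej))}

    tri_cleared = np.zeros(len(td), dtype=bool)
    h2 = []
    if maxdim >= 2 and len(td):
        tet = _tetrahedra(dist, thresh, tri)
        qi, qj, qk, ql, qd = tet
        tri_index = {(int(a), int(b), int(c)): m for m, (a, b, c) in enumerate(zip(ti, tj, tk))}
        cols = []
        for a, b, c, e in zip(qi, qj, qk, ql):
            col = 0
            for face in ((a, b, c), (a, b, e), (a, c, e), (b, c, e)):
                col |= 1 << tri_index[tuple(int(v) for v in sorted(face))]
            cols.append(col)
        pivots = _reduce(cols)
        for low, j in pivots.items():
            birth, death = td[low], qd[j]
            if death > birth:
                h2.append((birth, death))
            tri_cleared[low] = True
    diagrams[2] = np.array(h2) if h2 else np.empty((0, 2))

    # --- H1 from the triangle boundary matrix, clearing ∂3 pivot rows ---
    h1 = []
    if len(td):
        cols = []
        for a, b, c in zip(ti, tj, tk):
            col = (
                (1 << edge_index[(int(a), int(b))])
                | (1 << edge_index[(int(a), int(c))])
                | (1 << edge_index[(int(b), int(c))])
            )
            cols.append(col)
        pivots = _reduce(cols, skip=tri_cleared)
        paired_edges = set()
        for low, j in pivots.items():
            paired_edges.add(low)
            birth, death = ed[low], td[j]
            if death > birth:
                h1.append((birth, death))
        # positive edges never killed by a triangle are essential 1-cycles
        for m in np.flatnonzero(edge_positive):
            if m not in paired_edges and thresh > ed[m]:
                h1.append((ed[m], thresh))
    diagrams[1] = np.array(h1) if h1 else np.empty((0, 2))
    if maxdim < 2:
        diagrams.pop(2)
    return diagrams
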