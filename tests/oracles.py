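"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: plain double loops and
a naive full boundary-matrix reduction.
"""

from __future__ import annotations

import numpy as np
from itertools import combinations


def brute_correlation_integral(points: np.ndarray, radii: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    n = len(points)
    out = np.zeros(len(radii))
    for k, r in enumerate(radii):
        count = 0
        for i in range(n):
            for j in range(i + 1, n):
                if np.sqrt(((points[i] - points[j]) ** 2).sum()) <= r:
                    count += 1
        out[k] = count / (n * (n - 1) / 2)
    return out


def brute_l1(p: np.ndarray, q: np.ndarray) -> float:
    total = 0.0
    for a, b in zip(p, q):
        total += abs(a - b)
    return total


def brute_concentration(ripple_pts: np.ndarray, center: np.ndarray, p: int = 3) -> float:
    vectors = []
    for x in ripple_pts:
        v = x - center
        nv = np.sqrt((v**2).sum())
        if nv > 0:
            vectors.append(v / nv)
    rbar = np.sqrt((np.sum(vectors, axis=0) ** 2).sum()) / len(vectors)
    return rbar * (p - rbar**2) / (1 - rbar**2)


def naive_rips_persistence(points: np.ndarray, maxdim: int = 2, thresh: float | None = None):
    """Textbook global boundary-matrix reduction (no clearing, no bitsets)."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    if thresh is None:
        thresh = min(d[i].max() for i in range(n))

    simplices = [((i,), 0.0) for i in range(n)]
    for q in range(1, maxdim + 2):
        for comb in combinations(range(n), q + 1):
            diam = max(d[a][b] for a, b in combinations(comb, 2))
            if diam <= thresh:
                simplices.append((comb, diam))
    simplices.sort(key=lambda s: (s[1], len(s[0]), s[0]))
    index = {s: i for i, (s, _) in enumerate(simplices)}

    columns = []
    for s, _ in simplices:
        if len(s) == 1:
            columns.append(set())
        else:
            columns.append({index[tuple(f)] for f in combinations(s, len(s) - 1)})

    low_map = {}
    pairs = {}
    for j in range(len(columns)):
        col = columns[j]
        while col:
            low = max(col)
            if low not in low_map:
                low_map[low] = j
                pairs[low] = j
                break
            col ^= columns[low_map[low]]
        columns[j] = col

    paired_as_death = set(pairs.values())
    diagrams = {q: [] for q in range(maxdim + 1)}
    for i, (s, birth) in enumerate(simplices):
        q = len(s) - 1
        if q > maxdim:
            continue
        if i in paired_as_death:
            continue
        if i in pairs:  # positive simplex paired with a death
            death = simplices[pairs[i]][1]
            if death > birth:
                diagrams[q].append((birth, death))
        elif not columns[i]:  # essential
            diagrams[q].append((birth, thresh))
    return {q: np.array(v) if v else np.empty((0, 2)) for q, v in diagrams.items()}
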