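"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive and self-contained: dense GF(2)
boundary matrices reduced column by column, full simplex enumeration,
union-find over raw (uncollapsed) series, and BFS component counting.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

INF = math.inf


def _dist_matrix(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def enumerate_vr_simplices(points: np.ndarray, max_scale: float):
    """All simplices of dims 0-2 with their filtration values, sorted."""
    n = len(points)
    d = _dist_matrix(points)
    simplices = [((i,), 0.0) for i in range(n)]
    for i, j in combinations(range(n), 2):
        if d[i, j] <= max_scale:
            simplices.append(((i, j), float(d[i, j])))
    for i, j, k in combinations(range(n), 3):
        m = max(d[i, j], d[i, k], d[j, k])
        if m <= max_scale:
            simplices.append(((i, j, k), float(m)))
    simplices.sort(key=lambda sf: (sf[1], len(sf[0]), sf[0]))
    return simplices


def brute_force_vr_pairs(points: np.ndarray, max_scale: float, top_dim: int = 2):
    """Persistence pairing by reducing the full dense GF(2) boundary matrix.

    Returns a sorted list of (dim, birth, death) with death possibly inf;
    zero-persistence pairs are dropped. Infinite bars are reported only in
    dimensions strictly below ``top_dim``.
    """
    simplices = enumerate_vr_simplices(points, max_scale)
    index = {v: i for i, (v, _) in enumerate(simplices)}
    m = len(simplices)
    B = np.zeros((m, m), dtype=bool)
    for j, (verts, _) in enumerate(simplices):
        if len(verts) > 1:
            for face in combinations(verts, len(verts) - 1):
                B[index[face], j] = True

    low_owner: dict[int, int] = {}
    for j in range(m):
        while True:
            rows = np.nonzero(B[:, j])[0]
            if rows.size == 0:
                break
            low = int(rows.max())
            if low in low_owner:
                B[:, j] ^= B[:, low_owner[low]]
            else:
                low_owner[low] = j
                break

    destroyer = {creator: col for creator, col in low_owner.items()}
    pairs = []
    for i, (verts, birth) in enumerate(simplices):
        if B[:, i].any():
            continue  # negative column: i is a destroyer
        dim = len(verts) - 1
        if i in destroyer:
            death = simplices[destroyer[i]][1]
            if death > birth:
                pairs.append((dim, birth, death))
        elif dim < top_dim:
            pairs.append((dim, birth, INF))
    return sorted(pairs)


def gf2_rank(mat: np.ndarray) -> int:
    a = mat.astype(bool).copy()
    rank = 0
    rows, cols = a.shape
    for c in range(cols):
        pivots = np.nonzero(a[rank:, c])[0]
        if pivots.size == 0:
            continue
        p = rank + int(pivots[0])
        a[[rank, p]] = a[[p, rank]]
        hits = np.nonzero(a[:, c])[0]
        for r in hits:
            if r != rank:
                a[r] ^= a[rank]
        rank += 1
        if rank == rows:
            break
    return rank


def betti_numbers_at_scale(points: np.ndarray, scale: float) -> tuple[int, int]:
    """(beta0, beta1) of the VR complex (dims <= 2) at a fixed scale, via
    GF(2) boundary ranks: beta_p = dim C_p - rank d_p - rank d_{p+1}."""
    simplices = enumerate_vr_simplices(points, scale)
    by_dim = {0: [], 1: [], 2: []}
    for verts, _ in simplices:
        by_dim[len(verts) - 1].append(verts)
    idx0 = {v: i for i, v in enumerate(by_dim[0])}
    idx1 = {v: i for i, v in enumerate(by_dim[1])}

    d1 = np.zeros((len(by_dim[0]), len(by_dim[1])), dtype=bool)
    for j, e in enumerate(by_dim[1]):
        for face in combinations(e, 1):
            d1[idx0[face], j] = True
    d2 = np.zeros((len(by_dim[1]), len(by_dim[2])), dtype=bool)
    for j, t in enumerate(by_dim[2]):
        for face in combinations(t, 2):
            d2[idx1[face], j] = True

    r1 = gf2_rank(d1) if d1.size else 0
    r2 = gf2_rank(d2) if d2.size else 0
    beta0 = len(by_dim[0]) - r1
    beta1 = len(by_dim[1]) - r1 - r2
    return beta0, beta1


def kruskal_mst_weights(points: np.ndarray) -> list[float]:
    """Edge weights of the Euclidean MST via textbook Kruskal."""
    n = len(points)
    d = _dist_matrix(points)
    edges = sorted(
        ((float(d[i, j]), i, j) for i, j in combinations(range(n), 2))
    )
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    weights = []
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            weights.append(w)
    return sorted(weights)


def brute_force_sls_pairs(series: np.ndarray):
    """0-dim sublevel persistence by union-find over the raw series, nodes
    processed in (value, index) order; zero-persistence pairs dropped."""
    x = np.asarray(series, dtype=float)
    n = x.size
    order = sorted(range(n), key=lambda i: (x[i], i))
    parent = list(range(n))
    birth = [(0.0, 0)] * n
    active = [False] * n

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pairs = []
    for i in order:
        active[i] = True
        birth[i] = (float(x[i]), i)
        for nb in (i - 1, i + 1):
            if 0 <= nb < n and active[nb]:
                ri, rn = find(i), find(nb)
                if ri == rn:
                    continue
                elder, younger = (ri, rn) if birth[ri] <= birth[rn] else (rn, ri)
                if birth[younger][0] < x[i]:
                    pairs.append((0, birth[younger][0], float(x[i])))
                parent[younger] = elder
    root = find(order[0])
    pairs.append((0, birth[root][0], INF))
    return sorted(pairs)


def sublevel_component_count(series: np.ndarray, level: float) -> int:
    """Number of runs of consecutive samples with value <= level."""
    included = np.asarray(series) <= level
    return int(np.sum(included[1:] & ~included[:-1]) + included[0])
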