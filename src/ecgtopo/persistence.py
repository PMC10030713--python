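"""Persistent homology of point clouds and scalar time series.

Two filtrations are supported:

* The Vietoris-Rips filtration of a Euclidean point cloud, up to simplex
  dimension 2, yielding H0 and H1 persistence pairs. Filtration values are
  pairwise *distances* (edge diameters): an edge enters when the distance
  between its endpoints is reached, a triangle at its longest edge. Any
  ball-radius reading of the scale parameter is distance/2.
* The sublevel-set filtration of a piecewise-linear time series, yielding
  0-dimensional pairs: components are born at local minima and die when two
  components merge at a local maximum. The elder rule applies — at a merge
  the component with the higher (younger) birth dies; the global minimum's
  component never dies, so exactly one bar is infinite.

Pairing is computed over the two-element field by standard boundary-matrix
column reduction; H0 of a cloud additionally has a fast path through the
minimum spanning tree, whose edge weights are exactly the finite H0 deaths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist

from ecgtopo.embedding import PointCloud

__all__ = [
    "Filtration",
    "PersistencePair",
    "PersistenceDiagram",
    "FiltrationOrderError",
    "build_vr_filtration",
    "reduce_boundary_matrix",
    "vr_persistence",
    "h0_via_mst",
    "sls_persistence",
    "default_max_scale",
]

INF = math.inf


class FiltrationOrderError(ValueError):
    """A simplex precedes one of its faces in the filtration order."""


@dataclass(frozen=True, order=True)
class PersistencePair:
    """One birth-death interval of a homology class.

    ``death`` may be ``math.inf`` for classes alive at the end of the
    filtration. Zero-persistence pairs (birth == death) are produced by the
    reduction but excluded from diagrams.
    """

    dim: int
    birth: float
    death: float

    def __post_init__(self) -> None:
        if self.death < self.birth:
            raise ValueError(f"death {self.death} precedes birth {self.birth}")

    @property
    def persistence(self) -> float:
        return self.death - self.birth

    @property
    def is_zero(self) -> bool:
        return self.death == self.birth

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.death)


@dataclass
class Filtration:
    """Simplices with filtration values, sorted by (value, dim, vertices).

    Every face of a simplex must appear no later than the simplex itself and
    at a value no greater than the simplex's value.
    """

    simplices: list[tuple[tuple[int, ...], float]]
    max_scale: float = INF
    #: intended top simplex dimension; bars are reported strictly below it
    #: (unpaired creators of the top dimension are truncation artifacts).
    #: None -> inferred from the largest simplex present.
    max_dim: Optional[int] = None

    def __post_init__(self) -> None:
        self.simplices = sorted(
            ((tuple(sorted(v)), float(f)) for v, f in self.simplices),
            key=lambda sf: (sf[1], len(sf[0]), sf[0]),
        )

    def validate(self) -> None:
        index = {verts: i for i, (verts, _) in enumerate(self.simplices)}
        for i, (verts, value) in enumerate(self.simplices):
            if len(verts) == 1:
                continue
            for face in combinations(verts, len(verts) - 1):
                j = index.get(face)
                if j is None or j > i or self.simplices[j][1] > value:
                    raise FiltrationOrderError(
                        f"face {face} of simplex {verts} violates the order"
                    )

    def __len__(self) -> int:
        return len(self.simplices)


@dataclass
class PersistenceDiagram:
    """Birth-death pairs plus provenance; convertible to barcode form.

    The Betti number at scale s in dimension p is the number of pairs with
    dim == p and birth <= s < death.
    """

    pairs: list[PersistencePair]
    source: str = ""  # "vr" | "sls"
    params: dict = field(default_factory=dict)

    def in_dim(self, p: int) -> list[PersistencePair]:
        return [pr for pr in self.pairs if pr.dim == p]

    def betti(self, scale: float, p: int) -> int:
        return sum(
            1 for pr in self.pairs if pr.dim == p and pr.birth <= scale < pr.death
        )

    def max_finite(self) -> float:
        vals = [pr.death for pr in self.pairs if not pr.is_infinite]
        vals += [pr.birth for pr in self.pairs if math.isfinite(pr.birth)]
        return max(vals, default=0.0)

    def to_csv(self, path: str | Path) -> None:
        lines = ["dim,birth,death"]
        for pr in sorted(self.pairs):
            death = "inf" if pr.is_infinite else repr(pr.death)
            lines.append(f"{pr.dim},{pr.birth!r},{death}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path, source: str = "") -> "PersistenceDiagram":
        lines = Path(path).read_text().strip().splitlines()[1:]
        pairs = []
        for ln in lines:
            d, b, de = ln.split(",")
            pairs.append(
                PersistencePair(int(d), float(b), INF if de == "inf" else float(de))
            )
        return cls(pairs=pairs, source=source)


# ---------------------------------------------------------------------------
# Vietoris-Rips
# ---------------------------------------------------------------------------


def default_max_scale(dist: np.ndarray, n_points: int) -> float:
    """Cloud diameter for small clouds, 90th distance percentile above 200
    points (triangle enumeration is cubic; large clouds need a cap)."""
    if dist.size == 0:
        return 0.0
    if n_points <= 200:
        return float(dist.max())
    return float(np.percentile(dist, 90.0))


def build_vr_filtration(
    cloud: PointCloud,
    max_scale: Optional[float] = None,
    max_dim: int = 2,
) -> Filtration:
    """Vietoris-Rips filtration of a cloud up to simplex dimension 2.

    All vertices enter at 0; an edge enters at the distance between its
    endpoints when that distance is <= max_scale; a triangle enters once all
    three edges are present, at its longest edge's value.
    """
    if cloud.n_points == 0:
        raise ValueError("cloud must be nonempty")
    if max_dim not in (1, 2):
        raise ValueError("max_dim must be 1 or 2")
    condensed = pdist(cloud.points) if cloud.n_points > 1 else np.empty(0)
    if max_scale is None:
        max_scale = default_max_scale(condensed, cloud.n_points)
    if max_scale < 0:
        raise ValueError("max_scale must be nonnegative")
    dmat = squareform(condensed) if cloud.n_points > 1 else np.zeros((1, 1))

    n = cloud.n_points
    simplices: list[tuple[tuple[int, ...], float]] = [((i,), 0.0) for i in range(n)]
    adj = dmat <= max_scale
    np.fill_diagonal(adj, False)
    ii, jj = np.nonzero(np.triu(adj))
    for i, j in zip(ii.tolist(), jj.tolist()):
        simplices.append(((i, j), float(dmat[i, j])))
    if max_dim >= 2:
        neighbors = [np.nonzero(adj[i])[0] for i in range(n)]
        for i, j in zip(ii.tolist(), jj.tolist()):
            common = np.intersect1d(neighbors[i], neighbors[j], assume_unique=True)
            for k in common[common > j].tolist():
                value = max(dmat[i, j], dmat[i, k], dmat[j, k])
                simplices.append(((i, j, k), float(value)))
    return Filtration(simplices=simplices, max_scale=float(max_scale), max_dim=max_dim)


def reduce_boundary_matrix(filtration: Filtration) -> list[PersistencePair]:
    """Standard persistence pairing by column reduction over GF(2).

    Returns pairs for every homology dimension present (zero-persistence
    pairs included; callers filter). Unpaired creators become infinite bars.
    Raises :class:`FiltrationOrderError` on a face-ordering violation.
    """
    filtration.validate()
    simplices = filtration.simplices
    if not simplices:
        return []
    index = {verts: i for i, (verts, _) in enumerate(simplices)}
    m = len(simplices)

    columns: list[Optional[set[int]]] = []
    for verts, _ in simplices:
        if len(verts) == 1:
            columns.append(set())
        else:
            columns.append(
                {index[f] for f in combinations(verts, len(verts) - 1)}
            )

    pivot_of: dict[int, int] = {}  # low row -> column that owns it
    destroyed_by: dict[int, int] = {}  # creator index -> destroyer index
    for j in range(m):
        col = columns[j]
        while col:
            low = max(col)
            owner = pivot_of.get(low)
            if owner is None:
                break
            col ^= columns[owner]
        if col:
            low = max(col)
            pivot_of[low] = j
            destroyed_by[low] = j
        columns[j] = col

    top = (
        filtration.max_dim
        if filtration.max_dim is not None
        else max(len(v) for v, _ in simplices) - 1
    )
    max_bar_dim = max(top - 1, 0)
    pairs: list[PersistencePair] = []
    for i, (verts, birth) in enumerate(simplices):
        if columns[i]:  # negative column: i destroys, never creates
            continue
        dim = len(verts) - 1
        j = destroyed_by.get(i)
        if j is not None:
            pairs.append(PersistencePair(dim, birth, simplices[j][1]))
        elif dim <= max_bar_dim:
            pairs.append(PersistencePair(dim, birth, INF))
    return sorted(pairs)


def h0_via_mst(cloud: PointCloud) -> list[PersistencePair]:
    """H0 persistence of a cloud via the Euclidean minimum spanning tree.

    All n bars are born at 0; the n-1 finite deaths are exactly the MST edge
    weights, plus one infinite bar for the surviving component.
    """
    n = cloud.n_points
    if n == 0:
        raise ValueError("cloud must be nonempty")
    if n == 1:
        return [PersistencePair(0, 0.0, INF)]
    dmat = squareform(pdist(cloud.points))
    # csgraph treats zeros as absent edges; nudge exact duplicates onto a
    # representable positive weight (sparse input — the dense path drops
    # subnormal weights) and map back to 0 afterwards.
    tiny = np.finfo(float).tiny
    graph = csr_matrix(np.where(dmat == 0, tiny, dmat) - np.diag(np.full(n, tiny)))
    mst = minimum_spanning_tree(graph)
    weights = np.asarray(mst[mst.nonzero()]).ravel()
    weights = np.where(weights <= tiny, 0.0, weights)
    pairs = [PersistencePair(0, 0.0, float(w)) for w in np.sort(weights)]
    pairs.append(PersistencePair(0, 0.0, INF))
    return pairs


def vr_persistence(
    cloud: PointCloud,
    max_scale: Optional[float] = None,
    max_homology_dim: int = 1,
) -> PersistenceDiagram:
    """H0 and H1 persistence of the Vietoris-Rips filtration of a cloud.

    H0 uses the minimum-spanning-tree fast path (deaths beyond ``max_scale``
    become infinite bars, since those merges never happen inside the
    filtration); H1 pairs come from boundary-matrix reduction. Zero
    persistence pairs are dropped from the diagram.
    """
    if max_homology_dim not in (0, 1):
        raise ValueError("max_homology_dim must be 0 or 1")
    condensed = pdist(cloud.points) if cloud.n_points > 1 else np.empty(0)
    if max_scale is None:
        max_scale = default_max_scale(condensed, cloud.n_points)

    h0 = [
        p if p.death <= max_scale else PersistencePair(0, p.birth, INF)
        for p in h0_via_mst(cloud)
    ]
    pairs = [p for p in h0 if not p.is_zero]
    if max_homology_dim >= 1:
        filt = build_vr_filtration(cloud, max_scale=max_scale, max_dim=2)
        pairs += [
            p
            for p in reduce_boundary_matrix(filt)
            if p.dim == 1 and not p.is_zero
        ]
    return PersistenceDiagram(
        pairs=sorted(pairs),
        source="vr",
        params={
            "max_scale": float(max_scale),
            "n_points": cloud.n_points,
            "dimension": cloud.dimension,
            "record_id": cloud.record_id,
        },
    )


# ---------------------------------------------------------------------------
# Sublevel-set filtration of a time series
# ---------------------------------------------------------------------------


def sls_persistence(series: Sequence[float] | np.ndarray) -> PersistenceDiagram:
    """0-dimensional sublevel-set persistence of a piecewise-linear series.

    Sweeping the level upward, a component is born at each local minimum and
    the younger of two components merging at a local maximum dies there
    (elder rule). Boundary samples count as minima iff smaller than their
    single neighbour; plateaus are collapsed to a single node first, and
    ties between distinct minima at one level are broken leftmost-is-elder.
    The global minimum's bar never dies.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("series must be nonempty")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")

    # collapse plateaus of equal consecutive values to one node
    keep = np.ones(x.size, dtype=bool)
    keep[1:] = x[1:] != x[:-1]
    v = x[keep]
    m = v.size
    if m == 1:
        return PersistenceDiagram(
            pairs=[PersistencePair(0, float(v[0]), INF)], source="sls"
        )

    order = sorted(range(m), key=lambda i: (v[i], i))
    parent = list(range(m))
    birth_value = [0.0] * m
    birth_index = [0] * m
    active = [False] * m

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pairs: list[PersistencePair] = []
    for i in order:
        active[i] = True
        birth_value[i] = float(v[i])
        birth_index[i] = i
        for nb in (i - 1, i + 1):
            if 0 <= nb < m and active[nb]:
                ri, rn = find(i), find(nb)
                if ri == rn:
                    continue
                # elder: lower birth value, ties to the leftmost minimum
                elder, younger = (
                    (ri, rn)
                    if (birth_value[ri], birth_index[ri])
                    <= (birth_value[rn], birth_index[rn])
                    else (rn, ri)
                )
                if birth_value[younger] < v[i]:
                    pairs.append(
                        PersistencePair(0, birth_value[younger], float(v[i]))
                    )
                parent[younger] = elder
    root = find(order[0])
    pairs.append(PersistencePair(0, birth_value[root], INF))
    return PersistenceDiagram(pairs=sorted(pairs), source="sls", params={"n": int(x.size)})
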