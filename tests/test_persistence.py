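import math

import numpy as np
import pytest

from ecgtopo.embedding import PointCloud
from ecgtopo.persistence import (
    Filtration,
    FiltrationOrderError,
    PersistenceDiagram,
    PersistencePair,
    build_vr_filtration,
    h0_via_mst,
    reduce_boundary_matrix,
    sls_persistence,
    vr_persistence,
)

from conftest import random_cloud
from oracles import (
    brute_force_sls_pairs,
    brute_force_vr_pairs,
    betti_numbers_at_scale,
    kruskal_mst_weights,
    sublevel_component_count,
)

INF = math.inf


def as_tuples(pairs):
    return sorted((p.dim, p.birth, p.death) for p in pairs if not p.is_zero)


class TestBuildVRFiltration:
    def test_collinear_points_scale_one(self):
        cloud = PointCloud(np.array([[0.0], [1.0], [2.0]]))
        filt = build_vr_filtration(cloud, max_scale=1.0)
        edges = [v for v, _ in filt.simplices if len(v) == 2]
        triangles = [v for v, _ in filt.simplices if len(v) == 3]
        assert edges == [(0, 1), (1, 2)]
        assert triangles == []

    def test_unit_square_full_scale(self, unit_square_cloud):
        filt = build_vr_filtration(unit_square_cloud, max_scale=math.sqrt(2))
        by_dim = {d: sum(1 for v, _ in filt.simplices if len(v) == d + 1) for d in range(3)}
        assert by_dim == {0: 4, 1: 6, 2: 4}

    def test_scale_zero_vertices_only(self, unit_square_cloud):
        filt = build_vr_filtration(unit_square_cloud, max_scale=0.0)
        assert all(len(v) == 1 for v, _ in filt.simplices)

    def test_triangle_value_is_longest_edge(self, rng):
        cloud = random_cloud(rng, max_points=6)
        filt = build_vr_filtration(cloud)
        values = {v: f for v, f in filt.simplices}
        for verts, f in filt.simplices:
            if len(verts) == 3:
                i, j, k = verts
                assert f == max(values[(i, j)], values[(i, k)], values[(j, k)])

    def test_ordering_invariant(self, rng):
        filt = build_vr_filtration(random_cloud(rng))
        filt.validate()
        values = [f for _, f in filt.simplices]
        assert values == sorted(values)

    def test_matches_oracle_enumeration(self, rng):
        from oracles import enumerate_vr_simplices

        cloud = random_cloud(rng)
        filt = build_vr_filtration(cloud, max_scale=1.2)
        assert filt.simplices == enumerate_vr_simplices(cloud.points, 1.2)


class TestReduceBoundaryMatrix:
    def test_empty_filtration(self):
        assert reduce_boundary_matrix(Filtration(simplices=[])) == []

    def test_filled_triangle_hand_reduction(self):
        filt = Filtration(
            simplices=[
                ((0,), 0.0), ((1,), 0.0), ((2,), 0.0),
                ((0, 1), 1.0), ((0, 2), 1.0), ((1, 2), 1.0),
                ((0, 1, 2), 1.0),
            ]
        )
        pairs = reduce_boundary_matrix(filt)
        h0 = [p for p in pairs if p.dim == 0]
        h1 = [p for p in pairs if p.dim == 1]
        assert sorted((p.birth, p.death) for p in h0) == [(0.0, 1.0), (0.0, 1.0), (0.0, INF)]
        assert [(p.birth, p.death) for p in h1] == [(1.0, 1.0)]  # zero-persistence, flagged
        assert h1[0].is_zero

    def test_face_ordering_violation_raises(self):
        filt = Filtration(simplices=[((0,), 0.0), ((1,), 0.0), ((0, 1), 1.0)])
        filt.simplices[2], filt.simplices[0] = filt.simplices[0], filt.simplices[2]
        with pytest.raises(FiltrationOrderError):
            reduce_boundary_matrix(filt)

    def test_oracle_equivalence_on_random_clouds(self, rng):
        for _ in range(60):
            cloud = random_cloud(rng)
            scale = float(rng.uniform(0.3, 2.5))
            filt = build_vr_filtration(cloud, max_scale=scale)
            got = as_tuples(reduce_boundary_matrix(filt))
            expected = brute_force_vr_pairs(cloud.points, scale)
            assert got == pytest.approx(expected)


class TestH0ViaMST:
    def test_single_point(self):
        pairs = h0_via_mst(PointCloud(np.zeros((1, 2))))
        assert as_tuples(pairs) == [(0, 0.0, INF)]

    def test_three_points_on_a_line(self):
        cloud = PointCloud(np.array([[0.0], [1.0], [3.0]]))
        finite = sorted(p.death for p in h0_via_mst(cloud) if not p.is_infinite)
        assert finite == [1.0, 2.0]

    def test_matches_kruskal_weights(self, rng):
        for _ in range(40):
            cloud = random_cloud(rng)
            finite = sorted(p.death for p in h0_via_mst(cloud) if not p.is_infinite)
            assert finite == pytest.approx(kruskal_mst_weights(cloud.points))

    def test_matches_reduction_h0(self, rng):
        for _ in range(30):
            cloud = random_cloud(rng)
            filt = build_vr_filtration(cloud)  # full diameter
            via_reduction = [
                (p.birth, p.death)
                for p in reduce_boundary_matrix(filt)
                if p.dim == 0
            ]
            via_mst = [(p.birth, p.death) for p in h0_via_mst(cloud)]
            assert sorted(via_mst) == pytest.approx(sorted(via_reduction))

    def test_duplicate_points_give_zero_persistence_bars(self):
        cloud = PointCloud(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]]))
        pairs = h0_via_mst(cloud)
        assert sorted(p.death for p in pairs) == [0.0, 1.0, INF]


class TestVRPersistence:
    def test_isolated_points_alive_at_scale_zero(self, rng):
        cloud = PointCloud(rng.uniform(0, 10, size=(10, 2)))
        diagram = vr_persistence(cloud)
        assert diagram.betti(0.0, 0) == 10

    def test_unit_square_h1_bar(self, unit_square_cloud):
        diagram = vr_persistence(unit_square_cloud, max_scale=math.sqrt(2))
        assert as_tuples(diagram.in_dim(1)) == pytest.approx(
            [(1, 1.0, math.sqrt(2))]
        )

    def test_exactly_one_infinite_h0_bar(self, rng):
        for _ in range(20):
            cloud = random_cloud(rng)
            diagram = vr_persistence(cloud)  # default scale covers the diameter
            assert sum(1 for p in diagram.in_dim(0) if p.is_infinite) == 1

    def test_truncated_scale_leaves_multiple_infinite_bars(self):
        cloud = PointCloud(np.array([[0.0], [0.1], [5.0], [5.1]]))
        diagram = vr_persistence(cloud, max_scale=1.0)
        assert sum(1 for p in diagram.in_dim(0) if p.is_infinite) == 2

    def test_square_below_diagonal_scale_has_infinite_h1(self, unit_square_cloud):
        diagram = vr_persistence(unit_square_cloud, max_scale=1.0)
        assert as_tuples(diagram.in_dim(1)) == [(1, 1.0, INF)]

    def test_betti_step_function_matches_brute_force(self, rng):
        for _ in range(12):
            cloud = random_cloud(rng, max_points=7)
            diagram = vr_persistence(cloud)
            from scipy.spatial.distance import pdist

            scales = np.unique(pdist(cloud.points))
            for s in list(scales) + [0.0]:
                b0, b1 = betti_numbers_at_scale(cloud.points, s)
                assert diagram.betti(s, 0) == b0
                assert diagram.betti(s, 1) == b1

    def test_homogeneity_under_coordinate_scaling(self, rng):
        cloud = random_cloud(rng)
        a = 3.7
        scaled = PointCloud(cloud.points * a)
        d1 = as_tuples(vr_persistence(cloud).pairs)
        d2 = as_tuples(vr_persistence(scaled).pairs)
        assert len(d1) == len(d2)
        for (dim1, b1, de1), (dim2, b2, de2) in zip(d1, d2):
            assert dim1 == dim2
            assert b2 == pytest.approx(a * b1)
            assert de2 == pytest.approx(a * de1) if math.isfinite(de1) else math.isinf(de2)

    def test_circle_has_one_dominant_h1_loop(self):
        theta = np.linspace(0, 2 * np.pi, 13)[:-1]  # 12 points on a circle
        cloud = PointCloud(np.column_stack([np.cos(theta), np.sin(theta)]))
        h1 = sorted(vr_persistence(cloud).in_dim(1), key=lambda p: -p.persistence)
        assert h1, "expected at least one loop"
        dominant, rest = h1[0], h1[1:]
        finite_dom = min(dominant.death, 2.0) - dominant.birth
        assert all(finite_dom > 10 * p.persistence for p in rest)


class TestSLSPersistence:
    def test_hand_fixture(self):
        diagram = sls_persistence([2, 0, 1, -1, 3])
        assert as_tuples(diagram.pairs) == [(0, -1.0, INF), (0, 0.0, 1.0)]

    def test_strictly_increasing_series(self):
        diagram = sls_persistence([1.0, 2.0, 5.0])
        assert as_tuples(diagram.pairs) == [(0, 1.0, INF)]

    def test_exactly_one_infinite_bar(self, rng):
        for _ in range(50):
            x = rng.standard_normal(int(rng.integers(1, 60)))
            bars = sls_persistence(x).pairs
            assert sum(1 for p in bars if p.is_infinite) == 1

    def test_infinite_bar_born_at_global_min(self, rng):
        x = rng.standard_normal(40)
        (inf_bar,) = [p for p in sls_persistence(x).pairs if p.is_infinite]
        assert inf_bar.birth == x.min()

    def test_duality_negated_series(self, rng):
        x = rng.standard_normal(40)
        (inf_bar,) = [p for p in sls_persistence(-x).pairs if p.is_infinite]
        assert inf_bar.birth == -x.max()

    def test_matches_union_find_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 51))
            x = rng.standard_normal(n)
            if rng.uniform() < 0.3:  # exercise plateaus and ties
                x = np.round(x * 2) / 2
            got = as_tuples(sls_persistence(x).pairs)
            expected = sorted(
                (d, b, de) for d, b, de in brute_force_sls_pairs(x) if de > b
            )
            assert got == pytest.approx(expected)

    def test_finite_pair_count_equals_extra_minima(self, rng):
        for _ in range(50):
            x = rng.standard_normal(int(rng.integers(2, 50)))
            v = x[np.r_[True, x[1:] != x[:-1]]]  # collapse plateaus
            inner = np.sum((v[1:-1] < v[:-2]) & (v[1:-1] < v[2:]))
            boundary = int(v.size > 1 and v[0] < v[1]) + int(
                v.size > 1 and v[-1] < v[-2]
            )
            n_minima = int(inner) + boundary if v.size > 1 else 1
            finite = [p for p in sls_persistence(x).pairs if not p.is_infinite]
            assert len(finite) == n_minima - 1

    def test_betti_matches_component_count(self, rng):
        for _ in range(30):
            x = rng.standard_normal(30)
            diagram = sls_persistence(x)
            for level in x:
                assert diagram.betti(level, 0) == sublevel_component_count(x, level)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            sls_persistence([])


class TestDiagramType:
    def test_pair_validation(self):
        with pytest.raises(ValueError):
            PersistencePair(0, 2.0, 1.0)

    def test_csv_round_trip(self, tmp_path):
        diagram = PersistenceDiagram(
            pairs=[PersistencePair(0, 0.0, INF), PersistencePair(1, 0.5, 1.25)],
            source="vr",
        )
        path = tmp_path / "d.csv"
        diagram.to_csv(path)
        back = PersistenceDiagram.from_csv(path, source="vr")
        assert back.pairs == sorted(diagram.pairs)
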