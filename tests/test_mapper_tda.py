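"""Mapper core: distances, lenses, covers, clustering, nerve, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from leaftda.errors import DegenerateRangeError, GeometryError, StateError
from leaftda.landmark_io import assign_relative_node
from leaftda.mapper_tda import (
    Cover,
    DistanceMatrix,
    LensAssignment,
    MapperGraph,
    MapperVertex,
    build_cover,
    build_mapper,
    cluster_preimage,
    correlation_distance,
    graph_diagnostics,
    lens_from_heteroblasty,
    lens_from_pc1,
    nerve_oracle,
    pairwise_distances,
)
from leaftda.shape_align import ShapeVector

from .conftest import make_dataset, make_leaf


def sv(values, leaf_id="v"):
    return ShapeVector(leaf_id, np.asarray(values, float))


def pearson_textbook(u, v):
    u, v = np.asarray(u, float), np.asarray(v, float)
    num = ((u - u.mean()) * (v - v.mean())).sum()
    den = np.sqrt(((u - u.mean()) ** 2).sum() * ((v - v.mean()) ** 2).sum())
    return num / den


class TestCorrelationDistance:
    def test_self_distance_zero(self):
        assert correlation_distance(sv([1, 2, 3, 4]), sv([1, 2, 3, 4])) <= 1e-12

    def test_anticorrelated_is_two(self):
        assert correlation_distance(sv([1, 2, 3, 4]), sv([4, 3, 2, 1])) == pytest.approx(2.0)

    def test_matches_textbook_formula(self):
        u, v = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])
        expected = 1.0 - pearson_textbook(u, v)
        assert correlation_distance(u, v) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(GeometryError):
            correlation_distance(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=20),
        st.floats(0.01, 50),
        st.floats(-100, 100),
    )
    def test_affine_invariance(self, values, a, b):
        u = np.asarray(values)
        if np.std(u) < 1e-6:
            return
        assert correlation_distance(u, a * u + b) <= 1e-10

    @given(st.integers(0, 1000))
    def test_bounds_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        u, v = rng.normal(size=8), rng.normal(size=8)
        d1 = correlation_distance(sv(u), sv(v))
        d2 = correlation_distance(sv(v), sv(u))
        assert 0.0 <= d1 <= 2.0
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestPairwiseDistances:
    def test_identical_vectors(self):
        d = pairwise_distances([sv([1, 2, 3, 4], "a"), sv([1, 2, 3, 4], "b")])
        np.testing.assert_array_equal(d.d, np.zeros((2, 2)))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(42)
        vecs = [sv(rng.normal(size=10), f"L{i}") for i in range(5)]
        dmat = pairwise_distances(vecs)
        for i in range(5):
            for j in range(5):
                expected = (
                    0.0
                    if i == j
                    else 1.0 - pearson_textbook(vecs[i].values, vecs[j].values)
                )
                assert dmat.d[i, j] == pytest.approx(expected, abs=1e-10)

    def test_symmetry_exact(self):
        rng = np.random.default_rng(1)
        vecs = [sv(rng.normal(size=6), f"L{i}") for i in range(7)]
        dmat = pairwise_distances(vecs)
        np.testing.assert_array_equal(dmat.d, dmat.d.T)

    def test_constant_vector_named_in_error(self):
        vecs = [sv([1, 2, 3, 4], "ok"), sv([5, 5, 5, 5], "flat")]
        with pytest.raises(GeometryError, match="flat"):
            pairwise_distances(vecs)


class TestLenses:
    def test_heteroblasty_lens_values(self, two_vine_dataset):
        ds = assign_relative_node(two_vine_dataset)
        lens = lens_from_heteroblasty(ds)
        assert lens.lens_name == "heteroblasty"
        mapping = lens.as_mapping()
        for leaf in ds:
            assert mapping[leaf.leaf_id] == leaf.relative_node
        # tip leaf -> 0, base leaf -> 1
        assert mapping["a1"] == 0.0 and mapping["a5"] == 1.0

    def test_heteroblasty_lens_requires_assignment(self, two_vine_dataset):
        with pytest.raises(StateError):
            lens_from_heteroblasty(two_vine_dataset)

    def test_pc1_lens_affine_along_a_line(self):
        t = np.linspace(0, 1, 6)
        direction = np.array([2.0, -1.0, 0.5, 1.0])
        vecs = [sv(3.0 + ti * direction, f"L{i}") for i, ti in enumerate(t)]
        lens = lens_from_pc1(vecs)
        # scores affine in t: second differences vanish
        second = np.diff(lens.values, 2)
        np.testing.assert_allclose(second, 0.0, atol=1e-8)

    def test_pc1_lens_matches_eigh_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(5, 4))
        vecs = [sv(row, f"L{i}") for i, row in enumerate(x)]
        lens = lens_from_pc1(vecs)
        cov = np.cov(x, rowvar=False)
        vals, eigvecs = np.linalg.eigh(cov)
        pc1 = eigvecs[:, -1]
        if pc1[np.argmax(np.abs(pc1))] < 0:
            pc1 = -pc1
        expected = (x - x.mean(axis=0)) @ pc1
        np.testing.assert_allclose(lens.values, expected, atol=1e-8)


class TestBuildCover:
    def test_single_interval(self):
        lens = LensAssignment(("a", "b"), np.array([1.0, 3.0]), "pc1")
        cover = build_cover(lens, 1, 0.0)
        assert cover.intervals == ((1.0, 3.0),)

    def test_two_intervals_no_overlap(self):
        lens = LensAssignment(("a", "b"), np.array([0.0, 1.0]), "pc1")
        cover = build_cover(lens, 2, 0.0)
        np.testing.assert_allclose(cover.intervals, [(0.0, 0.5), (0.5, 1.0)])

    def test_three_intervals_third_overlap(self):
        lens = LensAssignment(("a", "b"), np.array([0.0, 1.0]), "pc1")
        cover = build_cover(lens, 3, 1.0 / 3.0)
        # interval length (1 - 0) / (3 - 2/3) = 3/7
        expected = [(0.0, 3 / 7), (2 / 7, 5 / 7), (4 / 7, 1.0)]
        np.testing.assert_allclose(cover.intervals, expected, atol=1e-12)

    def test_degenerate_range(self):
        lens = LensAssignment(("a", "b"), np.array([2.0, 2.0]), "pc1")
        with pytest.raises(DegenerateRangeError):
            build_cover(lens, 3, 0.2)
        assert build_cover(lens, 1, 0.2).intervals == ((2.0, 2.0),)

    @given(
        st.integers(1, 20),
        st.floats(0.0, 0.95),
        st.lists(st.floats(-50, 50), min_size=2, max_size=40),
        st.integers(0, 10_000),
    )
    def test_cover_invariants(self, n_intervals, overlap, values, salt):
        values = np.asarray(values)
        if np.ptp(values) < 1e-9:
            return
        lens = LensAssignment(
            tuple(f"L{i}" for i in range(values.size)), values, "pc1"
        )
        cover = build_cover(lens, n_intervals, overlap)
        lengths = [hi - lo for lo, hi in cover.intervals]
        assert max(lengths) - min(lengths) <= 1e-9 * max(1.0, np.ptp(values))
        starts = [lo for lo, _ in cover.intervals]
        assert starts == sorted(starts)
        assert cover.intervals[0][0] == values.min()
        assert cover.intervals[-1][1] == pytest.approx(values.max(), rel=1e-12)
        # every lens value covered; <= 2 intervals when overlap < 0.5
        for v in values:
            hits = cover.membership(v)
            assert hits
            if overlap < 0.5 and n_intervals > 1:
                assert len(hits) <= 2
        # consecutive intervals overlap by the overlap fraction of length
        for (lo1, hi1), (lo2, hi2) in zip(cover.intervals, cover.intervals[1:]):
            measured = hi1 - lo2
            assert measured == pytest.approx(
                overlap * (hi1 - lo1), abs=1e-9 * max(1.0, np.ptp(values))
            )


def explicit_dmat(ids, dense):
    d = np.asarray(dense, float)
    return DistanceMatrix(tuple(ids), d)


class TestClusterPreimage:
    def test_two_tight_groups(self):
        # block distances: within 0.01, between 1.0
        ids = ["a", "b", "c", "d"]
        d = np.array(
            [
                [0.0, 0.01, 1.0, 1.0],
                [0.01, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.01],
                [1.0, 1.0, 0.01, 0.0],
            ]
        )
        clusters, noise = cluster_preimage(ids, explicit_dmat(ids, d), eps=0.05, min_samples=1)
        assert clusters == [("a", "b"), ("c", "d")]
        assert noise == ()

    def test_transitive_closure_oracle_min_samples_one(self):
        # independent oracle: single-linkage components of the eps-graph
        rng = np.random.default_rng(3)
        n = 12
        pts = rng.normal(size=(n, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        d = np.clip(d / d.max() * 1.8, 0, 2)
        np.fill_diagonal(d, 0)
        ids = [f"L{i}" for i in range(n)]
        eps = 0.4
        clusters, noise = cluster_preimage(ids, explicit_dmat(ids, d), eps=eps, min_samples=1)
        # oracle: connected components of the thresholded graph
        adj = d <= eps
        seen, comps = set(), []
        for i in range(n):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                k = stack.pop()
                if k in comp:
                    continue
                comp.add(k)
                stack.extend(j for j in range(n) if adj[k, j] and j not in comp)
            seen |= comp
            comps.append(tuple(sorted(ids[j] for j in comp)))
        assert sorted(clusters) == sorted(comps)
        assert noise == ()

    def test_all_points_one_cluster_when_eps_large(self):
        ids = ["a", "b", "c"]
        d = np.array([[0, 0.5, 0.9], [0.5, 0, 0.4], [0.9, 0.4, 0]], float)
        clusters, noise = cluster_preimage(ids, explicit_dmat(ids, d), eps=1.0, min_samples=1)
        assert clusters == [("a", "b", "c")]

    def test_isolated_point_is_noise(self):
        ids = ["a", "b", "c"]
        d = np.array([[0, 0.01, 1.9], [0.01, 0, 1.9], [1.9, 1.9, 0]], float)
        clusters, noise = cluster_preimage(ids, explicit_dmat(ids, d), eps=0.05, min_samples=2)
        assert clusters == [("a", "b")]
        assert noise == ("c",)

    def test_empty_member_list(self):
        ids = ["a", "b"]
        d = np.zeros((2, 2))
        clusters, noise = cluster_preimage([], explicit_dmat(ids, d), eps=0.1, min_samples=1)
        assert clusters == [] and noise == ()


def random_mapper_inputs(seed, max_points=30):
    """Random small shape clouds with a random lens for oracle testing."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, max_points + 1))
    dim = int(rng.integers(2, 6)) * 2
    x = rng.normal(size=(n, dim))
    vecs = [ShapeVector(f"L{i:02d}", row) for i, row in enumerate(x)]
    lens = LensAssignment(
        tuple(v.leaf_id for v in vecs), rng.normal(size=n), "pc1"
    )
    params = {
        "n_intervals": int(rng.integers(1, 8)),
        "overlap": float(rng.uniform(0.0, 0.6)),
        "eps": float(rng.uniform(0.2, 1.5)),
        "min_samples": int(rng.integers(1, 4)),
    }
    return vecs, lens, params


def rebuild_clusters_for_oracle(vecs, lens, params):
    """Recompute per-interval clusters independently for the nerve oracle."""
    dmat = pairwise_distances(vecs)
    cover = build_cover(lens, params["n_intervals"], params["overlap"])
    mapping = lens.as_mapping()
    clusters = []
    for k, (lo, hi) in enumerate(cover.intervals):
        members = [i for i in dmat.ids if lo <= mapping[i] <= hi]
        found, _ = cluster_preimage(members, dmat, params["eps"], params["min_samples"])
        clusters.extend((k, c) for c in found)
    return clusters


class TestBuildMapperAgainstOracle:
    def test_single_interval_single_cluster(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 4)) * 0.01 + [1, 2, 3, 4]
        vecs = [ShapeVector(f"L{i}", row) for i, row in enumerate(x)]
        lens = LensAssignment(tuple(v.leaf_id for v in vecs), np.arange(6.0), "pc1")
        g = build_mapper(vecs, lens, n_intervals=1, overlap=0.0, eps=2.0, min_samples=1)
        assert g.n_vertices == 1 and g.n_edges == 0

    def test_hand_built_line_two_intervals(self):
        # six points on a line in shape space; lens splits them 4/4 with
        # overlap so the two middle points sit in both intervals
        t = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
        base = np.array([1.0, 2.0, 0.5, 1.5])
        x = np.outer(t, [1.0, -0.3, 0.8, 0.4]) + base
        vecs = [ShapeVector(f"L{i}", row) for i, row in enumerate(x)]
        lens = LensAssignment(tuple(v.leaf_id for v in vecs), t, "pc1")
        g = build_mapper(vecs, lens, n_intervals=2, overlap=0.4, eps=2.0, min_samples=1)
        assert g.n_vertices == 2
        assert g.n_edges == 1
        (pair,) = g.edges
        shared = set(g.vertex(pair[0]).member_ids) & set(g.vertex(pair[1]).member_ids)
        assert shared  # the overlap-zone points

    def test_disjoint_lens_clusters_no_cross_edges(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(10, 4))
        vecs = [ShapeVector(f"L{i}", row) for i, row in enumerate(x)]
        lens_values = np.array([0.0] * 5 + [10.0] * 5)
        lens = LensAssignment(tuple(v.leaf_id for v in vecs), lens_values, "pc1")
        g = build_mapper(vecs, lens, n_intervals=4, overlap=0.2, eps=2.0, min_samples=1)
        oracle = nerve_oracle(rebuild_clusters_for_oracle(vecs, lens, g.params))
        assert g.n_edges == oracle.n_edges

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_random_configs(self, seed):
        vecs, lens, params = random_mapper_inputs(seed)
        g = build_mapper(vecs, lens, **params)
        oracle = nerve_oracle(
            rebuild_clusters_for_oracle(vecs, lens, params), lens.as_mapping()
        )
        ours = {v.vertex_id: v.member_ids for v in g.vertices}
        theirs = {v.vertex_id: v.member_ids for v in oracle.vertices}
        assert ours == theirs
        assert set(g.edges) == set(oracle.edges)

    @pytest.mark.parametrize("seed", range(8))
    def test_membership_conservation_and_edge_locality(self, seed):
        vecs, lens, params = random_mapper_inputs(seed + 100)
        g = build_mapper(vecs, lens, **params)
        cover = build_cover(lens, params["n_intervals"], params["overlap"])
        mapping = lens.as_mapping()
        # each point appears, per interval it occupies, either in a vertex
        # or in that interval's noise record
        for k, (lo, hi) in enumerate(cover.intervals):
            members = {i for i in mapping if lo <= mapping[i] <= hi}
            in_vertices = set()
            for v in g.vertices:
                if v.interval_index == k:
                    in_vertices.update(v.member_ids)
            assert in_vertices | set(g.noise.get(k, ())) == members
        # edges only between same-or-adjacent intervals when overlap < 0.5
        if params["overlap"] < 0.5:
            for a, b in g.edges:
                ia = g.vertex(a).interval_index
                ib = g.vertex(b).interval_index
                assert abs(ia - ib) <= 1


class TestMapperVertexAnnotations:
    def test_composition_and_mean_lens(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(4, 4)) * 0.01 + [1, 2, 3, 4]
        vecs = [ShapeVector(f"L{i}", row) for i, row in enumerate(x)]
        lens = LensAssignment(tuple(v.leaf_id for v in vecs), np.array([0.0, 0.1, 0.2, 0.3]), "h")
        labels = {"L0": "a", "L1": "a", "L2": "b", "L3": "a"}
        g = build_mapper(vecs, lens, n_intervals=1, overlap=0.0, eps=2.0, min_samples=1, labels=labels)
        (v,) = g.vertices
        assert v.composition == {"a": 0.75, "b": 0.25}
        assert v.mean_lens == pytest.approx(0.15)

    def test_mean_shape_annotation(self):
        x = np.array([[0.0, 0.0, 1.0, 1.0], [2.0, 2.0, 3.0, 3.0]])
        vecs = [ShapeVector(f"L{i}", row) for i, row in enumerate(x)]
        lens = LensAssignment(("L0", "L1"), np.array([0.0, 1.0]), "h")
        shapes = {f"L{i}": row.reshape(-1, 2) for i, row in enumerate(x)}
        g = build_mapper(vecs, lens, n_intervals=1, overlap=0.0, eps=2.0, min_samples=1, shapes=shapes)
        (v,) = g.vertices
        np.testing.assert_allclose(v.mean_shape, [[1.0, 1.0], [2.0, 2.0]])


def path_graph(n, lens_values=None):
    lens_values = lens_values or list(range(n))
    vertices = tuple(
        MapperVertex(f"v{i}", i, (f"m{i}", f"s{i}"), float(lens_values[i]))
        for i in range(n)
    )
    edges = {}
    for i in range(n - 1):
        a, b = sorted((f"v{i}", f"v{i+1}"))
        edges[(a, b)] = 1
    # make edge contract hold: give consecutive vertices a shared member
    return vertices, edges


class TestGraphDiagnostics:
    def _graph(self, vertices, edges):
        return MapperGraph(vertices=vertices, edges=edges, params={})

    def _make(self, n_path=0, n_cycle=0):
        vertices = []
        edges = {}
        for i in range(n_path):
            members = [f"p{i}", f"p{i}.5"]
            if i > 0:
                members.append(f"p{i-1}.5")  # share with previous
            vertices.append(MapperVertex(f"a{i}", i, tuple(members), float(i)))
            if i > 0:
                edges[tuple(sorted((f"a{i-1}", f"a{i}")))] = 1
        for i in range(n_cycle):
            j = (i + 1) % n_cycle
            members = [f"c{i}", f"c{i}-{j}", f"c{(i-1)%n_cycle}-{i}"]
            vertices.append(MapperVertex(f"b{i}", 100 + i, tuple(members), float(i)))
        for i in range(n_cycle):
            j = (i + 1) % n_cycle
            edges[tuple(sorted((f"b{i}", f"b{j}")))] = 1
        return self._graph(tuple(vertices), edges)

    def test_path_graph(self):
        g = self._make(n_path=5)
        d = graph_diagnostics(g)
        assert d.n_components == 1
        assert d.cycle_rank == 0
        assert d.path_likeness == 1.0
        assert d.spine_monotonicity >= 1.0 - 1e-12
        assert len(d.spine) == 5

    def test_cycle_graph(self):
        g = self._make(n_cycle=5)
        d = graph_diagnostics(g)
        assert d.cycle_rank == 1

    def test_disjoint_path_plus_cycle(self):
        g = self._make(n_path=3, n_cycle=4)
        d = graph_diagnostics(g)
        assert d.n_components == 2
        assert d.cycle_rank == 6 - 7 + 2

    def test_empty_graph(self):
        d = graph_diagnostics(self._graph((), {}))
        assert d.empty
        assert d.n_vertices == 0 and d.cycle_rank == 0

    def test_spine_oriented_lens_ascending(self):
        g = self._make(n_path=4)
        d = graph_diagnostics(g)
        lens_seq = [g.vertex(v).mean_lens for v in d.spine]
        assert lens_seq[0] <= lens_seq[-1]


class TestGraphSerialization:
    def test_json_round_trip_is_deterministic(self):
        vecs, lens, params = random_mapper_inputs(7)
        g1 = build_mapper(vecs, lens, **params)
        g2 = build_mapper(vecs, lens, **params)
        assert g1.to_json() == g2.to_json()

    def test_graphml_written(self, tmp_path):
        vecs, lens, params = random_mapper_inputs(8)
        g = build_mapper(vecs, lens, **params)
        out = tmp_path / "g.graphml"
        g.write_graphml(out)
        import networkx as nx

        back = nx.read_graphml(out)
        assert back.number_of_nodes() == g.n_vertices
        assert back.number_of_edges() == g.n_edges
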