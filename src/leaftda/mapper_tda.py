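"""The Mapper algorithm over leaf-shape point clouds.

Pipeline: flatten leaves to shape vectors; measure dissimilarity with the
correlation distance 1 - r (Pearson), which is near zero for leaves whose
landmark vectors are highly correlated and is invariant to positive
affine rescaling of a vector; assign each leaf a one-dimensional lens
value (PC1 score, or the heteroblasty value = relative node position);
cover the lens range with overlapping equal-length intervals; cluster
each interval's preimage with DBSCAN on the precomputed distances; and
take the one-skeleton of the nerve -- one vertex per cluster, an edge
whenever two clusters share a leaf.

Cover intervals are closed: the data are finite, and closed endpoints
keep the extreme leaves inside the cover. A brute-force nerve oracle and
graph-structure diagnostics (component count, cycle rank, path-likeness,
spine monotonicity) support the "central spine vs branch-and-rejoin"
analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.stats
from sklearn.cluster import DBSCAN

from leaftda.errors import (
    DegenerateRangeError,
    GeometryError,
    InsufficientDataError,
    StateError,
)
from leaftda.landmark_io import LeafDataset
from leaftda.shape_align import ShapeVector
from leaftda.shape_space import pca_fit, pca_transform

__all__ = [
    "DistanceMatrix",
    "LensAssignment",
    "Cover",
    "MapperVertex",
    "MapperGraph",
    "correlation_distance",
    "pairwise_distances",
    "lens_from_heteroblasty",
    "lens_from_pc1",
    "build_cover",
    "cluster_preimage",
    "build_mapper",
    "nerve_oracle",
    "graph_diagnostics",
    "GraphDiagnostics",
]

#: Default cover parameters; hand-tunable per run, always recorded in
#: the graph's provenance.
DEFAULT_N_INTERVALS = 12
DEFAULT_OVERLAP = 0.35
#: Default DBSCAN parameters, in correlation-distance units.
DEFAULT_EPS = 0.05
DEFAULT_MIN_SAMPLES = 5


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric correlation-distance matrix over an ordered id list."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if d.min() < -1e-12 or d.max() > 2.0 + 1e-12:
            raise ValueError("correlation distances must lie in [0, 2]")
        d = np.clip(d, 0.0, 2.0)
        d.setflags(write=False)
        object.__setattr__(self, "d", d)

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        index = {i: k for k, i in enumerate(self.ids)}
        sel = [index[i] for i in ids]
        return self.d[np.ix_(sel, sel)]


@dataclass(frozen=True)
class LensAssignment:
    """One finite real lens value per leaf id."""

    ids: tuple[str, ...]
    values: np.ndarray
    lens_name: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids),):
            raise ValueError("one lens value per id required")
        if not np.all(np.isfinite(v)):
            raise ValueError("lens values must be finite")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.ids, self.values.tolist()))


def correlation_distance(u: ShapeVector | np.ndarray, v: ShapeVector | np.ndarray) -> float:
    """Correlation distance 1 - r between two flattened shapes.

    r is the Pearson correlation of the two coordinate sequences, so the
    result lies in [0, 2]: 0 for perfectly correlated vectors, 2 for
    perfectly anticorrelated ones. Undefined (raises) if either vector is
    constant.
    """
    a = u.values if isinstance(u, ShapeVector) else np.asarray(u, dtype=float)
    b = v.values if isinstance(v, ShapeVector) else np.asarray(v, dtype=float)
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 3:
        raise ValueError("need vectors of length >= 3")
    sa = a - a.mean()
    sb = b - b.mean()
    na = np.sqrt((sa**2).sum())
    nb = np.sqrt((sb**2).sum())
    if na == 0.0 or nb == 0.0:
        raise GeometryError("constant vector: Pearson correlation undefined")
    r = float((sa @ sb) / (na * nb))
    return float(np.clip(1.0 - r, 0.0, 2.0))


def pairwise_distances(vectors: Sequence[ShapeVector]) -> DistanceMatrix:
    """All-pairs correlation distances as a :class:`DistanceMatrix`."""
    if len(vectors) < 2:
        raise InsufficientDataError("need at least 2 shape vectors")
    x = np.array([v.values for v in vectors], dtype=float)
    sd = x.std(axis=1)
    flat = np.flatnonzero(sd == 0.0)
    if flat.size:
        bad = [vectors[i].leaf_id for i in flat]
        raise GeometryError(f"constant shape vector(s): {bad}")
    r = np.corrcoef(x)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(tuple(v.leaf_id for v in vectors), d)


def lens_from_heteroblasty(dataset: LeafDataset) -> LensAssignment:
    """Use the relative node position (0 = tip, 1 = base) as the lens."""
    unset = [leaf.leaf_id for leaf in dataset if leaf.relative_node is None]
    if unset:
        raise StateError(
            f"relative_node unset for {unset[:3]}...; run assign_relative_node first"
        )
    return LensAssignment(
        ids=tuple(leaf.leaf_id for leaf in dataset),
        values=np.array([leaf.relative_node for leaf in dataset], dtype=float),
        lens_name="heteroblasty",
    )


def lens_from_pc1(vectors: Sequence[ShapeVector]) -> LensAssignment:
    """Use the first principal component score of the flattened shapes as the lens."""
    model = pca_fit(vectors, n_components=1)
    scores = np.array([pca_transform(model, v)[0] for v in vectors])
    return LensAssignment(
        ids=tuple(v.leaf_id for v in vectors), values=scores, lens_name="pc1"
    )


@dataclass(frozen=True)
class Cover:
    """Ordered overlapping closed intervals spanning the lens range.

    With n intervals of common length l over [m, M] and overlap fraction g
    of consecutive intervals, l = (M - m) / (n - (n - 1) g) and interval k
    starts at m + k l (1 - g).
    """

    n_intervals: int
    overlap: float
    intervals: tuple[tuple[float, float], ...]

    def membership(self, value: float) -> list[int]:
        """Indices of the intervals containing a lens value (closed bounds)."""
        return [
            k for k, (lo, hi) in enumerate(self.intervals) if lo <= value <= hi
        ]


def build_cover(lens: LensAssignment, n_intervals: int, overlap: float) -> Cover:
    """Build the equal-length overlapping interval cover of the lens range."""
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    if lens.values.size == 0:
        raise InsufficientDataError("lens has no values")
    m = float(lens.values.min())
    big = float(lens.values.max())
    if big == m:
        if n_intervals > 1:
            raise DegenerateRangeError(
                "lens range is a single point; use n_intervals = 1"
            )
        return Cover(1, overlap, ((m, big),))
    length = (big - m) / (n_intervals - (n_intervals - 1) * overlap)
    step = length * (1.0 - overlap)
    intervals = []
    for k in range(n_intervals):
        lo = m + k * step
        hi = lo + length
        intervals.append((lo, hi))
    # pin the final endpoint to the exact maximum against rounding
    lo_last, _ = intervals[-1]
    intervals[-1] = (lo_last, big)
    return Cover(n_intervals, overlap, tuple(intervals))


def cluster_preimage(
    member_ids: Sequence[str],
    dmat: DistanceMatrix,
    eps: float = DEFAULT_EPS,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> tuple[list[tuple[str, ...]], tuple[str, ...]]:
    """DBSCAN a cover interval's preimage on the precomputed distances.

    Returns (clusters, noise): clusters are disjoint id tuples sorted by
    their lexicographically smallest member, noise is the tuple of outlier
    ids. DBSCAN needs no a-priori cluster count and tolerates outliers,
    which is why it is the clusterer of choice here.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    ids = list(member_ids)
    if not ids:
        return [], ()
    missing = [i for i in ids if i not in set(dmat.ids)]
    if missing:
        raise ValueError(f"ids not in distance matrix: {missing[:5]}")
    if len(ids) == 1:
        if min_samples == 1:
            return [tuple(ids)], ()
        return [], tuple(ids)
    sub = dmat.submatrix(ids)
    labels = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed").fit_predict(sub)
    clusters: dict[int, list[str]] = {}
    noise: list[str] = []
    for leaf_id, lab in zip(ids, labels):
        if lab == -1:
            noise.append(leaf_id)
        else:
            clusters.setdefault(int(lab), []).append(leaf_id)
    ordered = sorted((tuple(sorted(c)) for c in clusters.values()), key=lambda c: c[0])
    return list(ordered), tuple(sorted(noise))


@dataclass(frozen=True)
class MapperVertex:
    """One cluster of leaves: a vertex of the Mapper graph.

    ``composition`` maps group labels to member proportions (rendered as
    pie-chart vertices in figures); ``mean_shape`` is the member-average
    landmark configuration when shapes were supplied.
    """

    vertex_id: str
    interval_index: int
    member_ids: tuple[str, ...]
    mean_lens: float
    composition: dict[str, float] = field(default_factory=dict)
    mean_shape: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("a Mapper vertex must have at least one member")
        object.__setattr__(self, "member_ids", tuple(sorted(self.member_ids)))
        if self.composition:
            total = sum(self.composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"composition proportions sum to {total}, not 1")

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class MapperGraph:
    """One-skeleton of the nerve of the per-interval clusterings.

    ``edges`` maps unordered vertex-id pairs (stored sorted) to the
    shared-member count; ``noise`` records DBSCAN outliers per interval;
    ``params`` is the full provenance of lens, cover, and clustering
    settings.
    """

    vertices: tuple[MapperVertex, ...]
    edges: dict[tuple[str, str], int]
    params: dict
    noise: dict[int, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        byid = {v.vertex_id: v for v in self.vertices}
        if len(byid) != len(self.vertices):
            raise ValueError("duplicate vertex ids")
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop at {a}")
            if a > b:
                raise ValueError("edge keys must be sorted pairs")
            shared = set(byid[a].member_ids) & set(byid[b].member_ids)
            if not shared:
                raise ValueError(f"edge ({a}, {b}) has no shared member")
            if w != len(shared):
                raise ValueError(f"edge ({a}, {b}) weight {w} != shared count {len(shared)}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def vertex(self, vertex_id: str) -> MapperVertex:
        for v in self.vertices:
            if v.vertex_id == vertex_id:
                return v
        raise KeyError(vertex_id)

    def covered_ids(self) -> set[str]:
        out: set[str] = set()
        for v in self.vertices:
            out.update(v.member_ids)
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for v in self.vertices:
            g.add_node(
                v.vertex_id,
                interval=v.interval_index,
                size=v.size,
                mean_lens=v.mean_lens,
                composition=json.dumps(v.composition, sort_keys=True),
                mean_shape=""
                if v.mean_shape is None
                else ",".join(repr(float(x)) for x in np.asarray(v.mean_shape).ravel()),
            )
        for (a, b), w in sorted(self.edges.items()):
            g.add_edge(a, b, weight=w)
        return g

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": self.params,
                "vertices": [
                    {
                        "vertex_id": v.vertex_id,
                        "interval_index": v.interval_index,
                        "member_ids": list(v.member_ids),
                        "mean_lens": v.mean_lens,
                        "composition": v.composition,
                        "mean_shape": None
                        if v.mean_shape is None
                        else np.asarray(v.mean_shape).tolist(),
                    }
                    for v in self.vertices
                ],
                "edges": [
                    {"source": a, "target": b, "weight": w}
                    for (a, b), w in sorted(self.edges.items())
                ],
                "noise": {str(k): list(v) for k, v in sorted(self.noise.items())},
            },
            indent=1,
            sort_keys=True,
        )

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def membership_rows(self) -> list[dict[str, str]]:
        """Long-format leaf -> vertex membership (one row per occupancy)."""
        rows = []
        for v in self.vertices:
            for leaf_id in v.member_ids:
                rows.append({"leaf_id": leaf_id, "vertex_id": v.vertex_id})
        return rows


def _make_vertices(
    clusters_by_interval: Sequence[tuple[int, Sequence[tuple[str, ...]]]],
    lens_map: Mapping[str, float],
    labels: Mapping[str, str] | None,
    shapes: Mapping[str, np.ndarray] | None,
) -> tuple[MapperVertex, ...]:
    vertices = []
    for interval_index, clusters in clusters_by_interval:
        for c_index, members in enumerate(clusters):
            comp: dict[str, float] = {}
            if labels is not None:
                for m in members:
                    lab = labels[m]
                    comp[lab] = comp.get(lab, 0.0) + 1.0
                comp = {k: v / len(members) for k, v in sorted(comp.items())}
            mean_shape = None
            if shapes is not None:
                mean_shape = np.mean([np.asarray(shapes[m], dtype=float) for m in members], axis=0)
            vertices.append(
                MapperVertex(
                    vertex_id=f"i{interval_index}_c{c_index}",
                    interval_index=interval_index,
                    member_ids=tuple(members),
                    mean_lens=float(np.mean([lens_map[m] for m in members])),
                    composition=comp,
                    mean_shape=mean_shape,
                )
            )
    return tuple(vertices)


def _nerve_edges(vertices: Sequence[MapperVertex]) -> dict[tuple[str, str], int]:
    edges: dict[tuple[str, str], int] = {}
    for i in range(len(vertices)):
        vi = vertices[i]
        si = set(vi.member_ids)
        for j in range(i + 1, len(vertices)):
            vj = vertices[j]
            if vi.interval_index == vj.interval_index:
                continue  # clusters within one interval are disjoint
            shared = si & set(vj.member_ids)
            if shared:
                key = tuple(sorted((vi.vertex_id, vj.vertex_id)))
                edges[key] = len(shared)
    return edges


def build_mapper(
    vectors: Sequence[ShapeVector] | None,
    lens: LensAssignment,
    n_intervals: int = DEFAULT_N_INTERVALS,
    overlap: float = DEFAULT_OVERLAP,
    eps: float = DEFAULT_EPS,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    labels: Mapping[str, str] | None = None,
    shapes: Mapping[str, np.ndarray] | None = None,
    dmat: DistanceMatrix | None = None,
) -> MapperGraph:
    """Construct the Mapper graph of a shape point cloud.

    Either ``vectors`` (from which correlation distances are computed) or a
    precomputed ``dmat`` must be given. ``labels`` and ``shapes`` (leaf_id
    keyed) annotate vertices with group composition and mean shapes. All
    parameters are recorded in the graph's ``params`` for provenance.
    """
    if dmat is None:
        if vectors is None:
            raise ValueError("supply either vectors or a precomputed distance matrix")
        dmat = pairwise_distances(vectors)
    if set(lens.ids) != set(dmat.ids):
        raise ValueError("lens ids and distance-matrix ids differ")
    lens_map = lens.as_mapping()
    cover = build_cover(lens, n_intervals, overlap)
    clusters_by_interval = []
    noise: dict[int, tuple[str, ...]] = {}
    for k, (lo, hi) in enumerate(cover.intervals):
        members = [i for i in dmat.ids if lo <= lens_map[i] <= hi]
        clusters, interval_noise = cluster_preimage(members, dmat, eps, min_samples)
        clusters_by_interval.append((k, clusters))
        if interval_noise:
            noise[k] = interval_noise
    vertices = _make_vertices(clusters_by_interval, lens_map, labels, shapes)
    if not vertices:
        warnings.warn("all points classified as noise; returning empty graph", stacklevel=2)
    edges = _nerve_edges(vertices)
    params = {
        "lens_name": lens.lens_name,
        "n_intervals": n_intervals,
        "overlap": overlap,
        "eps": eps,
        "min_samples": min_samples,
        "n_points": len(dmat.ids),
        "cover_intervals": [list(iv) for iv in cover.intervals],
    }
    return MapperGraph(vertices=vertices, edges=edges, params=params, noise=noise)


def nerve_oracle(
    clusters: Sequence[tuple[int, Iterable[str]]],
    lens_map: Mapping[str, float] | None = None,
) -> MapperGraph:
    """Brute-force nerve: exhaustive pairwise intersection over all clusters.

    Test-only reference implementation. ``clusters`` is a flat list of
    (interval_index, member ids); cluster ids follow the same convention
    as :func:`build_mapper`.
    """
    grouped: dict[int, list[tuple[str, ...]]] = {}
    for interval_index, members in clusters:
        grouped.setdefault(interval_index, []).append(tuple(sorted(members)))
    for k in grouped:
        grouped[k] = sorted(grouped[k], key=lambda c: c[0])
    lens_map = lens_map or {}
    vertices = []
    for interval_index in sorted(grouped):
        for c_index, members in enumerate(grouped[interval_index]):
            vertices.append(
                MapperVertex(
                    vertex_id=f"i{interval_index}_c{c_index}",
                    interval_index=interval_index,
                    member_ids=members,
                    mean_lens=float(np.mean([lens_map.get(m, 0.0) for m in members])),
                )
            )
    edges: dict[tuple[str, str], int] = {}
    for i in range(len(vertices)):
        for j in range(i + 1, len(vertices)):
            a, b = vertices[i], vertices[j]
            if a.vertex_id == b.vertex_id:
                continue
            shared = set(a.member_ids) & set(b.member_ids)
            if shared and a.interval_index != b.interval_index:
                key = tuple(sorted((a.vertex_id, b.vertex_id)))
                edges[key] = len(shared)
    return MapperGraph(
        vertices=tuple(vertices), edges=edges, params={"oracle": True}, noise={}
    )


@dataclass(frozen=True)
class GraphDiagnostics:
    """Structure summary of a Mapper graph.

    ``cycle_rank`` is the first Betti number b1 = E - V + C: 0 for forests,
    >= 1 when a branch leaves and rejoins the spine (the reverse-hourglass
    signature). ``path_likeness`` is the fraction of vertices of degree
    <= 2. ``spine_monotonicity`` is the Spearman correlation between
    position along the spine (the longest simple path, oriented
    lens-ascending) and vertex mean lens value.
    """

    n_vertices: int
    n_edges: int
    n_components: int
    cycle_rank: int
    path_likeness: float
    spine_monotonicity: float
    spine: tuple[str, ...]
    empty: bool = False

    def as_dict(self) -> dict:
        return {
            "n_vertices": self.n_vertices,
            "n_edges": self.n_edges,
            "n_components": self.n_components,
            "cycle_rank": self.cycle_rank,
            "path_likeness": self.path_likeness,
            "spine_monotonicity": self.spine_monotonicity,
            "spine": list(self.spine),
            "empty": self.empty,
        }


def _longest_path(g: nx.Graph, state_budget: int = 500_000) -> list[str]:
    """Longest simple path by vertex count, via DFS with a state budget.

    Mapper graphs here are small and nearly path-like, so exhaustive DFS
    is cheap; if the budget is ever exceeded (densely cyclic input), fall
    back to the longest shortest path (a diameter path), which is a valid
    spine for diagnostics.
    """
    order = sorted(g.nodes, key=lambda v: (g.nodes[v].get("mean_lens", 0.0), v))
    best: list[str] = []
    states = 0

    def dfs(node: str, path: list[str], seen: set[str]) -> bool:
        nonlocal best, states
        states += 1
        if states > state_budget:
            return False
        if len(path) > len(best):
            best = list(path)
        for nb in sorted(g.neighbors(node), key=lambda v: (g.nodes[v].get("mean_lens", 0.0), v)):
            if nb not in seen:
                seen.add(nb)
                path.append(nb)
                ok = dfs(nb, path, seen)
                path.pop()
                seen.remove(nb)
                if not ok:
                    return False
        return True

    completed = True
    for start in order:
        if not dfs(start, [start], {start}):
            completed = False
            break
    if completed and best:
        return best
    # fallback: diameter path via BFS shortest paths
    best = []
    for start in order:
        lengths = nx.single_source_shortest_path(g, start)
        for path in lengths.values():
            if len(path) > len(best):
                best = path
    return best


def graph_diagnostics(graph: MapperGraph) -> GraphDiagnostics:
    """Component count, cycle rank, path-likeness, and spine monotonicity."""
    if graph.n_vertices == 0:
        return GraphDiagnostics(0, 0, 0, 0, 0.0, 0.0, (), empty=True)
    g = graph.to_networkx()
    n_components = nx.number_connected_components(g)
    cycle_rank = graph.n_edges - graph.n_vertices + n_components
    degrees = [d for _, d in g.degree()]
    path_likeness = float(np.mean([d <= 2 for d in degrees]))
    spine = _longest_path(g)
    lens_values = [g.nodes[v]["mean_lens"] for v in spine]
    if len(spine) >= 2 and lens_values[0] > lens_values[-1]:
        spine = spine[::-1]
        lens_values = lens_values[::-1]
    if len(spine) < 2:
        rho = 1.0
    elif len(set(lens_values)) == 1:
        rho = 0.0
    else:
        rho = float(
            scipy.stats.spearmanr(np.arange(len(spine)), lens_values).statistic
        )
    return GraphDiagnostics(
        n_vertices=graph.n_vertices,
        n_edges=graph.n_edges,
        n_components=n_components,
        cycle_rank=cycle_rank,
        path_likeness=path_likeness,
        spine_monotonicity=rho,
        spine=tuple(spine),
    )
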