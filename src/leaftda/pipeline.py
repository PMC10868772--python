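"""End-to-end orchestration of the leaf-series analyses.

From a config (YAML or constructed in code) the pipeline runs, per genus:
ingest or synthesize -> relative-node assignment -> PC1-lens Mapper ->
heteroblasty-lens Mapper -> base/tip split with per-part Mappers; then
jointly: shared-landmark subsetting (with reflection completion of
half-sampled genera) -> GPA -> joint PCA -> four-group LDA (genus x
shoot position, with ontogenetic/heteroblastic series labels emitted
alongside) -> graph diagnostics -> subway-map extraction -> export.

Every Mapper run is fully parameterized in the config and stamped into
the outputs; the whole run is deterministic given config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
import networkx as nx
import pandas as pd
import yaml

from leaftda.errors import EmptyResultError, LeafTDAError
from leaftda.landmark_io import (
    LeafDataset,
    assign_relative_node,
    builtin_scheme,
    read_landmark_table,
    reflect_dataset,
    split_by_position,
    split_by_vine_mean,
    subset_shared_landmarks,
    write_landmark_table,
)
from leaftda.mapper_tda import (
    DEFAULT_EPS,
    DEFAULT_MIN_SAMPLES,
    DEFAULT_N_INTERVALS,
    DEFAULT_OVERLAP,
    GraphDiagnostics,
    MapperGraph,
    build_mapper,
    graph_diagnostics,
    lens_from_heteroblasty,
    lens_from_pc1,
)
from leaftda.shape_align import AlignmentResult, flatten, gpa
from leaftda.shape_space import (
    LDAModel,
    PCAModel,
    lda_fit,
    lda_predict,
    lda_transform,
    pca_fit,
    pca_transform,
)
from leaftda.synthetic_data import SyntheticConfig, generate

__all__ = [
    "MapperParams",
    "GenusSpec",
    "AnalysisConfig",
    "ResultsBundle",
    "default_synthetic_analysis",
    "run_full_analysis",
    "extract_primary_structure",
    "export_bundle",
]


@dataclass(frozen=True)
class MapperParams:
    """Cover and clustering settings for one family of Mapper runs."""

    n_intervals: int = DEFAULT_N_INTERVALS
    overlap: float = DEFAULT_OVERLAP
    eps: float = DEFAULT_EPS
    min_samples: int = DEFAULT_MIN_SAMPLES

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GenusSpec:
    """One genus-level input: a landmark table or a synthetic config.

    ``shared_selection`` picks the landmarks used for the cross-genus
    morphospace; ``reflect`` completes half-sampled leaves by mirroring
    across the scheme's axis after subsetting (the grapevine case).
    """

    name: str
    table: str | None = None
    scheme: str | None = None
    synthetic: SyntheticConfig | None = None
    shared_selection: tuple[int, ...] = ()
    reflect: bool = False

    def __post_init__(self) -> None:
        if (self.table is None) == (self.synthetic is None):
            raise ValueError(
                f"genus {self.name!r}: exactly one of table/synthetic required"
            )


@dataclass(frozen=True)
class AnalysisConfig:
    genera: tuple[GenusSpec, ...]
    mapper: MapperParams = MapperParams()
    split_threshold: float = 0.5
    subway_min_vertex_size: int = 2
    outdir: str = "results/run"
    seed: int = 0

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def to_yaml(self) -> str:
        doc = {
            "seed": self.seed,
            "outdir": self.outdir,
            "split_threshold": self.split_threshold,
            "subway_min_vertex_size": self.subway_min_vertex_size,
            "mapper": self.mapper.as_dict(),
            "genera": [
                {
                    "name": g.name,
                    "table": g.table,
                    "scheme": g.scheme,
                    "synthetic": yaml.safe_load(g.synthetic.to_yaml())
                    if g.synthetic
                    else None,
                    "shared_selection": list(g.shared_selection),
                    "reflect": g.reflect,
                }
                for g in self.genera
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "AnalysisConfig":
        doc = yaml.safe_load(text)
        genera = []
        for g in doc.get("genera", []):
            synth = g.get("synthetic")
            genera.append(
                GenusSpec(
                    name=g["name"],
                    table=g.get("table"),
                    scheme=g.get("scheme"),
                    synthetic=SyntheticConfig(**synth) if synth else None,
                    shared_selection=tuple(g.get("shared_selection", ())),
                    reflect=bool(g.get("reflect", False)),
                )
            )
        mp = doc.get("mapper", {})
        return cls(
            genera=tuple(genera),
            mapper=MapperParams(**mp),
            split_threshold=doc.get("split_threshold", 0.5),
            subway_min_vertex_size=doc.get("subway_min_vertex_size", 2),
            outdir=doc.get("outdir", "results/run"),
            seed=doc.get("seed", 0),
        )


@dataclass
class GenusResults:
    """Per-genus artifacts of the run."""

    name: str
    dataset: LeafDataset
    mapper_pc1: MapperGraph
    mapper_heteroblasty: MapperGraph
    mapper_base: MapperGraph
    mapper_tip: MapperGraph
    subway: MapperGraph | None
    diagnostics: dict[str, GraphDiagnostics]


@dataclass
class ResultsBundle:
    """Everything a full run produces, stamped with config hash and seed."""

    config: AnalysisConfig
    genera: list[GenusResults]
    alignment: AlignmentResult | None
    pca: PCAModel | None
    lda: LDAModel | None
    score_table: pd.DataFrame | None
    provenance: dict


def default_synthetic_analysis(seed: int = 0, outdir: str = "results/run") -> AnalysisConfig:
    """Two synthetic genera mirroring the study layout.

    Genus "vitis" emulates the grapevine case: 15 landmarks digitized on
    one half of the leaf, completed by reflection for the shared
    morphospace, with no divergent species. Genus "passiflora" emulates
    maracuya: 21 landmarks, larger species effects, and one divergent
    species that branches off the shared trajectory mid-series and
    rejoins (the morphotype A/B signature).
    """
    vitis = SyntheticConfig(
        n_species=6,
        n_landmarks=15,
        species_effect_sd=0.015,
        lineage_effect_sd=0.1,
        ontogeny_amplitude=1.0,
        seed=seed * 1000 + 1,
        group_prefix="vit",
    )
    passiflora = SyntheticConfig(
        n_species=7,
        n_landmarks=21,
        species_effect_sd=0.02,
        lineage_effect_sd=0.1,
        ontogeny_amplitude=1.0,
        divergent_species=frozenset({"pas06"}),
        seed=seed * 1000 + 2,
        group_prefix="pas",
    )
    # shared selections pick homologous template-curve positions on one
    # side of the blade (petiolar base ... leaf tip at t ~ 0.5); each
    # genus is completed by reflection across the base -> tip axis
    return AnalysisConfig(
        genera=(
            GenusSpec(
                name="vitis",
                synthetic=vitis,
                shared_selection=(0, 2, 3, 5, 6, 7),
                reflect=True,
            ),
            GenusSpec(
                name="passiflora",
                synthetic=passiflora,
                shared_selection=(0, 3, 4, 7, 8, 10),
                reflect=True,
            ),
        ),
        outdir=outdir,
        seed=seed,
    )


def _load_genus(spec: GenusSpec) -> LeafDataset:
    if spec.synthetic is not None:
        ds = generate(spec.synthetic)
    else:
        scheme = builtin_scheme(spec.scheme)
        ds = read_landmark_table(spec.table, scheme, provenance=str(spec.table))
    return assign_relative_node(ds)


def _mapper_for(dataset: LeafDataset, lens, params: MapperParams) -> MapperGraph:
    vectors = [flatten(leaf) for leaf in dataset]
    labels = dict(zip(dataset.leaf_ids, dataset.group_labels))
    shapes = {leaf.leaf_id: leaf.landmarks for leaf in dataset}
    return build_mapper(
        vectors,
        lens,
        n_intervals=params.n_intervals,
        overlap=params.overlap,
        eps=params.eps,
        min_samples=params.min_samples,
        labels=labels,
        shapes=shapes,
    )


def extract_primary_structure(graph: MapperGraph, min_vertex_size: int = 1) -> MapperGraph:
    """Subway-map reduction: drop small vertices, keep the largest component.

    The subgraph induced by vertices with at least ``min_vertex_size``
    members is restricted to its largest connected component (ties broken
    by smallest vertex id); annotations are preserved. This realizes the
    "primary structure / central spine plus branches" rendering.
    """
    if min_vertex_size < 1:
        raise ValueError("min_vertex_size must be >= 1")
    keep = [v for v in graph.vertices if v.size >= min_vertex_size]
    if not keep:
        raise EmptyResultError(
            f"no vertex has >= {min_vertex_size} members"
        )
    keep_ids = {v.vertex_id for v in keep}
    g = graph.to_networkx().subgraph(keep_ids)
    components = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    main = set(components[0])
    vertices = tuple(v for v in graph.vertices if v.vertex_id in main)
    edges = {
        (a, b): w
        for (a, b), w in graph.edges.items()
        if a in main and b in main
    }
    params = dict(graph.params)
    params["primary_structure_min_vertex_size"] = min_vertex_size
    return MapperGraph(vertices=vertices, edges=edges, params=params, noise=graph.noise)


def _shared_dataset(spec: GenusSpec, dataset: LeafDataset) -> LeafDataset:
    if not spec.shared_selection:
        raise LeafTDAError(f"genus {spec.name!r}: shared_selection is empty")
    shared = subset_shared_landmarks(dataset, list(spec.shared_selection))
    if spec.reflect:
        # axis = first (petiolar base) to last (leaf tip) shared landmark
        shared = reflect_dataset(
            shared, axis_indices=(0, shared.scheme.n_landmarks - 1)
        )
    return shared


def run_full_analysis(config: AnalysisConfig) -> ResultsBundle:
    """Execute the full analysis; see the module docstring for the stages."""
    genus_results: list[GenusResults] = []
    shared_parts: list[tuple[str, LeafDataset]] = []
    for spec in config.genera:
        try:
            dataset = _load_genus(spec)
            vectors = [flatten(leaf) for leaf in dataset]
            g_pc1 = _mapper_for(dataset, lens_from_pc1(vectors), config.mapper)
            g_het = _mapper_for(dataset, lens_from_heteroblasty(dataset), config.mapper)
            base, tip = split_by_position(dataset, config.split_threshold)
            g_base = _mapper_for(base, lens_from_heteroblasty(base), config.mapper)
            g_tip = _mapper_for(tip, lens_from_heteroblasty(tip), config.mapper)
            subway = None
            if g_het.n_vertices:
                subway = extract_primary_structure(
                    g_het, config.subway_min_vertex_size
                )
            diagnostics = {
                "pc1": graph_diagnostics(g_pc1),
                "heteroblasty": graph_diagnostics(g_het),
                "base": graph_diagnostics(g_base),
                "tip": graph_diagnostics(g_tip),
            }
            if subway is not None:
                diagnostics["subway"] = graph_diagnostics(subway)
            genus_results.append(
                GenusResults(
                    name=spec.name,
                    dataset=dataset,
                    mapper_pc1=g_pc1,
                    mapper_heteroblasty=g_het,
                    mapper_base=g_base,
                    mapper_tip=g_tip,
                    subway=subway,
                    diagnostics=diagnostics,
                )
            )
            shared_parts.append((spec.name, _shared_dataset(spec, dataset)))
        except LeafTDAError as exc:
            raise LeafTDAError(f"[genus {spec.name}] {exc}") from exc

    alignment = pca = lda = score_table = None
    if len(shared_parts) >= 1:
        counts = {ds.scheme.n_landmarks for _, ds in shared_parts}
        if len(counts) != 1:
            raise LeafTDAError(
                f"shared-landmark counts differ across genera: {sorted(counts)}"
            )
        # pool genera into one dataset; leaf ids are prefixed to stay unique
        from leaftda.landmark_io import Leaf, LandmarkScheme

        n_lm = counts.pop()
        scheme = LandmarkScheme(
            "joint_shared", n_lm, tuple(f"lm{i:02d}" for i in range(n_lm))
        )
        pooled: list[Leaf] = []
        genus_of: dict[str, str] = {}
        for genus, ds in shared_parts:
            for leaf in ds:
                new_id = f"{genus}:{leaf.leaf_id}"
                genus_of[new_id] = genus
                pooled.append(
                    Leaf(
                        leaf_id=new_id,
                        group_label=leaf.group_label,
                        vine_id=f"{genus}:{leaf.vine_id}",
                        node_index=leaf.node_index,
                        landmarks=leaf.landmarks,
                        relative_node=leaf.relative_node,
                    )
                )
        joint = LeafDataset(scheme, tuple(pooled), provenance="joint_shared")
        alignment = gpa(joint)
        aligned = alignment.aligned
        vectors = [flatten(leaf) for leaf in aligned]
        pca = pca_fit(vectors)
        base_ds, tip_ds = split_by_position(aligned, config.split_threshold)
        base_ids = set(base_ds.leaf_ids)
        hetero_ds, onto_ds = split_by_vine_mean(aligned)
        hetero_ids = set(hetero_ds.leaf_ids)
        group4 = {
            leaf.leaf_id: f"{genus_of[leaf.leaf_id]}_"
            + ("base" if leaf.leaf_id in base_ids else "tip")
            for leaf in aligned
        }
        labels = [group4[v.leaf_id] for v in vectors]
        lda = lda_fit(vectors, labels)
        rows = []
        for leaf, vec in zip(aligned, vectors):
            pc = pca_transform(pca, vec)
            ld = lda_transform(lda, vec)
            rows.append(
                {
                    "leaf_id": leaf.leaf_id,
                    "genus": genus_of[leaf.leaf_id],
                    "group_label": leaf.group_label,
                    "relative_node": leaf.relative_node,
                    "position": "base" if leaf.leaf_id in base_ids else "tip",
                    "series": "heteroblastic"
                    if leaf.leaf_id in hetero_ids
                    else "ontogenetic",
                    "group4": group4[leaf.leaf_id],
                    "lda_predicted": lda_predict(lda, vec),
                    **{f"pc{i + 1}": pc[i] for i in range(min(4, pc.size))},
                    **{f"ld{i + 1}": ld[i] for i in range(ld.size)},
                }
            )
        score_table = pd.DataFrame(rows)

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": yaml.safe_load(config.to_yaml()),
    }
    return ResultsBundle(
        config=config,
        genera=genus_results,
        alignment=alignment,
        pca=pca,
        lda=lda,
        score_table=score_table,
        provenance=provenance,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def export_bundle(bundle: ResultsBundle, outdir: str | Path, plots: bool = True) -> dict:
    """Write all artifacts (tables, graphs, models, plots) plus a manifest.

    Returns the manifest: {relative path: sha256}. Identical bundles
    yield identical checksums.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(rel: str, text: str) -> None:
        p = out / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(text)
        written.append(p)

    emit("provenance.json", json.dumps(bundle.provenance, indent=1, sort_keys=True))

    for gres in bundle.genera:
        gdir = f"genus_{gres.name}"
        p = out / gdir
        p.mkdir(parents=True, exist_ok=True)
        write_landmark_table(gres.dataset, p / "dataset.csv")
        written.append(p / "dataset.csv")
        graphs = {
            "mapper_pc1": gres.mapper_pc1,
            "mapper_heteroblasty": gres.mapper_heteroblasty,
            "mapper_base": gres.mapper_base,
            "mapper_tip": gres.mapper_tip,
        }
        if gres.subway is not None:
            graphs["subway"] = gres.subway
        for name, graph in graphs.items():
            emit(f"{gdir}/{name}.json", graph.to_json())
            graph.write_graphml(p / f"{name}.graphml")
            written.append(p / f"{name}.graphml")
            rows = graph.membership_rows()
            emit(
                f"{gdir}/{name}_membership.csv",
                pd.DataFrame(rows, columns=["leaf_id", "vertex_id"]).to_csv(index=False),
            )
        emit(
            f"{gdir}/diagnostics.json",
            json.dumps(
                {k: d.as_dict() for k, d in gres.diagnostics.items()},
                indent=1,
                sort_keys=True,
            ),
        )

    if bundle.pca is not None:
        emit("joint/pca_model.json", bundle.pca.to_json())
    if bundle.lda is not None:
        emit("joint/lda_model.json", bundle.lda.to_json())
    if bundle.score_table is not None:
        emit("joint/scores.csv", bundle.score_table.to_csv(index=False))
    if bundle.alignment is not None:
        emit(
            "joint/gpa.json",
            json.dumps(
                {
                    "mean_shape": bundle.alignment.mean_shape.tolist(),
                    "iterations": bundle.alignment.iterations,
                    "final_change": bundle.alignment.final_change,
                    "converged": bundle.alignment.converged,
                },
                indent=1,
            ),
        )
        write_landmark_table(bundle.alignment.aligned, out / "joint" / "aligned.csv")
        written.append(out / "joint" / "aligned.csv")

    if plots:
        from leaftda import plotting

        for gres in bundle.genera:
            p = out / f"genus_{gres.name}"
            plotting.plot_mapper(
                gres.mapper_heteroblasty, p / "mapper_heteroblasty.png"
            )
            if gres.subway is not None:
                plotting.plot_subway(gres.subway, p / "subway.png")
            written += [p / "mapper_heteroblasty.png"]
            if gres.subway is not None:
                written.append(p / "subway.png")
        if bundle.score_table is not None:
            plotting.plot_scores(bundle.score_table, out / "joint")
            written += [out / "joint" / "pca_scatter.png", out / "joint" / "lda_scatter.png"]

    manifest = {
        str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
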