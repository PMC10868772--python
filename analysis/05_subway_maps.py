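"""Extract and draw the subway maps (primary Mapper structure).

Reduces each genus's heteroblasty-lens Mapper to its primary structure
(vertices with at least 2 members, largest connected component) and
renders the subway map with vertex glyphs showing the mean leaf shape,
colored by mean heteroblasty value.
"""

import json
from pathlib import Path

import numpy as np

from leaftda.mapper_tda import MapperGraph, MapperVertex, graph_diagnostics
from leaftda.pipeline import extract_primary_structure
from leaftda.plotting import plot_subway

MAPPER = Path("results/mapper")
OUT = Path("results/subway")
MIN_VERTEX_SIZE = 2


def load_graph(path: Path) -> MapperGraph:
    doc = json.loads(path.read_text())
    vertices = tuple(
        MapperVertex(
            vertex_id=v["vertex_id"],
            interval_index=v["interval_index"],
            member_ids=tuple(v["member_ids"]),
            mean_lens=v["mean_lens"],
            composition=v.get("composition") or {},
            mean_shape=None if v.get("mean_shape") is None else np.asarray(v["mean_shape"]),
        )
        for v in doc["vertices"]
    )
    edges = {
        tuple(sorted((e["source"], e["target"]))): e["weight"] for e in doc["edges"]
    }
    return MapperGraph(vertices=vertices, edges=edges, params=doc.get("params", {}))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for genus in ("vitis", "passiflora"):
        graph = load_graph(MAPPER / f"{genus}_heteroblasty.json")
        subway = extract_primary_structure(graph, MIN_VERTEX_SIZE)
        d = graph_diagnostics(subway)
        (OUT / f"{genus}_subway.json").write_text(subway.to_json())
        plot_subway(subway, OUT / f"{genus}_subway.png")
        print(
            f"{genus}: {graph.n_vertices} -> {subway.n_vertices} vertices retained; "
            f"cycle rank {d.cycle_rank}, spine length {len(d.spine)}, "
            f"spine monotonicity {d.spine_monotonicity:.3f}"
        )
    print(f"subway maps -> {OUT}/")


if __name__ == "__main__":
    main()
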