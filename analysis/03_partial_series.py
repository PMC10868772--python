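"""Rebuild Mapper graphs from shoot-base and growing-tip partial datasets.

Splits each genus at relative node 0.5 (0 = growing tip, 1 = shoot
base), rebuilds the heteroblasty-lens Mapper on each half with its own
cover, and checks that the partial graphs retain the structures of the
full graphs -- in particular that the divergent species' branch survives
in the half covering its divergence window.
"""

import json
from pathlib import Path

import yaml

from leaftda.landmark_io import builtin_scheme, read_landmark_table, split_by_position
from leaftda.mapper_tda import build_mapper, graph_diagnostics, lens_from_heteroblasty
from leaftda.shape_align import flatten

DATA = Path("results/data")
OUT = Path("results/partial")
SCHEMES = {"vitis": "grapevine", "passiflora": "maracuya"}
DIVERGENT = {"passiflora": "pas06"}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = yaml.safe_load((DATA / "analysis_config.yaml").read_text())
    for genus, scheme_name in SCHEMES.items():
        dataset = read_landmark_table(DATA / f"{genus}.csv", builtin_scheme(scheme_name))
        base, tip = split_by_position(dataset, config["split_threshold"])
        for part_name, part in (("base", base), ("tip", tip)):
            vectors = [flatten(leaf) for leaf in part]
            graph = build_mapper(
                vectors,
                lens_from_heteroblasty(part),
                labels=dict(zip(part.leaf_ids, part.group_labels)),
                **config["mapper"],
            )
            d = graph_diagnostics(graph)
            (OUT / f"{genus}_{part_name}.json").write_text(graph.to_json())
            (OUT / f"{genus}_{part_name}_diagnostics.json").write_text(
                json.dumps(d.as_dict(), indent=1)
            )
            note = ""
            if genus in DIVERGENT:
                branch = [
                    v.vertex_id
                    for v in graph.vertices
                    if v.composition.get(DIVERGENT[genus], 0.0) > 0.5
                ]
                note = f"; divergent-majority vertices: {len(branch)}"
            print(
                f"{genus}/{part_name}: {len(part)} leaves -> {d.n_vertices} vertices, "
                f"cycle rank {d.cycle_rank}{note}"
            )
    print(f"partial-dataset graphs -> {OUT}/")


if __name__ == "__main__":
    main()
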