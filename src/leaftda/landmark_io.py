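"""Data model and I/O for landmark-based leaf datasets.

A *leaf* is an ordered set of homologous 2-D landmarks (petiolar-junction
base, lobe tips, sinuses, leaf tip, ...) plus collection metadata: which
vine it came from and its node position counted from the growing tip.
Datasets group leaves sharing one landmark scheme.

The relative node position ("heteroblasty value") follows the convention
0 = growing tip, 1 = shoot base.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from leaftda.errors import (
    EmptyResultError,
    GeometryError,
    IntegrityError,
    ParseError,
    SchemaError,
    StateError,
)

__all__ = [
    "LandmarkScheme",
    "Leaf",
    "LeafDataset",
    "builtin_scheme",
    "default_column_map",
    "read_landmark_table",
    "write_landmark_table",
    "dataset_to_json",
    "dataset_from_json",
    "assign_relative_node",
    "subset_shared_landmarks",
    "reflect_to_complete",
    "reflect_dataset",
    "split_by_position",
    "split_by_vine_mean",
]


@dataclass(frozen=True)
class LandmarkScheme:
    """Named, ordered landmark configuration shared by every leaf of a dataset.

    Parameters
    ----------
    name
        Scheme identifier, e.g. ``"grapevine"``.
    n_landmarks
        Number of 2-D landmarks per leaf.
    landmark_names
        One name per landmark, in digitization order.
    axis_indices
        Optional pair of landmark indices defining the petiolar-junction ->
        leaf-tip midline, used to complete half-sampled leaves by reflection.
    """

    name: str
    n_landmarks: int
    landmark_names: tuple[str, ...]
    axis_indices: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_landmarks < 1:
            raise SchemaError(f"scheme {self.name!r}: n_landmarks must be positive")
        if len(self.landmark_names) != self.n_landmarks:
            raise SchemaError(
                f"scheme {self.name!r}: {len(self.landmark_names)} names for "
                f"{self.n_landmarks} landmarks"
            )
        if self.axis_indices is not None:
            i, j = self.axis_indices
            if i == j or not (0 <= i < self.n_landmarks and 0 <= j < self.n_landmarks):
                raise SchemaError(
                    f"scheme {self.name!r}: axis_indices {self.axis_indices} invalid"
                )


#: Names of the six landmarks shared between the grapevine and maracuya schemes.
SHARED_LANDMARK_NAMES = (
    "petiolar_junction_base",
    "proximal_lobe_tip",
    "proximal_sinus",
    "distal_lobe_tip",
    "distal_sinus",
    "leaf_tip",
)

_BUILTIN: dict[str, LandmarkScheme] = {
    # 15 landmarks digitized on one half of the grapevine leaf; positional
    # names, with the petiolar-junction base first and the leaf tip last by
    # convention so the reflection axis is (0, 14).
    "grapevine": LandmarkScheme(
        "grapevine",
        15,
        tuple(f"lm{i:02d}" for i in range(15)),
        axis_indices=(0, 14),
    ),
    # 21 landmarks covering the whole maracuya (Passiflora) leaf.
    "maracuya": LandmarkScheme(
        "maracuya",
        21,
        tuple(f"lm{i:02d}" for i in range(21)),
        axis_indices=None,
    ),
    "shared": LandmarkScheme(
        "shared",
        6,
        SHARED_LANDMARK_NAMES,
        axis_indices=(0, 5),
    ),
}


def builtin_scheme(name: str) -> LandmarkScheme:
    """Return one of the built-in schemes: ``grapevine``, ``maracuya``, ``shared``."""
    try:
        return _BUILTIN[name]
    except KeyError:
        raise SchemaError(
            f"unknown scheme {name!r}; built-ins: {sorted(_BUILTIN)}"
        ) from None


@dataclass(frozen=True)
class Leaf:
    """One leaf: ordered 2-D landmarks plus identity metadata.

    ``node_index`` counts from the growing tip of the vine (1 = youngest
    leaf). ``relative_node`` in [0, 1] is assigned later from the per-vine
    node ranking (0 = tip, 1 = base) and doubles as the heteroblasty value.
    """

    leaf_id: str
    group_label: str
    vine_id: str
    node_index: int
    landmarks: np.ndarray  # shape (n, 2), float
    relative_node: float | None = None

    def __post_init__(self) -> None:
        lm = np.asarray(self.landmarks, dtype=float)
        if lm.ndim != 2 or lm.shape[1] != 2:
            raise SchemaError(f"leaf {self.leaf_id!r}: landmarks must be (n, 2)")
        if not np.all(np.isfinite(lm)):
            raise SchemaError(f"leaf {self.leaf_id!r}: non-finite coordinates")
        lm.setflags(write=False)
        object.__setattr__(self, "landmarks", lm)
        if self.node_index < 1:
            raise SchemaError(f"leaf {self.leaf_id!r}: node_index must be >= 1")
        if self.relative_node is not None and not 0.0 <= self.relative_node <= 1.0:
            raise SchemaError(
                f"leaf {self.leaf_id!r}: relative_node {self.relative_node} not in [0, 1]"
            )

    @property
    def n_landmarks(self) -> int:
        return self.landmarks.shape[0]


def _sort_key(leaf: Leaf) -> tuple[str, int, str]:
    return (leaf.vine_id, leaf.node_index, leaf.leaf_id)


@dataclass(frozen=True)
class LeafDataset:
    """A collection of leaves under one landmark scheme.

    Iteration order is deterministic: sorted by (vine_id, node_index,
    leaf_id).
    """

    scheme: LandmarkScheme
    leaves: tuple[Leaf, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.leaves, key=_sort_key))
        object.__setattr__(self, "leaves", ordered)
        seen: set[str] = set()
        for leaf in ordered:
            if leaf.n_landmarks != self.scheme.n_landmarks:
                raise SchemaError(
                    f"leaf {leaf.leaf_id!r} has {leaf.n_landmarks} landmarks; "
                    f"scheme {self.scheme.name!r} requires {self.scheme.n_landmarks}"
                )
            if leaf.leaf_id in seen:
                raise IntegrityError(f"duplicate leaf_id {leaf.leaf_id!r}")
            seen.add(leaf.leaf_id)

    def __len__(self) -> int:
        return len(self.leaves)

    def __iter__(self) -> Iterator[Leaf]:
        return iter(self.leaves)

    @property
    def leaf_ids(self) -> tuple[str, ...]:
        return tuple(leaf.leaf_id for leaf in self.leaves)

    @property
    def group_labels(self) -> tuple[str, ...]:
        return tuple(leaf.group_label for leaf in self.leaves)

    def vines(self) -> dict[str, tuple[Leaf, ...]]:
        """Leaves grouped by vine_id, preserving dataset order."""
        out: dict[str, list[Leaf]] = {}
        for leaf in self.leaves:
            out.setdefault(leaf.vine_id, []).append(leaf)
        return {k: tuple(v) for k, v in out.items()}

    def with_leaves(self, leaves: Iterable[Leaf], provenance: str | None = None) -> "LeafDataset":
        return LeafDataset(
            self.scheme,
            tuple(leaves),
            self.provenance if provenance is None else provenance,
        )

    def coordinate_matrix(self) -> np.ndarray:
        """Stack flattened landmarks into an (n_leaves, 2n) array."""
        return np.array([leaf.landmarks.ravel() for leaf in self.leaves], dtype=float)


def default_column_map(scheme: LandmarkScheme) -> dict[str, object]:
    """Column mapping for the standard layout: metadata columns plus x1,y1,...

    This matches the layout written by :func:`write_landmark_table` and the
    usual public deposits of per-leaf landmark tables (one row per leaf,
    interleaved coordinate columns).
    """
    coords: list[str] = []
    for i in range(1, scheme.n_landmarks + 1):
        coords.extend([f"x{i}", f"y{i}"])
    return {
        "leaf_id": "leaf_id",
        "group_label": "group_label",
        "vine_id": "vine_id",
        "node_index": "node_index",
        "coord_columns": coords,
    }


def _read_frame(source, sep: str | None) -> pd.DataFrame:
    if sep is None:
        name = getattr(source, "name", source if isinstance(source, (str, Path)) else "")
        sep = "\t" if str(name).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(source, sep=sep, dtype=str)


def read_landmark_table(
    source,
    scheme: LandmarkScheme,
    column_map: Mapping[str, object] | None = None,
    sep: str | None = None,
    provenance: str = "",
) -> LeafDataset:
    """Read a delimited landmark table into a validated :class:`LeafDataset`.

    Parameters
    ----------
    source
        Path or text stream of a delimited table with a header row.
    scheme
        Landmark scheme the table must conform to.
    column_map
        Mapping with keys ``leaf_id``, ``group_label``, ``vine_id``,
        ``node_index`` (column names) and ``coord_columns`` (the 2n
        coordinate columns in x1,y1,x2,y2,... order). Defaults to
        :func:`default_column_map`.
    sep
        Field delimiter; autodetected from the file extension when None
        (TSV for ``.tsv``/``.tab``, comma otherwise).

    Rows with missing coordinates are dropped with a warning listing the
    offending row numbers (1-based, excluding the header).
    """
    cmap = dict(column_map) if column_map is not None else default_column_map(scheme)
    coord_cols = list(cmap["coord_columns"])
    if len(coord_cols) != 2 * scheme.n_landmarks:
        raise SchemaError(
            f"scheme {scheme.name!r} needs {2 * scheme.n_landmarks} coordinate "
            f"columns, column_map names {len(coord_cols)}: {coord_cols}"
        )
    frame = _read_frame(source, sep)
    missing = [c for c in coord_cols if c not in frame.columns]
    meta_cols = [cmap["leaf_id"], cmap["group_label"], cmap["vine_id"], cmap["node_index"]]
    missing += [c for c in meta_cols if c not in frame.columns]
    if missing:
        raise SchemaError(f"columns missing from table: {missing}")

    leaves: list[Leaf] = []
    dropped: list[int] = []
    for pos, (_, row) in enumerate(frame.iterrows(), start=1):
        raw = row[coord_cols]
        if raw.isna().any():
            dropped.append(pos)
            continue
        try:
            values = raw.astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric coordinate in row {pos}: {exc}") from exc
        try:
            node = int(float(row[cmap["node_index"]]))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric node_index in row {pos}") from exc
        rel_col = cmap.get("relative_node", "relative_node")
        relative = None
        if rel_col in frame.columns and not pd.isna(row[rel_col]):
            try:
                relative = float(row[rel_col])
            except (TypeError, ValueError) as exc:
                raise ParseError(f"non-numeric relative_node in row {pos}") from exc
        leaves.append(
            Leaf(
                leaf_id=str(row[cmap["leaf_id"]]),
                group_label=str(row[cmap["group_label"]]),
                vine_id=str(row[cmap["vine_id"]]),
                node_index=node,
                landmarks=values.reshape(-1, 2),
                relative_node=relative,
            )
        )
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} row(s) with missing coordinates: {dropped}",
            stacklevel=2,
        )
    return LeafDataset(scheme, tuple(leaves), provenance=provenance)


def write_landmark_table(dataset: LeafDataset, target, sep: str | None = None) -> None:
    """Write a dataset in the standard layout (see :func:`default_column_map`).

    Coordinates are written with shortest round-tripping repr, so
    read -> write -> read preserves them bit-for-bit.
    """
    if sep is None:
        sep = "\t" if str(target).endswith((".tsv", ".tab")) else ","
    cmap = default_column_map(dataset.scheme)
    rows = []
    for leaf in dataset:
        row: dict[str, object] = {
            "leaf_id": leaf.leaf_id,
            "group_label": leaf.group_label,
            "vine_id": leaf.vine_id,
            "node_index": leaf.node_index,
        }
        if leaf.relative_node is not None:
            row["relative_node"] = repr(leaf.relative_node)
        for col, value in zip(cmap["coord_columns"], leaf.landmarks.ravel()):
            row[col] = repr(float(value))
        rows.append(row)
    columns = ["leaf_id", "group_label", "vine_id", "node_index"]
    if any("relative_node" in r for r in rows):
        columns.append("relative_node")
    columns += list(cmap["coord_columns"])
    pd.DataFrame(rows, columns=columns).to_csv(target, sep=sep, index=False)


def dataset_to_json(dataset: LeafDataset) -> str:
    """Serialize scheme + leaves to a single JSON document (fixture format)."""
    doc = {
        "scheme": {
            "name": dataset.scheme.name,
            "n_landmarks": dataset.scheme.n_landmarks,
            "landmark_names": list(dataset.scheme.landmark_names),
            "axis_indices": list(dataset.scheme.axis_indices)
            if dataset.scheme.axis_indices
            else None,
        },
        "provenance": dataset.provenance,
        "leaves": [
            {
                "leaf_id": leaf.leaf_id,
                "group_label": leaf.group_label,
                "vine_id": leaf.vine_id,
                "node_index": leaf.node_index,
                "relative_node": leaf.relative_node,
                "landmarks": leaf.landmarks.tolist(),
            }
            for leaf in dataset
        ],
    }
    return json.dumps(doc, indent=1)


def dataset_from_json(text: str) -> LeafDataset:
    doc = json.loads(text)
    s = doc["scheme"]
    scheme = LandmarkScheme(
        s["name"],
        s["n_landmarks"],
        tuple(s["landmark_names"]),
        tuple(s["axis_indices"]) if s.get("axis_indices") else None,
    )
    leaves = tuple(
        Leaf(
            leaf_id=item["leaf_id"],
            group_label=item["group_label"],
            vine_id=item["vine_id"],
            node_index=item["node_index"],
            landmarks=np.asarray(item["landmarks"], dtype=float),
            relative_node=item.get("relative_node"),
        )
        for item in doc["leaves"]
    )
    return LeafDataset(scheme, leaves, provenance=doc.get("provenance", ""))


def assign_relative_node(dataset: LeafDataset) -> LeafDataset:
    """Assign relative node positions per vine: 0 = growing tip, 1 = shoot base.

    Within each vine the observed node indices are ranked from the tip
    (node_index 1 is the youngest leaf); a leaf at rank k of N distinct
    nodes gets relative_node (k - 1) / (N - 1). Ranks, not raw indices,
    are used so vines with collection gaps still span [0, 1]. Vines with a
    single leaf are excluded with a warning.
    """
    out: list[Leaf] = []
    skipped: list[str] = []
    for vine_id, vine_leaves in dataset.vines().items():
        nodes = [leaf.node_index for leaf in vine_leaves]
        if len(set(nodes)) != len(nodes):
            dupes = sorted({n for n in nodes if nodes.count(n) > 1})
            raise IntegrityError(
                f"vine {vine_id!r}: duplicate node_index values {dupes}"
            )
        if len(nodes) < 2:
            skipped.append(vine_id)
            continue
        order = sorted(nodes)
        n = len(order)
        rank = {node: i for i, node in enumerate(order)}
        for leaf in vine_leaves:
            out.append(replace(leaf, relative_node=rank[leaf.node_index] / (n - 1)))
    if skipped:
        warnings.warn(
            f"excluded {len(skipped)} single-leaf vine(s): {skipped}", stacklevel=2
        )
    if not out:
        raise EmptyResultError("no vine has >= 2 leaves; nothing to assign")
    return dataset.with_leaves(out)


def subset_shared_landmarks(
    dataset: LeafDataset, selection: Sequence[int], name: str | None = None
) -> LeafDataset:
    """Restrict every leaf to the selected landmark indices, in selection order."""
    sel = list(selection)
    if not sel:
        raise SchemaError("empty landmark selection")
    if len(set(sel)) != len(sel):
        raise SchemaError(f"selection contains duplicates: {sel}")
    n = dataset.scheme.n_landmarks
    bad = [i for i in sel if not 0 <= i < n]
    if bad:
        raise IndexError(f"landmark indices out of range for scheme: {bad}")
    axis = dataset.scheme.axis_indices
    new_axis = None
    if axis is not None and axis[0] in sel and axis[1] in sel:
        new_axis = (sel.index(axis[0]), sel.index(axis[1]))
    scheme = LandmarkScheme(
        name or f"{dataset.scheme.name}_subset",
        len(sel),
        tuple(dataset.scheme.landmark_names[i] for i in sel),
        axis_indices=new_axis,
    )
    leaves = tuple(
        Leaf(
            leaf_id=leaf.leaf_id,
            group_label=leaf.group_label,
            vine_id=leaf.vine_id,
            node_index=leaf.node_index,
            landmarks=leaf.landmarks[sel],
            relative_node=leaf.relative_node,
        )
        for leaf in dataset
    )
    return LeafDataset(scheme, leaves, provenance=dataset.provenance)


def _reflect_points(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Mirror points across the line through a and b."""
    d = b - a
    norm2 = float(d @ d)
    if norm2 == 0.0:
        raise GeometryError("axis landmarks coincide; reflection line undefined")
    u = d / np.sqrt(norm2)
    rel = points - a
    # reflection: 2 (rel . u) u - rel, shifted back
    return a + 2.0 * np.outer(rel @ u, u) - rel


def reflect_to_complete(leaf: Leaf, axis_indices: tuple[int, int]) -> Leaf:
    """Complete a half-sampled leaf by mirroring across its midline.

    Every non-axis landmark is reflected across the line through the two
    axis landmarks (petiolar-junction base -> leaf tip) and appended in the
    original landmark order; axis landmarks are kept once. A leaf with n
    landmarks becomes one with 2n - 2.
    """
    i, j = axis_indices
    a, b = leaf.landmarks[i], leaf.landmarks[j]
    mirrored = _reflect_points(leaf.landmarks, a, b)
    keep = [k for k in range(leaf.n_landmarks) if k not in (i, j)]
    landmarks = np.vstack([leaf.landmarks, mirrored[keep]])
    return Leaf(
        leaf_id=leaf.leaf_id,
        group_label=leaf.group_label,
        vine_id=leaf.vine_id,
        node_index=leaf.node_index,
        landmarks=landmarks,
        relative_node=leaf.relative_node,
    )


def reflect_dataset(dataset: LeafDataset, axis_indices: tuple[int, int] | None = None) -> LeafDataset:
    """Apply :func:`reflect_to_complete` to every leaf, deriving a new scheme."""
    axis = axis_indices if axis_indices is not None else dataset.scheme.axis_indices
    if axis is None:
        raise GeometryError(
            f"scheme {dataset.scheme.name!r} has no reflection axis"
        )
    i, j = axis
    old = dataset.scheme
    names = list(old.landmark_names) + [
        f"{old.landmark_names[k]}_mirror" for k in range(old.n_landmarks) if k not in (i, j)
    ]
    scheme = LandmarkScheme(
        f"{old.name}_completed", 2 * old.n_landmarks - 2, tuple(names), axis_indices=axis
    )
    leaves = tuple(reflect_to_complete(leaf, axis) for leaf in dataset)
    return LeafDataset(scheme, leaves, provenance=dataset.provenance)


def _require_relative(dataset: LeafDataset, op: str) -> None:
    unset = [leaf.leaf_id for leaf in dataset if leaf.relative_node is None]
    if unset:
        raise StateError(
            f"{op}: relative_node unset for {len(unset)} leaf/leaves "
            f"(first: {unset[:3]}); run assign_relative_node first"
        )


def split_by_position(
    dataset: LeafDataset, threshold: float = 0.5
) -> tuple[LeafDataset, LeafDataset]:
    """Partition into (shoot base, growing tip) at a relative-node threshold.

    Under the 0 = tip convention, the growing tip half is
    relative_node <= threshold (boundary leaves go to the tip) and the
    shoot base is relative_node > threshold.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    _require_relative(dataset, "split_by_position")
    tip = [leaf for leaf in dataset if leaf.relative_node <= threshold]
    base = [leaf for leaf in dataset if leaf.relative_node > threshold]
    return (
        dataset.with_leaves(base, provenance=f"{dataset.provenance}|base>{threshold}"),
        dataset.with_leaves(tip, provenance=f"{dataset.provenance}|tip<={threshold}"),
    )


def split_by_vine_mean(dataset: LeafDataset) -> tuple[LeafDataset, LeafDataset]:
    """Partition into (heteroblastic, ontogenetic) leaf series per vine.

    Leaves at or below their vine's mean relative node (closer to the
    growing tip, still expanding) form the ontogenetic series; leaves above
    the mean form the heteroblastic series.
    """
    _require_relative(dataset, "split_by_vine_mean")
    means = {
        vine_id: float(np.mean([leaf.relative_node for leaf in vine_leaves]))
        for vine_id, vine_leaves in dataset.vines().items()
    }
    onto = [leaf for leaf in dataset if leaf.relative_node <= means[leaf.vine_id]]
    hetero = [leaf for leaf in dataset if leaf.relative_node > means[leaf.vine_id]]
    return (
        dataset.with_leaves(hetero, provenance=f"{dataset.provenance}|heteroblastic"),
        dataset.with_leaves(onto, provenance=f"{dataset.provenance}|ontogenetic"),
    )
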