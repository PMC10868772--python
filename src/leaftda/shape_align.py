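"""Procrustes superimposition of landmark configurations.

Removes translation, scale, and rotation so that only shape remains:
pairwise orthogonal Procrustes and iterative generalized Procrustes
analysis (GPA) to a converged mean shape. Rotations are proper
(determinant +1); reflections are never introduced implicitly, because
leaf handedness is biologically meaningful. Mirror-image completion is
an explicit, separate operation (``reflect_to_complete``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from leaftda.errors import GeometryError
from leaftda.landmark_io import Leaf, LeafDataset

__all__ = ["ShapeVector", "AlignmentResult", "flatten", "procrustes_pair", "gpa"]


@dataclass(frozen=True)
class ShapeVector:
    """A leaf's landmarks flattened to (x1, y1, x2, y2, ..., xn, yn)."""

    leaf_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size % 2 != 0:
            raise ValueError(f"shape vector for {self.leaf_id!r} must be 1-D of even length")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"shape vector for {self.leaf_id!r} has non-finite entries")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of generalized Procrustes analysis.

    ``aligned`` holds the superimposed coordinates; ``mean_shape`` is the
    converged consensus (centroid at origin, centroid size 1).
    """

    aligned: LeafDataset
    mean_shape: np.ndarray
    iterations: int
    final_change: float
    converged: bool
    objective_history: tuple[float, ...] = ()


def flatten(leaf: Leaf) -> ShapeVector:
    """Flatten a leaf's (n, 2) landmarks to a 2n-vector in x,y interleaved order."""
    return ShapeVector(leaf.leaf_id, leaf.landmarks.ravel())


def centroid_size(points: np.ndarray) -> float:
    """Root summed squared distance of landmarks to their centroid."""
    centered = points - points.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def _normalize(points: np.ndarray, label: str = "shape") -> np.ndarray:
    """Center at the origin and scale to unit centroid size."""
    centered = points - points.mean(axis=0)
    size = np.sqrt((centered**2).sum())
    if size == 0.0:
        raise GeometryError(f"{label}: all landmarks coincident; cannot normalize")
    return centered / size


def _optimal_rotation(target: np.ndarray, reference: np.ndarray, allow_reflection: bool) -> np.ndarray:
    """Rotation R (2x2) minimizing ||target @ R - reference||_F.

    Standard orthogonal Procrustes via SVD of target^T reference; the
    determinant is forced to +1 unless reflections are allowed.
    """
    u, _, vt = np.linalg.svd(target.T @ reference)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


def _canonical_rotation(mean: np.ndarray) -> np.ndarray:
    """Proper rotation bringing a mean shape to a canonical orientation.

    Aligns the shape's principal axes with the coordinate axes (major axis
    on x), then resolves the remaining 180-degree ambiguity by requiring
    the first landmark's x (or, if that is ~0, y) coordinate to be
    non-negative. Makes GPA output invariant to global rotation of the
    input dataset. Unstable only for exactly isotropic means.
    """
    cov = mean.T @ mean
    _, vecs = np.linalg.eigh(cov)
    r = vecs[:, ::-1]  # major axis first
    if np.linalg.det(r) < 0:
        r[:, 1] *= -1.0
    first = mean @ r
    if first[0, 0] < -1e-12 or (abs(first[0, 0]) <= 1e-12 and first[0, 1] < 0):
        r = -r  # 180-degree rotation (proper in 2-D)
    return r


def procrustes_pair(
    reference: Leaf, target: Leaf, allow_reflection: bool = False
) -> tuple[Leaf, float]:
    """Superimpose ``target`` onto ``reference``.

    Both configurations are centered and scaled to unit centroid size; the
    target is then rotated (properly, unless ``allow_reflection``) to
    minimize the summed squared landmark distance. Returns the aligned
    target and the minimized sum (the Procrustes disparity).
    """
    if reference.n_landmarks != target.n_landmarks:
        raise GeometryError(
            f"landmark counts differ: {reference.n_landmarks} vs {target.n_landmarks}"
        )
    if reference.n_landmarks < 2:
        raise GeometryError("need at least 2 landmarks")
    ref = _normalize(reference.landmarks, f"reference {reference.leaf_id!r}")
    tgt = _normalize(target.landmarks, f"target {target.leaf_id!r}")
    rot = _optimal_rotation(tgt, ref, allow_reflection)
    aligned = tgt @ rot
    disparity = float(((aligned - ref) ** 2).sum())
    new_leaf = Leaf(
        leaf_id=target.leaf_id,
        group_label=target.group_label,
        vine_id=target.vine_id,
        node_index=target.node_index,
        landmarks=aligned,
        relative_node=target.relative_node,
    )
    return new_leaf, max(disparity, 0.0)


def gpa(
    dataset: LeafDataset,
    tol: float = 1e-7,
    max_iter: int = 100,
    allow_reflection: bool = False,
) -> AlignmentResult:
    """Generalized Procrustes analysis of a dataset.

    Iterates: rotate every (unit-size, centered) configuration to the
    current mean, recompute and renormalize the mean, until the root summed
    squared change of the mean drops below ``tol``. The initial mean is the
    first leaf after normalization, so the result is deterministic for a
    fixed dataset order. The objective (sum of squared distances to the
    mean) is non-increasing across iterations.
    """
    if len(dataset) == 0:
        raise GeometryError("cannot align an empty dataset")
    shapes = [
        _normalize(leaf.landmarks, f"leaf {leaf.leaf_id!r}") for leaf in dataset
    ]
    mean = shapes[0].copy()
    iterations = 0
    change = np.inf
    objective: list[float] = []
    if len(shapes) == 1:
        iterations = 1
        change = 0.0
        objective.append(0.0)
    else:
        for iterations in range(1, max_iter + 1):
            shapes = [
                s @ _optimal_rotation(s, mean, allow_reflection) for s in shapes
            ]
            objective.append(float(sum(((s - mean) ** 2).sum() for s in shapes)))
            new_mean = _normalize(np.mean(shapes, axis=0), "mean shape")
            change = float(np.sqrt(((new_mean - mean) ** 2).sum()))
            mean = new_mean
            if change < tol:
                break
    converged = change < tol
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations (last change {change:.3e})",
            stacklevel=2,
        )
    # canonical orientation, then a final rotation pass onto the mean
    canon = _canonical_rotation(mean)
    mean = mean @ canon
    shapes = [s @ _optimal_rotation(s, mean, allow_reflection) for s in shapes]
    leaves = tuple(
        Leaf(
            leaf_id=leaf.leaf_id,
            group_label=leaf.group_label,
            vine_id=leaf.vine_id,
            node_index=leaf.node_index,
            landmarks=aligned,
            relative_node=leaf.relative_node,
        )
        for leaf, aligned in zip(dataset, shapes)
    )
    aligned_ds = dataset.with_leaves(
        leaves, provenance=f"{dataset.provenance}|gpa"
    )
    return AlignmentResult(
        aligned=aligned_ds,
        mean_shape=mean,
        iterations=iterations,
        final_change=change,
        converged=converged,
        objective_history=tuple(objective),
    )
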