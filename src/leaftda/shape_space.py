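"""Ordination of flattened leaf shapes: PCA morphospaces and LDA.

PCA (via scikit-learn, wrapped with a deterministic sign convention)
supplies both the morphospace visualization -- eigenleaf reconstruction
through the inverse transform -- and the PC1 lens used by the Mapper
stage. LDA separates the four genus x shoot-position groups; the fit
solves the between/within generalized eigenproblem directly so the
within-class scatter can be ridge-regularized deterministically, and is
cross-checked against scikit-learn in the test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
from sklearn.decomposition import PCA as _SKPCA

from leaftda.errors import InsufficientDataError
from leaftda.shape_align import ShapeVector

__all__ = [
    "PCAModel",
    "LDAModel",
    "pca_fit",
    "pca_transform",
    "pca_inverse",
    "morphospace_grid",
    "lda_fit",
    "lda_transform",
    "lda_predict",
]


def _as_matrix(vectors: Sequence[ShapeVector]) -> tuple[np.ndarray, list[str]]:
    if len(vectors) == 0:
        raise InsufficientDataError("no shape vectors supplied")
    lengths = {v.values.size for v in vectors}
    if len(lengths) != 1:
        raise InsufficientDataError(f"mixed vector lengths: {sorted(lengths)}")
    return np.array([v.values for v in vectors], dtype=float), [v.leaf_id for v in vectors]


def _fix_signs(axes: np.ndarray) -> np.ndarray:
    """Flip each row so its largest-|loading| entry is positive.

    PCA/LDA axis signs are arbitrary; a fixed convention keeps lens values
    and plots reproducible across runs and library versions.
    """
    out = axes.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


@dataclass(frozen=True)
class PCAModel:
    """Principal components of centered shape vectors.

    ``components`` rows are unit-norm and mutually orthogonal;
    ``explained_variance`` is non-increasing.
    """

    mean_vector: np.ndarray
    components: np.ndarray  # (k, 2n)
    explained_variance: np.ndarray
    total_variance: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean_vector": self.mean_vector.tolist(),
                "components": self.components.tolist(),
                "explained_variance": self.explained_variance.tolist(),
                "total_variance": self.total_variance,
            }
        )


def pca_fit(vectors: Sequence[ShapeVector], n_components: int | None = None) -> PCAModel:
    """Fit a PCA model to flattened shapes.

    ``n_components`` defaults to min(n_samples - 1, dimension). Explained
    variances use the usual n-1 denominator.
    """
    x, _ = _as_matrix(vectors)
    if x.shape[0] < 2:
        raise InsufficientDataError("PCA needs at least 2 shape vectors")
    limit = min(x.shape[0] - 1, x.shape[1])
    if n_components is None:
        n_components = limit
    if not 1 <= n_components <= limit:
        raise InsufficientDataError(
            f"n_components must be in [1, {limit}], got {n_components}"
        )
    sk = _SKPCA(n_components=n_components, svd_solver="full")
    sk.fit(x)
    centered = x - x.mean(axis=0)
    total = float((centered**2).sum() / (x.shape[0] - 1))
    return PCAModel(
        mean_vector=x.mean(axis=0),
        components=_fix_signs(sk.components_),
        explained_variance=sk.explained_variance_.copy(),
        total_variance=total,
    )


def pca_transform(model: PCAModel, v: ShapeVector | np.ndarray) -> np.ndarray:
    """Project a shape vector onto the principal components."""
    values = v.values if isinstance(v, ShapeVector) else np.asarray(v, dtype=float)
    if values.shape[-1] != model.mean_vector.size:
        raise ValueError(
            f"vector length {values.shape[-1]} != model dimension {model.mean_vector.size}"
        )
    return (values - model.mean_vector) @ model.components.T


def pca_inverse(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Reconstruct a shape vector from component scores (mean + sum s_i c_i)."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape[-1] > model.n_components:
        raise ValueError(
            f"{scores.shape[-1]} scores for a model with {model.n_components} components"
        )
    return model.mean_vector + scores @ model.components[: scores.shape[-1]]


def morphospace_grid(
    model: PCAModel, pc_indices: tuple[int, int], grid: Sequence[tuple[float, float]]
) -> list[np.ndarray]:
    """Reconstruct landmark shapes over a grid of scores on two components.

    Each grid point (s_a, s_b) is embedded as a full score vector with
    zeros elsewhere and pushed through the inverse transform; the result
    is a list of (n, 2) landmark arrays tracing the morphospace.
    """
    a, b = pc_indices
    for idx in (a, b):
        if not 0 <= idx < model.n_components:
            raise ValueError(f"component index {idx} out of range")
    shapes = []
    for sa, sb in grid:
        scores = np.zeros(model.n_components)
        scores[a] = sa
        scores[b] = sb
        shapes.append(pca_inverse(model, scores).reshape(-1, 2))
    return shapes


@dataclass(frozen=True)
class LDAModel:
    """Fisher discriminant axes for labeled shape vectors.

    At most (n_classes - 1) axes; classification is by nearest class mean
    in discriminant space.
    """

    class_labels: tuple[str, ...]
    discriminant_axes: np.ndarray  # (k, 2n)
    class_means: np.ndarray  # (n_classes, k) scores of class centroids
    grand_mean: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.discriminant_axes.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "class_labels": list(self.class_labels),
                "discriminant_axes": self.discriminant_axes.tolist(),
                "class_means": self.class_means.tolist(),
                "grand_mean": self.grand_mean.tolist(),
            }
        )


def lda_fit(vectors: Sequence[ShapeVector], labels: Sequence[str]) -> LDAModel:
    """Fit Fisher LDA maximizing between- to within-class scatter.

    Solves the generalized eigenproblem Sb v = l Sw v with scipy; a ridge
    term (1e-6 * trace(Sw)/dim, plus an absolute floor) is added to Sw when
    it is singular -- possible when the dimension exceeds the sample count
    -- with a warning. Axis signs follow the same convention as PCA.
    """
    x, _ = _as_matrix(vectors)
    labels = [str(l) for l in labels]
    if len(labels) != x.shape[0]:
        raise InsufficientDataError(
            f"{len(labels)} labels for {x.shape[0]} vectors"
        )
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise InsufficientDataError("LDA needs at least 2 classes")
    counts = {c: labels.count(c) for c in classes}
    small = [c for c, k in counts.items() if k < 2]
    if small:
        raise InsufficientDataError(f"classes with fewer than 2 members: {small}")

    grand = x.mean(axis=0)
    centered_all = x - grand
    # Work in the range of the total scatter: aligned shape coordinates are
    # rank-deficient (Procrustes superimposition removes translation, size
    # and rotation degrees of freedom), and discriminant directions in that
    # null space are artifacts, not structure.
    _, s, vt = np.linalg.svd(centered_all, full_matrices=False)
    basis = vt[s > 1e-9 * s[0]]
    z = centered_all @ basis.T
    dim = z.shape[1]

    sw = np.zeros((dim, dim))
    sb = np.zeros((dim, dim))
    for c in classes:
        zc = z[[i for i, l in enumerate(labels) if l == c]]
        mc = zc.mean(axis=0)
        centered = zc - mc
        sw += centered.T @ centered
        diff = mc[:, None]
        sb += zc.shape[0] * (diff @ diff.T)

    # regularize if within-class scatter is still (near-)singular
    if np.linalg.matrix_rank(sw, hermitian=True) < dim:
        lam = 1e-6 * np.trace(sw) / dim
        if lam <= 0:
            lam = 1e-12
        warnings.warn(
            f"singular within-class scatter; applying ridge lambda={lam:.3e}",
            stacklevel=2,
        )
        sw = sw + lam * np.eye(dim)

    eigvals, eigvecs = scipy.linalg.eigh(sb, sw)
    order = np.argsort(eigvals)[::-1]
    n_axes = min(len(classes) - 1, dim)
    axes = eigvecs[:, order[:n_axes]].T @ basis
    axes = axes / np.linalg.norm(axes, axis=1, keepdims=True)
    axes = _fix_signs(axes)

    class_means = np.array(
        [
            (x[[i for i, l in enumerate(labels) if l == c]].mean(axis=0) - grand) @ axes.T
            for c in classes
        ]
    )
    return LDAModel(
        class_labels=tuple(classes),
        discriminant_axes=axes,
        class_means=class_means,
        grand_mean=grand,
    )


def lda_transform(model: LDAModel, v: ShapeVector | np.ndarray) -> np.ndarray:
    """Project a shape vector onto the discriminant axes."""
    values = v.values if isinstance(v, ShapeVector) else np.asarray(v, dtype=float)
    return (values - model.grand_mean) @ model.discriminant_axes.T


def lda_predict(model: LDAModel, v: ShapeVector | np.ndarray) -> str:
    """Classify by nearest class mean in discriminant space."""
    scores = lda_transform(model, v)
    dists = np.linalg.norm(model.class_means - scores, axis=1)
    return model.class_labels[int(np.argmin(dists))]
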