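"""Static figures: Mapper graphs with pie-chart vertices, subway maps
with mean-shape glyphs, and PCA/LDA score scatters.

Layouts are seeded and label colors follow a fixed lexicographic order,
so reruns produce identical figures.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from leaftda.mapper_tda import MapperGraph

__all__ = ["plot_mapper", "plot_subway", "plot_scores", "label_colors"]

_LAYOUT_SEED = 12


def label_colors(labels) -> dict[str, tuple]:
    """Deterministic label -> color assignment (lexicographic order)."""
    ordered = sorted(set(labels))
    cmap = plt.get_cmap("tab20")
    return {lab: cmap(i % 20) for i, lab in enumerate(ordered)}


def _layout(graph: MapperGraph) -> dict[str, np.ndarray]:
    g = graph.to_networkx()
    # seed the spring layout and nudge x toward the lens coordinate so the
    # spine reads left-to-right
    pos = nx.spring_layout(g, seed=_LAYOUT_SEED)
    for v in graph.vertices:
        x, y = pos[v.vertex_id]
        pos[v.vertex_id] = np.array([0.7 * v.mean_lens * 4 + 0.3 * x, y])
    return pos


def plot_mapper(graph: MapperGraph, path: str | Path, title: str | None = None) -> None:
    """Draw a Mapper graph with pie-chart vertices colored by group composition."""
    fig, ax = plt.subplots(figsize=(9, 6))
    if graph.n_vertices == 0:
        ax.text(0.5, 0.5, "empty graph", ha="center")
        fig.savefig(path, dpi=110)
        plt.close(fig)
        return
    pos = _layout(graph)
    all_labels = sorted({lab for v in graph.vertices for lab in v.composition})
    colors = label_colors(all_labels)
    for (a, b), _ in sorted(graph.edges.items()):
        xa, ya = pos[a]
        xb, yb = pos[b]
        ax.plot([xa, xb], [ya, yb], color="0.6", lw=1.0, zorder=1)
    max_size = max(v.size for v in graph.vertices)
    for v in graph.vertices:
        x, y = pos[v.vertex_id]
        radius = 0.06 + 0.10 * np.sqrt(v.size / max_size)
        start = 0.0
        comp = v.composition or {"": 1.0}
        for lab in sorted(comp):
            frac = comp[lab]
            wedge = plt.matplotlib.patches.Wedge(
                (x, y),
                radius,
                360 * start,
                360 * (start + frac),
                color=colors.get(lab, "0.4"),
                zorder=2,
            )
            ax.add_patch(wedge)
            start += frac
    handles = [
        plt.Line2D([], [], marker="o", ls="", color=colors[lab], label=lab)
        for lab in all_labels
    ]
    if handles:
        ax.legend(handles=handles, fontsize=7, loc="upper left", ncols=2)
    ax.set_title(title or f"Mapper ({graph.params.get('lens_name', '?')} lens)")
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def plot_subway(graph: MapperGraph, path: str | Path, glyph_scale: float = 0.45) -> None:
    """Subway map: the primary structure with mean-shape glyphs at vertices."""
    fig, ax = plt.subplots(figsize=(10, 6))
    if graph.n_vertices == 0:
        ax.text(0.5, 0.5, "empty graph", ha="center")
        fig.savefig(path, dpi=110)
        plt.close(fig)
        return
    pos = _layout(graph)
    for (a, b), _ in sorted(graph.edges.items()):
        xa, ya = pos[a]
        xb, yb = pos[b]
        ax.plot([xa, xb], [ya, yb], color="0.7", lw=2.0, zorder=1)
    for v in graph.vertices:
        x, y = pos[v.vertex_id]
        if v.mean_shape is None:
            ax.plot(x, y, "o", color="0.3")
            continue
        shape = np.asarray(v.mean_shape, dtype=float)
        shape = shape - shape.mean(axis=0)
        norm = np.sqrt((shape**2).sum())
        if norm > 0:
            shape = shape / norm * glyph_scale
        poly = np.vstack([shape, shape[:1]]) + np.array([x, y])
        ax.fill(poly[:, 0], poly[:, 1], color=plt.get_cmap("viridis")(v.mean_lens), alpha=0.85, zorder=2)
    ax.set_title("Subway map (vertex = mean leaf shape, color = mean heteroblasty)")
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def plot_scores(score_table: pd.DataFrame, outdir: str | Path) -> None:
    """PCA scatter (by group and by heteroblasty) and LDA scatter (4 groups)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    fig, axes = plt.subplots(1, 2, figsize=(12, 5))
    colors = label_colors(score_table["group4"])
    for lab, sub in score_table.groupby("group4"):
        axes[0].scatter(sub["pc1"], sub["pc2"], s=9, color=colors[lab], label=lab, alpha=0.7)
    axes[0].legend(fontsize=7)
    axes[0].set_xlabel("PC1")
    axes[0].set_ylabel("PC2")
    axes[0].set_title("Joint morphospace by genus x position")
    sc = axes[1].scatter(
        score_table["pc1"],
        score_table["pc2"],
        c=score_table["relative_node"],
        cmap="viridis",
        s=9,
    )
    fig.colorbar(sc, ax=axes[1], label="relative node (0 = tip)")
    axes[1].set_xlabel("PC1")
    axes[1].set_ylabel("PC2")
    axes[1].set_title("Joint morphospace by heteroblasty")
    fig.savefig(out / "pca_scatter.png", dpi=110, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6.5, 5))
    for lab, sub in score_table.groupby("group4"):
        ax.scatter(sub["ld1"], sub["ld2"], s=9, color=colors[lab], label=lab, alpha=0.7)
    ax.legend(fontsize=7)
    ax.set_xlabel("LD1")
    ax.set_ylabel("LD2")
    ax.set_title("Linear discriminants of the four groups")
    fig.savefig(out / "lda_scatter.png", dpi=110, bbox_inches="tight")
    plt.close(fig)
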