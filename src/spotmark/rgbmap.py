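"""RGB color-space mapping of per-cell transcriptomes.

Keratin-positive (tumor) cells are embedded into three components with a
nonlinear reducer; each component is rescaled to 0-255 and mapped to the red,
green and blue channels respectively, so transcriptionally similar cells share
a color when plotted back at their tissue coordinates. Embeddings are computed
independently per sample and are never compared across samples.

A regular tiling of the tissue bounding box summarizes the cluster content of
each spatial block as a treemap: per block and cluster, the cell count and the
mean RGB color of that cluster's cells in the block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class RGBEmbedding:
    """Per-cell 3-component embedding and its 0-255 RGB rendering."""

    sample_id: str
    cell_ids: pd.Series
    coords: np.ndarray       # n x 3, finite
    rgb: np.ndarray          # n x 3, uint8-valued ints in [0, 255]


@dataclass
class TreemapBlock:
    block_id: str
    bounds: tuple[float, float, float, float]  # (x0, y0, x1, y1)
    entries: list[dict] = field(default_factory=list)  # cluster, count, mean_rgb


@dataclass
class TreemapSummary:
    blocks: list[TreemapBlock]
    total_cells: int


def _round_half_away(v: np.ndarray) -> np.ndarray:
    """Round half away from zero (inputs here are non-negative)."""
    return np.floor(v + 0.5).astype(int)


def embed3(
    norm_counts: sparse.spmatrix,
    keratin_positive: np.ndarray,
    seed: int = 0,
    method: str = "umap",
    sample_id: str = "sample",
    cell_ids: pd.Series | None = None,
    **backend_kwargs,
) -> RGBEmbedding:
    """Reduce tumor-cell expression to 3 components.

    The caller must restrict the input to keratin-positive cells; the flag
    column is asserted here. Backends: ``"umap"`` (nonlinear, default) and
    ``"pca"`` (deterministic linear reducer, useful for fast exact tests).
    """
    flags = np.asarray(keratin_positive, dtype=bool)
    X = sparse.csr_matrix(norm_counts)
    if X.shape[0] != len(flags):
        raise ValueError("flag column length does not match cell count")
    if not flags.all():
        n_bad = int((~flags).sum())
        raise ValueError(
            f"{n_bad} keratin-negative cells present; exclude normal cells "
            "before dimension reduction"
        )
    if X.shape[0] < 10:
        raise ValueError(f"need at least 10 cells to embed, got {X.shape[0]}")
    if method == "umap":
        import warnings

        import umap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(n_components=3, random_state=seed, **backend_kwargs)
            coords = np.asarray(reducer.fit_transform(X), dtype=float)
    elif method == "pca":
        from sklearn.decomposition import PCA

        dense = X.toarray()
        coords = PCA(n_components=3, random_state=seed).fit_transform(dense)
    else:
        raise ValueError(f"unknown embedding backend {method!r}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("embedding produced non-finite coordinates")
    if cell_ids is None:
        cell_ids = pd.Series([f"cell_{i}" for i in range(X.shape[0])])
    rgb = scale_to_rgb(coords)
    return RGBEmbedding(sample_id=sample_id, cell_ids=cell_ids.reset_index(drop=True),
                        coords=coords, rgb=rgb)


def scale_to_rgb(embedding: np.ndarray) -> np.ndarray:
    """Rescale each embedding component to 0-255 and map to (R, G, B).

    Per channel: v' = round(255 * (v - min) / (max - min)), rounding half away
    from zero. A degenerate (constant) channel maps to all zeros. Invariant to
    positive-slope affine transforms of a channel.
    """
    coords = np.asarray(embedding, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("embedding must be n x 3")
    if coords.shape[0] < 1:
        raise ValueError("need at least one cell")
    if not np.all(np.isfinite(coords)):
        raise ValueError("embedding contains non-finite values")
    rgb = np.zeros_like(coords, dtype=int)
    for ch in range(3):
        v = coords[:, ch]
        lo, hi = v.min(), v.max()
        if hi > lo:
            rgb[:, ch] = _round_half_away(255.0 * (v - lo) / (hi - lo))
    return rgb


def spatial_rgb_table(cells: pd.DataFrame, embedding: RGBEmbedding) -> pd.DataFrame:
    """Join RGB colors onto tissue coordinates: one row per cell."""
    ids = cells["cell_id"].reset_index(drop=True)
    if sorted(ids) != sorted(embedding.cell_ids):
        raise ValueError("cell ids in the embedding do not match the cell table")
    emb = pd.DataFrame({
        "cell_id": embedding.cell_ids,
        "u1": embedding.coords[:, 0],
        "u2": embedding.coords[:, 1],
        "u3": embedding.coords[:, 2],
        "R": embedding.rgb[:, 0],
        "G": embedding.rgb[:, 1],
        "B": embedding.rgb[:, 2],
    })
    out = cells[["cell_id", "x", "y"]].merge(emb, on="cell_id", validate="1:1")
    return out


def render_rgb_map(table: pd.DataFrame, path, point_size: float = 2.0) -> None:
    """Draw one filled marker per cell at (x, y) in its RGB color.

    Axes span the tissue bounding box; y increases downward (image
    convention)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = table[["R", "G", "B"]].to_numpy(float) / 255.0
    fig, ax = plt.subplots(figsize=(8, 6))
    ax.scatter(table["x"], table["y"], s=point_size, c=colors, linewidths=0)
    ax.set_xlim(table["x"].min(), table["x"].max())
    ax.set_ylim(table["y"].max(), table["y"].min())
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def treemap_summary(
    cells: pd.DataFrame,
    cluster_labels: np.ndarray,
    rgb: np.ndarray,
    grid: tuple[int, int] = (8, 8),
) -> TreemapSummary:
    """Per spatial block: clusters present, cell counts and mean RGB.

    The tissue bounding box is tiled into an ``n_x x n_y`` regular grid. Tiles
    are half-open, ``[lo, hi)`` in x then y; cells on the global max edge fall
    into the last tile. Clusters with zero cells in a block are omitted.
    Counts conserve: sums over blocks equal the input cell count.
    """
    nx, ny = grid
    if nx < 1 or ny < 1:
        raise ValueError("grid must have at least one tile per axis")
    if len(cells) == 0:
        raise ValueError("empty cell table")
    labels = np.asarray(cluster_labels)
    rgb = np.asarray(rgb, dtype=float)
    x = cells["x"].to_numpy(float)
    y = cells["y"].to_numpy(float)
    x0, x1 = x.min(), x.max()
    y0, y1 = y.min(), y.max()
    wx = (x1 - x0) / nx if x1 > x0 else 1.0
    wy = (y1 - y0) / ny if y1 > y0 else 1.0
    ix = np.clip(((x - x0) / wx).astype(int), 0, nx - 1)
    iy = np.clip(((y - y0) / wy).astype(int), 0, ny - 1)

    blocks = []
    for j in range(ny):
        for i in range(nx):
            mask = (ix == i) & (iy == j)
            block = TreemapBlock(
                block_id=f"r{j}c{i}",
                bounds=(x0 + i * wx, y0 + j * wy, x0 + (i + 1) * wx, y0 + (j + 1) * wy),
            )
            if mask.any():
                for k in np.unique(labels[mask]):
                    sub = mask & (labels == k)
                    mean_rgb = _round_half_away(rgb[sub].mean(axis=0))
                    block.entries.append({
                        "cluster": int(k),
                        "count": int(sub.sum()),
                        "mean_rgb": [int(c) for c in mean_rgb],
                    })
            blocks.append(block)
    return TreemapSummary(blocks=blocks, total_cells=len(cells))


def treemap_to_dict(summary: TreemapSummary) -> dict:
    return {
        "total_cells": summary.total_cells,
        "blocks": [
            {"block_id": b.block_id, "bounds": list(b.bounds), "entries": b.entries}
            for b in summary.blocks
        ],
    }
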