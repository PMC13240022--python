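"""Per-cell neighbourhood metrics for integration quality.

Two scores over the k nearest neighbours of each cell in an embedding
(k = 30 by default): the batch mixing score (fraction of neighbours from a
different sample; higher = better mixing) and the tissue separation score
(fraction of neighbours of a different tissue type; lower = tighter
tissue clustering).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_K = 30


@dataclass
class NeighbourGraph:
    """k nearest neighbours per cell (self excluded), with distances."""

    indices: np.ndarray    # (n_cells, k) int
    distances: np.ndarray  # (n_cells, k) float
    k: int


def knn_neighbors(embedding: np.ndarray, k: int = DEFAULT_K,
                  chunk_size: int = 512) -> NeighbourGraph:
    """Exact Euclidean k nearest neighbours, self excluded.

    Computed by chunked brute-force distance sorting with a stable sort, so
    ties at the k-th distance break deterministically by cell index.
    """
    coords = np.asarray(embedding, dtype=float)
    if coords.ndim != 2:
        raise ValidationError("embedding must be a 2-D array (cells × dimensions)")
    n = coords.shape[0]
    if k < 1:
        raise ValidationError(f"k must be ≥ 1, got {k}")
    if n <= k:
        raise ValidationError(f"need more cells than neighbours: n_cells={n} ≤ k={k}")

    indices = np.empty((n, k), dtype=int)
    distances = np.empty((n, k), dtype=float)
    sq = np.einsum("ij,ij->i", coords, coords)
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        block = coords[start:stop]
        d2 = sq[start:stop, None] - 2.0 * block @ coords.T + sq[None, :]
        np.maximum(d2, 0.0, out=d2)
        d2[np.arange(stop - start), np.arange(start, stop)] = np.inf  # exclude self
        order = np.argsort(d2, axis=1, kind="stable")[:, :k]
        indices[start:stop] = order
        distances[start:stop] = np.sqrt(np.take_along_axis(d2, order, axis=1))
    return NeighbourGraph(indices=indices, distances=distances, k=k)


def _label_mismatch_fraction(graph: NeighbourGraph, labels: pd.Series | np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape[0] != graph.indices.shape[0]:
        raise ValidationError("labels must cover all cells")
    if pd.isna(labels).any():
        raise ValidationError("missing label for at least one cell")
    neighbour_labels = labels[graph.indices]
    return (neighbour_labels != labels[:, None]).mean(axis=1)


def batch_mixing_score(graph: NeighbourGraph, sample_labels) -> np.ndarray:
    """Fraction of a cell's neighbours originating from a different sample."""
    return _label_mismatch_fraction(graph, sample_labels)


def tissue_separation_score(graph: NeighbourGraph, tissue_labels) -> np.ndarray:
    """Fraction of a cell's neighbours not belonging to the same tissue type."""
    return _label_mismatch_fraction(graph, tissue_labels)


def qc_scores(cell_table: pd.DataFrame, k: int = DEFAULT_K,
              embedding_cols: tuple[str, str] = ("embedding_1", "embedding_2"),
              sample_col: str = "sample", tissue_col: str = "tissue") -> pd.DataFrame:
    """Append batch_mixing and tissue_separation columns to a copy of the cell table."""
    coords = cell_table[list(embedding_cols)].to_numpy(dtype=float)
    graph = knn_neighbors(coords, k=k)
    out = cell_table.copy()
    out["batch_mixing"] = batch_mixing_score(graph, cell_table[sample_col])
    out["tissue_separation"] = tissue_separation_score(graph, cell_table[tissue_col])
    return out
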