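"""Cell-type clustering of single-cell Hi-C matrices.

Each cell's per-chromosome matrix (raw, imputed, or decoder-reconstructed)
is flattened over the upper triangle, reduced with PCA across cells,
concatenated over chromosomes, reduced again to 2D, and clustered with
k-means; agreement with known types is measured by the adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "CellFeatureSet",
    "reduce_per_chromosome",
    "cluster_cells",
    "adjusted_rand_index",
]


@dataclass
class CellFeatureSet:
    """Per-cell feature vectors after per-chromosome reduction."""

    features: np.ndarray  # (n_cells, dim * n_chroms)
    labels: np.ndarray | None = None


def _flatten_upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0])
    return np.asarray(m, dtype=float)[iu]


def reduce_per_chromosome(
    matrices: list[list[np.ndarray]],
    dim: int = 10,
    labels=None,
) -> CellFeatureSet:
    """First-round reduction: PCA per chromosome across cells.

    ``matrices[cell][chrom]`` are square matrices; each chromosome's
    flattened upper triangles are reduced to ``dim`` components across
    cells, and the reduced vectors are concatenated per cell.
    """
    n_cells = len(matrices)
    if n_cells == 0:
        raise ValueError("no cells given")
    n_chroms = len(matrices[0])
    if any(len(row) != n_chroms for row in matrices):
        raise ValueError("all cells must share the same chromosome set")
    if dim >= n_cells:
        raise ValueError(f"dim ({dim}) must be smaller than the number of cells ({n_cells})")
    parts = []
    for c in range(n_chroms):
        flat = np.stack([_flatten_upper(matrices[cell][c]) for cell in range(n_cells)])
        parts.append(PCA(n_components=dim, svd_solver="full").fit_transform(flat))
    feats = np.concatenate(parts, axis=1)
    return CellFeatureSet(
        features=feats, labels=None if labels is None else np.asarray(labels)
    )


def cluster_cells(features: CellFeatureSet, k: int, seed: int = 0) -> np.ndarray:
    """Second-round reduction to 2D followed by k-means with restarts."""
    x = features.features
    n_cells = x.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_cells:
        raise ValueError(f"k ({k}) exceeds the number of cells ({n_cells})")
    x2 = PCA(n_components=min(2, x.shape[1]), svd_solver="full").fit_transform(x)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(x2)


def adjusted_rand_index(pred, truth) -> float:
    """Chance-corrected agreement between two labelings, in [-1, 1]."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    return float(adjusted_rand_score(truth, pred))
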