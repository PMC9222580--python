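"""scHiCluster-style imputation of sparse single-cell Hi-C matrices.

The pipeline is: mean-filter smoothing of the raw count matrix, degree
normalization (the classic row-stochastic form or the symmetric
``W^{-1/2} B W^{-1/2}`` variant), random walk with restart to diffuse mass
along the contact graph, and finally binarization keeping the top t% of
entries.  The symmetric variant keeps every intermediate matrix — and the
binary output — exactly symmetric, which makes the output usable as a graph
adjacency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .hic_io import ContactMatrix, GenomeBins

__all__ = [
    "ImputeParams",
    "BinaryAdjacency",
    "smooth",
    "normalize_rows",
    "normalize_symmetric",
    "rwr",
    "binarize_top",
    "impute_cell",
]


@dataclass
class ImputeParams:
    """Parameters of the imputation pipeline.

    h: half-width of the (2h+1)x(2h+1) all-ones smoothing filter.
    p_restart: walk-continuation probability p in D_t = p D_{t-1} C + (1-p) I.
    rwr_tol: Frobenius-norm stopping tolerance of the walk iteration.
    top_t: percentage of entries kept as ones in the binary output.
    normalization: "symmetric" (default, keeps everything symmetric) or "row".
    """

    h: int = 1
    p_restart: float = 0.5
    rwr_tol: float = 1e-6
    top_t: float = 20.0
    normalization: str = "symmetric"
    max_iter: int = 1000
    clip_filter_mass: bool = False

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("h must be >= 0")
        if not 0 < self.p_restart < 1:
            raise ValueError("p_restart must be in (0, 1)")
        if self.rwr_tol <= 0:
            raise ValueError("rwr_tol must be positive")
        if not 0 < self.top_t <= 100:
            raise ValueError("top_t must be in (0, 100]")
        if self.normalization not in ("row", "symmetric"):
            raise ValueError("normalization must be 'row' or 'symmetric'")


@dataclass
class BinaryAdjacency:
    """0/1 matrix defining graph edges between bins."""

    bins: GenomeBins
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"adjacency must be square, got {v.shape}")
        if not np.all((v == 0) | (v == 1)):
            raise ValueError("adjacency entries must be 0 or 1")
        self.values = v


def smooth(a: np.ndarray, h: int, clip_filter_mass: bool = False) -> np.ndarray:
    """Mean-filter smoothing with an all-ones (2h+1)^2 window.

    Windows are clipped at the matrix edge but by default the denominator
    stays the full filter mass (2h+1)^2, so border entries are damped.  Set
    ``clip_filter_mass`` to divide by the number of in-bounds cells instead.
    """
    a = np.asarray(a, dtype=float)
    if h == 0:
        return a.copy()
    size = 2 * h + 1
    if clip_filter_mass:
        # uniform_filter in 'constant' mode divides by the full window; undo
        # by renormalizing with the smoothed indicator of in-bounds cells.
        num = uniform_filter(a, size=size, mode="constant", cval=0.0)
        den = uniform_filter(np.ones_like(a), size=size, mode="constant", cval=0.0)
        return num / den
    return uniform_filter(a, size=size, mode="constant", cval=0.0)


def normalize_rows(b: np.ndarray) -> np.ndarray:
    """Row-stochastic normalization; all-zero rows stay zero."""
    b = np.asarray(b, dtype=float)
    row_sums = b.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(row_sums > 0, b / row_sums, 0.0)
    return c


def normalize_symmetric(b: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization C = W^{-1/2} B W^{-1/2}.

    W is diagonal with row sums of B; zero-sum rows map to zero rows.
    """
    b = np.asarray(b, dtype=float)
    w = b.sum(axis=1)
    inv_sqrt = np.zeros_like(w)
    nz = w > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(w[nz])
    return b * inv_sqrt[:, None] * inv_sqrt[None, :]


def rwr(
    c: np.ndarray,
    p_restart: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, bool]:
    """Random walk with restart: D_t = p D_{t-1} C + (1-p) I.

    Starts from D_0 = I and iterates until ``||D_t - D_{t-1}||_F <= tol``.
    Returns ``(D, converged)``; with p = 0.5 the fixed point is
    ``0.5 (I - 0.5 C)^{-1}``.
    """
    c = np.asarray(c, dtype=float)
    n = c.shape[0]
    eye = np.eye(n)
    d = eye.copy()
    restart = (1.0 - p_restart) * eye
    converged = False
    for _ in range(max_iter):
        d_next = p_restart * (d @ c) + restart
        if not np.all(np.isfinite(d_next)):
            raise FloatingPointError("random walk iteration produced non-finite values")
        if np.linalg.norm(d_next - d, "fro") <= tol:
            d = d_next
            converged = True
            break
        d = d_next
    return d, converged


def binarize_top(d: np.ndarray, top_t: float, symmetrize: bool = False) -> np.ndarray:
    """Binary matrix keeping the top ``top_t`` percent of all entries.

    The threshold is the (100 - top_t)-th percentile over all n^2 values,
    diagonal included; ties at the threshold become ones.  With
    ``symmetrize`` the result is OR-symmetrized (used on the symmetric path,
    where it only guards against floating-point asymmetry).
    """
    if not 0 < top_t <= 100:
        raise ValueError("top_t must be in (0, 100]")
    d = np.asarray(d, dtype=float)
    if top_t == 100:
        return np.ones_like(d)
    thr = np.quantile(d, 1.0 - top_t / 100.0)
    e = (d >= thr).astype(float)
    if symmetrize:
        e = np.maximum(e, e.T)
    return e


def impute_cell(a: ContactMatrix, params: ImputeParams | None = None) -> BinaryAdjacency:
    """Full imputation pipeline: smooth, normalize, random walk, binarize."""
    if params is None:
        params = ImputeParams()
    b = smooth(a.values, params.h, clip_filter_mass=params.clip_filter_mass)
    if params.normalization == "symmetric":
        c = normalize_symmetric(b)
    else:
        c = normalize_rows(b)
    d, _ = rwr(c, params.p_restart, params.rwr_tol, params.max_iter)
    e = binarize_top(d, params.top_t, symmetrize=params.normalization == "symmetric")
    return BinaryAdjacency(bins=a.bins, values=e)
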