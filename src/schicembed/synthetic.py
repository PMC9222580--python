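"""Synthetic data generators.

Everything the pipeline consumes can be generated here with fixed seeds:
block-diagonal "naive TAD" binary matrices with known boundaries, sparse
distance-decay single-cell contact maps (optionally with planted TAD
enrichment), random-walk polymer 3D structures with distance-thresholded
contact maps, multi-type cell cohorts, and fine-resolution methylation-like
tracks with dips at boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hic_io import ContactMatrix, GenomeBins, Structure3D
from .impute import BinaryAdjacency
from .structure import contacts_from_structure
from .tads import TadPartition

__all__ = [
    "NaiveTadSpec",
    "PolymerSpec",
    "ScHicSpec",
    "make_naive_tads",
    "make_polymer",
    "make_schic_cell",
    "make_cohort",
    "make_methylation_track",
]


@dataclass
class NaiveTadSpec:
    """Block-diagonal ground-truth TAD layout.

    ``retention`` is the fraction of within-TAD off-diagonal entries kept
    (1.0, 0.9 and 0.8 mirror the 100/90/80% degradation levels); thinning is
    independent per entry unless ``exact_counts`` asks for exact
    without-replacement selection.
    """

    n_bins: int
    tad_lengths: list[int]
    retention: float = 1.0
    seed: int = 0
    exact_counts: bool = False

    def __post_init__(self) -> None:
        if any(l < 1 for l in self.tad_lengths):
            raise ValueError("TAD lengths must be >= 1")
        if sum(self.tad_lengths) != self.n_bins:
            raise ValueError(
                f"TAD lengths sum to {sum(self.tad_lengths)}, expected {self.n_bins}"
            )
        if not 0 < self.retention <= 1:
            raise ValueError("retention must be in (0, 1]")


@dataclass
class PolymerSpec:
    """Random-walk polymer model standing in for imaging-derived structures."""

    n_beads: int
    step_size: float = 1.0
    contact_threshold: float | None = None  # default: 10% density quantile
    seed: int = 0
    model: str = "gaussian_walk"
    confinement_radius: float | None = None

    def __post_init__(self) -> None:
        if self.n_beads < 10:
            raise ValueError("need at least 10 beads")
        if self.contact_threshold is not None and self.contact_threshold <= 0:
            raise ValueError("contact_threshold must be positive")
        if self.model not in ("gaussian_walk", "confined_walk"):
            raise ValueError("model must be 'gaussian_walk' or 'confined_walk'")


@dataclass
class ScHicSpec:
    """Sparse single-cell-like contact map with power-law distance decay.

    Pair (i, j) is drawn with probability proportional to |i - j|^-alpha,
    times ``enrichment`` if both bins fall in the same planted block.
    """

    n_bins: int
    total_contacts: int
    decay_exponent: float = 1.0
    tad_lengths: list[int] | None = None
    enrichment: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_contacts < 1:
            raise ValueError("total_contacts must be >= 1")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        if self.tad_lengths is not None and sum(self.tad_lengths) != self.n_bins:
            raise ValueError("planted TAD lengths must sum to n_bins")


def _partition_from_lengths(lengths: list[int], n_bins: int, bins=None) -> TadPartition:
    clusters = []
    start = 0
    for l in lengths:
        clusters.append((start, start + l - 1))
        start += l
    return TadPartition(clusters=clusters, n_bins=n_bins, bins=bins)


def make_naive_tads(spec: NaiveTadSpec, resolution: int = 50_000, chrom: str = "chrS"):
    """Block-diagonal 0/1 matrix with known TADs.

    All entries within a TAD are one, everything else zero; off-diagonal
    within-TAD entries are then thinned to the requested retention (the
    diagonal is always kept).  Returns ``(ContactMatrix, TadPartition)``.
    """
    rng = np.random.default_rng(spec.seed)
    bins = GenomeBins(chrom=chrom, resolution=resolution, n_bins=spec.n_bins)
    truth = _partition_from_lengths(spec.tad_lengths, spec.n_bins, bins=bins)
    m = np.zeros((spec.n_bins, spec.n_bins))
    for start, end in truth.clusters:
        m[start : end + 1, start : end + 1] = 1.0
    if spec.retention < 1.0:
        iu = np.triu_indices(spec.n_bins, k=1)
        within = m[iu] > 0
        idx = np.flatnonzero(within)
        if spec.exact_counts:
            n_drop = int(round(len(idx) * (1.0 - spec.retention)))
            drop = rng.choice(idx, size=n_drop, replace=False)
        else:
            drop = idx[rng.random(len(idx)) > spec.retention]
        keep_mask = np.ones(len(iu[0]), dtype=bool)
        keep_mask[drop] = False
        upper = np.zeros_like(m)
        upper[iu] = m[iu] * keep_mask
        m = upper + upper.T + np.diag(np.diag(m))
    return ContactMatrix(bins=bins, values=m), truth


def make_polymer(spec: PolymerSpec, resolution: int = 50_000, chrom: str = "chrP"):
    """Random-walk 3D structure and its distance-thresholded contact map.

    Without an explicit threshold, the 10% quantile of pairwise distances is
    used, giving roughly 10% contact density.  Returns
    ``(Structure3D, BinaryAdjacency)``.
    """
    rng = np.random.default_rng(spec.seed)
    steps = rng.normal(scale=spec.step_size, size=(spec.n_beads - 1, 3))
    coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    if spec.model == "confined_walk":
        radius = spec.confinement_radius or spec.step_size * np.sqrt(spec.n_beads) / 2.0
        for i in range(1, spec.n_beads):
            r = np.linalg.norm(coords[i])
            if r > radius:
                coords[i:] -= (coords[i] / r) * (r - radius)
    bins = GenomeBins(chrom=chrom, resolution=resolution, n_bins=spec.n_beads)
    s = Structure3D(bins=bins, coords=coords)
    threshold = spec.contact_threshold
    if threshold is None:
        from scipy.spatial.distance import pdist

        threshold = float(np.quantile(pdist(coords), 0.10))
    adj = contacts_from_structure(s, threshold)
    return s, adj


def make_schic_cell(spec: ScHicSpec, resolution: int = 500_000, chrom: str = "chrC") -> ContactMatrix:
    """Sparse single-cell-like contact map with |i-j|^-alpha decay."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_bins
    ii, jj = np.triu_indices(n, k=1)
    prob = (jj - ii).astype(float) ** (-spec.decay_exponent)
    if spec.tad_lengths is not None and spec.enrichment != 1.0:
        block = np.repeat(np.arange(len(spec.tad_lengths)), spec.tad_lengths)
        same = block[ii] == block[jj]
        prob = np.where(same, prob * spec.enrichment, prob)
    prob = prob / prob.sum()
    counts = rng.multinomial(spec.total_contacts, prob)
    m = np.zeros((n, n))
    m[ii, jj] = counts
    m = m + m.T
    bins = GenomeBins(chrom=chrom, resolution=resolution, n_bins=n)
    return ContactMatrix(bins=bins, values=m)


def make_cohort(
    n_cells_per_type: int, type_specs: list[ScHicSpec], seed: int = 0
):
    """Shuffled multi-type cohort of synthetic cells with type labels.

    Each cell of type t is drawn from ``type_specs[t]`` with a distinct
    sub-seed; cells and labels are returned in a shuffled common order.
    """
    if len(type_specs) < 2:
        raise ValueError("need at least 2 cell types")
    rng = np.random.default_rng(seed)
    cells, labels = [], []
    for t, spec in enumerate(type_specs):
        for c in range(n_cells_per_type):
            sub = ScHicSpec(
                n_bins=spec.n_bins,
                total_contacts=spec.total_contacts,
                decay_exponent=spec.decay_exponent,
                tad_lengths=spec.tad_lengths,
                enrichment=spec.enrichment,
                seed=int(rng.integers(2**31 - 1)),
            )
            cells.append(make_schic_cell(sub))
            labels.append(t)
    order = rng.permutation(len(cells))
    return [cells[i] for i in order], np.asarray(labels)[order]


def make_methylation_track(
    n_fine_bins: int,
    boundaries_fine: np.ndarray,
    dip_depth: float = 0.3,
    dip_width: int = 10,
    baseline: float = 0.8,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> np.ndarray:
    """Methylation-density-like track with a Gaussian dip at each boundary.

    ``boundaries_fine`` are positions in fine-bin units; the dip has depth
    ``dip_depth`` and standard deviation ``dip_width`` fine bins.
    """
    rng = np.random.default_rng(seed)
    track = np.full(n_fine_bins, baseline)
    pos = np.arange(n_fine_bins)
    for b in np.asarray(boundaries_fine, dtype=float).ravel():
        track -= dip_depth * np.exp(-0.5 * ((pos - b) / dip_width) ** 2)
    if noise_sd > 0:
        track += rng.normal(scale=noise_sd, size=n_fine_bins)
    return track
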