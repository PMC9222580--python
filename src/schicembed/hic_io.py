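"""Reading and writing single-cell Hi-C artifacts.

Contact matrices come in as sparse COO text (``i j count`` per line, optional
``#chrom= #resolution= #n_bins=`` header lines), 3D structures as one
``x y z`` line per bin, and TAD calls go out as BED-like intervals.  Cells
with too few informative contacts are dropped with the standard
non-diagonal-contact filter.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomeBins",
    "ContactMatrix",
    "Structure3D",
    "read_contacts",
    "write_contacts",
    "count_nondiagonal_contacts",
    "filter_cells",
    "read_structure",
    "write_structure",
    "write_tads",
]


@dataclass(frozen=True)
class GenomeBins:
    """Equal-width genomic bins of one chromosome.

    Bin ``i`` covers the 0-based half-open interval
    ``[i * resolution, (i + 1) * resolution)``.
    """

    chrom: str
    resolution: int
    n_bins: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if self.n_bins < 2:
            raise ValueError(f"need at least 2 bins, got {self.n_bins}")

    def bin_start(self, i: int) -> int:
        return i * self.resolution

    def bin_end(self, i: int) -> int:
        return (i + 1) * self.resolution


@dataclass
class ContactMatrix:
    """Square symmetric non-negative contact matrix with bin metadata.

    ``values`` holds raw counts or imputed weights; the diagonal (self
    contacts) is stored but treated specially by downstream steps.
    """

    bins: GenomeBins
    values: np.ndarray
    diagonal_included: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"contact matrix must be square, got shape {v.shape}")
        if v.shape[0] != self.bins.n_bins:
            raise ValueError(
                f"matrix size {v.shape[0]} does not match n_bins {self.bins.n_bins}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("contact matrix has non-finite entries")
        if np.any(v < 0):
            raise ValueError("contact matrix has negative entries")
        if not np.allclose(v, v.T):
            raise ValueError("contact matrix must be symmetric")
        self.values = v

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins


@dataclass
class Structure3D:
    """Per-bin 3D coordinates of a reconstructed chromosome."""

    bins: GenomeBins
    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError(f"coords must be n x 3, got shape {c.shape}")
        if c.shape[0] != self.bins.n_bins:
            raise ValueError(
                f"coords rows {c.shape[0]} do not match n_bins {self.bins.n_bins}"
            )
        if not np.all(np.isfinite(c)):
            raise ValueError("coords contain non-finite values")
        self.coords = c


def _parse_header(lines: Iterable[str]) -> dict:
    meta = {}
    for line in lines:
        if not line.startswith("#"):
            break
        for token in line[1:].replace(",", " ").split():
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k.strip().lstrip("#")] = v.strip()
    return meta


def read_contacts(path: str | os.PathLike, bins: GenomeBins | None = None) -> ContactMatrix:
    """Read a COO-text contact list into a dense symmetric matrix.

    Records are mirrored across the diagonal and duplicates are summed.  If
    ``bins`` is omitted the header must carry ``chrom``, ``resolution`` and
    ``n_bins``.
    """
    with open(path) as fh:
        raw_lines = fh.read().splitlines()
    if bins is None:
        meta = _parse_header(raw_lines)
        try:
            bins = GenomeBins(
                chrom=meta.get("chrom", "chr?"),
                resolution=int(meta["resolution"]),
                n_bins=int(meta["n_bins"]),
            )
        except KeyError as exc:
            raise ValueError(
                f"{path}: no bins given and header lacks {exc} (need "
                "#resolution= and #n_bins=)"
            ) from None
    n = bins.n_bins
    m = np.zeros((n, n))
    for lineno, line in enumerate(raw_lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'i j count', got {line!r}")
        i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(
                f"{path}:{lineno}: bin index out of range for {n} bins: ({i}, {j})"
            )
        if c < 0:
            raise ValueError(f"{path}:{lineno}: negative count {c}")
        m[i, j] += c
        if i != j:
            m[j, i] += c
    return ContactMatrix(bins=bins, values=m)


def write_contacts(m: ContactMatrix, path: str | os.PathLike) -> None:
    """Write the upper triangle (incl. diagonal) of a contact matrix as COO text."""
    with open(path, "w") as fh:
        fh.write(
            f"#chrom={m.bins.chrom} #resolution={m.bins.resolution} "
            f"#n_bins={m.bins.n_bins}\n"
        )
        ii, jj = np.nonzero(np.triu(m.values))
        for i, j in zip(ii, jj):
            v = m.values[i, j]
            fh.write(f"{i}\t{j}\t{v:.10g}\n")


def count_nondiagonal_contacts(m: ContactMatrix) -> float:
    """Total off-diagonal contact mass, each unordered pair counted once."""
    return float(np.triu(m.values, k=1).sum())


def filter_cells(
    cells: Sequence[ContactMatrix], threshold: float = 5000.0
) -> list[ContactMatrix]:
    """Keep cells with strictly more than ``threshold`` non-diagonal contacts.

    All cells must share the same bin definition; order is preserved.
    """
    cells = list(cells)
    if cells:
        ref = cells[0].bins
        for c in cells[1:]:
            if c.bins != ref:
                raise ValueError(
                    f"mixed bin definitions: {c.bins} vs {ref}; filter cells "
                    "per chromosome"
                )
    return [c for c in cells if count_nondiagonal_contacts(c) > threshold]


def write_structure(s: Structure3D, path: str | os.PathLike) -> None:
    """Write one ``x y z`` line per bin, 8 significant digits."""
    with open(path, "w") as fh:
        for x, y, z in s.coords:
            fh.write(f"{x:.8g}\t{y:.8g}\t{z:.8g}\n")


def read_structure(path: str | os.PathLike, bins: GenomeBins | None = None) -> Structure3D:
    """Read an ``x y z``-per-line structure file."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 coordinates, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed coordinate in {line!r}")
    if not rows:
        raise ValueError(f"{path}: empty structure file")
    coords = np.asarray(rows)
    if bins is None:
        bins = GenomeBins(chrom="chr?", resolution=1, n_bins=len(rows))
    return Structure3D(bins=bins, coords=coords)


def write_tads(partition, path: str | os.PathLike) -> None:
    """Write a TAD partition as BED-like lines: chrom, start_bp, end_bp, id."""
    bins = partition.bins
    with open(path, "w") as fh:
        for idx, (start, end) in enumerate(partition.clusters):
            fh.write(
                f"{bins.chrom}\t{bins.bin_start(start)}\t{bins.bin_end(end)}\t"
                f"tad_{idx}\n"
            )
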