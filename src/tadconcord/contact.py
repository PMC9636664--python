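"""Hi-C contact matrices: in-memory container and file ingestion.

Supports three inputs: dense square whitespace-delimited text, 3-column
sparse triplet text (``i j value``, bin indices or bp positions), and
chromosome extraction from cool/h5 containers (the .cool layout is plain
HDF5, read here directly with h5py).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import h5py
import numpy as np

from .core import GenomicBinning

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "read_dense_matrix",
    "read_sparse_triplet",
    "extract_chromosome",
    "write_dense_matrix",
    "write_sparse_triplet",
    "MatrixError",
]

SYMMETRY_RTOL = 1e-9


class MatrixError(ValueError):
    """Raised on malformed contact-matrix input."""


@dataclass(frozen=True)
class ContactMatrix:
    """A square symmetric nonnegative matrix tied to a genomic binning.

    ``mask`` holds the indices of bins with zero marginal sum; these bins
    carry no information and are excluded from balancing.
    """

    values: np.ndarray
    binning: GenomicBinning
    mask: frozenset[int] = field(default=frozenset())

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise MatrixError(f"matrix must be square, got shape {v.shape}")
        if v.shape[0] != self.binning.n_bins:
            raise MatrixError(
                f"matrix size {v.shape[0]} != binning.n_bins {self.binning.n_bins}"
            )
        if not np.all(np.isfinite(v)):
            raise MatrixError("matrix contains non-finite entries")
        if np.any(v < 0):
            raise MatrixError("matrix contains negative entries")
        scale = max(np.abs(v).max(), 1.0)
        if np.abs(v - v.T).max() > SYMMETRY_RTOL * scale:
            raise MatrixError(
                f"matrix asymmetric beyond tolerance "
                f"(max |M - M^T| = {np.abs(v - v.T).max():g})"
            )
        object.__setattr__(self, "values", v)
        zero = frozenset(int(i) for i in np.flatnonzero(v.sum(axis=0) == 0))
        object.__setattr__(self, "mask", zero)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def unmasked(self) -> np.ndarray:
        """Sorted indices of bins with nonzero marginal sum."""
        return np.array(sorted(set(range(self.n_bins)) - self.mask), dtype=int)


def read_dense_matrix(
    path: str | os.PathLike, chrom: str, resolution: int
) -> ContactMatrix:
    """Read a whitespace-delimited dense square matrix; n_bins from row count."""
    path = os.fspath(path)
    try:
        v = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise MatrixError(f"{path}: cannot parse dense matrix: {exc}") from exc
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise MatrixError(f"{path}: matrix must be square, got shape {v.shape}")
    binning = GenomicBinning(chrom, resolution, v.shape[0])
    return ContactMatrix(v, binning)


def read_sparse_triplet(
    path: str | os.PathLike,
    chrom: str,
    resolution: int,
    n_bins: int,
) -> ContactMatrix:
    """Read ``i j value`` triplets into a symmetrized dense matrix.

    Coordinates may be bin indices or bp positions divisible by the
    resolution; bp mode is auto-detected when any coordinate is >= n_bins
    and all coordinates are multiples of the resolution. Duplicate entries
    (including an (i,j)/(j,i) pair) are summed with a warning.
    """
    path = os.fspath(path)
    try:
        data = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise MatrixError(f"{path}: cannot parse triplet file: {exc}") from exc
    if data.size == 0:
        raise MatrixError(f"{path}: empty triplet file")
    if data.shape[1] != 3:
        raise MatrixError(f"{path}: expected 3 columns, got {data.shape[1]}")

    coords = data[:, :2]
    if np.any(coords != np.floor(coords)):
        raise MatrixError(f"{path}: non-integer bin coordinates")
    ii = coords[:, 0].astype(int)
    jj = coords[:, 1].astype(int)
    vals = data[:, 2]
    if np.any(vals < 0):
        raise MatrixError(f"{path}: negative contact values")

    bp_mode = (ii.max(initial=0) >= n_bins or jj.max(initial=0) >= n_bins) and (
        np.all(ii % resolution == 0) and np.all(jj % resolution == 0)
    )
    if bp_mode:
        logger.info("%s: interpreting triplet coordinates as bp", path)
        ii = ii // resolution
        jj = jj // resolution
    if ii.min(initial=0) < 0 or max(ii.max(initial=0), jj.max(initial=0)) >= n_bins:
        raise MatrixError(f"{path}: bin index out of range [0, {n_bins})")

    m = np.zeros((n_bins, n_bins))
    seen = np.zeros((n_bins, n_bins), dtype=bool)
    dup = 0
    for i, j, v in zip(ii, jj, vals):
        a, b = (i, j) if i <= j else (j, i)
        if seen[a, b]:
            dup += 1
        seen[a, b] = True
        m[a, b] += v
    if dup:
        logger.warning("%s: %d duplicate triplet entr(ies) summed", path, dup)
    m = m + np.triu(m, k=1).T  # mirror the upper triangle
    binning = GenomicBinning(chrom, resolution, n_bins)
    return ContactMatrix(m, binning)


def extract_chromosome(
    path: str | os.PathLike,
    chrom: str,
    resolution: int | None = None,
) -> ContactMatrix:
    """Extract one chromosome's dense cis matrix from a cool/h5 container.

    Accepts single-resolution ``.cool`` files and multi-resolution ``.mcool``
    files (groups under ``/resolutions``). For multi-resolution containers
    ``resolution`` must be given explicitly. The container's own bin table
    supplies the resolution and bin extents.
    """
    path = os.fspath(path)
    with h5py.File(path, "r") as f:
        grp = _select_group(f, resolution)
        chrom_names = [
            c.decode() if isinstance(c, bytes) else str(c)
            for c in grp["chroms/name"][:]
        ]
        if chrom not in chrom_names:
            raise MatrixError(
                f"{path}: chromosome {chrom!r} not in container "
                f"(available: {', '.join(chrom_names)})"
            )
        res = int(grp.attrs.get("bin-size", 0))
        bin_chrom = grp["bins/chrom"][:]
        bin_start = grp["bins/start"][:]
        bin_end = grp["bins/end"][:]
        cidx = chrom_names.index(chrom)
        sel = np.flatnonzero(bin_chrom == cidx)
        if sel.size == 0:
            raise MatrixError(f"{path}: no bins recorded for {chrom!r}")
        if res == 0:
            res = int(np.max(bin_end[sel] - bin_start[sel]))
        lo, hi = int(sel[0]), int(sel[-1]) + 1
        n = hi - lo

        bin1 = grp["pixels/bin1_id"][:]
        bin2 = grp["pixels/bin2_id"][:]
        count = grp["pixels/count"][:].astype(float)
        keep = (bin1 >= lo) & (bin1 < hi) & (bin2 >= lo) & (bin2 < hi)

        m = np.zeros((n, n))
        b1 = bin1[keep] - lo
        b2 = bin2[keep] - lo
        np.add.at(m, (b1, b2), count[keep])
        off = b1 != b2
        np.add.at(m, (b2[off], b1[off]), count[keep][off])

    binning = GenomicBinning(chrom, res, n)
    return ContactMatrix(m, binning)


def _select_group(f: h5py.File, resolution: int | None) -> h5py.Group:
    if "resolutions" in f:
        names = sorted(f["resolutions"].keys(), key=int)
        if resolution is None:
            if len(names) > 1:
                raise MatrixError(
                    f"multi-resolution container; specify one of: {', '.join(names)}"
                )
            return f["resolutions"][names[0]]
        if str(resolution) not in f["resolutions"]:
            raise MatrixError(
                f"resolution {resolution} not in container "
                f"(available: {', '.join(names)})"
            )
        return f["resolutions"][str(resolution)]
    if "pixels" not in f:
        raise MatrixError("not a cool-layout container (no pixels table)")
    return f["/"]


def write_dense_matrix(matrix: ContactMatrix, path: str | os.PathLike) -> None:
    np.savetxt(os.fspath(path), matrix.values, fmt="%.10g", delimiter="\t")


def write_sparse_triplet(matrix: ContactMatrix, path: str | os.PathLike) -> None:
    """Write the upper triangle (incl. diagonal) of nonzero cells as triplets."""
    v = matrix.values
    iu, ju = np.triu_indices(matrix.n_bins)
    nz = v[iu, ju] != 0
    with open(os.fspath(path), "w") as fh:
        for i, j, val in zip(iu[nz], ju[nz], v[iu, ju][nz]):
            fh.write(f"{i}\t{j}\t{val:.10g}\n")
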