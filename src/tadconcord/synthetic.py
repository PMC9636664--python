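"""Synthetic TAD partitions and block-model contact matrices.

Provides controlled inputs for every analysis in the package: random
partitions with tunable domain sizes and gaps, perturbation operators
(boundary jitter, merge/split) that emulate the disagreement modes of real
TAD callers — the same region called as fewer large domains or as many
small ones — and a Poisson block-model contact matrix whose diagonal
blocks follow a given partition.

All operations are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact import ContactMatrix
from .core import GenomicBinning, TadDomain, TadSet

__all__ = [
    "SyntheticSpec",
    "generate_partition",
    "jitter",
    "merge_split",
    "generate_matrix",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a random left-to-right TAD partition.

    Domain sizes are Uniform{min_size..max_size} bins; after each domain a
    gap of Uniform{1..gap_max} bins is inserted with probability
    ``gap_prob``. Generation stops when the next domain would not fit.
    """

    n_bins: int
    min_size: int = 5
    max_size: int = 25
    gap_prob: float = 0.0
    gap_max: int = 3
    seed: int = 0
    chrom: str = "chrS"
    resolution: int = 40_000

    def __post_init__(self) -> None:
        if not (1 <= self.min_size <= self.max_size):
            raise ValueError(
                f"need 1 <= min_size <= max_size, got {self.min_size}, {self.max_size}"
            )
        if self.min_size > self.n_bins:
            raise ValueError(
                f"min_size {self.min_size} exceeds n_bins {self.n_bins}"
            )
        if not 0.0 <= self.gap_prob <= 1.0:
            raise ValueError(f"gap_prob must be in [0, 1], got {self.gap_prob}")

    @property
    def binning(self) -> GenomicBinning:
        return GenomicBinning(self.chrom, self.resolution, self.n_bins)


def generate_partition(spec: SyntheticSpec, label: str | None = None) -> TadSet:
    """Draw a random partition satisfying all TadSet invariants."""
    rng = np.random.default_rng(spec.seed)
    domains: list[TadDomain] = []
    pos = 0
    while True:
        size = int(rng.integers(spec.min_size, spec.max_size + 1))
        if pos + size > spec.n_bins:
            break
        domains.append(TadDomain(pos, pos + size))
        pos += size
        if spec.gap_prob > 0 and rng.random() < spec.gap_prob:
            pos += int(rng.integers(1, spec.gap_max + 1))
    if label is None:
        label = f"synthetic_seed{spec.seed}"
    return TadSet(label, spec.binning, tuple(domains))


def jitter(tads: TadSet, magnitude: int, seed: int = 0) -> TadSet:
    """Move every interior boundary by Uniform{-magnitude..+magnitude} bins.

    Boundaries are processed left to right; each displacement is clamped so
    the domain order is preserved and every domain keeps >= 1 bin (a moved
    boundary stops 1 bin short of its neighbour). Magnitude 0 is the
    identity. A start and end meeting at the same bin move together, so
    adjacent domains stay adjacent.
    """
    if magnitude < 0:
        raise ValueError(f"magnitude must be >= 0, got {magnitude}")
    if magnitude == 0 or len(tads) == 0:
        return tads
    rng = np.random.default_rng(seed)
    # Distinct boundary points left to right; a falling boundary that
    # coincides with the next rising boundary is one point and moves as one,
    # so adjacent domains stay adjacent.
    coords: list[int] = []
    for d in tads:
        for c in (d.start_bin, d.end_bin):
            if not coords or c != coords[-1]:
                coords.append(c)
    orig = list(coords)
    for k in range(len(coords)):
        delta = int(rng.integers(-magnitude, magnitude + 1))
        lo = coords[k - 1] + 1 if k > 0 else 0
        # stop 1 bin short of the next (not-yet-moved) boundary
        hi = orig[k + 1] - 1 if k + 1 < len(orig) else tads.binning.n_bins
        coords[k] = int(np.clip(orig[k] + delta, lo, hi))
    # Map moved points back onto the domain structure.
    pos = {o: c for o, c in zip(orig, coords)}
    domains = tuple(
        TadDomain(pos[d.start_bin], pos[d.end_bin]) for d in tads
    )
    return TadSet(tads.label, tads.binning, domains)


def merge_split(
    tads: TadSet, p_merge: float, p_split: float, seed: int = 0
) -> TadSet:
    """Merge adjacent domain pairs and/or split domains at random.

    Each adjacent pair (in left-to-right order) is merged with probability
    ``p_merge`` — a merge spans the union including any gap between the
    two — then each surviving domain of size >= 2 is split at a uniform
    interior point with probability ``p_split``. High ``p_merge`` emulates
    callers that find fewer, larger domains; high ``p_split`` emulates
    callers that find many small ones.
    """
    for name, p in (("p_merge", p_merge), ("p_split", p_split)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    merged: list[list[int]] = []
    for d in tads:
        if merged and rng.random() < p_merge:
            merged[-1][1] = d.end_bin
        else:
            merged.append([d.start_bin, d.end_bin])
    out: list[TadDomain] = []
    for s, e in merged:
        if e - s >= 2 and rng.random() < p_split:
            cut = int(rng.integers(s + 1, e))
            out.append(TadDomain(s, cut))
            out.append(TadDomain(cut, e))
        else:
            out.append(TadDomain(s, e))
    return TadSet(tads.label, tads.binning, tuple(out))


def generate_matrix(
    tads: TadSet,
    intra_rate: float = 20.0,
    inter_rate: float = 2.0,
    seed: int = 0,
) -> ContactMatrix:
    """Poisson block-model contact matrix for a partition.

    Cells inside a domain's diagonal block draw Poisson(``intra_rate``),
    all other cells Poisson(``inter_rate``); the matrix is symmetric by
    construction (only the upper triangle is drawn).
    """
    if not intra_rate > inter_rate >= 0:
        raise ValueError(
            f"need intra_rate > inter_rate >= 0, got {intra_rate}, {inter_rate}"
        )
    rng = np.random.default_rng(seed)
    n = tads.binning.n_bins
    lam = np.full((n, n), float(inter_rate))
    for d in tads:
        lam[d.start_bin:d.end_bin, d.start_bin:d.end_bin] = intra_rate
    upper = rng.poisson(lam).astype(float)
    m = np.triu(upper)
    m = m + np.triu(m, k=1).T
    return ContactMatrix(m, tads.binning)
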