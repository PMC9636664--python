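"""Core data model for binned TAD analysis.

Everything downstream works on a shared coordinate frame: a chromosome cut
into fixed-width bins. TADs are half-open bin-index intervals on that frame;
boundaries are the bin indices where a domain starts (rising) or ends
(falling). Keeping the frame explicit lets every comparison check that two
datasets actually live on the same grid before any metric is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "GenomicBinning",
    "TadDomain",
    "TadSet",
    "BoundarySet",
    "boundaries_of",
]


@dataclass(frozen=True)
class GenomicBinning:
    """A chromosome divided into ``n_bins`` bins of ``resolution`` bp.

    Bin ``i`` spans the bp interval ``[i * resolution, (i + 1) * resolution)``,
    0-based and half-open.
    """

    chrom: str
    resolution: int
    n_bins: int

    def __post_init__(self) -> None:
        if int(self.resolution) < 1:
            raise ValueError(f"resolution must be >= 1, got {self.resolution}")
        if int(self.n_bins) < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")

    @property
    def length_bp(self) -> int:
        return self.resolution * self.n_bins

    def bp_to_bin_interval(self, start_bp: int, end_bp: int) -> tuple[int, int]:
        """Convert a bp interval to bins: floor the start, ceil the end.

        This preserves full coverage of partially-aligned intervals.
        """
        start_bin = start_bp // self.resolution
        end_bin = -(-end_bp // self.resolution)
        return int(start_bin), int(end_bin)


@dataclass(frozen=True, order=True)
class TadDomain:
    """A single TAD as a half-open bin interval ``[start_bin, end_bin)``."""

    start_bin: int
    end_bin: int

    def __post_init__(self) -> None:
        if self.start_bin < 0:
            raise ValueError(f"start_bin must be >= 0, got {self.start_bin}")
        if self.end_bin <= self.start_bin:
            raise ValueError(
                f"domain must span >= 1 bin: [{self.start_bin}, {self.end_bin})"
            )

    @property
    def size_bins(self) -> int:
        return self.end_bin - self.start_bin

    def overlap_bins(self, other: "TadDomain") -> int:
        """Number of bins shared with ``other`` (0 if disjoint)."""
        return max(
            0, min(self.end_bin, other.end_bin) - max(self.start_bin, other.start_bin)
        )


@dataclass(frozen=True)
class TadSet:
    """An ordered, non-overlapping set of TADs from one dataset.

    Domains are sorted by start, pairwise disjoint (a falling boundary may
    coincide with the next rising boundary), and contained in
    ``[0, binning.n_bins]``. Gaps between domains are allowed: real callers
    leave unassigned regions.
    """

    label: str
    binning: GenomicBinning
    domains: tuple[TadDomain, ...]

    def __post_init__(self) -> None:
        doms = tuple(self.domains)
        object.__setattr__(self, "domains", doms)
        prev_end = None
        for d in doms:
            if d.end_bin > self.binning.n_bins:
                raise ValueError(
                    f"{self.label!r}: domain [{d.start_bin}, {d.end_bin}) exceeds "
                    f"n_bins={self.binning.n_bins}"
                )
            if prev_end is not None and d.start_bin < prev_end:
                raise ValueError(
                    f"{self.label!r}: overlapping domains at "
                    f"[{d.start_bin}, {d.end_bin}) (previous ends at {prev_end})"
                )
            prev_end = d.end_bin

    def __len__(self) -> int:
        return len(self.domains)

    def __iter__(self) -> Iterator[TadDomain]:
        return iter(self.domains)

    @property
    def sizes(self) -> np.ndarray:
        """Domain sizes in bins, in domain order."""
        return np.array([d.size_bins for d in self.domains], dtype=int)

    def with_label(self, label: str) -> "TadSet":
        return TadSet(label, self.binning, self.domains)

    @classmethod
    def from_intervals(
        cls,
        label: str,
        binning: GenomicBinning,
        intervals: Iterable[tuple[int, int]],
    ) -> "TadSet":
        """Build from ``(start_bin, end_bin)`` pairs, sorting them first."""
        doms = tuple(TadDomain(int(s), int(e)) for s, e in sorted(intervals))
        return cls(label, binning, doms)


@dataclass(frozen=True)
class BoundarySet:
    """Sorted unique bin indices of domain starts and ends.

    The shared corner of two adjacent domains appears once (set semantics).
    """

    bins: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        uniq = tuple(sorted(set(int(b) for b in self.bins)))
        object.__setattr__(self, "bins", uniq)

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self) -> Iterator[int]:
        return iter(self.bins)

    def as_array(self) -> np.ndarray:
        return np.array(self.bins, dtype=int)


def boundaries_of(tads: TadSet) -> BoundarySet:
    """Union of all rising (start) and falling (end) boundaries of a TadSet."""
    bins: list[int] = []
    for d in tads:
        bins.append(d.start_bin)
        bins.append(d.end_bin)
    return BoundarySet(tuple(bins))
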