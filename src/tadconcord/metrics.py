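"""Count, size, and tolerance-based sharing statistics for TAD datasets.

Two boundaries are shared at tolerance ``t`` when they lie within ``t``
genomic bins of each other (``t = 0`` demands identity; ``t`` bins equal
``t * resolution`` bp). A domain is shared when both its rising and falling
boundaries match a single domain of the other dataset within the tolerance.
Matching is existential — an element of ``a`` is shared as soon as any
element of ``b`` is close enough; no one-to-one assignment is made.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BoundarySet, TadDomain, TadSet, boundaries_of

__all__ = [
    "SizeSummary",
    "SharingProfile",
    "count_tads",
    "size_stats",
    "shared_boundaries",
    "shared_domains",
    "one_vs_all_boundaries",
    "one_vs_all_domains",
    "sharing_profile",
]


@dataclass(frozen=True)
class SizeSummary:
    """Five-number summary plus mean of domain sizes, in bins."""

    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    mean: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n, "min": self.min, "q1": self.q1,
            "median": self.median, "q3": self.q3, "max": self.max,
            "mean": self.mean,
        }


def count_tads(tads: TadSet) -> int:
    """Number of domains in the dataset."""
    return len(tads)


def size_stats(tads: TadSet) -> SizeSummary:
    """Domain-size summary in bins; quartiles by linear interpolation.

    Raises ``ValueError`` on an empty TadSet.
    """
    if len(tads) == 0:
        raise ValueError(f"{tads.label!r}: cannot summarize an empty TadSet")
    sizes = tads.sizes.astype(float)
    q1, med, q3 = np.percentile(sizes, [25, 50, 75])  # linear interpolation
    return SizeSummary(
        n=len(sizes), min=float(sizes.min()), q1=float(q1), median=float(med),
        q3=float(q3), max=float(sizes.max()), mean=float(sizes.mean()),
    )


def _check_tolerance(tolerance: int) -> int:
    t = int(tolerance)
    if t < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    return t


def _boundary_matched(x: int, b: np.ndarray, t: int) -> bool:
    """True iff some element of sorted array ``b`` lies within ``t`` of ``x``."""
    idx = np.searchsorted(b, x)
    if idx < b.size and b[idx] - x <= t:
        return True
    return idx > 0 and x - b[idx - 1] <= t


def shared_boundaries(
    a: BoundarySet, b: BoundarySet, tolerance: int
) -> tuple[int, tuple[int, ...]]:
    """Boundaries of ``a`` with a match in ``b`` within ``tolerance`` bins.

    Returns ``(count, matched)`` where ``matched`` is the sorted subset of
    ``a``'s boundaries that found a partner. Asymmetric in general:
    ``shared_boundaries(a, b, t)`` counts elements of ``a``, not pairs.
    """
    t = _check_tolerance(tolerance)
    barr = b.as_array()
    if barr.size == 0:
        return 0, ()
    matched = tuple(x for x in a if _boundary_matched(x, barr, t))
    return len(matched), matched


def shared_domains(
    a: TadSet, b: TadSet, tolerance: int
) -> tuple[int, tuple[TadDomain, ...]]:
    """Domains of ``a`` whose start AND end both match one domain of ``b``.

    A domain ``[s, e)`` of ``a`` is shared iff some ``[s', e')`` in ``b``
    has ``|s - s'| <= t`` and ``|e - e'| <= t``.
    """
    if a.binning != b.binning:
        raise ValueError(
            f"binning mismatch between {a.label!r} and {b.label!r}"
        )
    t = _check_tolerance(tolerance)
    if len(b) == 0:
        return 0, ()
    starts = np.array([d.start_bin for d in b])
    ends = np.array([d.end_bin for d in b])
    matched = tuple(
        d for d in a
        if np.any(
            (np.abs(starts - d.start_bin) <= t) & (np.abs(ends - d.end_bin) <= t)
        )
    )
    return len(matched), matched


def _one_vs_all(
    ref: TadSet,
    others: list[TadSet],
    tolerances: list[int],
    count_fn,
) -> pd.DataFrame:
    if not others:
        raise ValueError("need at least one other dataset")
    labels = [d.label for d in others]
    table = pd.DataFrame(
        index=pd.Index(labels, name="dataset"),
        columns=pd.Index([int(t) for t in tolerances], name="tolerance"),
        dtype=int,
    )
    for d in others:
        for t in tolerances:
            table.loc[d.label, int(t)] = count_fn(ref, d, int(t))
    return table


def one_vs_all_boundaries(
    ref: TadSet, others: list[TadSet], tolerances: list[int]
) -> pd.DataFrame:
    """Raw shared-boundary counts of ``ref`` against each other dataset.

    Rows are the other datasets, columns the tolerances; entry ``(d, t)``
    is the number of ``ref`` boundaries matched by ``d`` at tolerance ``t``.
    Entries are non-decreasing along the tolerance axis.
    """
    ref_b = boundaries_of(ref)
    return _one_vs_all(
        ref, others, tolerances,
        lambda r, d, t: shared_boundaries(ref_b, boundaries_of(d), t)[0],
    )


def one_vs_all_domains(
    ref: TadSet, others: list[TadSet], tolerances: list[int]
) -> pd.DataFrame:
    """Raw shared-domain counts of ``ref`` against each other dataset."""
    return _one_vs_all(
        ref, others, tolerances,
        lambda r, d, t: shared_domains(r, d, t)[0],
    )


@dataclass(frozen=True)
class SharingProfile:
    """Per-dataset histogram of how many other datasets match each element.

    ``counts.loc[d, k]`` is the number of dataset ``d``'s boundaries (or
    domains) matched by exactly ``k`` of the other ``K - 1`` datasets.
    ``percentages`` divides each row by the dataset's element total.
    """

    mode: str
    tolerance: int
    counts: pd.DataFrame
    percentages: pd.DataFrame


def sharing_profile(
    sets: list[TadSet], tolerance: int, mode: str = "boundaries"
) -> SharingProfile:
    """All-vs-all sharing histogram (the stacked-bar-graph data).

    For every element of every dataset, count the number ``k`` of OTHER
    datasets containing a match within ``tolerance``; histogram over
    ``k = 0 .. K-1`` per dataset. ``mode`` is ``boundaries`` or ``domains``.
    """
    if len(sets) < 2:
        raise ValueError("sharing profile needs at least 2 datasets")
    if mode not in ("boundaries", "domains"):
        raise ValueError(f"mode must be 'boundaries' or 'domains', got {mode!r}")
    t = _check_tolerance(tolerance)
    k_max = len(sets) - 1
    labels = [s.label for s in sets]
    counts = pd.DataFrame(
        0,
        index=pd.Index(labels, name="dataset"),
        columns=pd.Index(range(k_max + 1), name="n_matching_datasets"),
    )
    for s in sets:
        others = [o for o in sets if o is not s]
        if mode == "boundaries":
            sb = boundaries_of(s)
            arrs = [boundaries_of(o).as_array() for o in others]
            for x in sb:
                k = sum(
                    1 for arr in arrs if arr.size and _boundary_matched(x, arr, t)
                )
                counts.loc[s.label, k] += 1
        else:
            for d in s:
                k = sum(1 for o in others if shared_domains(
                    TadSet(s.label, s.binning, (d,)), o, t)[0])
                counts.loc[s.label, k] += 1
    totals = counts.sum(axis=1)
    pct = counts.div(totals.replace(0, 1), axis=0) * 100.0
    return SharingProfile(mode=mode, tolerance=t, counts=counts, percentages=pct)
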