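"""Measure of Concordance (MoC) between TAD partitions.

For two datasets A (domains :math:`A_1..A_{N_A}`) and B (:math:`B_1..B_{N_B}`)
the per-pair overlap term is

.. math:: \\frac{|A_i \\cap B_j|^2}{|A_i| \\cdot |B_j|}

with sizes and overlaps in genomic bins, and

.. math:: \\mathrm{MoC}(A, B) = \\frac{\\sum_{i,j} |A_i \\cap B_j|^2 /
          (|A_i||B_j|) - 1}{\\sqrt{N_A N_B} - 1}

with the convention MoC = 1 when :math:`N_A = N_B = 1`. Identical
partitions score exactly 1; the score is symmetric and scale-invariant.
For partitions that fully tile the region MoC is nonnegative; gapped
datasets can produce small negative values, which are reported raw with
a warning rather than clamped — a strongly negative MoC signals a data
problem, not a similarity of zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import TadDomain, TadSet

logger = logging.getLogger(__name__)

__all__ = [
    "overlap_term",
    "moc",
    "moc_one_vs_all",
    "moc_matrix_and_average",
    "MoCMatrix",
]


def overlap_term(a: TadDomain, b: TadDomain) -> float:
    """Squared overlap divided by the size product: |a∩b|²/(|a|·|b|)."""
    ov = a.overlap_bins(b)
    if ov == 0:
        return 0.0
    return ov * ov / (a.size_bins * b.size_bins)


def moc(a: TadSet, b: TadSet) -> float:
    """Measure of Concordance between two non-empty TAD datasets."""
    if a.binning != b.binning:
        raise ValueError(f"binning mismatch between {a.label!r} and {b.label!r}")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("MoC is undefined for an empty TadSet")
    n_a, n_b = len(a), len(b)
    if n_a == 1 and n_b == 1:
        return 1.0

    # Interval sweep: domains of both sets are sorted, so each a-domain only
    # overlaps a contiguous run of b-domains.
    b_doms = b.domains
    s = 0.0
    j0 = 0
    for da in a.domains:
        while j0 < n_b and b_doms[j0].end_bin <= da.start_bin:
            j0 += 1
        j = j0
        while j < n_b and b_doms[j].start_bin < da.end_bin:
            s += overlap_term(da, b_doms[j])
            j += 1

    value = (s - 1.0) / (np.sqrt(n_a * n_b) - 1.0)
    if value < 0:
        logger.warning(
            "MoC(%s, %s) = %.4g is negative: the datasets share almost no "
            "coverage (gapped or disjoint inputs)", a.label, b.label, value,
        )
    return float(value)


def moc_one_vs_all(ref: TadSet, others: list[TadSet]) -> pd.Series:
    """MoC of a reference dataset against each other dataset."""
    if not others:
        raise ValueError("need at least one other dataset")
    return pd.Series(
        [moc(ref, d) for d in others],
        index=pd.Index([d.label for d in others], name="dataset"),
        name=f"moc_vs_{ref.label}",
    )


@dataclass(frozen=True)
class MoCMatrix:
    """All-vs-all MoC values plus per-dataset averages over the others."""

    labels: tuple[str, ...]
    values: pd.DataFrame
    averages: pd.Series


def moc_matrix_and_average(sets: list[TadSet]) -> MoCMatrix:
    """Full symmetric K×K MoC matrix with per-dataset off-diagonal means."""
    if len(sets) < 2:
        raise ValueError("MoC matrix needs at least 2 datasets")
    labels = tuple(s.label for s in sets)
    k = len(sets)
    m = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            m[i, j] = m[j, i] = moc(sets[i], sets[j])
    values = pd.DataFrame(m, index=list(labels), columns=list(labels))
    off = m.copy()
    np.fill_diagonal(off, np.nan)
    averages = pd.Series(
        np.nanmean(off, axis=1), index=list(labels), name="average_moc"
    )
    return MoCMatrix(labels=labels, values=values, averages=averages)
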