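"""Reading and writing TAD domain files.

TAD callers emit intervals in two common dialects: BED3 (``chrom start end``)
and a headerless two-column ``start end`` form. Coordinates may be in base
pairs or already in bin units; both dialect and units can be auto-detected.
Internally everything becomes 0-based half-open bin indices on a
:class:`~tadconcord.core.GenomicBinning`.
"""

from __future__ import annotations

import logging
import os
from typing import Literal

from .core import GenomicBinning, TadDomain, TadSet

logger = logging.getLogger(__name__)

__all__ = ["read_tad_set", "write_tad_set", "TadFileError"]

Dialect = Literal["bed3", "two_column", "auto"]
Units = Literal["bp", "bins", "auto"]


class TadFileError(ValueError):
    """Raised when a TAD domain file cannot be parsed into a valid TadSet."""


def _parse_lines(path: str) -> list[tuple[int, str, list[str]]]:
    """Return (line_no, raw, fields) for data lines, skipping comments."""
    rows = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            rows.append((i, line, line.split()))
    return rows


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _detect_dialect(rows: list[tuple[int, str, list[str]]]) -> str:
    """bed3 if first field is non-numeric with >= 3 columns, else two_column."""
    for _, _, fields in rows:
        if len(fields) >= 3 and not _is_number(fields[0]):
            return "bed3"
        if len(fields) >= 2 and _is_number(fields[0]) and _is_number(fields[1]):
            return "two_column"
    return "two_column"


def _to_int(value: str, line_no: int, path: str) -> int:
    try:
        f = float(value)
    except ValueError:
        raise TadFileError(
            f"{path}:{line_no}: non-numeric coordinate {value!r}"
        ) from None
    if f != int(f):
        raise TadFileError(f"{path}:{line_no}: non-integer coordinate {value!r}")
    return int(f)


def read_tad_set(
    path: str | os.PathLike,
    binning: GenomicBinning,
    label: str | None = None,
    dialect: Dialect = "auto",
    units: Units = "auto",
) -> TadSet:
    """Parse a TAD domain file into a validated :class:`TadSet`.

    Parameters
    ----------
    path
        Text file with one domain per line, tab/space-delimited. Lines
        starting with ``#`` or ``track`` are skipped.
    binning
        The coordinate frame. Rows on a different chromosome are dropped
        (logged); domains are converted to bins and overlap-validated.
    label
        Dataset name; defaults to the file's basename without extension.
    dialect
        ``bed3`` (``chrom start end``), ``two_column`` (``start end``) or
        ``auto`` (detected from the first data line).
    units
        ``bp``, ``bins`` or ``auto``. Auto treats coordinates as bins when
        the maximum coordinate is below ``2 * n_bins``, else bp. bp
        intervals are converted with floor(start) / ceil(end) so a
        partially-aligned interval keeps full bin coverage.

    Raises
    ------
    TadFileError
        On unreadable files, non-integer coordinates, end <= start after
        conversion, or overlapping domains after conversion.
    """
    path = os.fspath(path)
    if label is None:
        label = os.path.splitext(os.path.basename(path))[0]
    rows = _parse_lines(path)

    if dialect == "auto":
        dialect = _detect_dialect(rows)  # type: ignore[assignment]

    raw_intervals: list[tuple[int, int, int]] = []  # (line_no, start, end)
    dropped = 0
    for line_no, line, fields in rows:
        if dialect == "bed3":
            if len(fields) < 3:
                raise TadFileError(
                    f"{path}:{line_no}: expected >= 3 columns (chrom start end), "
                    f"got {line!r}"
                )
            chrom, s, e = fields[0], fields[1], fields[2]
            if chrom != binning.chrom:
                dropped += 1
                continue
        else:
            if len(fields) < 2:
                raise TadFileError(
                    f"{path}:{line_no}: expected >= 2 columns (start end), got {line!r}"
                )
            s, e = fields[0], fields[1]
        start = _to_int(s, line_no, path)
        end = _to_int(e, line_no, path)
        if end <= start:
            raise TadFileError(
                f"{path}:{line_no}: end <= start ({start} >= {end})"
            )
        raw_intervals.append((line_no, start, end))

    if dropped:
        logger.info(
            "%s: dropped %d row(s) on chromosomes other than %s",
            path, dropped, binning.chrom,
        )

    if units == "auto":
        max_coord = max((e for _, _, e in raw_intervals), default=0)
        units = "bins" if max_coord < 2 * binning.n_bins else "bp"  # type: ignore[assignment]
        logger.info("%s: auto-detected units=%s (max coordinate %d)", path, units, max_coord)

    intervals: list[tuple[int, int, int]] = []
    for line_no, start, end in raw_intervals:
        if units == "bp":
            sb, eb = binning.bp_to_bin_interval(start, end)
        else:
            sb, eb = start, end
        if eb <= sb:
            raise TadFileError(
                f"{path}:{line_no}: zero-length domain after conversion "
                f"([{start}, {end}) -> [{sb}, {eb}))"
            )
        if sb < 0 or eb > binning.n_bins:
            raise TadFileError(
                f"{path}:{line_no}: domain [{sb}, {eb}) outside [0, {binning.n_bins}]"
            )
        intervals.append((line_no, sb, eb))

    intervals.sort(key=lambda t: (t[1], t[2]))
    prev_end = None
    prev_line = None
    for line_no, sb, eb in intervals:
        if prev_end is not None and sb < prev_end:
            raise TadFileError(
                f"{path}: overlapping domains after conversion "
                f"(line {prev_line} ends at bin {prev_end}, line {line_no} starts "
                f"at bin {sb})"
            )
        prev_end, prev_line = eb, line_no

    domains = tuple(TadDomain(sb, eb) for _, sb, eb in intervals)
    return TadSet(label, binning, domains)


def write_tad_set(
    tads: TadSet,
    path: str | os.PathLike,
    units: Literal["bp", "bins"] = "bp",
) -> None:
    """Write a TadSet as tab-delimited BED3.

    ``units="bp"`` multiplies bin indices by the resolution (the exact
    inverse of reading bin-aligned bp intervals); ``units="bins"`` writes
    raw bin indices. Round-trips through :func:`read_tad_set` reproduce
    the input exactly in both modes.
    """
    res = tads.binning.resolution if units == "bp" else 1
    with open(os.fspath(path), "w") as fh:
        fh.write(
            f"# chrom={tads.binning.chrom} resolution={tads.binning.resolution} "
            f"n_bins={tads.binning.n_bins} units={units}\n"
        )
        for d in tads:
            fh.write(
                f"{tads.binning.chrom}\t{d.start_bin * res}\t{d.end_bin * res}\n"
            )
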