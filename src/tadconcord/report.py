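"""Full comparison runs: orchestrate every analysis and write the report.

A run takes two or more TAD datasets on a common binning and produces a
directory of CSV/JSON files mirroring the analysis suite: counts, size
summaries, one-vs-all shared-boundary and shared-domain tables, all-vs-all
sharing profiles, the MoC matrix with per-dataset averages, and PCA/t-SNE
embeddings. A provenance block (config echo, package version, seeds) makes
every run reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .concordance import moc_matrix_and_average, moc_one_vs_all
from .contact import read_dense_matrix, write_dense_matrix
from .core import GenomicBinning, TadSet
from .embedding import pca_embed, tsne_embed, vectorize
from .io import read_tad_set
from .metrics import (
    count_tads,
    one_vs_all_boundaries,
    one_vs_all_domains,
    sharing_profile,
    size_stats,
)
from .normalize import ConvergenceError, normalize

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ComparisonReport", "run_compare", "run_normalize"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one comparison run."""

    tad_paths: tuple[str, ...]
    labels: tuple[str, ...]
    chrom: str
    resolution: int
    n_bins: int
    tolerances: tuple[int, ...] = (0, 1, 2, 3)
    moc: bool = True
    embedding_modes: tuple[str, ...] = ("PCA", "TSNE")
    seed: int = 0
    units: str = "auto"
    out_dir: str = "tadconcord_run"
    plots: bool = False

    def __post_init__(self) -> None:
        if len(self.tad_paths) < 2:
            raise ValueError("comparison needs at least 2 TAD datasets")
        if len(self.labels) != len(self.tad_paths):
            raise ValueError("labels and tad_paths must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    @property
    def binning(self) -> GenomicBinning:
        return GenomicBinning(self.chrom, self.resolution, self.n_bins)


@dataclass
class ComparisonReport:
    """In-memory result of a comparison run; ``write`` emits the files."""

    config: RunConfig
    counts: pd.Series
    size_summaries: pd.DataFrame
    boundary_tables: dict[str, pd.DataFrame]
    domain_tables: dict[str, pd.DataFrame]
    boundary_profiles: dict[int, object]
    domain_profiles: dict[int, object]
    moc_values: pd.DataFrame | None
    moc_averages: pd.Series | None
    moc_one_vs_all: pd.DataFrame | None
    embeddings: dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, out_dir: str | os.PathLike) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        kw = dict(float_format="%.10g")
        self.counts.to_frame("n_tads").to_csv(out / "counts.csv", **kw)
        self.size_summaries.to_csv(out / "size_summaries.csv", **kw)
        for label, table in self.boundary_tables.items():
            table.to_csv(out / f"shared_boundaries_vs_{label}.csv", **kw)
        for label, table in self.domain_tables.items():
            table.to_csv(out / f"shared_domains_vs_{label}.csv", **kw)
        for t, prof in self.boundary_profiles.items():
            prof.counts.to_csv(out / f"boundary_profile_counts_t{t}.csv", **kw)
            prof.percentages.to_csv(out / f"boundary_profile_pct_t{t}.csv", **kw)
        for t, prof in self.domain_profiles.items():
            prof.counts.to_csv(out / f"domain_profile_counts_t{t}.csv", **kw)
            prof.percentages.to_csv(out / f"domain_profile_pct_t{t}.csv", **kw)
        if self.moc_values is not None:
            self.moc_values.to_csv(out / "moc_matrix.csv", **kw)
            self.moc_averages.to_frame("average_moc").to_csv(
                out / "moc_averages.csv", **kw
            )
            self.moc_one_vs_all.to_csv(out / "moc_one_vs_all.csv", **kw)
        for method, df in self.embeddings.items():
            df.to_csv(out / f"embedding_{method.lower()}.csv", **kw)
        provenance = {
            "version": __version__,
            "config": dataclasses.asdict(self.config),
        }
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True) + "\n"
        )
        return out


def run_compare(config: RunConfig, write: bool = True) -> ComparisonReport:
    """Execute the full comparison suite for a run configuration.

    Reads and validates every dataset, computes all analyses, and (when
    ``write`` is true) writes the report directory. Identical configs
    produce byte-identical reports.
    """
    binning = config.binning
    sets: list[TadSet] = []
    for path, label in zip(config.tad_paths, config.labels):
        try:
            sets.append(
                read_tad_set(path, binning, label=label, units=config.units)
            )
        except Exception as exc:
            raise RuntimeError(f"dataset {label!r}: {exc}") from exc
    return compare_sets(
        sets,
        tolerances=config.tolerances,
        moc=config.moc,
        embedding_modes=config.embedding_modes,
        seed=config.seed,
        config=config,
        out_dir=config.out_dir if write else None,
    )


def compare_sets(
    sets: list[TadSet],
    tolerances: tuple[int, ...] = (0, 1, 2, 3),
    moc: bool = True,
    embedding_modes: tuple[str, ...] = ("PCA", "TSNE"),
    seed: int = 0,
    config: RunConfig | None = None,
    out_dir: str | os.PathLike | None = None,
) -> ComparisonReport:
    """Library-level entry point for already-loaded TadSets."""
    if len(sets) < 2:
        raise ValueError("comparison needs at least 2 TAD datasets")
    labels = [s.label for s in sets]
    if config is None:
        b = sets[0].binning
        config = RunConfig(
            tad_paths=tuple(f"<memory:{l}>" for l in labels),
            labels=tuple(labels),
            chrom=b.chrom, resolution=b.resolution, n_bins=b.n_bins,
            tolerances=tuple(int(t) for t in tolerances),
            moc=moc, embedding_modes=tuple(embedding_modes), seed=seed,
        )

    counts = pd.Series(
        [count_tads(s) for s in sets],
        index=pd.Index(labels, name="dataset"), name="n_tads",
    )
    size_summaries = pd.DataFrame(
        [size_stats(s).as_dict() for s in sets],
        index=pd.Index(labels, name="dataset"),
    )

    tol = [int(t) for t in tolerances]
    boundary_tables: dict[str, pd.DataFrame] = {}
    domain_tables: dict[str, pd.DataFrame] = {}
    for s in sets:
        others = [o for o in sets if o is not s]
        boundary_tables[s.label] = one_vs_all_boundaries(s, others, tol)
        domain_tables[s.label] = one_vs_all_domains(s, others, tol)

    boundary_profiles = {t: sharing_profile(sets, t, "boundaries") for t in tol}
    domain_profiles = {t: sharing_profile(sets, t, "domains") for t in tol}

    moc_values = moc_averages = moc_ova = None
    if moc:
        mm = moc_matrix_and_average(sets)
        moc_values, moc_averages = mm.values, mm.averages
        moc_ova = pd.DataFrame(
            {s.label: moc_one_vs_all(s, [o for o in sets if o is not s])
             for s in sets}
        )

    embeddings: dict[str, pd.DataFrame] = {}
    embedding_objects = {}
    if embedding_modes:
        features = vectorize(sets, mode="boundary_dilated", tolerance=1)
        for method in embedding_modes:
            m = method.upper()
            if m == "PCA":
                embedding_objects["PCA"] = pca_embed(features)
            elif m == "TSNE":
                if len(sets) >= 4:
                    embedding_objects["TSNE"] = tsne_embed(features, seed=seed)
                else:
                    logger.warning("t-SNE skipped: needs >= 4 datasets")
            else:
                raise ValueError(f"unknown embedding method {method!r}")
        embeddings = {m: e.as_frame() for m, e in embedding_objects.items()}

    report = ComparisonReport(
        config=config, counts=counts, size_summaries=size_summaries,
        boundary_tables=boundary_tables, domain_tables=domain_tables,
        boundary_profiles=boundary_profiles, domain_profiles=domain_profiles,
        moc_values=moc_values, moc_averages=moc_averages,
        moc_one_vs_all=moc_ova, embeddings=embeddings,
    )
    if out_dir is not None:
        report.write(out_dir)
        if config.plots and embedding_objects:
            from .plotting import plot_embedding

            for m, emb in embedding_objects.items():
                plot_embedding(emb, Path(out_dir) / f"embedding_{m.lower()}.png")
    return report


def run_normalize(
    matrix_path: str | os.PathLike,
    methods: list[str],
    out_dir: str | os.PathLike,
    chrom: str = "chr0",
    resolution: int = 1,
    tol: float = 1e-5,
    max_iter: int | None = None,
) -> dict[str, Path]:
    """Balance one matrix with each requested method; write one file each.

    A method that fails to converge is reported in the convergence log and
    skipped without aborting the remaining methods. Returns the mapping
    method -> output path for the methods that succeeded.
    """
    if not methods:
        raise ValueError("no normalization methods requested")
    matrix = read_dense_matrix(matrix_path, chrom, resolution)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    log_lines = []
    for method in methods:
        m = method.upper().replace("-", "_")
        try:
            result = normalize(matrix, m, max_iter=max_iter, tol=tol)
        except ConvergenceError as exc:
            log_lines.append(f"{m}: FAILED - {exc}")
            logger.error("%s", exc)
            continue
        path = out / f"normalized_{m.lower()}.txt"
        write_dense_matrix(result, path)
        written[m] = path
        log_lines.append(f"{m}: ok -> {path.name}")
    (out / "convergence.log").write_text("\n".join(log_lines) + "\n")
    return written
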