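"""Low-dimensional embeddings that group TAD datasets by similarity.

Each dataset is first turned into a per-bin feature vector on the common
binning; PCA or t-SNE then projects the K datasets to 2D, so datasets
that call similar domains land close together. The feature representation
defaults to dilated boundary indicators, which encodes the same
tolerance-window notion of similarity the sharing metrics use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .core import TadSet, boundaries_of

logger = logging.getLogger(__name__)

__all__ = ["FeatureMatrix", "Embedding2D", "vectorize", "pca_embed", "tsne_embed"]

MODES = ("boundary", "occupancy", "boundary_dilated")


@dataclass(frozen=True)
class FeatureMatrix:
    """K × n_bins per-bin feature vectors, one row per dataset."""

    labels: tuple[str, ...]
    vectors: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.vectors, index=list(self.labels))


@dataclass(frozen=True)
class Embedding2D:
    """2D coordinates per dataset produced by PCA or t-SNE."""

    labels: tuple[str, ...]
    coords: np.ndarray
    method: str
    seed: int | None = None

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords, index=pd.Index(list(self.labels), name="dataset"),
            columns=["x", "y"],
        )
        df["method"] = self.method
        df["seed"] = "" if self.seed is None else self.seed
        return df


def vectorize(
    sets: list[TadSet],
    mode: str = "boundary_dilated",
    tolerance: int = 1,
) -> FeatureMatrix:
    """Encode each dataset as a binary per-bin vector.

    Modes
    -----
    ``boundary``
        1 at every bin holding a domain start or end.
    ``occupancy``
        1 at every bin covered by a domain.
    ``boundary_dilated``
        Boundary indicators dilated by ±``tolerance`` bins, so boundaries
        within the tolerance window overlap in feature space (default,
        tolerance 1).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if len(sets) < 2:
        raise ValueError("vectorize needs at least 2 datasets")
    binning = sets[0].binning
    for s in sets[1:]:
        if s.binning != binning:
            raise ValueError(
                f"binning mismatch: {s.label!r} differs from {sets[0].label!r}"
            )
    n = binning.n_bins
    rows = np.zeros((len(sets), n))
    for r, s in enumerate(sets):
        if mode == "occupancy":
            for d in s:
                rows[r, d.start_bin:d.end_bin] = 1.0
        else:
            for b in boundaries_of(s):
                if mode == "boundary":
                    lo, hi = b, b + 1
                else:
                    lo, hi = b - tolerance, b + tolerance + 1
                rows[r, max(lo, 0):min(hi, n)] = 1.0
    return FeatureMatrix(labels=tuple(s.label for s in sets), vectors=rows)


def pca_embed(features: FeatureMatrix) -> Embedding2D:
    """Project datasets onto the top two principal axes.

    Rows are centered; the sign of each axis is fixed so its
    largest-magnitude loading is positive, making the output
    deterministic. If all datasets are identical (zero variance) every
    point sits at the origin and a warning is logged.
    """
    x = features.vectors
    k = x.shape[0]
    if k < 2:
        raise ValueError("PCA embedding needs at least 2 datasets")
    centered = x - x.mean(axis=0)
    if np.allclose(centered, 0):
        logger.warning("all datasets identical: PCA places every point at origin")
        return Embedding2D(features.labels, np.zeros((k, 2)), method="PCA")
    n_comp = min(2, k, x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(x)
    for c in range(coords.shape[1]):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, c] *= -1
    if coords.shape[1] < 2:  # K = 2: second component is identically zero
        coords = np.hstack([coords, np.zeros((k, 2 - coords.shape[1]))])
    return Embedding2D(features.labels, coords, method="PCA")


def tsne_embed(
    features: FeatureMatrix,
    seed: int = 0,
    perplexity: float | None = None,
) -> Embedding2D:
    """t-SNE embedding of the feature rows; reproducible for a fixed seed.

    Requires K >= 4 datasets. Perplexity defaults to
    ``min(30, (K - 1) / 3)`` and is clamped there (with a warning) if a
    larger value is requested.
    """
    x = features.vectors
    k = x.shape[0]
    if k < 4:
        raise ValueError(f"t-SNE needs at least 4 datasets, got {k}")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature matrix contains non-finite values")
    max_perp = (k - 1) / 3
    if perplexity is None:
        perplexity = min(30.0, max_perp)
    elif perplexity > max_perp:
        logger.warning(
            "perplexity %.3g too large for K=%d datasets; clamped to %.3g",
            perplexity, k, max_perp,
        )
        perplexity = max_perp
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=int(seed),
        init="pca",
        method="exact",
    )
    coords = tsne.fit_transform(x)
    return Embedding2D(features.labels, np.asarray(coords, dtype=float),
                       method="TSNE", seed=int(seed))
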