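"""Optional scatter plots for embedding results."""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .embedding import Embedding2D

__all__ = ["plot_embedding"]


def plot_embedding(embedding: Embedding2D, path: str | os.PathLike) -> None:
    """Write a labelled scatter plot of a 2D embedding to an image file."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(embedding.coords[:, 0], embedding.coords[:, 1], s=40)
    for label, (x, y) in zip(embedding.labels, embedding.coords):
        ax.annotate(label, (x, y), textcoords="offset points", xytext=(4, 4),
                    fontsize=8)
    ax.set_xlabel(f"{embedding.method} 1")
    ax.set_ylabel(f"{embedding.method} 2")
    ax.set_title(f"{embedding.method} embedding of TAD datasets")
    fig.tight_layout()
    fig.savefig(os.fspath(path), dpi=150)
    plt.close(fig)
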