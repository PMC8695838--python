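"""Figure helpers: ancestry painting, triangle plot, tract-length histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_painting", "plot_triangle", "plot_tract_histogram"]

_STATE_COLORS = {-1: "#dddddd", 0: "#1f78b4", 1: "#b2df8a", 2: "#e31a1c"}


def plot_painting(states: np.ndarray, site_table: pd.DataFrame, samples: list[str],
                  path: str | None = None):
    """Ancestry painting: one row per individual, sites ordered by scaffold
    length (longest first), colored hom-0 / het / hom-1 / missing."""
    scaf_len = site_table.groupby("scaffold")["pos"].max().sort_values(ascending=False)
    order = np.concatenate([
        np.flatnonzero((site_table["scaffold"] == s).to_numpy()) for s in scaf_len.index])
    img = states[:, order]
    rgb = np.zeros(img.shape + (3,))
    for val, color in _STATE_COLORS.items():
        rgb[img == val] = matplotlib.colors.to_rgb(color)
    fig, ax = plt.subplots(figsize=(10, 0.4 * len(samples) + 1))
    ax.imshow(rgb, aspect="auto", interpolation="nearest")
    ax.set_yticks(range(len(samples)), samples, fontsize=7)
    ax.set_xlabel("diagnostic sites (scaffolds sorted by length)")
    # scaffold boundaries
    bounds = np.cumsum([(site_table["scaffold"] == s).sum() for s in scaf_len.index])[:-1]
    for b in bounds:
        ax.axvline(b - 0.5, color="grey", lw=0.5)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_triangle(table: pd.DataFrame, path: str | None = None):
    """Hybrid index vs fixed-site heterozygosity with the F1/backcross triangle."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    ax.plot([0, 0.5, 1], [0, 1, 0], color="grey", lw=1, ls="--", zorder=1)
    ax.scatter(table["hybrid_index"], table["heterozygosity"], s=30, zorder=2)
    for _, r in table.iterrows():
        ax.annotate(str(r["sample"]), (r["hybrid_index"], r["heterozygosity"]),
                    fontsize=6, xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel("hybrid index")
    ax.set_ylabel("fixed-site heterozygosity")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.05)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_tract_histogram(tracts: pd.DataFrame, path: str | None = None):
    """Per-individual tract bp-length histograms on a log axis."""
    ids = tracts["id"].unique()
    fig, axes = plt.subplots(len(ids), 1, figsize=(6, 1.4 * len(ids) + 1),
                             sharex=True, squeeze=False)
    edges = np.geomspace(max(tracts["bp"].min(), 1), tracts["bp"].max() + 1, 30)
    for ax, sid in zip(axes.ravel(), ids):
        ax.hist(tracts.loc[tracts["id"] == sid, "bp"], bins=edges)
        ax.set_ylabel(sid, fontsize=7, rotation=0, ha="right")
        ax.set_xscale("log")
    axes.ravel()[-1].set_xlabel("ancestry tract length (bp)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
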