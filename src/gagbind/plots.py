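"""Plotting helpers for benchmark reports (matplotlib, file output only)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from gagbind.analysis import BenchmarkReport, CorrelationMatrix


def density_scatter(predicted, actual, path, title: str = "") -> None:
    """Predicted-vs-actual scatter coloured by 2D kernel density estimate."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    pts = np.vstack([actual, predicted])
    try:
        color = gaussian_kde(pts)(pts)
    except np.linalg.LinAlgError:  # degenerate cloud
        color = np.zeros(len(predicted))
    fig, ax = plt.subplots(figsize=(5, 5))
    order = np.argsort(color)
    ax.scatter(actual[order], predicted[order], c=color[order], s=6, cmap="viridis")
    lims = [min(actual.min(), predicted.min()), max(actual.max(), predicted.max())]
    ax.plot(lims, lims, "r--", lw=1, label="ideal (y = x)")
    ax.set_xlabel("actual MM-GBSA energy (kcal/mol)")
    ax.set_ylabel("predicted (kcal/mol)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def mae_bars(report: BenchmarkReport, path, with_lie: bool = True) -> None:
    """Per-family MAE bars on train/test/validation, with repetition error bars."""
    df = report.to_frame()
    df = df[df["with_lie"] == with_lie]
    if df.empty:
        raise ValueError("no benchmark cells to plot")
    fig, ax = plt.subplots(figsize=(9, 4))
    splits = list(dict.fromkeys(df["split"]))
    families = list(dict.fromkeys(df["family"]))
    width = 0.8 / len(splits)
    x = np.arange(len(families))
    for si, split in enumerate(splits):
        sub = df[df["split"] == split].set_index("family").reindex(families)
        ax.bar(x + si * width, sub["mae_mean"], width, yerr=sub["mae_std"],
               label=split, capsize=2)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(families, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("MAE (kcal/mol)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def correlation_heatmap(matrix: CorrelationMatrix, path) -> None:
    """Correlation matrix heatmap, reordered by the clustering leaf order."""
    order = list(matrix.leaf_order) if matrix.leaf_order else list(range(len(matrix.labels)))
    r = matrix.r.to_numpy()[np.ix_(order, order)]
    labels = [matrix.labels[i] for i in order]
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(r, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def reduction_curve_plot(points: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(points["fraction"] * 100, points["r2"], "o-")
    ax.set_xscale("log")
    ax.set_xlabel("training data retained (%)")
    ax.set_ylabel("validation R$^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
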