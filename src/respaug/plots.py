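"""Report figures: per-class FAD bars, cross-correlation heatmaps, MCD
bars, and 2-d PCA scatters of MFCC summary features (real vs synthetic).

All functions write PNG files and return the path; the Agg backend is
forced so they run headless.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def fad_bars(fad_by_variant: dict[str, dict[str, float]],
             path) -> Path:
    """Grouped bar chart of per-class FAD for each generative model."""
    variants = sorted(fad_by_variant)
    classes = sorted(next(iter(fad_by_variant.values())))
    x = np.arange(len(classes))
    width = 0.8 / len(variants)
    fig, ax = plt.subplots(figsize=(8, 4))
    for i, v in enumerate(variants):
        ax.bar(x + i * width, [fad_by_variant[v][c] for c in classes],
               width, label=v)
    ax.set_xticks(x + width, classes, rotation=30, ha="right")
    ax.set_ylabel("FAD")
    ax.set_title("Fréchet Audio Distance of synthetic vs real audio")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)


def cc_heatmap(mean: dict[str, dict[str, float]], path,
               title: str = "mean max cross-correlation") -> Path:
    """Heatmap of mean maximum correlation, synthetic class x real class."""
    syn_classes = sorted(mean)
    real_classes = sorted(next(iter(mean.values())))
    grid = np.array([[mean[s][r] for r in real_classes]
                     for s in syn_classes])
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(grid, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(real_classes)), real_classes, rotation=30,
                  ha="right")
    ax.set_yticks(range(len(syn_classes)), syn_classes)
    ax.set_xlabel("real class")
    ax.set_ylabel("synthetic class")
    ax.set_title(title)
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            ax.text(j, i, f"{grid[i, j]:.2f}", ha="center", va="center",
                    fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)


def mcd_bars(mean: dict[str, dict[str, float]],
             std: dict[str, dict[str, float]], path) -> Path:
    """Per-class MCD mean ± std for each generative model."""
    variants = sorted(mean)
    classes = sorted(next(iter(mean.values())))
    x = np.arange(len(classes))
    width = 0.8 / len(variants)
    fig, ax = plt.subplots(figsize=(8, 4))
    for i, v in enumerate(variants):
        ax.bar(x + i * width, [mean[v][c] for c in classes], width,
               yerr=[std[v][c] for c in classes], capsize=2, label=v)
    ax.set_xticks(x + width, classes, rotation=30, ha="right")
    ax.set_ylabel("MCD (dB)")
    ax.set_title("DTW-aligned mel cepstral distortion")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)


def pca_scatter(real_coords: np.ndarray, syn_coords: np.ndarray,
                label: str, path) -> Path:
    """Real vs synthetic 39-d MFCC summaries projected to 2 dimensions."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(real_coords[:, 0], real_coords[:, 1], s=18, alpha=0.8,
               label="real")
    ax.scatter(syn_coords[:, 0], syn_coords[:, 1], s=18, alpha=0.5,
               marker="x", label="synthetic")
    ax.set_xlabel("PC 1")
    ax.set_ylabel("PC 2")
    ax.set_title(f"MFCC summary features, {label}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)


def confusion_heatmap(cm: np.ndarray, class_labels, path,
                      title: str = "confusion matrix") -> Path:
    fig, ax = plt.subplots(figsize=(5.5, 5))
    ax.imshow(cm, cmap="Blues")
    ax.set_xticks(range(len(class_labels)), class_labels, rotation=30,
                  ha="right")
    ax.set_yticks(range(len(class_labels)), class_labels)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(title)
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, str(int(cm[i, j])), ha="center", va="center",
                    fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)
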