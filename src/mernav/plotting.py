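"""Summary figures: group-averaged NRMS curves and depth spectrograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

GROUP_COLORS = {"awake": "tab:blue", "ketamine": "tab:gray", "n2o": "tab:red"}


def plot_nrms_curves(grid, curves_by_group, path) -> Path:
    """Mean ± SEM NRMS per group on the normalized depth axis."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for g, (mean, sem) in curves_by_group.items():
        color = GROUP_COLORS.get(g)
        ax.plot(grid, mean, label=g, color=color)
        if np.isfinite(sem).all():
            ax.fill_between(grid, mean - sem, mean + sem, alpha=0.25,
                            color=color, linewidth=0)
    ax.axvline(0.0, ls="--", c="k", lw=0.8)
    ax.axvline(1.0, ls="--", c="k", lw=0.8)
    ax.set_xlabel("normalized distance (0 = STN entry, 1 = exit)")
    ax.set_ylabel("NRMS")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_depth_spectrogram(grid, freqs, matrix_percent, path, fmax=60.0,
                           title="") -> Path:
    """Depth x frequency heat map (percent of total power)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    keep = freqs <= fmax
    im = ax.pcolormesh(grid, freqs[keep], matrix_percent[:, keep].T,
                       shading="auto", cmap="viridis")
    fig.colorbar(im, ax=ax, label="% of total power")
    ax.set_xlabel("normalized distance (0 = STN entry, 1 = exit)")
    ax.set_ylabel("frequency (Hz)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_metric_by_group(values_by_group, ylabel, path) -> Path:
    """Per-group scatter with group means, violin-style summary."""
    fig, ax = plt.subplots(figsize=(5, 4))
    names = list(values_by_group)
    data = [np.asarray(values_by_group[g], dtype=float) for g in names]
    parts = ax.violinplot(data, showmedians=True)
    for body, g in zip(parts["bodies"], names):
        body.set_facecolor(GROUP_COLORS.get(g, "C0"))
    for i, v in enumerate(data, start=1):
        ax.scatter(np.full_like(v, i) + np.random.default_rng(0).uniform(
            -0.06, 0.06, v.size), v, s=8, c="gold", edgecolors="k",
            linewidths=0.3, zorder=3)
    ax.set_xticks(range(1, len(names) + 1), names)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
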