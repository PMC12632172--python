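"""Diagnostic plots: posterior heatmaps, convergence traces, cost bars."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .design_space import DesignSpace  # noqa: E402
from .surrogate import PosteriorField, clip_probability  # noqa: E402


def plot_posterior_2d(
    field: PosteriorField,
    space: DesignSpace,
    dims: tuple[int, int] = (0, 1),
    samples=None,
    path=None,
):
    """Heatmap of the (clipped) posterior mean over a 2D grid field.

    ``samples`` may be an (n, 2) array of flow coordinates, or (n, 3)
    with the observed PS fraction as the third column (used as the
    marker colour).
    """
    field = clip_probability(field)
    n = round(np.sqrt(len(field.points)))
    if n * n != len(field.points):
        raise ValueError("posterior heatmap requires a 2D square grid field")
    x = field.points[:, 0].reshape(n, n)
    y = field.points[:, 1].reshape(n, n)
    mu = field.mu.reshape(n, n)
    fig, ax = plt.subplots(figsize=(5, 4))
    pcm = ax.pcolormesh(x, y, mu, cmap="coolwarm", vmin=0, vmax=1, shading="auto")
    fig.colorbar(pcm, ax=ax, label="predicted PS fraction")
    if samples is not None:
        samples = np.asarray(samples, dtype=float)
        colors = samples[:, 2] if samples.shape[1] > 2 else "k"
        ax.scatter(
            samples[:, 0], samples[:, 1], c=colors, cmap="coolwarm",
            vmin=0, vmax=1, edgecolors="k", s=30, linewidths=0.7,
        )
    ax.set_xlabel(f"{space.names[dims[0]]} flow (µL/h)")
    ax.set_ylabel(f"{space.names[dims[1]]} flow (µL/h)")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_convergence(trace_df, space: DesignSpace, path=None):
    """RSS-KL trace plus per-dimension transect RSS and length scales."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    axes[0].plot(trace_df["iteration"], trace_df["rss_kl"], "o-")
    axes[0].set_yscale("log")
    axes[0].set_xlabel("iteration")
    axes[0].set_ylabel("RSS KL divergence")
    for name in space.names:
        axes[1].plot(trace_df["iteration"], trace_df[f"rss_kl_{name}"], "o-", label=name)
        axes[2].plot(
            trace_df["iteration"], trace_df[f"length_scale_{name}"], "o-", label=name
        )
    axes[1].set_yscale("log")
    axes[1].set_xlabel("iteration")
    axes[1].set_ylabel("per-dimension RSS KL")
    axes[2].set_xlabel("iteration")
    axes[2].set_ylabel("length scale (µL/h)")
    axes[1].legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_cost_comparison(table, path=None):
    """Grouped bars of total time and material per workflow and dims."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 3.5))
    for ax, col, label in (
        (axes[0], "total_min", "total time (min)"),
        (axes[1], "material_mg", "material (mg)"),
    ):
        for method, sub in table.groupby("method"):
            ax.plot(sub["dims"], sub[col], "o-", label=method)
        ax.set_yscale("log")
        ax.set_xlabel("dimensions")
        ax.set_ylabel(label)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
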