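"""Matplotlib figure builders for profiles, heatmaps, tracks and modules.

Every function returns a Figure; :func:`save_figure` writes it with
metadata stripped so identical inputs produce identical image bytes.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from methagene.clustering import ModuleAssignment
from methagene.types import MetageneProfile, RankedHeatmap

__all__ = [
    "plot_profile",
    "plot_heatmap",
    "plot_chromosome_levels",
    "plot_distributions",
    "plot_modules",
    "save_figure",
]


def _mark_flanks(ax, flank_bins: int, body_bins: int) -> None:
    if flank_bins > 0:
        ax.axvline(flank_bins - 0.5, color="grey", lw=0.8, ls="--")
        ax.axvline(flank_bins + body_bins - 0.5, color="grey", lw=0.8, ls="--")
        ax.set_xticks(
            [flank_bins / 2, flank_bins + body_bins / 2, 1.5 * flank_bins + body_bins]
        )
        ax.set_xticklabels(["upstream", "body", "downstream"])


def plot_profile(profiles, labels=None, title: str | None = None):
    """Overlay one or more metagene profiles with their confidence bands."""
    if isinstance(profiles, MetageneProfile):
        profiles = [profiles]
    labels = labels or [p.sample_id or f"profile {i}" for i, p in enumerate(profiles)]
    fig, ax = plt.subplots(figsize=(7, 4))
    for prof, label in zip(profiles, labels):
        x = np.arange(prof.n_total_bins)
        ax.fill_between(x, prof.ci_lower, prof.ci_upper, alpha=0.25, linewidth=0)
        ax.plot(x, prof.smoothed_mean, lw=1.6, label=f"{label} ({prof.context})")
    _mark_flanks(ax, profiles[0].flank_bins, profiles[0].body_bins)
    ax.set_ylabel("methylation density")
    ax.set_xlabel("metagene bin")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def plot_heatmap(heatmap: RankedHeatmap, title: str | None = None):
    """Regions (ranked by overall methylation density) x bins heatmap."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(
        np.ma.masked_invalid(heatmap.values),
        aspect="auto",
        interpolation="nearest",
        cmap="viridis",
        vmin=0,
        vmax=1,
    )
    _mark_flanks(ax, heatmap.flank_bins, heatmap.body_bins)
    ax.set_ylabel("regions (high → low methylation)")
    ax.set_xlabel("metagene bin")
    fig.colorbar(im, ax=ax, label="density")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_chromosome_levels(tracks: pd.DataFrame, title: str | None = None):
    """One panel per chromosome; one line per context along the windows."""
    chroms = sorted(tracks["chrom"].unique())
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(8, 1.8 * max(len(chroms), 1)), squeeze=False,
        sharex=False,
    )
    for ax, chrom in zip(axes.ravel(), chroms):
        sub = tracks[tracks["chrom"] == chrom]
        for ctx, grp in sub.groupby("context", observed=True):
            ax.plot(
                (grp["window_start"] + grp["window_length"] / 2) / 1e6,
                grp["density"],
                lw=1.2,
                label=ctx,
            )
        ax.set_ylabel(chrom, fontsize=8)
        ax.set_ylim(0, 1)
    axes.ravel()[0].legend(frameon=False, fontsize=7, ncol=3)
    axes.ravel()[-1].set_xlabel("position (Mb)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def plot_distributions(summary: pd.DataFrame, values=None, title: str | None = None):
    """Violin (when raw values are given) or box representation of
    per-region density distributions per labelled entry."""
    fig, ax = plt.subplots(figsize=(6, 4))
    labels = summary["label"].tolist() if "label" in summary else summary["sample_id"].tolist()
    if values is not None:
        ax.violinplot([np.asarray(v) for v in values], showmedians=True)
    else:
        boxes = [
            {
                "label": row.get("label", row.get("sample_id", "")),
                "med": row["median"],
                "q1": row["q1"],
                "q3": row["q3"],
                "whislo": row["whisker_low"],
                "whishi": row["whisker_high"],
                "fliers": [],
            }
            for _, row in summary.iterrows()
        ]
        ax.bxp(boxes, showfliers=False)
    ax.set_xticks(np.arange(1, len(labels) + 1))
    ax.set_xticklabels(labels, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("methylation density")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_modules(matrix, assignment: ModuleAssignment, profiles: pd.DataFrame,
                 title: str | None = None):
    """Heatmap with rows grouped by module plus consensus line plots."""
    order = np.argsort(assignment.labels, kind="stable")
    order = order[assignment.labels[order] > 0]
    fig, (ax0, ax1) = plt.subplots(
        1, 2, figsize=(10, 4.5), gridspec_kw={"width_ratios": [1.2, 1]}
    )
    im = ax0.imshow(
        np.ma.masked_invalid(matrix.density[order]),
        aspect="auto",
        interpolation="nearest",
        cmap="viridis",
        vmin=0,
        vmax=1,
    )
    ax0.set_ylabel("regions grouped by module")
    ax0.set_xlabel("metagene bin")
    fig.colorbar(im, ax=ax0, label="density")
    bin_cols = [c for c in profiles.columns if c.startswith("bin_")]
    for _, row in profiles.iterrows():
        ax1.plot(
            np.arange(len(bin_cols)),
            row[bin_cols].to_numpy(float),
            lw=1.5,
            label=f"module {int(row['module_id'])} (n={int(row['n_members'])})",
        )
    ax1.set_xlabel("metagene bin")
    ax1.set_ylabel("consensus density")
    ax1.legend(frameon=False, fontsize=7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def save_figure(fig, path, fmt: str = "png") -> None:
    """Write a figure without volatile metadata (dates, hashes), so reruns
    on identical inputs give identical bytes."""
    if fmt == "svg":
        with plt.rc_context({"svg.hashsalt": "methagene"}):
            fig.savefig(path, format="svg", metadata={"Date": None})
    else:
        fig.savefig(path, format=fmt)
    plt.close(fig)
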