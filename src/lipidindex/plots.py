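"""Plot emission for the analysis bundle.

Every figure's numeric backing table is written by the pipeline alongside
the image; the plots themselves are conventional matplotlib renderings
(bar, radar, three-panel volcano, bubble, correlation heatmap, PCA/PLS-DA
scores with Hotelling ellipses, VIP bars, clustered heatmap with
dendrograms) and carry no information that is not in the CSVs.
"""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Ellipse
from scipy.cluster import hierarchy

from .multivariate import hotelling_ellipse

CATEGORY_COLORS = {"Structural": "#4C72B0", "Signaling": "#DD8452", "Energy": "#55A868"}


def _savefig(fig, path):
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def summary_bars(comparison: pd.DataFrame, path) -> None:
    t = comparison[comparison["comparable"]].sort_values("log2fc")
    fig, ax = plt.subplots(figsize=(7, max(3, 0.25 * len(t))))
    colors = [CATEGORY_COLORS.get(c, "grey") for c in t["category"]]
    ax.barh(t["name"], t["log2fc"], xerr=t["se_log2fc"], color=colors)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("log2 fold change (EXP vs CTRL)")
    _savefig(fig, path)


def radar_plot(comparison: pd.DataFrame, path) -> None:
    t = comparison[comparison["comparable"]]
    if len(t) < 3:
        return
    angles = np.linspace(0, 2 * math.pi, len(t), endpoint=False)
    values = t["log2fc"].to_numpy()
    fig = plt.figure(figsize=(7, 7))
    ax = fig.add_subplot(polar=True)
    ax.plot(np.r_[angles, angles[:1]], np.r_[values, values[:1]], lw=1.2)
    ax.fill(np.r_[angles, angles[:1]], np.r_[values, values[:1]], alpha=0.25)
    ax.set_xticks(angles)
    ax.set_xticklabels(t["name"], fontsize=6)
    _savefig(fig, path)


def dominance_bars(dominance: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(
        dominance["category"],
        dominance["dominance"].fillna(0.0),
        color=[CATEGORY_COLORS.get(c, "grey") for c in dominance["category"]],
    )
    ax.set_ylabel("dominance (sum sig |log2FC| / n evaluated)")
    _savefig(fig, path)


def volcano_panels(comparison: pd.DataFrame, path, p_threshold=0.05, fc_threshold=1.0) -> None:
    t = comparison[comparison["comparable"]]
    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=True)
    for ax, cat in zip(axes, ("Structural", "Signaling", "Energy")):
        sub = t[t["category"] == cat]
        if not sub.empty:
            logp = -np.log10(sub["p_value"].clip(lower=1e-300))
            ax.scatter(sub["log2fc"], logp,
                       c=np.where(sub["significant"], CATEGORY_COLORS[cat], "lightgrey"))
        ax.axhline(-math.log10(p_threshold), ls="--", c="k", lw=0.7)
        for x in (-fc_threshold, fc_threshold):
            ax.axvline(x, ls="--", c="k", lw=0.7)
        ax.set_title(cat)
        ax.set_xlabel("log2FC")
    axes[0].set_ylabel("-log10 p")
    _savefig(fig, path)


def bubble_plot(comparison: pd.DataFrame, path, top: int = 10) -> None:
    """Bubble heatmap of the top indices (smallest p); size = significance,
    colour = fold change."""
    t = comparison[comparison["comparable"]].nsmallest(top, "p_value")
    if t.empty:
        return
    fig, ax = plt.subplots(figsize=(5, max(2.5, 0.4 * len(t))))
    logp = -np.log10(t["p_value"].clip(lower=1e-300))
    sc = ax.scatter(
        np.zeros(len(t)), range(len(t)), s=40 * (1 + logp), c=t["log2fc"],
        cmap="coolwarm", vmin=-max(abs(t["log2fc"])), vmax=max(abs(t["log2fc"])),
    )
    ax.set_yticks(range(len(t)))
    ax.set_yticklabels(t["name"], fontsize=7)
    ax.set_xticks([])
    fig.colorbar(sc, label="log2FC")
    _savefig(fig, path)


def correlation_heatmap(corr: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.columns)))
    ax.set_xticklabels(corr.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(len(corr.index)))
    ax.set_yticklabels(corr.index, fontsize=5)
    fig.colorbar(im, label="correlation")
    _savefig(fig, path)


def score_plot(latent, groups: pd.Series, path, with_ellipses: bool = False) -> None:
    scores = latent.scores
    if scores.shape[1] < 2:
        return
    fig, ax = plt.subplots(figsize=(5, 5))
    for g in pd.unique(groups):
        pts = scores.loc[groups.index[groups == g]].iloc[:, :2].to_numpy()
        ax.scatter(pts[:, 0], pts[:, 1], label=str(g))
        if with_ellipses and len(pts) >= 3:
            e = hotelling_ellipse(pts)
            ax.add_patch(
                Ellipse(e["center"], e["width"], e["height"], angle=e["angle_deg"],
                        fill=False, ls="--")
            )
    labels = [
        f"{c} ({f * 100:.1f}%)" for c, f in zip(scores.columns[:2], latent.explained[:2])
    ]
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    ax.legend()
    _savefig(fig, path)


def loading_plot(latent, path) -> None:
    loadings = latent.loadings
    if loadings.shape[1] < 2:
        return
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(loadings.iloc[:, 0], loadings.iloc[:, 1], s=10)
    for name, row in loadings.iterrows():
        ax.annotate(name, (row.iloc[0], row.iloc[1]), fontsize=5)
    ax.axhline(0, c="k", lw=0.5)
    ax.axvline(0, c="k", lw=0.5)
    ax.set_xlabel(loadings.columns[0])
    ax.set_ylabel(loadings.columns[1])
    _savefig(fig, path)


def vip_bars(vip: pd.Series, path) -> None:
    v = vip.sort_values(ascending=True)
    fig, ax = plt.subplots(figsize=(6, max(3, 0.2 * len(v))))
    ax.barh(v.index, v.to_numpy())
    ax.axvline(1.0, ls="--", c="k", lw=0.8)
    ax.set_xlabel("VIP")
    _savefig(fig, path)


def heatmap_figure(hm, path) -> None:
    fig = plt.figure(figsize=(9, 7))
    ax_dend = fig.add_axes([0.05, 0.75, 0.65, 0.2])
    hierarchy.dendrogram(hm.sample_linkage, ax=ax_dend, no_labels=True, color_threshold=0)
    ax_dend.axis("off")
    ax = fig.add_axes([0.05, 0.05, 0.65, 0.68])
    ax.imshow(hm.matrix.to_numpy().T, aspect="auto", cmap="vlag" if hasattr(plt.cm, "vlag") else "RdBu_r")
    ax.set_xticks(range(len(hm.matrix.index)))
    ax.set_xticklabels(hm.matrix.index, rotation=90, fontsize=5)
    ax.set_yticks(range(len(hm.matrix.columns)))
    ax.set_yticklabels(hm.matrix.columns, fontsize=5)
    _savefig(fig, path)


def emit_all(model, results, pca_model, pls, hm, corr, outdir) -> None:
    """Write the standard figure set next to their backing tables."""
    if results is not None:
        summary_bars(results.comparison, outdir / "summary_bars.png")
        radar_plot(results.comparison, outdir / "radar.png")
        dominance_bars(results.dominance(), outdir / "dominance.png")
        volcano_panels(results.comparison, outdir / "volcano.png",
                       results.p_threshold, results.fc_threshold)
        bubble_plot(results.comparison, outdir / "bubble.png")
    correlation_heatmap(corr, outdir / "correlations.png")
    score_plot(pca_model, model.groups, outdir / "pca_scores.png")
    loading_plot(pca_model, outdir / "pca_loadings.png")
    score_plot(pls, model.groups, outdir / "plsda_scores.png", with_ellipses=True)
    loading_plot(pls, outdir / "plsda_loadings.png")
    vip_bars(pls.vip, outdir / "vip.png")
    heatmap_figure(hm, outdir / "heatmap.png")
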