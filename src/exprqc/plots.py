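"""Figure rendering for the QC report.

One function per figure, all writing through a non-interactive backend;
:func:`render_all` walks the computed report and emits whichever figures
have results: counts-distribution box plot, mapped-read density,
housekeeping profiles, both PCA scatter plots, the MFA factor map (or a
skip note), the sample dendrogram, Pearson/Spearman heatmaps, GC-bias
curves and the optional single-gene expression plot.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .bias import HousekeepingSkipped
from .multivariate import CorrelationResult, MFAResult, MFASkipped, PCAResult
from .normalize import log2p1


def _group_colors(groups: pd.Series) -> dict[str, str]:
    cmap = plt.get_cmap("tab10")
    return {g: cmap(i % 10) for i, g in enumerate(dict.fromkeys(groups))}


def _save(fig, path: Path, outputs: list[str]) -> None:
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    outputs.append(path.name)


def plot_count_distribution(report, path: Path, outputs: list[str]) -> None:
    logged = log2p1(report.dataset.counts).values
    fig, ax = plt.subplots(figsize=(1.2 * logged.shape[1] + 2, 4))
    ax.boxplot(
        [logged[c].to_numpy() for c in logged.columns], tick_labels=list(logged.columns)
    )
    ax.set_ylabel("log2(count + 1)")
    ax.set_title("Counts distribution")
    ax.tick_params(axis="x", rotation=45)
    _save(fig, path, outputs)


def plot_density(report, path: Path, outputs: list[str]) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in report.density:
        style = {"linestyle": ":"} if curve.flat else {}
        ax.plot(curve.grid, curve.density, label=curve.sample_id, **style)
    ax.set_xlabel("log2(normalized expression + 1)")
    ax.set_ylabel("density")
    ax.set_title("Mapped read density")
    ax.legend(fontsize=7)
    _save(fig, path, outputs)


def plot_housekeeping(report, path: Path, outputs: list[str]) -> None:
    hk = report.housekeeping
    if isinstance(hk, HousekeepingSkipped) or hk is None:
        return
    df = pd.DataFrame({p.gene: p.values for p in hk})
    x = np.arange(len(df))
    width = 0.38
    fig, ax = plt.subplots(figsize=(1.0 * len(df) + 2, 4))
    for i, gene in enumerate(df.columns):
        ax.bar(x + (i - 0.5) * width, df[gene], width, label=gene)
    ax.set_xticks(x, df.index, rotation=45)
    ax.set_ylabel("log2(count + 1)")
    ax.set_title("Housekeeping gene expression")
    ax.legend()
    _save(fig, path, outputs)


def _plot_pca(result: PCAResult, groups: pd.Series, title: str, path: Path, outputs) -> None:
    colors = _group_colors(groups)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for sample in result.scores.index:
        x, y = result.scores.loc[sample, ["PC1", "PC2"]] if "PC2" in result.scores else (
            result.scores.loc[sample, "PC1"],
            0.0,
        )
        ax.scatter(x, y, color=colors[groups[sample]], s=40)
        ax.annotate(sample, (x, y), fontsize=7, xytext=(3, 3), textcoords="offset points")
    ve = result.variance_explained
    ax.set_xlabel(f"PC1 ({100 * ve[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * ve[1]:.1f}%)" if len(ve) > 1 else "PC2")
    ax.set_title(title)
    _save(fig, path, outputs)


def plot_mfa(report, path: Path, note_path: Path, outputs: list[str]) -> None:
    res = report.mfa
    if res is None:
        return
    if isinstance(res, MFASkipped):
        note_path.write_text(f"MFA not computed: {res.reason}\n")
        outputs.append(note_path.name)
        return
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4.5))
    groups = report.dataset.pheno.groups
    colors = _group_colors(groups)
    for sample in res.scores.index:
        x = res.scores.loc[sample, "PC1"]
        y = res.scores.loc[sample, "PC2"] if "PC2" in res.scores else 0.0
        ax1.scatter(x, y, color=colors[groups[sample]], s=40)
        ax1.annotate(sample, (x, y), fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax1.set_xlabel("PC1")
    ax1.set_ylabel("PC2")
    ax1.set_title("MFA sample map")
    contrib = res.group_contributions["PC1"]
    ax2.bar(contrib.index, contrib.to_numpy())
    ax2.set_ylabel("share of component 1")
    ax2.set_title("Group contributions")
    ax2.tick_params(axis="x", rotation=30)
    _save(fig, path, outputs)


def plot_dendrogram(report, path: Path, outputs: list[str]) -> None:
    fig, ax = plt.subplots(figsize=(1.0 * len(report.dataset.sample_ids) + 2, 4))
    hierarchy.dendrogram(
        report.dendrogram.linkage_matrix,
        labels=report.dendrogram.sample_ids,
        ax=ax,
        leaf_rotation=45,
    )
    ax.set_ylabel("Euclidean distance")
    ax.set_title(f"Hierarchical clustering ({report.dendrogram.method} linkage)")
    _save(fig, path, outputs)


def plot_correlation(res: CorrelationResult, path: Path, outputs: list[str]) -> None:
    order = res.leaf_order
    mat = res.matrix.loc[order, order]
    fig, ax = plt.subplots(figsize=(5.5, 4.8))
    im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(order)), order, fontsize=7)
    ax.set_title(f"{res.method.capitalize()} correlation")
    fig.colorbar(im, ax=ax, shrink=0.85)
    _save(fig, path, outputs)


def plot_gc_bias(report, path: Path, outputs: list[str]) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in report.gc_curves:
        ax.plot(curve.gc, curve.fitted, label=curve.sample_id)
    ax.set_xlabel("GC fraction")
    ax.set_ylabel("LOWESS of log2(count + 1)")
    ax.set_title("GC bias")
    ax.legend(fontsize=7)
    _save(fig, path, outputs)


def plot_gene(report, path: Path, outputs: list[str]) -> None:
    prof = report.gene
    fig, ax = plt.subplots(figsize=(1.0 * len(prof.values) + 2, 4))
    ax.bar(prof.values.index, prof.values.to_numpy())
    ax.set_ylabel("log2(count + 1)")
    ax.set_title(f"Expression of {prof.gene}")
    ax.tick_params(axis="x", rotation=45)
    _save(fig, path, outputs)


def render_all(report, config, outdir: Path) -> None:
    ext = config.plot_format
    out = report.outputs
    groups = report.dataset.pheno.groups
    if report.distribution is not None:
        plot_count_distribution(report, outdir / f"count_distribution.{ext}", out)
    if report.density is not None:
        plot_density(report, outdir / f"mapped_density.{ext}", out)
    if report.housekeeping is not None:
        plot_housekeeping(report, outdir / f"housekeeping.{ext}", out)
    if report.pca_zscored is not None:
        _plot_pca(
            report.pca_zscored, groups, "PCA (z-score normalized)",
            outdir / f"pca_zscored.{ext}", out,
        )
    if report.pca_unnormalized is not None:
        _plot_pca(
            report.pca_unnormalized, groups, "PCA (un-normalized)",
            outdir / f"pca_unnormalized.{ext}", out,
        )
    plot_mfa(report, outdir / f"mfa.{ext}", outdir / "mfa_skipped.txt", out)
    if report.dendrogram is not None:
        plot_dendrogram(report, outdir / f"dendrogram.{ext}", out)
    for res in (report.pearson, report.spearman):
        if res is not None:
            plot_correlation(res, outdir / f"correlation_{res.method}.{ext}", out)
    if report.gc_curves is not None:
        plot_gc_bias(report, outdir / f"gc_bias.{ext}", out)
    if report.gene is not None:
        plot_gene(report, outdir / f"gene_{report.gene.gene}.{ext}", out)
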