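"""Figure rendering for pipeline outputs.

Four figure kinds: the score-matrix heatmap (red = upregulated, green =
downregulated, grey = not measured), the quadrant scatter of IBD-vs-tumor
mean fold changes, per-cluster line charts of mean Log2FC along the disease
axis, and per-comparison volcano plots.  Guide lines default to the
significance criteria used everywhere else: |Log2FC| = 1 and
-Log10Q = 1.3 (Q = 0.05).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap

from .diffexpr import StageComparison
from .ingest import STAGES
from .integrate import (
    DEFAULT_FC_THRESHOLD,
    DEFAULT_Q_THRESHOLD,
    ClusterResult,
    GroupAssignment,
    ScoreMatrix,
    score_gene,
)

#: Diverging palette: green (down) -> white -> red (up).
SCORE_CMAP = LinearSegmentedColormap.from_list(
    "chemoatlas_score", ["#1a7837", "#f7f7f7", "#b2182b"]
)

GROUP_COLORS = {"i": "#b2182b", "ii": "#e08214", "iii": "#878787", "iv": "#1a7837"}

_STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p_value: float) -> str:
    """Conventional star annotation: * p<0.05, ** p<0.01, *** p<0.001,
    **** p<0.0001; empty string otherwise."""
    for threshold, stars in _STAR_THRESHOLDS:
        if p_value < threshold:
            return stars
    return ""


def volcano_flags(
    comparison: StageComparison,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> set[str]:
    """Genes beyond both volcano guide lines — by construction exactly the
    genes whose significance vote is nonzero."""
    return {
        gene
        for gene, result in comparison.results.items()
        if score_gene(result, fc_threshold, q_threshold) != 0
    }


def plot_heatmap(
    matrix: ScoreMatrix,
    clusters: Optional[ClusterResult] = None,
    path: Union[str, Path] = "heatmap.png",
) -> Path:
    """Score-matrix heatmap; genes ordered by cluster then dendrogram leaf
    order when a clustering is given, missing cells rendered grey."""
    if matrix.values.empty:
        raise ValueError("score matrix is empty")
    if clusters is not None:
        leaf = clusters.leaf_order()
        order = sorted(leaf, key=lambda g: (clusters.labels[g], leaf.index(g)))
        order += [g for g in matrix.genes if g not in set(order)]
    else:
        order = list(matrix.genes)
    data = matrix.values.reindex(order)
    fig, ax = plt.subplots(
        figsize=(2 + 0.6 * len(matrix.stages), 1 + 0.22 * len(order))
    )
    cmap = SCORE_CMAP.copy()
    cmap.set_bad("#cccccc")
    masked = np.ma.masked_invalid(data.to_numpy(dtype=float))
    im = ax.imshow(masked, cmap=cmap, vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(len(data.columns)), data.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(order)), order, fontsize=6)
    fig.colorbar(im, ax=ax, label="ratio of significant difference")
    ax.set_title("Chemokine significance votes per stage")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_scatter(
    assignments: Sequence[GroupAssignment],
    path: Union[str, Path] = "scatter.png",
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> Path:
    """IBD-vs-tumor mean Log2FC scatter with +/- threshold guide lines and
    points colored by quadrant group."""
    fig, ax = plt.subplots(figsize=(6, 6))
    for group in ("i", "ii", "iii", "iv"):
        pts = [a for a in assignments if a.group == group]
        if pts:
            ax.scatter(
                [a.x for a in pts],
                [a.y for a in pts],
                s=22,
                color=GROUP_COLORS[group],
                label=f"group {group} (n={len(pts)})",
            )
    for value in (fc_threshold, -fc_threshold):
        ax.axvline(value, color="grey", linestyle="--", linewidth=0.8)
        ax.axhline(value, color="grey", linestyle="--", linewidth=0.8)
    ax.set_xlabel("mean Log2FC, IBD vs healthy")
    ax.set_ylabel("mean Log2FC, tumor (adenoma/carcinoma) vs healthy")
    ax.legend(loc="best", fontsize=8)
    ax.set_title("Expression-pattern groups")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_lines(
    comparisons: Sequence[StageComparison],
    groups: Mapping[str, str],
    path: Union[str, Path] = "lines.png",
) -> Path:
    """Mean Log2FC per stage, one line per group, for one dataset's
    stage-vs-healthy comparisons (``groups`` maps gene -> group label)."""
    by_stage = {c.contrast.test_stage: c for c in comparisons}
    stages = [s for s in STAGES if s in by_stage]
    if not stages:
        raise ValueError("no stage comparisons supplied")
    fig, ax = plt.subplots(figsize=(6, 4))
    labels = sorted(set(groups.values()))
    for label in labels:
        members = [g for g, lab in groups.items() if lab == label]
        means = []
        for stage in stages:
            values = [
                by_stage[stage].results[g].log2fc
                for g in members
                if g in by_stage[stage].results
            ]
            means.append(np.mean(values) if values else np.nan)
        color = GROUP_COLORS.get(str(label))
        ax.plot(range(len(stages)), means, marker="o", label=f"group {label}", color=color)
    ax.axhline(0.0, color="grey", linewidth=0.8)
    ax.set_xticks(range(len(stages)), stages, rotation=30, ha="right")
    ax.set_ylabel("mean Log2FC vs healthy")
    ax.legend(fontsize=8)
    ax.set_title("Expression trend along the disease axis")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_volcano(
    comparison: StageComparison,
    path: Union[str, Path] = "volcano.png",
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> Path:
    """Volcano plot: x = Log2FC, y = -Log10Q, guide lines at the
    significance criteria, significant genes highlighted and labeled."""
    flagged = volcano_flags(comparison, fc_threshold, q_threshold)
    fig, ax = plt.subplots(figsize=(6, 5))
    for gene, result in comparison.results.items():
        neglog_q = -np.log10(max(result.q_value, 1e-300))
        hit = gene in flagged
        ax.scatter(
            result.log2fc,
            neglog_q,
            s=20 if hit else 10,
            color="#b2182b" if (hit and result.log2fc > 0) else
            "#1a7837" if hit else "#bbbbbb",
            zorder=3 if hit else 2,
        )
        if hit:
            ax.annotate(gene, (result.log2fc, neglog_q), fontsize=6,
                        textcoords="offset points", xytext=(3, 3))
    ax.axvline(fc_threshold, color="grey", linestyle="--", linewidth=0.8)
    ax.axvline(-fc_threshold, color="grey", linestyle="--", linewidth=0.8)
    ax.axhline(-np.log10(q_threshold), color="grey", linestyle="--", linewidth=0.8)
    ax.set_xlabel("Log2FC")
    ax.set_ylabel("-Log10 Q")
    ax.set_title(f"{comparison.dataset_id}: {comparison.contrast.label}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
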