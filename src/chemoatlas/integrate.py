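"""Vote-counting integration across cohorts.

No attempt is made to merge expression matrices from different platforms.
Instead each dataset votes per gene and stage: +1 if the gene is
significantly up (Q < 0.05 and Log2FC > 1), -1 if significantly down
(Q < 0.05 and Log2FC < -1), 0 otherwise.  The "ratio of significant
difference" is the arithmetic mean of those votes over the datasets that
measure the gene at that stage — a signed value in [-1, 1] (e.g. a gene
significantly up in 3 of 4 IBD cohorts scores 3/4 = 0.75).  The gene × stage
matrix of these means is the score matrix.

Two further summaries are derived from per-dataset fold changes:

* quadrant classification — x = mean Log2FC across IBD cohorts, y = mean of
  the adenoma-mean and carcinoma-mean Log2FC; with a two-fold (|Log2FC| = 1)
  cutoff genes fall into group i (neoplasm-upregulated: both high), group ii
  (inflammation-specific: x high, y near 0), group iv
  (neoplasm-downregulated: y low, x near 0), or group iii (no clear change);
* agglomerative hierarchical clustering (Euclidean distance, average
  linkage) of score-matrix rows into k = 4 expression-pattern clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .diffexpr import GeneResult, StageComparison
from .ingest import STAGES

DEFAULT_FC_THRESHOLD = 1.0
DEFAULT_Q_THRESHOLD = 0.05

GROUPS = ("i", "ii", "iii", "iv")


def score_gene(
    result: GeneResult,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> int:
    """Per-dataset significance vote: +1 / -1 / 0.

    +1 requires Q < ``q_threshold`` and Log2FC > ``fc_threshold``; -1 the
    mirror image.  The defaults are the two-fold / Q < 0.05 criteria
    (equivalently -Log10Q > 1.3).
    """
    if not np.isfinite(result.log2fc) or not np.isfinite(result.q_value):
        raise ValueError(f"{result.gene}: non-finite log2fc or q_value")
    if result.q_value < q_threshold:
        if result.log2fc > fc_threshold:
            return 1
        if result.log2fc < -fc_threshold:
            return -1
    return 0


def ratio_of_significant_difference(scores: Sequence[int]) -> float:
    """Arithmetic mean of per-dataset votes for one gene at one stage."""
    if len(scores) == 0:
        raise ValueError("no datasets measure this gene at this stage (missing cell)")
    return float(np.mean(scores))


@dataclass
class ScoreMatrix:
    """Gene × stage matrix of mean votes, with per-cell denominators."""

    values: pd.DataFrame  # genes × stages, in [-1, 1], NaN where no dataset measures
    counts: pd.DataFrame  # same shape, integer denominators

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def build_score_matrix(
    comparisons: Sequence[StageComparison],
    genes: Optional[Sequence[str]] = None,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> ScoreMatrix:
    """Aggregate per-dataset votes into the score matrix.

    All comparisons must share one reference stage (disease stages are
    compared against healthy controls; the metastasis-vs-primary analysis is
    aggregated separately).  A cell's denominator counts only the datasets
    that both cover the stage and measure the gene; cells with denominator 0
    are missing, not 0.
    """
    references = {c.contrast.reference_stage for c in comparisons}
    if len(references) > 1:
        raise ValueError(f"comparisons mix reference stages: {sorted(references)}")
    votes: dict[tuple[str, str], list[int]] = {}
    seen_genes: list[str] = []
    seen_set: set[str] = set()
    stages_present: set[str] = set()
    for comp in comparisons:
        stage = comp.contrast.test_stage
        stages_present.add(stage)
        for gene, result in comp.results.items():
            votes.setdefault((gene, stage), []).append(
                score_gene(result, fc_threshold, q_threshold)
            )
            if gene not in seen_set:
                seen_set.add(gene)
                seen_genes.append(gene)
    index = list(genes) if genes is not None else seen_genes
    columns = [s for s in STAGES if s in stages_present]
    values = pd.DataFrame(np.nan, index=index, columns=columns, dtype=float)
    counts = pd.DataFrame(0, index=index, columns=columns, dtype=int)
    for (gene, stage), cell in votes.items():
        if gene in values.index:
            values.loc[gene, stage] = ratio_of_significant_difference(cell)
            counts.loc[gene, stage] = len(cell)
    return ScoreMatrix(values=values, counts=counts)


@dataclass(frozen=True)
class GroupAssignment:
    """Quadrant label for one gene: x = IBD mean Log2FC, y = tumor mean."""

    gene: str
    x: float
    y: float
    group: str


def classify_point(x: float, y: float, fc_threshold: float = DEFAULT_FC_THRESHOLD) -> str:
    """Quadrant rule with a two-fold cutoff on both axes.

    group i: x and y both above the cutoff (up in inflammation and tumor);
    group ii: x above, y within the band (inflammation-specific);
    group iv: y below -cutoff, x within the band (neoplasm-downregulated);
    group iii: everything else.  Values exactly at a threshold fall on the
    less-extreme side.  The unnamed corner x > cutoff with y < -cutoff is
    resolved by the nearest archetype: the larger absolute coordinate wins,
    with exact ties falling to group iii.
    """
    thr = fc_threshold
    if x > thr and y > thr:
        return "i"
    if x > thr and abs(y) <= thr:
        return "ii"
    if abs(x) <= thr and y < -thr:
        return "iv"
    if x > thr and y < -thr:
        if abs(x) > abs(y):
            return "ii"
        if abs(y) > abs(x):
            return "iv"
        return "iii"
    return "iii"


def _mean_log2fc(comparisons: Sequence[StageComparison], gene: str) -> Optional[float]:
    values = [c.results[gene].log2fc for c in comparisons if gene in c.results]
    return float(np.mean(values)) if values else None


def classify_groups(
    ibd_comparisons: Sequence[StageComparison],
    adenoma_comparisons: Sequence[StageComparison],
    carcinoma_comparisons: Sequence[StageComparison],
    genes: Sequence[str],
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> tuple[list[GroupAssignment], list[tuple[str, str]]]:
    """Assign each gene to one of the four expression-pattern groups.

    x is the unweighted mean of per-dataset Log2FC over IBD cohorts; y is the
    arithmetic mean of the adenoma-cohort mean and the carcinoma-cohort mean
    (if a gene is covered on only one of the two tumor stages, that stage's
    mean stands alone).  Genes lacking coverage on the IBD axis or on both
    tumor stages are reported unclassifiable with a reason instead of being
    plotted.  Returns ``(assignments, unclassifiable)``.
    """
    assignments: list[GroupAssignment] = []
    unclassifiable: list[tuple[str, str]] = []
    for gene in genes:
        x = _mean_log2fc(ibd_comparisons, gene)
        adenoma = _mean_log2fc(adenoma_comparisons, gene)
        carcinoma = _mean_log2fc(carcinoma_comparisons, gene)
        if x is None:
            unclassifiable.append((gene, "no IBD dataset measures this gene"))
            continue
        tumor_means = [v for v in (adenoma, carcinoma) if v is not None]
        if not tumor_means:
            unclassifiable.append((gene, "no adenoma or carcinoma dataset measures this gene"))
            continue
        y = float(np.mean(tumor_means))
        assignments.append(
            GroupAssignment(gene=gene, x=x, y=y, group=classify_point(x, y, fc_threshold))
        )
    return assignments, unclassifiable


def assignments_to_frame(assignments: Sequence[GroupAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [a.gene for a in assignments],
            "ibd_mean_log2fc": [a.x for a in assignments],
            "tumor_mean_log2fc": [a.y for a in assignments],
            "group": [a.group for a in assignments],
        }
    )


@dataclass
class ClusterResult:
    """Hierarchical clustering of score-matrix rows."""

    labels: dict[str, int]  # gene -> cluster label in 1..k
    linkage: np.ndarray  # scipy linkage matrix (merge history)
    genes: tuple[str, ...]  # gene order used (sorted by symbol)

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.genes[i] for i in order]


def cluster_genes(matrix: ScoreMatrix, k: int = 4) -> ClusterResult:
    """Agglomerative clustering of genes by score-matrix profile.

    Euclidean distance, average linkage, cut at ``k`` clusters.  Missing
    cells are imputed as 0 ("no evidence of change") only here; gene order is
    fixed to sorted symbols so results are deterministic.  Coincident rows
    merge at distance 0, so fewer than ``k`` distinct clusters can result
    when rows duplicate; cluster labels are renumbered 1..k in order of first
    appearance.
    """
    genes = tuple(sorted(matrix.genes))
    if len(genes) < k:
        raise ValueError(f"cannot form {k} clusters from {len(genes)} genes")
    data = matrix.values.loc[list(genes)].fillna(0.0).to_numpy(dtype=float)
    linkage = hierarchy.linkage(data, method="average", metric="euclidean")
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels: dict[str, int] = {}
    for gene, lab in zip(genes, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels[gene] = relabel[lab]
    return ClusterResult(labels=labels, linkage=linkage, genes=genes)
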