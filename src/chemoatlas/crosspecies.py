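"""Cross-species fold-change correlation.

Mouse colitis and colon-cancer models (DSS, TNBS, AOM-DSS, ApcMin/+) are
evaluated by correlating their per-gene chemokine Log2FC against the mean
Log2FC across human cohorts for the matching contrast.  Gene pairing goes
through the registry's human → mouse ortholog map; genes without an
ortholog, or with an ortholog the model platform does not measure, are
reported rather than silently dropped.  The statistic is Pearson's r on
(mouse Log2FC, human mean Log2FC) pairs with the usual two-tailed t-test of
r = 0 on n - 2 degrees of freedom (Spearman available as an option).

A leave-one-out influence diagnostic reports r recomputed without each gene,
generalizing the kind of ad-hoc single-gene exclusion (e.g. the interferon-
driven CXCL10/11) that such comparisons often require.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .diffexpr import StageComparison
from .errors import InsufficientSamplesError
from .registry import GeneRegistry


class CorrelationPoint(NamedTuple):
    gene: str  # human symbol
    mouse_log2fc: float
    human_mean_log2fc: float


@dataclass
class ModelCorrelation:
    """Correlation of one mouse model against the human cohort aggregate."""

    model_id: str
    points: list[CorrelationPoint]
    r: float
    p_value: float
    method: str = "pearson"
    excluded_genes: dict[str, str] = field(default_factory=dict)  # gene -> reason
    unpaired_genes: dict[str, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.points)


def _correlate(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(res.statistic), float(res.pvalue)


def model_vs_human(
    model_comparison: StageComparison,
    human_comparisons: Sequence[StageComparison],
    registry: GeneRegistry,
    exclusions: Sequence[str] = (),
    method: str = "pearson",
) -> ModelCorrelation:
    """Correlate a mouse model's fold changes with the human aggregate.

    The human value per gene is the unweighted mean Log2FC across the human
    cohorts that measure it; the mouse value comes from the model comparison,
    matched through the ortholog map.  ``exclusions`` (human symbols) are
    removed before correlating.  Fewer than 3 paired points is an error.
    """
    if not human_comparisons:
        raise ValueError("no human comparisons supplied")
    excluded = {registry.resolve(g) for g in exclusions}
    human_genes: list[str] = []
    for comp in human_comparisons:
        for gene in comp.results:
            if gene not in human_genes:
                human_genes.append(gene)

    points: list[CorrelationPoint] = []
    excluded_genes: dict[str, str] = {}
    unpaired: dict[str, str] = {}
    for gene in human_genes:
        record = registry.lookup(gene)
        if record.mouse_homolog is None:
            unpaired[record.symbol] = "no mouse ortholog"
            continue
        if record.mouse_homolog not in model_comparison.results:
            unpaired[record.symbol] = "ortholog not measured in model dataset"
            continue
        human_values = [
            c.results[gene].log2fc for c in human_comparisons if gene in c.results
        ]
        if record.symbol in excluded:
            excluded_genes[record.symbol] = "excluded by request"
            continue
        points.append(
            CorrelationPoint(
                gene=record.symbol,
                mouse_log2fc=model_comparison.results[record.mouse_homolog].log2fc,
                human_mean_log2fc=float(np.mean(human_values)),
            )
        )
    if len(points) < 3:
        raise InsufficientSamplesError(
            f"{model_comparison.dataset_id}: only {len(points)} paired gene(s); need >= 3"
        )
    x = np.array([p.mouse_log2fc for p in points])
    y = np.array([p.human_mean_log2fc for p in points])
    r, p = _correlate(x, y, method)
    return ModelCorrelation(
        model_id=model_comparison.dataset_id,
        points=points,
        r=r,
        p_value=p,
        method=method,
        excluded_genes=excluded_genes,
        unpaired_genes=unpaired,
    )


def leave_one_out_influence(correlation: ModelCorrelation) -> dict[str, float]:
    """r recomputed without each gene, ordered by decreasing |Δr|.

    Flags single genes whose removal moves the correlation most — the
    principled version of excluding an outlying chemokine by hand.
    """
    if correlation.n < 4:
        raise InsufficientSamplesError("leave-one-out requires >= 4 points")
    x = np.array([p.mouse_log2fc for p in correlation.points])
    y = np.array([p.human_mean_log2fc for p in correlation.points])
    out: dict[str, float] = {}
    for i, point in enumerate(correlation.points):
        mask = np.ones(len(x), dtype=bool)
        mask[i] = False
        r, _ = _correlate(x[mask], y[mask], correlation.method)
        out[point.gene] = r
    return dict(
        sorted(out.items(), key=lambda kv: (-abs(kv[1] - correlation.r), kv[0]))
    )


def correlation_summary(correlation: ModelCorrelation) -> dict:
    """JSON-ready summary (model id, r, p, n, exclusions)."""
    return {
        "model_id": correlation.model_id,
        "method": correlation.method,
        "r": correlation.r,
        "p_value": correlation.p_value,
        "n": correlation.n,
        "excluded_genes": dict(correlation.excluded_genes),
        "unpaired_genes": dict(correlation.unpaired_genes),
    }
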