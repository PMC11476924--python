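"""Per-dataset differential expression.

For one cohort and one stage-vs-reference contrast this module computes, per
gene: the log2 fold change (difference of group means on the log2 scale), a
two-tailed t-test p-value, and a Benjamini–Hochberg Q-value.  Following the
study design this re-implements, the unpaired test is the equal-variance
(pooled, Student) t-test — not Welch — and paired cohorts use the paired
t-test over complete pairs.  BH adjustment is applied within one
dataset-contrast over exactly the gene panel analyzed there.

Degenerate inputs are handled deterministically: when both arms (or the
paired differences) have zero variance, equal means give p = 1 and unequal
means are tested with a variance floor of 1e-12 instead of producing an
infinite t statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientSamplesError
from .ingest import STAGES, GeneExpressionTable

#: Variance floor for zero-variance groups/differences (keeps t finite).
VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class Contrast:
    """A stage-vs-reference comparison within one dataset."""

    test_stage: str
    reference_stage: str = "healthy_control"
    design: str = "unpaired"  # "unpaired" | "paired"

    def __post_init__(self) -> None:
        for stage in (self.test_stage, self.reference_stage):
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
        if self.test_stage == self.reference_stage:
            raise ValueError("test and reference stage must differ")
        if self.design not in ("paired", "unpaired"):
            raise ValueError(f"unknown design {self.design!r}")

    @property
    def label(self) -> str:
        return f"{self.test_stage}_vs_{self.reference_stage}"


@dataclass(frozen=True)
class GeneResult:
    gene: str
    log2fc: float
    p_value: float
    q_value: float
    n_test: int
    n_ref: int


@dataclass
class StageComparison:
    """All per-gene results for one dataset and one contrast."""

    dataset_id: str
    contrast: Contrast
    results: dict[str, GeneResult] = field(default_factory=dict)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.results)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": r.gene,
                "log2fc": r.log2fc,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "n_test": r.n_test,
                "n_ref": r.n_ref,
                "dataset_id": self.dataset_id,
                "test_stage": self.contrast.test_stage,
                "reference_stage": self.contrast.reference_stage,
                "design": self.contrast.design,
            }
            for r in self.results.values()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> list["StageComparison"]:
        """Rebuild comparisons from a (possibly concatenated) results table."""
        out = []
        keys = ["dataset_id", "test_stage", "reference_stage", "design"]
        for (ds, test, ref, design), grp in frame.groupby(keys, sort=False):
            comp = cls(dataset_id=ds, contrast=Contrast(test, ref, design))
            for _, row in grp.iterrows():
                comp.results[row["gene"]] = GeneResult(
                    gene=row["gene"],
                    log2fc=float(row["log2fc"]),
                    p_value=float(row["p_value"]),
                    q_value=float(row["q_value"]),
                    n_test=int(row["n_test"]),
                    n_ref=int(row["n_ref"]),
                )
            out.append(comp)
        return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (q-values), input order preserved.

    q_(i) = min_{j : p_(j) >= p_(i)} m * p_(j) / rank(j), clipped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-tailed equal-variance t-test with deterministic degenerate handling."""
    n1, n2 = len(x), len(y)
    v1 = float(np.var(x, ddof=1))
    v2 = float(np.var(y, ddof=1))
    diff = float(np.mean(x) - np.mean(y))
    if v1 == 0.0 and v2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        df = n1 + n2 - 2
        se = np.sqrt(VARIANCE_FLOOR * (1.0 / n1 + 1.0 / n2))
        t = diff / se
        return t, float(2.0 * stats.t.sf(abs(t), df))
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def _paired_t(diffs: np.ndarray) -> tuple[float, float]:
    n = len(diffs)
    mean = float(np.mean(diffs))
    var = float(np.var(diffs, ddof=1))
    if var == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        t = mean / np.sqrt(VARIANCE_FLOOR / n)
        return t, float(2.0 * stats.t.sf(abs(t), n - 1))
    t, p = stats.ttest_rel(diffs, np.zeros(n))
    return float(t), float(p)


def run_contrast(
    table: GeneExpressionTable,
    contrast: Contrast,
    genes: Optional[Sequence[str]] = None,
) -> StageComparison:
    """Differential expression of ``contrast`` for a gene panel.

    ``genes`` defaults to every gene in the table; genes absent from the
    platform yield no result (they are omitted, never NA-filled), and BH
    adjustment runs over exactly the genes that produced a p-value.
    Unpaired contrasts need >= 2 samples per arm, paired contrasts >= 2
    complete pairs; per-gene missing values are dropped case-wise (a gene
    left with fewer observations than that is omitted).
    """
    panel = [g for g in (genes if genes is not None else table.genes) if g in set(table.genes)]
    comparison = StageComparison(dataset_id=table.dataset_id, contrast=contrast)

    if contrast.design == "paired":
        pairs = table.pairs_between(contrast.test_stage, contrast.reference_stage)
        if len(pairs) < 2:
            raise InsufficientSamplesError(
                f"{table.dataset_id}: {len(pairs)} complete pair(s) for "
                f"{contrast.label}; need >= 2"
            )
        test_cols = [a for a, _ in pairs]
        ref_cols = [b for _, b in pairs]
        records = []
        for gene in panel:
            x = table.values.loc[gene, test_cols].to_numpy(dtype=float)
            y = table.values.loc[gene, ref_cols].to_numpy(dtype=float)
            keep = ~(np.isnan(x) | np.isnan(y))  # complete-case pairs
            if keep.sum() < 2:
                continue
            d = x[keep] - y[keep]
            t, p = _paired_t(d)
            records.append((gene, float(np.mean(d)), p, int(keep.sum()), int(keep.sum())))
    else:
        test_cols = table.columns_for_stage(contrast.test_stage)
        ref_cols = table.columns_for_stage(contrast.reference_stage)
        for name, cols in ((contrast.test_stage, test_cols), (contrast.reference_stage, ref_cols)):
            if len(cols) < 2:
                raise InsufficientSamplesError(
                    f"{table.dataset_id}: {name} arm has n={len(cols)}; need >= 2"
                )
        records = []
        for gene in panel:
            x = table.values.loc[gene, test_cols].to_numpy(dtype=float)
            y = table.values.loc[gene, ref_cols].to_numpy(dtype=float)
            x, y = x[~np.isnan(x)], y[~np.isnan(y)]
            if len(x) < 2 or len(y) < 2:
                continue
            _, p = _pooled_t(x, y)
            records.append((gene, float(np.mean(x) - np.mean(y)), p, len(x), len(y)))

    if records:
        q = bh_adjust([r[2] for r in records])
        for (gene, lfc, p, n_test, n_ref), q_val in zip(records, q):
            comparison.results[gene] = GeneResult(
                gene=gene,
                log2fc=lfc,
                p_value=p,
                q_value=float(q_val),
                n_test=n_test,
                n_ref=n_ref,
            )
    return comparison


def run_standard_contrasts(
    table: GeneExpressionTable, genes: Optional[Sequence[str]] = None
) -> list[StageComparison]:
    """All contrasts a cohort supports: each disease stage vs healthy control,
    plus metastasis vs primary carcinoma when both are present.  Paired
    cohorts use the paired design."""
    design = "paired" if table.paired else "unpaired"
    present = table.stages_present()
    comparisons = []
    if "healthy_control" in present:
        for stage in present:
            if stage == "healthy_control":
                continue
            comparisons.append(
                run_contrast(table, Contrast(stage, "healthy_control", design), genes)
            )
    if "metastasis" in present and "primary_carcinoma" in present:
        comparisons.append(
            run_contrast(table, Contrast("metastasis", "primary_carcinoma", design), genes)
        )
    return comparisons
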