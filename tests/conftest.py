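"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pytest

from chemoatlas import (
    GeneExpressionTable,
    SampleAnnotation,
    build_default_registry,
)


@pytest.fixture(scope="session")
def registry():
    return build_default_registry()


def build_table(
    gene_values: Mapping[str, Mapping[str, Sequence[float]]],
    dataset_id: str = "toy",
    paired: bool = False,
    species: str = "human",
) -> GeneExpressionTable:
    """Build a gene x sample log2 table from per-gene, per-stage value lists.

    ``gene_values[gene][stage]`` is the list of log2 intensities for that
    arm; arm sizes must agree across genes.  Paired tables reuse pair ids
    P1..Pn across stages.
    """
    genes = list(gene_values)
    stages = list(gene_values[genes[0]])
    samples: list[SampleAnnotation] = []
    columns: dict[str, list[float]] = {}
    for stage in stages:
        n = len(gene_values[genes[0]][stage])
        for i in range(n):
            sid = f"{stage}_{i + 1}"
            samples.append(
                SampleAnnotation(
                    sample_id=sid,
                    raw_label=stage,
                    stage=stage,
                    pair_id=f"P{i + 1}" if paired else None,
                )
            )
            columns[sid] = [float(gene_values[g][stage][i]) for g in genes]
    values = pd.DataFrame(columns, index=genes, dtype=float)
    return GeneExpressionTable(
        dataset_id=dataset_id, values=values, samples=samples,
        paired=paired, species=species,
    )


def bh_step_up_bruteforce(p_values: Sequence[float]) -> np.ndarray:
    """Independent brute-force BH: for each p_i, the minimum over all p_j >=
    p_i of m * p_j / rank(j), clipped at 1 (ranks from the sorted vector,
    maximal rank for ties)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    # maximal rank per sorted position (ties share the largest rank)
    ranks = np.array(
        [np.max(np.nonzero(sorted_p <= sorted_p[i])[0]) + 1 for i in range(m)]
    )
    q = np.empty(m)
    for i in range(m):
        candidates = [
            m * sorted_p[j] / ranks[j] for j in range(m) if sorted_p[j] >= sorted_p[i]
        ]
        q[order[i]] = min(1.0, min(candidates))
    return q
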