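"""Reading and standardizing expression cohorts.

Each cohort is one dataset: a probe × sample intensity matrix plus a
probe → gene map and per-sample disease-stage annotations.  Cohorts come from
different array platforms, so gene coverage, group sizes and annotation
vocabulary differ between them; this module harmonizes all of that into a
uniform in-memory form:

1. free-text sample labels are mapped onto five harmonized stages
   (healthy control, IBD, adenoma, primary carcinoma, metastasis) —
   ulcerative colitis and Crohn's disease are pooled as IBD, liver and lung
   metastases as metastasis;
2. linear-scale intensities are converted to log2 (values ≤ 0 are clamped to
   1.0 first, so they map to 0);
3. multiple probes per gene are collapsed to the probe with the strongest
   signal, defined as the highest mean log2 intensity across all samples of
   the dataset, with ties broken by lexicographically smallest probe id.

Statistics are always computed within a dataset; matrices from different
platforms are never merged, so no cross-dataset normalization is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ParseError, StageAnnotationError

STAGES = ("healthy_control", "IBD", "adenoma", "primary_carcinoma", "metastasis")

#: Built-in label → stage vocabulary (matched case-insensitively, trimmed).
BUILTIN_STAGE_RULES: Mapping[str, str] = {
    "none": "healthy_control",
    "control": "healthy_control",
    "normal": "healthy_control",
    "normal colonic mucosa": "healthy_control",
    "healthy": "healthy_control",
    "ibd": "IBD",
    "uc": "IBD",
    "cd": "IBD",
    "ulcerative colitis": "IBD",
    "crohn's disease": "IBD",
    "adenoma": "adenoma",
    "colon adenoma": "adenoma",
    "colorectal cancer": "primary_carcinoma",
    "primary tumor": "primary_carcinoma",
    "carcinoma": "primary_carcinoma",
    "metastatic cancer": "metastasis",
    "liver metastasis": "metastasis",
    "lung metastasis": "metastasis",
}

#: Linear intensities above this are implausible for log2 data.
LINEAR_DETECTION_THRESHOLD = 50.0

#: Clamp for non-positive linear values before the log2 transform.
LOG2_EPSILON = 1.0


def harmonize_stage(raw_label: str, rules: Optional[Mapping[str, str]] = None) -> str:
    """Map a free-text sample label to one of the five harmonized stages.

    User-supplied ``rules`` take precedence over the built-in vocabulary.
    Matching is case-insensitive and whitespace-trimmed on both sides.
    An unmatched label raises :class:`StageAnnotationError` (labels are never
    silently dropped).
    """
    key = raw_label.strip().lower()
    if rules:
        user = {k.strip().lower(): v for k, v in rules.items()}
        if key in user:
            stage = user[key]
            if stage not in STAGES:
                raise StageAnnotationError(
                    f"rule for {raw_label!r} maps to unknown stage {stage!r}"
                )
            return stage
    if key in BUILTIN_STAGE_RULES:
        return BUILTIN_STAGE_RULES[key]
    raise StageAnnotationError(f"no stage rule for sample label {raw_label!r}")


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    raw_label: str
    stage: str
    pair_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageAnnotationError(f"unknown stage {self.stage!r}")


@dataclass
class ExpressionDataset:
    """One cohort: probe × sample matrix with annotations and a probe map."""

    dataset_id: str
    species: str  # "human" | "mouse"
    scale: str  # "linear" | "log2"
    matrix: pd.DataFrame  # probes (rows) × samples (columns)
    probe_gene_map: dict[str, str]
    samples: list[SampleAnnotation]
    paired: bool = False

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ParseError(f"{self.dataset_id}: duplicate sample ids")
        if list(self.matrix.columns) != ids:
            raise ParseError(
                f"{self.dataset_id}: matrix columns do not match sample annotations"
            )
        if not ids:
            raise ParseError(f"{self.dataset_id}: dataset has no samples")

    def annotation(self, sample_id: str) -> SampleAnnotation:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def stages_present(self) -> tuple[str, ...]:
        present = {s.stage for s in self.samples}
        return tuple(st for st in STAGES if st in present)


@dataclass
class GeneExpressionTable:
    """Gene × sample log2 table (one row per gene, probes already collapsed)."""

    dataset_id: str
    values: pd.DataFrame  # genes × samples, log2
    samples: list[SampleAnnotation]
    paired: bool = False
    species: str = "human"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ParseError(f"{self.dataset_id}: duplicate gene rows")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    def columns_for_stage(self, stage: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.stage == stage]

    def pairs_between(self, stage_a: str, stage_b: str) -> list[tuple[str, str]]:
        """(sample_a, sample_b) for every pair_id annotated in both stages."""
        by_pair: dict[str, dict[str, str]] = {}
        for s in self.samples:
            if s.pair_id is not None:
                by_pair.setdefault(s.pair_id, {})[s.stage] = s.sample_id
        out = []
        for pair_id in sorted(by_pair):
            stages = by_pair[pair_id]
            if stage_a in stages and stage_b in stages:
                out.append((stages[stage_a], stages[stage_b]))
        return out

    def stages_present(self) -> tuple[str, ...]:
        present = {s.stage for s in self.samples}
        return tuple(st for st in STAGES if st in present)

    def to_tsv(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")
        return path


def detect_scale(matrix: pd.DataFrame, threshold: float = LINEAR_DETECTION_THRESHOLD) -> str:
    """Heuristic scale detection: log2 microarray intensities rarely exceed
    ~20, so a maximum above ``threshold`` indicates linear data."""
    maximum = np.nanmax(matrix.to_numpy(dtype=float)) if matrix.size else 0.0
    return "linear" if maximum > threshold else "log2"


def to_log2(dataset: ExpressionDataset, epsilon: float = LOG2_EPSILON) -> ExpressionDataset:
    """Standardize a dataset to log2 scale (idempotent).

    Linear values are clamped from below at ``epsilon`` (default 1.0, mapping
    background-subtracted non-positive intensities to 0) before the
    transform.  Missing values stay missing.
    """
    if dataset.scale == "log2":
        return dataset
    if dataset.scale != "linear":
        raise ValueError(f"unknown scale {dataset.scale!r}")
    values = dataset.matrix.to_numpy(dtype=float)
    transformed = np.log2(np.clip(values, epsilon, None))
    transformed[np.isnan(values)] = np.nan
    matrix = pd.DataFrame(transformed, index=dataset.matrix.index, columns=dataset.matrix.columns)
    return replace(dataset, matrix=matrix, scale="log2")


def collapse_probes(
    dataset: ExpressionDataset, genes: Optional[Sequence[str]] = None
) -> GeneExpressionTable:
    """Collapse probes to one row per gene by strongest signal.

    For each gene with at least one probe, the probe with the maximal mean
    log2 intensity across all samples is kept; ties are broken by the
    lexicographically smallest probe id.  Genes with no probe on the platform
    are omitted (never zero-filled).  ``genes`` optionally restricts the
    output panel.
    """
    if dataset.scale != "log2":
        raise ValueError("collapse_probes requires a log2-standardized dataset")
    probes_by_gene: dict[str, list[str]] = {}
    for probe in dataset.matrix.index:
        gene = dataset.probe_gene_map.get(probe)
        if gene is not None:
            probes_by_gene.setdefault(gene, []).append(probe)
    wanted = list(genes) if genes is not None else sorted(probes_by_gene)
    means = dataset.matrix.mean(axis=1, skipna=True)
    rows, index = [], []
    for gene in wanted:
        probes = probes_by_gene.get(gene)
        if not probes:
            continue
        best = min(
            probes,
            key=lambda p: (-(means[p] if not math.isnan(means[p]) else -math.inf), p),
        )
        rows.append(dataset.matrix.loc[best])
        index.append(gene)
    values = pd.DataFrame(rows, index=index, columns=dataset.matrix.columns, dtype=float)
    return GeneExpressionTable(
        dataset_id=dataset.dataset_id,
        values=values,
        samples=list(dataset.samples),
        paired=dataset.paired,
        species=dataset.species,
    )


# ---------------------------------------------------------------------------
# File I/O: series-matrix-like TSV + companion annotation and probe-map TSVs
# ---------------------------------------------------------------------------

def _read_metadata(path: Path) -> tuple[dict[str, str], int]:
    """Leading ``!key<TAB>value`` lines form the dataset metadata block."""
    meta: dict[str, str] = {}
    skip = 0
    with path.open("r", encoding="utf-8") as handle:
        for line in handle:
            if not line.startswith("!"):
                break
            skip += 1
            parts = line[1:].rstrip("\n").split("\t", 1)
            if len(parts) == 2:
                meta[parts[0].strip().lower()] = parts[1].strip()
    return meta, skip


def read_series_matrix(
    matrix_path: Union[str, Path],
    annotations: Union[str, Path, pd.DataFrame],
    probe_map: Union[str, Path, pd.DataFrame, Mapping[str, str]],
    *,
    dataset_id: Optional[str] = None,
    species: Optional[str] = None,
    scale: Optional[str] = None,
    paired: Optional[bool] = None,
    label_rules: Optional[Mapping[str, str]] = None,
) -> ExpressionDataset:
    """Read one cohort from a series-matrix-like TSV and its companions.

    The matrix file may open with ``!key<TAB>value`` metadata lines
    (``dataset_id``, ``species``, ``scale``, ``paired``); the first
    non-metadata row is a header of sample ids and the first column holds
    probe ids.  ``annotations`` is a TSV (or frame) with columns
    ``sample_id``, ``raw_label`` and optional ``pair_id``; ``probe_map`` a
    TSV/frame with ``probe_id``, ``gene_symbol`` (or a plain mapping).
    Keyword arguments override file metadata; scale falls back to
    auto-detection.  Every sample label must harmonize — an unknown label
    raises :class:`StageAnnotationError` naming it.
    """
    matrix_path = Path(matrix_path)
    meta, skip = _read_metadata(matrix_path)
    try:
        matrix = pd.read_csv(matrix_path, sep="\t", skiprows=skip, index_col=0)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{matrix_path}: malformed matrix ({exc})") from exc
    if matrix.shape[1] == 0:
        raise ParseError(f"{matrix_path}: matrix has no sample columns")
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    matrix = matrix.astype(float)

    if isinstance(annotations, (str, Path)):
        annotations = pd.read_csv(annotations, sep="\t", dtype=str)
    required = {"sample_id", "raw_label"}
    if not required.issubset(annotations.columns):
        raise ParseError(f"annotation table must have columns {sorted(required)}")
    samples = []
    for _, row in annotations.iterrows():
        pair = row.get("pair_id")
        if pair is not None and (pd.isna(pair) or str(pair) == ""):
            pair = None
        samples.append(
            SampleAnnotation(
                sample_id=str(row["sample_id"]),
                raw_label=str(row["raw_label"]),
                stage=harmonize_stage(str(row["raw_label"]), label_rules),
                pair_id=None if pair is None else str(pair),
            )
        )
    if not samples:
        raise ParseError(f"{matrix_path}: empty sample annotation table")
    order = [s.sample_id for s in samples]
    missing = [c for c in order if c not in matrix.columns]
    if missing:
        raise ParseError(f"{matrix_path}: annotated samples missing from matrix: {missing}")
    extra = [c for c in matrix.columns if c not in set(order)]
    if extra:
        raise ParseError(f"{matrix_path}: unannotated matrix columns: {extra}")
    matrix = matrix[order]

    if isinstance(probe_map, (str, Path)):
        probe_map = pd.read_csv(probe_map, sep="\t", dtype=str)
    if isinstance(probe_map, pd.DataFrame):
        if not {"probe_id", "gene_symbol"}.issubset(probe_map.columns):
            raise ParseError("probe map must have columns probe_id, gene_symbol")
        probe_map = dict(zip(probe_map["probe_id"], probe_map["gene_symbol"]))
    probe_map = dict(probe_map)

    resolved_scale = scale or meta.get("scale") or detect_scale(matrix)
    if resolved_scale not in ("linear", "log2"):
        raise ParseError(f"unknown scale {resolved_scale!r}")
    resolved_paired = (
        paired
        if paired is not None
        else meta.get("paired", "false").lower() in ("true", "1", "yes")
    )
    return ExpressionDataset(
        dataset_id=dataset_id or meta.get("dataset_id") or matrix_path.stem,
        species=species or meta.get("species") or "human",
        scale=resolved_scale,
        matrix=matrix,
        probe_gene_map=probe_map,
        samples=samples,
        paired=resolved_paired,
    )


def write_dataset(dataset: ExpressionDataset, directory: Union[str, Path]) -> Path:
    """Serialize a dataset to ``matrix.tsv`` / ``annotations.tsv`` /
    ``probe_map.tsv`` in ``directory`` (the dialect ``read_series_matrix``
    reads, closing the simulate → ingest loop)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrix_path = directory / "matrix.tsv"
    with matrix_path.open("w", encoding="utf-8") as handle:
        handle.write(f"!dataset_id\t{dataset.dataset_id}\n")
        handle.write(f"!species\t{dataset.species}\n")
        handle.write(f"!scale\t{dataset.scale}\n")
        handle.write(f"!paired\t{str(dataset.paired).lower()}\n")
        dataset.matrix.to_csv(handle, sep="\t", index_label="probe_id", float_format="%.10g")
    ann = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in dataset.samples],
            "raw_label": [s.raw_label for s in dataset.samples],
            "pair_id": [s.pair_id or "" for s in dataset.samples],
        }
    )
    ann.to_csv(directory / "annotations.tsv", sep="\t", index=False)
    pm = pd.DataFrame(
        sorted(dataset.probe_gene_map.items()), columns=["probe_id", "gene_symbol"]
    )
    pm.to_csv(directory / "probe_map.tsv", sep="\t", index=False)
    return directory


def read_dataset(directory: Union[str, Path], **kwargs) -> ExpressionDataset:
    """Read a dataset serialized by :func:`write_dataset`."""
    directory = Path(directory)
    return read_series_matrix(
        directory / "matrix.tsv",
        directory / "annotations.tsv",
        directory / "probe_map.tsv",
        **kwargs,
    )
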