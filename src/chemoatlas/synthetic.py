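"""Synthetic multi-cohort generator.

Emulates the statistical structure of a multi-center microarray compendium
so the whole pipeline is testable without downloading anything: several
independent cohorts on different platforms (gene subsets), differing group
sizes, paired and unpaired designs, heterogeneous free-text stage labels,
and genes drawn from four expression archetypes —

* ``neoplasm_up``: up in IBD and still up in adenoma/carcinoma,
* ``inflammation_specific``: up in IBD only,
* ``unchanged``: flat everywhere,
* ``neoplasm_down``: down in adenoma/carcinoma, flat in IBD.

Per gene and sample the generated log2 intensity is

    baseline + stage effect (archetype) + pair offset (paired cohorts)
             + N(0, noise_sd)

i.e. additive homoscedastic Gaussian noise on the log2 scale, matching the
equal-variance t-test the analysis applies.  Everything is reproducible from
the cohort seed.  Default effect sizes (|Log2FC| 2–3) and noise
(noise_sd = 0.8) mirror the magnitudes such compendia report for strongly
regulated chemokines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .ingest import (
    STAGES,
    ExpressionDataset,
    SampleAnnotation,
    harmonize_stage,
    write_dataset,
)
from .registry import GeneRegistry, build_default_registry

#: Heterogeneous raw labels per stage (all harmonizable by the ingest rules).
STAGE_LABEL_POOL: Mapping[str, tuple[str, ...]] = {
    "healthy_control": ("normal", "control", "normal colonic mucosa", "none"),
    "IBD": ("UC", "CD", "IBD"),
    "adenoma": ("adenoma", "colon adenoma"),
    "primary_carcinoma": ("colorectal cancer", "primary tumor", "carcinoma"),
    "metastasis": ("metastatic cancer", "liver metastasis", "lung metastasis"),
}


@dataclass(frozen=True)
class ArchetypeSpec:
    """A named expression pattern: true Log2FC per disease stage.

    Effects for IBD/adenoma/primary_carcinoma are relative to healthy
    control; the metastasis effect is relative to primary carcinoma.
    """

    name: str
    stage_effects: Mapping[str, float]

    def effect(self, stage: str) -> float:
        return float(self.stage_effects.get(stage, 0.0))


NEOPLASM_UP = ArchetypeSpec(
    "neoplasm_up", {"IBD": 2.5, "adenoma": 2.0, "primary_carcinoma": 2.0, "metastasis": 0.0}
)
INFLAMMATION_SPECIFIC = ArchetypeSpec(
    "inflammation_specific",
    {"IBD": 3.0, "adenoma": 0.0, "primary_carcinoma": 0.0, "metastasis": 0.0},
)
UNCHANGED = ArchetypeSpec(
    "unchanged", {"IBD": 0.0, "adenoma": 0.0, "primary_carcinoma": 0.0, "metastasis": 0.0}
)
NEOPLASM_DOWN = ArchetypeSpec(
    "neoplasm_down", {"IBD": 0.0, "adenoma": -2.0, "primary_carcinoma": -2.5, "metastasis": 0.0}
)

ARCHETYPES: Mapping[str, ArchetypeSpec] = {
    a.name: a for a in (NEOPLASM_UP, INFLAMMATION_SPECIFIC, UNCHANGED, NEOPLASM_DOWN)
}

#: Expected quadrant group per archetype (for recovery checks).
ARCHETYPE_GROUP: Mapping[str, str] = {
    "neoplasm_up": "i",
    "inflammation_specific": "ii",
    "unchanged": "iii",
    "neoplasm_down": "iv",
}

# Archetype membership for the default cohort, following the published
# grouping of the chemokine family (group i/ii/iv ligands plus the four
# receptors with significant stage changes; everything else unchanged).
_GROUP_I_GENES = (
    "CXCL1", "CXCL2", "CXCL3", "PF4", "CXCL5", "CXCL6", "PPBP", "CXCL8",
    "CXCL11", "CCL20", "CCL24", "CXCR2",
)
_GROUP_II_GENES = (
    "CXCL9", "CXCL10", "CXCL16", "CCL2", "CCL3", "CCL4", "CCL11", "CCL18",
    "CCL22", "CCR1",
)
_GROUP_IV_GENES = (
    "CXCL12", "CXCL13", "CXCL14", "CCL5", "CCL8", "CCL13", "CCL14", "CCL15",
    "CCL19", "CCL21", "CCL23", "XCL1", "XCL2", "CXCR5", "CCR2",
)


def default_gene_assignments(
    registry: Optional[GeneRegistry] = None,
) -> dict[str, ArchetypeSpec]:
    """Archetype per gene for the full 39-ligand + 22-receptor panel."""
    registry = registry or build_default_registry()
    assignments: dict[str, ArchetypeSpec] = {}
    for symbol in registry.all_symbols():
        if symbol in _GROUP_I_GENES:
            assignments[symbol] = NEOPLASM_UP
        elif symbol in _GROUP_II_GENES:
            assignments[symbol] = INFLAMMATION_SPECIFIC
        elif symbol in _GROUP_IV_GENES:
            assignments[symbol] = NEOPLASM_DOWN
        else:
            assignments[symbol] = UNCHANGED
    return assignments


@dataclass
class DatasetSpec:
    """One synthetic cohort: which stages it covers and how it is sampled."""

    dataset_id: str
    stages: tuple[str, ...]  # disease stages; healthy_control is implicit
    n_per_arm: int = 10
    paired: bool = False
    platform_exclude: tuple[str, ...] = ()  # genes absent from this platform
    noise_sd: float = 0.8
    scale: str = "log2"  # emit log2 or exponentiated linear intensities
    #: per-gene, per-stage true-effect overrides (dataset heterogeneity)
    effect_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError(f"{self.dataset_id}: n_per_arm must be >= 2")
        if self.noise_sd < 0:
            raise ValueError(f"{self.dataset_id}: noise_sd must be >= 0")
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"{self.dataset_id}: unknown scale {self.scale!r}")
        for stage in self.stages:
            if stage not in STAGES or stage == "healthy_control":
                raise ValueError(f"{self.dataset_id}: invalid disease stage {stage!r}")


@dataclass
class CohortSpec:
    """A whole synthetic compendium: datasets + gene archetype assignments."""

    datasets: list[DatasetSpec]
    gene_assignments: dict[str, ArchetypeSpec]
    seed: int = 0
    baseline_range: tuple[float, float] = (6.0, 10.0)

    def validate(self) -> None:
        if not self.datasets:
            raise ValueError("cohort spec has no datasets")
        if not self.gene_assignments:
            raise ValueError("cohort spec has no genes")
        ids = [d.dataset_id for d in self.datasets]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate dataset ids")
        for ds in self.datasets:
            ds.validate()


def default_cohort_spec(
    seed: int = 0,
    n_per_arm: int = 10,
    noise_sd: float = 0.8,
    registry: Optional[GeneRegistry] = None,
) -> CohortSpec:
    """The reference study design: 4 IBD cohorts, 2 adenoma, 3 carcinoma
    (one of them paired), n = 10 per arm, noise_sd = 0.8, with small platform
    differences so gene coverage varies across datasets."""
    datasets = [
        DatasetSpec("ibd_1", ("IBD",), n_per_arm, noise_sd=noise_sd),
        DatasetSpec("ibd_2", ("IBD",), n_per_arm, noise_sd=noise_sd),
        DatasetSpec("ibd_3", ("IBD",), n_per_arm, noise_sd=noise_sd),
        DatasetSpec("ibd_4", ("IBD",), n_per_arm, noise_sd=noise_sd,
                    platform_exclude=("CCL28",)),
        DatasetSpec("adenoma_1", ("adenoma",), n_per_arm, noise_sd=noise_sd),
        DatasetSpec("adenoma_2", ("adenoma",), n_per_arm, noise_sd=noise_sd,
                    platform_exclude=("CCL26",)),
        DatasetSpec("carcinoma_1", ("primary_carcinoma",), n_per_arm, noise_sd=noise_sd),
        DatasetSpec("carcinoma_2", ("primary_carcinoma",), n_per_arm, noise_sd=noise_sd),
        DatasetSpec("carcinoma_3", ("primary_carcinoma",), n_per_arm, paired=True,
                    noise_sd=noise_sd),
    ]
    return CohortSpec(
        datasets=datasets,
        gene_assignments=default_gene_assignments(registry),
        seed=seed,
    )


def _true_effect(spec: DatasetSpec, assignments, gene: str, stage: str) -> float:
    """True Log2FC vs healthy for one gene/stage, with dataset overrides.

    The metastasis archetype effect is defined vs primary carcinoma, so a
    metastasis arm stacks on top of the primary-carcinoma effect.
    """
    overrides = spec.effect_overrides.get(gene, {})
    archetype = assignments[gene]

    def eff(st: str) -> float:
        return float(overrides.get(st, archetype.effect(st)))

    if stage == "healthy_control":
        return 0.0
    if stage == "metastasis":
        return eff("primary_carcinoma") + eff("metastasis")
    return eff(stage)


def generate_cohort(
    spec: CohortSpec, registry: Optional[GeneRegistry] = None
) -> list[ExpressionDataset]:
    """Generate every dataset of the cohort (reproducible from ``spec.seed``).

    Per-gene baselines are drawn once per cohort; paired cohorts add a shared
    per-pair, per-gene intercept of sd ``noise_sd / 2`` across stages, which
    makes the paired t-test strictly more powerful than the unpaired one on
    the same data.  The first two genes of each platform get a second,
    weaker probe so probe collapse is exercised end to end.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = sorted(spec.gene_assignments)
    lo, hi = spec.baseline_range
    baselines = dict(zip(genes, rng.uniform(lo, hi, size=len(genes))))
    datasets = []
    for index, ds in enumerate(spec.datasets):
        ds_rng = np.random.default_rng([spec.seed, index])
        datasets.append(_generate_dataset(ds, spec, baselines, ds_rng))
    return datasets


def _generate_dataset(
    ds: DatasetSpec,
    cohort: CohortSpec,
    baselines: Mapping[str, float],
    rng: np.random.Generator,
) -> ExpressionDataset:
    platform = [g for g in sorted(cohort.gene_assignments) if g not in set(ds.platform_exclude)]
    stages = ("healthy_control",) + tuple(ds.stages)
    n = ds.n_per_arm

    samples: list[SampleAnnotation] = []
    for stage in stages:
        pool = STAGE_LABEL_POOL[stage]
        for i in range(n):
            samples.append(
                SampleAnnotation(
                    sample_id=f"{ds.dataset_id}_{stage}_{i + 1}",
                    raw_label=str(rng.choice(pool)),
                    stage=stage,
                    pair_id=f"P{i + 1}" if ds.paired else None,
                )
            )

    pair_offsets = (
        rng.normal(0.0, ds.noise_sd / 2.0, size=(n, len(platform))) if ds.paired else None
    )
    columns: dict[str, np.ndarray] = {}
    for stage_idx, stage in enumerate(stages):
        effects = np.array(
            [_true_effect(ds, cohort.gene_assignments, g, stage) for g in platform]
        )
        base = np.array([baselines[g] for g in platform])
        for i in range(n):
            noise = rng.normal(0.0, ds.noise_sd, size=len(platform))
            values = base + effects + noise
            if pair_offsets is not None:
                values = values + pair_offsets[i]
            columns[f"{ds.dataset_id}_{stage}_{i + 1}"] = values

    probe_rows: dict[str, np.ndarray] = {}
    probe_map: dict[str, str] = {}
    sample_ids = [s.sample_id for s in samples]
    stacked = np.column_stack([columns[sid] for sid in sample_ids])
    for gi, gene in enumerate(platform):
        probe_map[f"{gene}_p1"] = gene
        probe_rows[f"{gene}_p1"] = stacked[gi]
    for gene in platform[:2]:  # weaker duplicate probes for collapse testing
        probe_id = f"{gene}_p0"
        probe_map[probe_id] = gene
        probe_rows[probe_id] = probe_rows[f"{gene}_p1"] - 1.5
    matrix = pd.DataFrame.from_dict(probe_rows, orient="index", columns=sample_ids)

    scale = "log2"
    if ds.scale == "linear":
        matrix = 2.0 ** matrix
        scale = "linear"
    return ExpressionDataset(
        dataset_id=ds.dataset_id,
        species="human",
        scale=scale,
        matrix=matrix,
        probe_gene_map=probe_map,
        samples=samples,
        paired=ds.paired,
    )


def generate_mouse_model(
    human_spec: CohortSpec,
    target_correlation: float,
    seed: int,
    *,
    registry: Optional[GeneRegistry] = None,
    model_id: str = "mouse_model",
    disease_stage: str = "IBD",
    n_per_arm: int = 10,
    noise_sd: float = 0.8,
) -> ExpressionDataset:
    """Generate a two-arm (healthy vs disease) mouse model dataset whose true
    effects correlate with the human cohort's true effects at
    ``target_correlation``.

    Mouse effects are built as rho * z(human effects) + sqrt(1 - rho^2) *
    independent standard-normal noise, then rescaled back to Log2FC units
    (the human effects' mean and sd), and gene symbols are renamed through
    the ortholog map, so only genes with a mouse ortholog appear.
    """
    rho = float(target_correlation)
    if not -1.0 <= rho <= 1.0:
        raise ValueError("target_correlation must lie in [-1, 1]")
    registry = registry or build_default_registry()
    homologs = registry.homolog_map
    genes = [g for g in sorted(human_spec.gene_assignments) if g in homologs]
    if len(genes) < 3:
        raise ValueError("need at least 3 ortholog genes")
    rng = np.random.default_rng([seed, 2**20])
    human_effects = np.array(
        [human_spec.gene_assignments[g].effect(disease_stage) for g in genes]
    )
    sd = float(np.std(human_effects))
    if sd == 0.0:
        raise ValueError("human true effects are constant; correlation undefined")
    z = (human_effects - human_effects.mean()) / sd
    noise = rng.standard_normal(len(genes))
    mouse_effects = human_effects.mean() + sd * (rho * z + np.sqrt(1.0 - rho**2) * noise)

    mouse_genes = [homologs[g] for g in genes]
    baselines = rng.uniform(6.0, 10.0, size=len(genes))
    samples: list[SampleAnnotation] = []
    columns: dict[str, np.ndarray] = {}
    for stage, effects in (
        ("healthy_control", np.zeros(len(genes))),
        (disease_stage, mouse_effects),
    ):
        pool = STAGE_LABEL_POOL[stage]
        for i in range(n_per_arm):
            sid = f"{model_id}_{stage}_{i + 1}"
            samples.append(
                SampleAnnotation(
                    sample_id=sid,
                    raw_label=str(rng.choice(pool)),
                    stage=stage,
                )
            )
            columns[sid] = baselines + effects + rng.normal(0.0, noise_sd, len(genes))
    sample_ids = [s.sample_id for s in samples]
    matrix = pd.DataFrame(
        np.column_stack([columns[sid] for sid in sample_ids]),
        index=[f"{g}_p1" for g in mouse_genes],
        columns=sample_ids,
    )
    return ExpressionDataset(
        dataset_id=model_id,
        species="mouse",
        scale="log2",
        matrix=matrix,
        probe_gene_map={f"{g}_p1": g for g in mouse_genes},
        samples=samples,
        paired=False,
    )


def write_cohort(
    datasets: Sequence[ExpressionDataset], directory: Union[str, Path]
) -> list[Path]:
    """Write each dataset to ``directory/<dataset_id>/`` in the TSV dialect
    the ingest module reads back."""
    directory = Path(directory)
    return [write_dataset(ds, directory / ds.dataset_id) for ds in datasets]


# -- YAML round trip for cohort specs ---------------------------------------

def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    return {
        "seed": spec.seed,
        "baseline_range": list(spec.baseline_range),
        "datasets": [
            {
                "dataset_id": d.dataset_id,
                "stages": list(d.stages),
                "n_per_arm": d.n_per_arm,
                "paired": d.paired,
                "platform_exclude": list(d.platform_exclude),
                "noise_sd": d.noise_sd,
                "scale": d.scale,
                "effect_overrides": {
                    g: dict(st) for g, st in d.effect_overrides.items()
                },
            }
            for d in spec.datasets
        ],
        "gene_assignments": {
            gene: arch.name for gene, arch in spec.gene_assignments.items()
        },
    }


def cohort_spec_from_dict(data: Mapping) -> CohortSpec:
    datasets = [
        DatasetSpec(
            dataset_id=d["dataset_id"],
            stages=tuple(d["stages"]),
            n_per_arm=int(d.get("n_per_arm", 10)),
            paired=bool(d.get("paired", False)),
            platform_exclude=tuple(d.get("platform_exclude", ())),
            noise_sd=float(d.get("noise_sd", 0.8)),
            scale=d.get("scale", "log2"),
            effect_overrides=d.get("effect_overrides", {}),
        )
        for d in data["datasets"]
    ]
    assignments = {
        gene: ARCHETYPES[name] for gene, name in data["gene_assignments"].items()
    }
    spec = CohortSpec(
        datasets=datasets,
        gene_assignments=assignments,
        seed=int(data.get("seed", 0)),
        baseline_range=tuple(data.get("baseline_range", (6.0, 10.0))),
    )
    spec.validate()
    return spec


def load_cohort_spec(path: Union[str, Path]) -> CohortSpec:
    with open(path, "r", encoding="utf-8") as handle:
        return cohort_spec_from_dict(yaml.safe_load(handle))


def save_cohort_spec(spec: CohortSpec, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(cohort_spec_to_dict(spec), handle, sort_keys=True)
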