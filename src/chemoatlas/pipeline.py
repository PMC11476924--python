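"""End-to-end orchestration.

``run_pipeline`` drives the whole analysis from a single configuration:
load (or synthesize) the cohorts, standardize to log2 and collapse probes,
run every supported stage contrast per dataset, aggregate the vote-counting
score matrix, cluster and classify genes, correlate mouse models against the
human aggregate, and render figures.  All tabular outputs are deterministic
given the seed (stable row order, fixed float formatting, no timestamps), so
re-running a configuration reproduces byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from . import __version__
from .crosspecies import correlation_summary, leave_one_out_influence, model_vs_human
from .diffexpr import Contrast, StageComparison, run_contrast, run_standard_contrasts
from .errors import ChemoatlasError
from .ingest import GeneExpressionTable, collapse_probes, read_dataset, to_log2
from .integrate import (
    ScoreMatrix,
    assignments_to_frame,
    build_score_matrix,
    classify_groups,
    cluster_genes,
)
from .registry import build_default_registry
from .synthetic import default_cohort_spec, generate_cohort, generate_mouse_model
from .viz import plot_heatmap, plot_lines, plot_scatter, plot_volcano


@dataclass
class MouseModelConfig:
    """One mouse model: either synthesized (``target_correlation``) or read
    from a serialized dataset directory."""

    model_id: str
    target_correlation: Optional[float] = None
    directory: Optional[str] = None
    disease_stage: str = "IBD"  # which human contrast the model mimics


@dataclass
class RunConfig:
    """Pipeline configuration (YAML-loadable)."""

    seed: int = 0
    panel: str = "both"  # ligands | receptors | both
    fc_threshold: float = 1.0
    q_threshold: float = 0.05
    clusters: int = 4
    exclude: tuple[str, ...] = ()
    #: synthetic-cohort parameters (used when no dataset paths are given)
    n_per_arm: int = 10
    noise_sd: float = 0.8
    #: directories of serialized datasets (write_dataset layout); empty ->
    #: generate the default synthetic cohort
    dataset_dirs: tuple[str, ...] = ()
    mouse_models: tuple[MouseModelConfig, ...] = (
        MouseModelConfig("tnbs_like", 0.7, disease_stage="IBD"),
        MouseModelConfig("dss_like", 0.6, disease_stage="IBD"),
        MouseModelConfig("aomdss_like", 0.7, disease_stage="primary_carcinoma"),
        MouseModelConfig("apcmin_like", 0.3, disease_stage="primary_carcinoma"),
    )
    figures: bool = True

    def validate(self) -> None:
        if self.panel not in ("ligands", "receptors", "both"):
            raise ValueError(f"unknown panel {self.panel!r}")
        if self.fc_threshold <= 0 or not 0 < self.q_threshold < 1:
            raise ValueError("thresholds must be positive (q in (0, 1))")
        if self.clusters < 2:
            raise ValueError("clusters must be >= 2")
        for directory in self.dataset_dirs:
            if not Path(directory).is_dir():
                raise FileNotFoundError(f"dataset directory not found: {directory}")
        for model in self.mouse_models:
            if model.directory is not None and not Path(model.directory).is_dir():
                raise FileNotFoundError(
                    f"mouse dataset directory not found: {model.directory}"
                )
            if model.directory is None and model.target_correlation is None:
                raise ValueError(
                    f"mouse model {model.model_id}: need directory or target_correlation"
                )

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        models = tuple(
            MouseModelConfig(
                model_id=m["model_id"],
                target_correlation=m.get("target_correlation"),
                directory=m.get("directory"),
                disease_stage=m.get("disease_stage", "IBD"),
            )
            for m in data.get("mouse_models", ())
        )
        config = cls(
            seed=int(data.get("seed", 0)),
            panel=data.get("panel", "both"),
            fc_threshold=float(data.get("fc_threshold", 1.0)),
            q_threshold=float(data.get("q_threshold", 0.05)),
            clusters=int(data.get("clusters", 4)),
            exclude=tuple(data.get("exclude", ())),
            n_per_arm=int(data.get("n_per_arm", 10)),
            noise_sd=float(data.get("noise_sd", 0.8)),
            dataset_dirs=tuple(data.get("dataset_dirs", ())),
            figures=bool(data.get("figures", True)),
        )
        if models:
            config.mouse_models = models
        return config

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})


def _load_tables(config: RunConfig, registry, panel) -> list[GeneExpressionTable]:
    if config.dataset_dirs:
        datasets = [read_dataset(d) for d in config.dataset_dirs]
    else:
        spec = default_cohort_spec(
            seed=config.seed,
            n_per_arm=config.n_per_arm,
            noise_sd=config.noise_sd,
            registry=registry,
        )
        datasets = generate_cohort(spec, registry)
    return [collapse_probes(to_log2(ds), panel) for ds in datasets]


def _write_frame(frame: pd.DataFrame, path: Path) -> Path:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def run_pipeline(config: RunConfig, outdir: Union[str, Path]) -> dict[str, str]:
    """Run the full analysis; returns a manifest of output paths."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = build_default_registry()
    excluded = {registry.resolve(g) for g in config.exclude}
    panel = [g for g in registry.panel(config.panel) if g not in excluded]

    tables = _load_tables(config, registry, panel)
    comparisons: list[StageComparison] = []
    for table in tables:
        comparisons.extend(run_standard_contrasts(table, panel))

    outputs: dict[str, str] = {}
    all_frames = [c.to_frame() for c in comparisons if c.results]
    comparisons_frame = pd.concat(all_frames, ignore_index=True)
    outputs["comparisons"] = str(
        _write_frame(comparisons_frame, outdir / "comparisons.tsv")
    )

    healthy = [c for c in comparisons if c.contrast.reference_stage == "healthy_control"]
    matrix = build_score_matrix(
        healthy, panel, config.fc_threshold, config.q_threshold
    )
    measured = [g for g in matrix.genes if matrix.counts.loc[g].sum() > 0]
    matrix = ScoreMatrix(
        values=matrix.values.loc[measured], counts=matrix.counts.loc[measured]
    )
    clusters = cluster_genes(matrix, k=config.clusters)
    score_frame = matrix.values.copy()
    score_frame.insert(0, "gene", score_frame.index)
    score_frame["cluster"] = [clusters.labels[g] for g in score_frame.index]
    outputs["score_matrix"] = str(
        _write_frame(score_frame, outdir / "score_matrix.tsv")
    )
    counts_frame = matrix.counts.copy()
    counts_frame.insert(0, "gene", counts_frame.index)
    outputs["score_counts"] = str(
        _write_frame(counts_frame, outdir / "score_counts.tsv")
    )

    by_stage = lambda stage: [c for c in healthy if c.contrast.test_stage == stage]
    assignments, unclassifiable = classify_groups(
        by_stage("IBD"),
        by_stage("adenoma"),
        by_stage("primary_carcinoma"),
        measured,
        config.fc_threshold,
    )
    groups_frame = assignments_to_frame(assignments)
    groups_frame["cluster"] = [clusters.labels[g] for g in groups_frame["gene"]]
    outputs["groups"] = str(_write_frame(groups_frame, outdir / "groups.tsv"))
    if unclassifiable:
        outputs["unclassifiable"] = str(
            _write_frame(
                pd.DataFrame(unclassifiable, columns=["gene", "reason"]),
                outdir / "unclassifiable.tsv",
            )
        )

    # -- mouse models -------------------------------------------------------
    correlations = []
    spec = default_cohort_spec(
        seed=config.seed, n_per_arm=config.n_per_arm,
        noise_sd=config.noise_sd, registry=registry,
    )
    for offset, model in enumerate(config.mouse_models):
        if model.directory is not None:
            mouse_ds = read_dataset(model.directory)
        else:
            mouse_ds = generate_mouse_model(
                spec,
                model.target_correlation,
                seed=config.seed + offset + 1,
                registry=registry,
                model_id=model.model_id,
                disease_stage=model.disease_stage,
                n_per_arm=config.n_per_arm,
                noise_sd=config.noise_sd,
            )
        mouse_table = collapse_probes(to_log2(mouse_ds))
        mouse_comp = run_contrast(
            mouse_table, Contrast(model.disease_stage, "healthy_control")
        )
        human = by_stage(model.disease_stage)
        if not human:
            continue
        corr = model_vs_human(mouse_comp, human, registry)
        summary = correlation_summary(corr)
        influence = leave_one_out_influence(corr)
        summary["leave_one_out_top5"] = {
            g: influence[g] for g in list(influence)[:5]
        }
        correlations.append(summary)
    correlations_path = outdir / "correlations.json"
    correlations_path.write_text(
        json.dumps(correlations, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    outputs["correlations"] = str(correlations_path)

    # -- figures ------------------------------------------------------------
    if config.figures:
        outputs["heatmap"] = str(
            plot_heatmap(matrix, clusters, outdir / "heatmap.png")
        )
        outputs["scatter"] = str(plot_scatter(assignments, outdir / "scatter.png"))
        groups_by_gene = dict(zip(groups_frame["gene"], groups_frame["group"]))
        richest = max(
            {c.dataset_id for c in healthy},
            key=lambda ds: (len([c for c in healthy if c.dataset_id == ds]), ds),
        )
        outputs["lines"] = str(
            plot_lines(
                [c for c in healthy if c.dataset_id == richest],
                groups_by_gene,
                outdir / "lines.png",
            )
        )
        first = healthy[0]
        outputs["volcano"] = str(
            plot_volcano(
                first,
                outdir / f"volcano_{first.dataset_id}_{first.contrast.test_stage}.png",
                config.fc_threshold,
                config.q_threshold,
            )
        )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "panel": config.panel,
        "fc_threshold": config.fc_threshold,
        "q_threshold": config.q_threshold,
        "clusters": config.clusters,
        "exclude": sorted(excluded),
        "n_datasets": len(tables),
        "dataset_ids": sorted(t.dataset_id for t in tables),
        "outputs": {k: str(Path(v).name) for k, v in sorted(outputs.items())},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    outputs["manifest"] = str(manifest_path)
    return outputs
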