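"""Cross-species comparison: correlate a simulated mouse colitis model with
the human IBD aggregate, with a leave-one-out influence diagnostic."""

from chemoatlas import (
    Contrast,
    build_default_registry,
    collapse_probes,
    default_cohort_spec,
    generate_cohort,
    generate_mouse_model,
    leave_one_out_influence,
    model_vs_human,
    run_contrast,
    to_log2,
)

registry = build_default_registry()
spec = default_cohort_spec(seed=1)
datasets = generate_cohort(spec, registry)
human = [
    run_contrast(collapse_probes(to_log2(ds)), Contrast("IBD"))
    for ds in datasets
    if "IBD" in {s.stage for s in ds.samples}
]

mouse = generate_mouse_model(spec, target_correlation=0.7, seed=8,
                             registry=registry, model_id="tnbs_like")
mouse_comp = run_contrast(collapse_probes(to_log2(mouse)), Contrast("IBD"))

corr = model_vs_human(mouse_comp, human, registry)
print(f"{corr.model_id}: Pearson r = {corr.r:.2f} "
      f"(p = {corr.p_value:.1e}, n = {corr.n} ortholog genes)")
print(f"unpaired genes (no ortholog / not on platform): "
      f"{sorted(corr.unpaired_genes)[:5]} ...")

influence = leave_one_out_influence(corr)
gene, r_without = next(iter(influence.items()))
print(f"most influential single gene: {gene} (r without it = {r_without:.2f})")
# The model was simulated with a true effect correlation of 0.7; the
# measured r is attenuated slightly by within-cohort sampling noise.
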