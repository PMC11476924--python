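"""Vote-counting integration: the ratio-of-significant-difference matrix,
expression-pattern clustering, and the quadrant classification."""

from chemoatlas import (
    Contrast,
    build_score_matrix,
    classify_groups,
    cluster_genes,
    collapse_probes,
    default_cohort_spec,
    generate_cohort,
    run_contrast,
    to_log2,
)

spec = default_cohort_spec(seed=1)
tables = [collapse_probes(to_log2(ds)) for ds in generate_cohort(spec)]

by_stage = {"IBD": [], "adenoma": [], "primary_carcinoma": []}
for t in tables:
    for stage in by_stage:
        if stage in t.stages_present():
            by_stage[stage].append(run_contrast(t, Contrast(stage)))

comparisons = [c for comps in by_stage.values() for c in comps]
matrix = build_score_matrix(comparisons)
print("ratio of significant difference (mean of +1/0/-1 votes per stage):")
print(matrix.values.loc[["CXCL8", "CXCL9", "CXCL12", "CCL25"]].round(2))
# +1.0 = significantly up in every cohort measuring the gene at that stage,
# -1.0 = down in every cohort, 0 = no consistent significant change.

clusters = cluster_genes(matrix, k=4)
assignments, _ = classify_groups(
    by_stage["IBD"], by_stage["adenoma"], by_stage["primary_carcinoma"],
    list(matrix.genes),
)
print("\nquadrant groups (x = IBD mean Log2FC, y = tumor mean Log2FC):")
for a in assignments:
    if a.gene in ("CXCL8", "CXCL9", "CXCL12", "CCL25"):
        print(f"  {a.gene:8} x={a.x:5.2f} y={a.y:5.2f} -> group {a.group} "
              f"(cluster {clusters.labels[a.gene]})")
# group i = up in IBD and tumor, ii = inflammation-specific,
# iii = unrelated to disease, iv = neoplasm-downregulated.
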