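# chemoatlas

Multi-cohort expression profiling of the chemokine family along the
colitis-to-colorectal-cancer axis.

## The problem

Chemokines — 39 human ligands in four subfamilies (CXC, CC, CX3C, XC) and 22
receptors — drive immune-cell infiltration in inflammatory bowel disease
(IBD) and shape the tumor microenvironment in colorectal cancer. Public
transcriptome datasets each cover only one slice of the disease course, on
different array platforms, with different sample annotations and group
sizes. `chemoatlas` is for researchers who want to integrate many such
cohorts into one picture of how each chemokine behaves across five
harmonized stages — healthy control, IBD, adenoma, primary carcinoma,
metastasis — without ever merging incomparable matrices.

## The method

All statistics are computed **within** each dataset, then combined by vote
counting:

1. **Standardize** — sample labels are harmonized onto the five stages
   (UC/CD pooled as IBD, liver/lung pooled as metastasis), linear
   intensities converted to log2, and multiple probes per gene collapsed to
   the probe with the strongest mean signal.
2. **Differential expression** — per dataset and stage-vs-reference
   contrast: Log2FC = mean(log2 test) − mean(log2 reference), a two-tailed
   equal-variance Student t-test (paired t-test for paired cohorts), and
   Benjamini–Hochberg Q-values over the chemokine panel.
3. **Vote counting** — each dataset scores each gene per stage:
   +1 if Q < 0.05 and Log2FC > 1, −1 if Q < 0.05 and Log2FC < −1, else 0.
   The *ratio of significant difference* is the arithmetic mean of these
   votes over the datasets measuring the gene (a gene significantly up in
   3 of 4 IBD cohorts scores 3/4 = 0.75). The gene × stage matrix of these
   means drives a heatmap and an average-linkage hierarchical clustering
   into four expression patterns.
4. **Quadrant classification** — with x = mean IBD Log2FC and y = mean of
   the adenoma-mean and carcinoma-mean Log2FC, a two-fold cutoff splits
   genes into group i (neoplasm-upregulated), ii (inflammation-specific),
   iii (disease-unrelated) and iv (neoplasm-downregulated).
5. **Cross-species correlation** — mouse disease-model fold changes are
   paired with human mean fold changes through an ortholog map and
   summarized by Pearson's r, with leave-one-out influence diagnostics.

A fully seeded synthetic-cohort generator reproduces the structure such
compendia have (multiple platforms, paired/unpaired designs, messy labels,
four expression archetypes), so the entire pipeline is testable offline.

## Worked example

```python
from chemoatlas import (Contrast, build_score_matrix, collapse_probes,
                        default_cohort_spec, generate_cohort, run_contrast,
                        to_log2)

spec = default_cohort_spec(seed=1)              # 4 IBD + 2 adenoma + 3 carcinoma cohorts
tables = [collapse_probes(to_log2(ds)) for ds in generate_cohort(spec)]
comparisons = [run_contrast(t, Contrast(stage))
               for t in tables for stage in t.stages_present()
               if stage != "healthy_control"]
matrix = build_score_matrix(comparisons)
print(matrix.values.loc[["CXCL8", "CXCL9", "CXCL12", "CCL25"]].round(2))
```

prints

```
        IBD  adenoma  primary_carcinoma
CXCL8   1.0      1.0                1.0
CXCL9   1.0      0.0                0.0
CXCL12  0.0     -1.0               -1.0
CCL25   0.0      0.0                0.0
```

CXCL8 (ELR+, neoplasm-upregulated) is significantly up in every cohort at
every disease stage; CXCL9 is up only in the IBD cohorts
(inflammation-specific); CXCL12 is down in every tumor cohort
(neoplasm-downregulated); CCL25 shows no consistent change. The
`examples/` directory walks through each capability — registry lookups,
simulation + ingest, differential expression, score matrix + groups, mouse
correlation, and the full pipeline — as short runnable scripts. The same
pipeline runs from the shell:

```bash
chemoatlas all --out out/ --seed 1          # synthetic demo cohort
chemoatlas simulate --out cohort/ --seed 1  # write TSV cohorts to disk
```

Real cohorts are read from series-matrix-like TSVs with companion
annotation and probe-map tables (`read_series_matrix`).

## Layout

- `src/chemoatlas/` — `registry` (roster, pairing, orthologs), `ingest`,
  `diffexpr`, `integrate`, `crosspecies`, `synthetic`, `viz`, `pipeline`,
  `cli`
- `docs/methods.md` — model, assumptions, parameter defaults, limitations
- `examples/` — one narrative script per capability
- `tests/` — unit, property and end-to-end acceptance tests
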