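# Methods

## Scope and model

`chemoatlas` integrates independent expression cohorts covering different
parts of the colitis → adenoma → carcinoma → metastasis axis. The central
modeling decision is that cohorts are never merged at the matrix level:
platforms, normalizations and dynamic ranges differ, so every statistic is
computed within one dataset and aggregation happens only at the level of
per-dataset summaries (significance votes and fold changes). This is
vote-counting meta-analysis: it is robust to cross-platform scale
differences but discards effect-size precision and gives every dataset
equal weight regardless of sample size.

## Gene registry

The roster fixes 39 ligands and 22 receptors. The ligand list contains
every family member the analysis tracks by name (CXCL1–14 with PF4/PPBP
under their HGNC symbols, CXCL16, CCL2–5, CCL7, CCL8, CCL11, CCL13–16,
CCL18–24, CCL25, CCL26, CCL28, XCL1/2, CX3CL1); the receptor list is
CXCR1–6, CCR1–10, XCR1, CX3CR1 plus the four atypical receptors ACKR1–4.
ELR+ status marks exactly CXCL1, 2, 3, 5, 6, 7 (PPBP) and 8. Aliases
(CXCL4 → PF4, CXCL7 → PPBP, CXCR7 → ACKR3, IL8 → CXCL8) resolve at lookup.
The human → mouse ortholog map is a bundled static table rather than a live
database query, for reproducibility; it is injective, and genes without a
mouse ortholog (CXCL8, CXCL6, CCL13–16, CCL18, CCL23, XCL2) are absent from
it rather than mapped to placeholders. CXCL6 is left unmapped because mouse
Cxcl5/LIX is the shared ortholog of human CXCL5 and CXCL6 and the map keeps
one-to-one pairs only.

## Standardization

* **Stage harmonization.** Free-text labels map case-insensitively onto
  five stages; ulcerative colitis and Crohn's disease are pooled as IBD and
  liver/lung metastases as metastasis. User rules extend and override the
  built-in vocabulary; an unmatched label is an error, never a silent drop.
* **log2 conversion.** Datasets detected (max value > 50) or declared as
  linear are transformed by log2 after clamping values below 1.0 to 1.0 —
  background-subtracted microarray intensities can be ≤ 0, and the clamp
  maps them to 0 rather than −∞. The transform is idempotent; data already
  on log2 scale pass through unchanged. Whether a source dataset was
  distributed on log scale is sometimes ambiguous; the threshold heuristic
  is overridable per dataset.
* **Probe collapse.** "Strongest signal" is interpreted as the highest mean
  log2 intensity across all samples of the dataset (not the maximum single
  value, not per-group means), with ties broken by the lexicographically
  smallest probe id. Genes absent from a platform are simply absent rows —
  downstream denominators must count only the datasets that measure a gene.
* **Missing values** propagate as missing (case-wise deletion in tests,
  skip-NaN means in collapse); nothing is imputed, except that clustering
  (below) fills missing score cells with 0.

## Differential expression

Per dataset and contrast (disease stage vs healthy control; metastasis vs
primary carcinoma), Log2FC is the difference of group means on the log2
scale. Unpaired cohorts use the two-tailed pooled-variance Student t-test —
equal variances are an explicit modeling assumption here, not an oversight,
and Welch's correction is deliberately not applied. Paired cohorts use the
paired t-test over complete pairs (pairs with a missing member are
dropped). Degenerate inputs are deterministic: when both arms (or the
paired differences) have zero variance, equal means give p = 1, and a
nonzero mean difference is tested with a variance floor of 1e-12 instead of
yielding an infinite statistic.

Q-values are Benjamini–Hochberg, computed within one dataset-contrast over
exactly the gene panel analyzed (by default the chemokine genes present on
the platform). This matches an extract-the-panel-first workflow; the BH
family is therefore small (≤ 61 genes) and the choice is configurable by
passing a different panel. Adjustment per dataset-contrast, rather than
globally over all contrasts, was chosen because each comparison is reported
as its own test family.

## Integration

* **Vote.** +1 iff Q < 0.05 and Log2FC > 1; −1 iff Q < 0.05 and
  Log2FC < −1; else 0. Equivalently the −Log10Q > 1.3, |Log2FC| > 1
  criteria; thresholds are parameters with these defaults.
* **Ratio of significant difference.** The signed arithmetic mean of votes
  over the datasets measuring the gene at that stage, in [−1, 1]. A cell
  with no measuring dataset is missing, never 0. The signed mean (rather
  than an unsigned percentage) is used so that direction survives
  aggregation; conflicting datasets cancel toward 0.
* **Clustering.** Agglomerative hierarchical clustering of score-matrix
  rows, Euclidean distance, average linkage, cut at k = 4 (configurable).
  Gene order is fixed to sorted symbols, making results deterministic;
  missing cells are imputed as 0 ("no evidence of change") only inside the
  clustering. Coincident rows merge at distance zero, so fewer than k
  distinct clusters can result for degenerate matrices.
* **Quadrant classification.** x = unweighted mean of per-dataset IBD
  Log2FC; y = arithmetic mean of the adenoma-cohort mean and the
  carcinoma-cohort mean (if only one tumor stage covers a gene, that mean
  stands alone). With threshold t = 1: group i iff x > t and y > t; group
  ii iff x > t and |y| ≤ t; group iv iff y < −t and |x| ≤ t; group iii
  otherwise. Values exactly at a threshold fall on the less-extreme side.
  The corner x > t, y < −t (up in inflammation, down in tumor) has no named
  pattern; it is resolved by the nearest archetype — the larger absolute
  coordinate wins, exact ties fall to group iii.

## Cross-species correlation

The human reference value per gene is the unweighted mean Log2FC across the
human cohorts for the matching contrast (not sample-size weighted — every
cohort is one vote, consistent with the integration above). Mouse model
fold changes are paired through the ortholog map; genes without an ortholog
or absent from the model platform are reported as unpaired. The statistic
is Pearson's r with the two-tailed t-test on n − 2 degrees of freedom
(Spearman available). Explicit exclusion lists are supported, and a
leave-one-out diagnostic reports r without each gene, ranked by influence,
as the principled counterpart of ad-hoc single-gene exclusions.

## Synthetic cohorts

The generator emulates: several independent cohorts with platform-specific
gene subsets, n per arm from desk-scale study sizes, paired and unpaired
designs, heterogeneous annotation strings drawn from the real vocabulary,
linear- or log-scale emission, and a duplicated weaker probe for the first
two genes of each platform so probe collapse is exercised end to end.

Defaults define the reference study conditions: 4 IBD + 2 adenoma + 3
carcinoma cohorts (one carcinoma cohort paired), n = 10 per arm,
noise_sd = 0.8 on the log2 scale. Archetype effects are
neoplasm_up (+2.5 IBD, +2.0 adenoma/carcinoma), inflammation_specific
(+3.0 IBD only), neoplasm_down (−2.0 adenoma, −2.5 carcinoma) and
unchanged (0) — magnitudes chosen to resemble the strongly regulated
chemokines such compendia report (IBD inductions of Log2FC 2–3, carcinoma
silencing near −3). Noise is additive Gaussian, homoscedastic per dataset,
matching the equal-variance assumption of the t-test; paired cohorts add a
shared per-pair, per-gene intercept with sd noise_sd/2, which makes the
paired test strictly more powerful and keeps the two designs
distinguishable in tests. Per-dataset effect overrides allow controlled
heterogeneity (e.g. a gene with an effect in only 3 of 4 cohorts).

Mouse models are generated from a target true-effect correlation ρ: mouse
effects = ρ · z(human effects) + √(1−ρ²) · independent noise, rescaled to
the human effects' mean and sd, restricted to ortholog genes and renamed to
mouse symbols. Measured correlations are mildly attenuated below ρ by
within-cohort sampling noise (about 4% under the defaults).

What the generator does **not** emulate: probe-level platform artifacts
(dye bias, spatial effects), heavy-tailed or heteroscedastic noise,
correlated genes, batch effects, or annotation errors. Passing tests
therefore demonstrate correctness of the pipeline's logic and its
statistical calibration under its own assumptions, not robustness to every
pathology of real microarray data.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale by design: 61-gene
panels, 9-cohort compendia, n = 10 per arm, 20 generator seeds for
archetype recovery, 200 replicates for the null FDR check and 500 for
correlation recovery. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; pipeline tables are written with fixed
float formatting and no timestamps, so a configuration + seed reproduces
byte-identical TSV/JSON outputs.

## Known limitations

* Vote counting ignores effect-size magnitude and dataset precision; a
  3-sample and a 186-sample cohort carry equal weight.
* The equal-variance t-test is kept for fidelity to the analysis design
  even where Welch would be more defensible statistically.
* The BH family is the small chemokine panel; genome-wide Q-values would
  differ.
* The quadrant rule hard-codes the two-fold cutoff geometry; genes with
  real but sub-two-fold changes land in group iii ("unrelated") even when
  Q is very small.
* Real-accession ingest expects pre-exported series-matrix-like TSVs; no
  SOFT/MINiML download machinery is included.
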