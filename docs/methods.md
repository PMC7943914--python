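# Methods

This note documents the models, parameter choices, and numerical conventions behind
`scith`, and what the synthetic-data tests do and do not establish about real data.

## Synthetic cohort model

The generator (`scith.simulate`) emulates a droplet scRNA-seq cohort spanning an
ordered set of tissue conditions (default `normal → early → advanced`), with
`n_patients_per_condition = 3` patients of `n_cells_per_patient = 500` cells over
`n_genes = 2000` genes on 10 pseudo-chromosomes.

**Counts.** Counts are gamma-Poisson: for a cell of type *t*, condition *k*,
patient *p*, gene *g*,

```
mu_gc = depth_c · base_g · 2^(type effect) · 2^(condition effect) · 2^(CNV dosage)
x_gc ~ Poisson( Gamma(1/φ_k, mu_gc·φ_k) )        # NB with inverse-size φ_k
```

`depth_c` is log-normal (σ = 0.35). The per-condition dispersion φ defaults to 0.1,
with 0.3 in the last (most advanced) condition — the 3× contrast that drives the
transcriptional-noise comparisons. Gene means are renormalized neither per cell nor
globally, so a planted 2× dosage yields exactly 2× expected counts.

**Expression levels.** The simulated genes represent a cell's *expressed* gene
panel (the part of the transcriptome that survives HVG-style selection), not the
full ~20k-gene annotation, so base means are gamma(shape 0.8) scaled to 6,000
expected counts per typical cell (~3 counts per gene on average, middle-decile
genes at ~1–3 counts). This matters statistically: NB variance is
`μ + φμ²`, so condition-dispersion differences are only visible on genes with
μ ≳ 1; a panel dominated by near-silent genes would hide any dispersion contrast
behind Poisson sampling no matter the method.

**Programs.** Each cell type carries a 50-gene program at log2 effect 1.5; each
condition a 30-gene program at log2 effect 1.0 applied to all of its cells.
Program genes are drawn from reasonably expressed genes (≥ 40th / ≥ 60th
percentile of base mean) — condition markers in real data are expressed genes —
and never touch the mitochondrial block.

**CNV.** Malignant patients (all patients outside the first condition) carry one
cohort-shared +1 gain plus 2 (early) or 3 (advanced) patient-specific segments of
up to 150 genes with log2 dosages in {±1, ±0.58}. The shared gain reflects the
recurrent arm-level events characteristic of lung adenocarcinoma; it is also what
makes a correlation-to-consensus malignancy criterion meaningful — with purely
private events no cross-patient consensus profile exists.

**Other structure.** The last 10 genes form an `MT-`-prefixed mitochondrial block
carrying ~6% of baseline expression. 2% of cells per patient are "shallow"
(depth × 0.03) and 2% "dying" (mitochondrial means × 12), the planted QC
violations. Five ligand–receptor pairs are planted (one unique per condition, one
common to all, one shared by the two tumor conditions) by forcing the ligand mean
to 1.0 in sender-type cells and the receptor in receiver-type cells within the
planted conditions; three decoy pairs stay at a 0.002 baseline everywhere. All
labels, programs, segments, and pairs are recorded in a `GroundTruth` ledger.

**What the generator does not model:** batch/chemistry effects, doublets, ambient
RNA, per-patient baseline shifts beyond CNV, gene–gene correlation beyond the
planted programs, and zero-inflation beyond NB sparsity. Passing tests therefore
establish method correctness under clean NB assumptions, not robustness to
real-data artifacts (batch structure in particular is explicitly out of scope —
annotations and conditions are single-batch by construction).

## QC, normalization, embedding

Cells are removed when they express fewer than `min_genes = 200` genes, more than
`max_genes = 7000`, or carry more than `max_mito_fraction = 0.20` of counts in
`MT-` genes — all strict inequalities, so boundary cells (exactly 200 genes,
exactly 20%) are retained. Removal counts are reported per criterion with a fixed
precedence (low genes → high genes → mito) so they partition the total. A gene is
"detected" when its count exceeds 0. QC is applied to the pooled cohort; the
generator is single-batch, so per-sample-then-pool and pool-then-filter coincide.

Normalization is `ln(1 + 10⁴ · x / library)`; raw counts are retained in
`layers["counts"]` because interaction detection is a count concept. HVG selection
uses the 20-bin mean-binned standardized-dispersion method (scanpy's `seurat`
flavor) with `n_hvg = 2000`; features are centered and scaled (no clipping) before
an exact-SVD PCA with `n_pcs = 50` and a deterministic sign convention (largest
loading positive). Downstream statistics (diversity, lineage shift, domain
clustering) use the top 10 PCs: with 2,000 features and a few thousand cells, 10
components comfortably capture the planted structure while keeping Gaussian
covariance estimation well conditioned at 400-cell subsamples.

## CNV inference and malignancy

Per gene, the reference mean (immune/stromal cells: T, B, myeloid, fibroblast) is
subtracted from the log-normalized matrix; values are divided by ln 2 (log2 units),
clipped to ±3, moving-averaged over a 101-gene window within each chromosome (the
window shrinks at chromosome edges), and recentred by each cell's median. Window
101 and clip 3 follow inferCNV convention; genes with mean normalized expression
below 0.1 (the usual inferCNV expression cutoff) or without a genomic position are
dropped and logged. At least 30 reference cells are required.

The malignancy score is the mean squared profile entry. A cell is flagged when its
score exceeds the 95th percentile of reference scores **and** its profile
correlates above 0.3 with the mean profile of the top-5%-scoring cells; the second
criterion exists because score alone misflags high-variance but diploid cells.
Both thresholds are configurable module defaults. The exact scoring formula in the
original analyses of this kind is typically unpublished; mean-squared-CNV with a
quantile-plus-correlation flag is the standard construction and is used here as a
stated substitute.

## Diversity and transcriptional noise

**Diversity** of a tumor = mean Euclidean distance of the patient's malignant
cells to their centroid in the top 10 PCs. The inclusion rule (strictly more than
`min_cells` malignant cells) defaults to 500, the published cohort-scale rule; the
bundled 4,500-cell pipeline sets it to 100 because no fixture-scale patient holds
500 malignant cells — a scaling choice, not a change of statistic. For an
isotropic Gaussian cloud the score has the closed form
`σ·√2·Γ((d+1)/2)/Γ(d/2) ≈ 3.0844σ` at d = 10, which the tests verify to 2%.
Condition comparison uses the two-sided Wilcoxon rank-sum (exact by enumeration
for ≤ 12 pooled patients — with 3 patients per condition the smallest attainable
two-sided p is 0.1).

**Noise.** Invariant genes are the middle mean-expression decile (the quantile
band 0.45–0.55, centred on the median) ranked by lowest cross-cohort coefficient
of variation; the default panel size of 500 assumes a real-scale gene universe,
and the pipeline uses 150 on the 2,000-gene fixture (the band holds only ~200
candidates; the implementation falls back to all candidates with a warning).
Noise per cell is the squared distance to its (cell type, condition) stratum mean;
strata under 20 cells are skipped; with `equalize` (default) strata are
downsampled to the smallest retained stratum before computing means, since
unequal n otherwise biases the variance estimates, and noise is reported for the
sampled cells. Early-vs-advanced comparison is a two-sided rank-sum per cell type
with BH adjustment across cell types; significance at adjusted p < 0.05.

Under label permutation this procedure is exact, so the probability that *any*
cell type is flagged in a permuted run equals the nominal 5% BH family-wise rate.
The permutation-null tests therefore assert calibration — the observed flag count
over seeded permutation runs must lie within the exact one-sided 99%
binomial(runs, 0.05) envelope — rather than a hard "zero flags in 95% of runs"
cutoff, which would reject a perfectly calibrated implementation about half the
time.

## Bhattacharyya lineage shift

For a lineage with at least `n_sub` cells in each condition: `n_boot = 100`
repeats of (sample `n_sub = 400` cells per condition without replacement, fit
Gaussian summaries in the top `d = 10` PCs, compute the Bhattacharyya distance).
Covariances get a ridge of `1e-6 · trace/d · I` so they are invertible; a
singular pooled covariance raises with its condition number. The null repeats the
procedure on random two-way partitions of the pooled cells. Finite-sample
covariance estimation biases every distance upward, so even the null mean is
strictly positive; the fold change divides the observed mean by the null mean,
comparing against that bias rather than zero. The p-value is a two-sided rank-sum
between the observed and null distance clouds (the original analyses do not state
their test). Each lineage draws from a fresh name-keyed seed stream so lineage
order cannot leak randomness. The bundled pipeline uses `n_sub = 150` because
fixture-scale lineages hold ~200–330 cells per condition; the library default
stays 400.

## Markers, network, interactions, signatures

The rank-sum test is exact by complete enumeration (midranks for ties) when the
pooled sample has ≤ 12 observations and otherwise uses the tie-corrected normal
approximation without continuity correction (the convention of the major scRNA
toolkits). log2 fold changes compare expm1 means with a 1e-9 pseudocount; genes
detected in fewer than 3 cells are skipped; BH runs across tested genes.

Condition-related genes: per cell type, each condition versus the rest of that
type; genes at FDR < 0.01 and log2FC > 0.5 *toward the condition* are unioned per
condition (up-only, because under one-vs-rest a two-sided threshold would also
file every enriched gene under the conditions it is depleted from); the top-10
table ranks by minimum FDR, then |log2FC|. Stage markers use log2FC > 0.5 (strict)
and FDR < 0.05 (strict), up-regulated only. Domain clusters: a cluster is a
condition domain when its maximal condition fraction is ≥ 0.60 (inclusive); exact
ties are never domains. The bundled pipeline re-clusters the myeloid lineage
(k-means, k = 10, top 10 PCs) before applying the rule, mirroring the
macrophage-recluster use case.

The cell-type network is built per condition over types with ≥ 20 cells: node
profiles are mean normalized expression over the HVGs, edges are all pairwise
Pearson correlations (sorted by |r|), and the hub is the most abundant type — the
"centroid" reading that keeps the full edge set so no information is discarded.
Constant centroids yield explicitly recorded undefined edges.

Interaction calling works on raw counts: a gene is expressed by a (cell type,
condition) when strictly more than `min_cells = 10` cells of that type detect it
in strictly more than `min_patient_frac = 0.5` of the condition's patients; a
patient lacking the cell type counts as non-qualifying. An interaction is called
when the ligand passes in the sender type and the receptor in the receiver type.
Classes partition exhaustively: *unique* = called in exactly one condition,
*common* = two or more (the `n_conditions` column exposes the ≥ 3 subset, since
"more than two conditions" alone would leave two-condition calls unclassified in
a three-condition design).

Panel scores are mean per-gene z-scores across cells (constant genes contribute
0; no control-bin subtraction — the simplest convention, configurable by panel
orientation). Pathway activity is the relative-mean construction: per gene, the
type mean divided by the unweighted average of type means; per pathway and type,
the mean of those ratios, so each pathway averages to exactly 1 across types.
Significance comes from `n_perm = 1000` cell-type label shuffles with add-one
smoothing, upper and lower tails reported.

## Pipeline and reproducibility

`run_pipeline` executes simulate → qc → embed → cnv → diversity → noise → shift →
markers → network → talk → score from a strict (unknown-key-rejecting) YAML
config. A single global seed is expanded per stage by name (`seed XOR
crc32(stage)`), so inserting a stage never shifts downstream randomness; reruns
with the same config are bit-identical (verified byte-for-byte in the tests).
Every stage writes flat TSV/JSON outputs plus a manifest with its parameters,
seed, and SHA-256 input hashes. Problem sizes throughout the test suite and the
acceptance script (4,500 × 2,000 cohort, 2,000-cell CNV fixture, 200-cell DE
groups, 20-seed diversity replicates, 200 permutation runs) are the package's
chosen desk-scale study conditions.

## Known limitations

- CNV inference reports smoothed dosage patterns, not discrete states; no HMM
  segmentation, subclone trees, or allele-specific events.
- The noise statistic assumes strata are internally homogeneous apart from the
  condition effect; strong unmodeled substructure within a (type, condition)
  stratum inflates noise for biological rather than stochastic reasons.
- Lineage-shift subsamples are not patient-stratified; with very unbalanced
  patient contributions the Gaussian summaries can be dominated by one patient.
- Interaction calling is presence/absence only — no expression-magnitude scoring
  or per-pair permutation p-values.
- All guarantees quantified in the tests hold under the generator's NB
  assumptions; batch effects, doublets, and ambient RNA are out of scope.
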