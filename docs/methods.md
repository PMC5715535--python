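# Methods

## Scope and data model

The package analyses plate-based single-cell RNA-seq of developing fetal
liver quantified as FPKM, with 92 ERCC spike-in control rows flagged by the
`ERCC-` id prefix. All correlation, clustering and test statistics operate
on log2(FPKM+1); "detected" means FPKM > 1 (strict). Matrices are genes ×
cells with unique string ids, stored as TSV or MatrixMarket plus row/column
id files.

## Synthetic study generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream stage is validated.

**Composition.** Six cell types — hepatoblast, mesenchymal, endothelial,
erythrocyte, macrophage, megakaryocyte — sampled per stage from a
configured simplex. The default proportions interpolate from
(0.28, 0.24, 0.10, 0.22, 0.11, 0.05) at the earliest stage to
(0.50, 0.04, 0.10, 0.12, 0.19, 0.05) at the latest, so hepatoblasts expand
while mesenchymal and erythroid fractions decline stepwise, as in
mid-gestation liver. Default: 7 stages (E11.5–P2.5), 60 cells/stage; the
demo uses 5 stages (E11.5–E16.5), 80 cells/stage.

**Expression tiers.** Primary lineage markers (the annotation panels) are
expressed at 1000–3000 FPKM in their own type — hemoglobin- and
platelet-class genes highest — and 0.1 FPKM elsewhere. Secondary
isolation-marker candidates (Cdh1, Anpep, Prom1, Gcgr, Cdhr2, Lgr5, Cd24a,
Igdcc4, plus filler markers) sit at 120 FPKM in their type. Thirty
hepatoblast trajectory genes take per-gene base levels of 1–64 FPKM and
change 2-fold per stage step (half up, half down) in hepatoblasts only.
Cholangiocyte genes (Sox9, Spp1, Krt7, Krt19, Epcam, Hes1) are silent
(0.05 FPKM) in all six fetal types. The remaining ~1900 neutral genes draw
means log-uniformly over 0.5–1000 FPKM. These levels were chosen so the
simulated transcriptome has a realistic density of strongly differential
genes (~4–6% above the noise-fit floor) — the regime in which the noise
filter is well posed.

**Noise law.** Given a target mean μ, expression is drawn from a gamma
distribution with CV² = a₁/μ + a₀ (defaults a₀ = 0.05, a₁ = 4 FPKM), then
zeroed by a Bernoulli drop-out whose keep probability rises logistically in
ln μ around `dropout_midpoint` (0.5 FPKM, slope 2). Spike-ins share one
global mean profile (1–1000 FPKM) across all cells and carry gamma noise
but no drop-out, making them pure technical controls. With a₀ = a₁ = 0 and
drop-out disabled the generator degenerates to exact means — the zero-noise
limit used in tests.

**Cholangiocytes.** Sorted Epcam-positive cells are drawn around the
earliest-stage hepatoblast centroid with cholangiocyte genes activated,
hepatoblast markers silenced, a shared random 35% of neutral genes shut
down and mild extra per-cell drop-out (keep 0.8). The shared shutdown is
what real differentiation looks like at the matrix level: fewer detected
genes per cell but cells still strongly correlated with their population
median — uniform random extra drop-out would instead decorrelate every
cell and fail any profile-similarity QC.

**Degraded libraries.** `inject_outliers` rescales chosen cells by 0.05
and keeps only 25% of entries, collapsing detected-gene counts far below
the healthy population.

**What the generator does not emulate.** Read-level sampling, UMIs,
amplification chimeras, batch effects beyond a scalar, gene–gene
correlation within a type beyond the stage-driven one, and heavy-tailed
per-cell capture efficiency. Passing tests therefore show the algorithms
recover the structure this model encodes, not that they are robust to
every artefact of real libraries.

## Quality control

FPKM values produced against separate genome and spike-in references are
rescaled per cell: gene rows by genome_reads/(genome+spikein), spike-in
rows by the complementary fraction. Cell outliers are flagged when the
detected-gene count falls below median − 3 · scaled MAD, or when the
median pairwise spike-in correlation (log2 scale) drops below 0.5.
Retention percentage is 100·retained/in rounded half-up to one decimal.
For sorted populations a second pass removes cells whose Pearson
correlation to the median profile of first-pass survivors is below 0.6.
The MAD rule, the 0.5 spike-in floor and the 0.6 profile floor are this
package's own reproducible replacements for a vendor tool's undocumented
defaults; all are configurable.

## Technical-noise model

Moments use the sample mean and unbiased variance per gene across cells
(spike-ins excluded by default); CV² = σ²/μ² is defined only for μ > 0.
The floor μ_th is the smallest candidate (0 or an observed mean) above
which a non-empty gene set has at most 5% of CV² values exceeding 0.3;
an empty surviving set does not count as satisfying the rule, so the
"no threshold exists" error is reachable.

The regression of CV² on 1/μ uses a gamma-family GLM with identity link;
if the GLM cannot run (non-positive CV² values break the gamma support, or
IRLS fails) the model falls back to ordinary least squares. Because the
observed CV² mixes technical noise with biological variability, the fit is
made robust with one trimmed re-fit: genes whose CV² exceeds 3× their
first-pass fitted value are set aside and the regression is solved once
more. On clean technical-noise data nothing is trimmed and the fit is
unchanged (a noiseless CV² = 4/μ + 0.05 table is recovered to 1e-6);
under the default simulation the trimmed fit recovers the generating
constants to within a few percent where the untrimmed fit is biased
several-fold by differential genes. Negative estimates are clipped at 0
with a warning.

The 95% interval of criterion 1 is the normal approximation
μ ± z√σ₀² with z = 1.96 — the only construction available from μ and σ₀²
alone. Criterion 2 uses strict σ² > σ₀².

## Cell typing

PCA gene scores are the maximum absolute loading over the leading
components that explain 85% of variance (centred, full SVD); scores are
rounded to 12 decimals before rank/tie-break by gene id so cell order
cannot perturb the ranking. Clustering is agglomerative with distance
1 − Pearson and average linkage, cut by `maxclust`; cells are processed in
lexicographic id order for determinism. Panel scores z-score cluster-mean
expression across clusters and average over panel genes; exact ties give
"unassigned". Because z-scores measure contrast, a population containing
only hepatoblasts is detected by absolute panel expression instead (mean
log2 of hepatoblast panel genes > 1 in both first-pass clusters means
there is no second population and the second pass is skipped). Clusters in
the second pass that share a top-scoring panel are merged — this is what
operationally reproduces the merge of two macrophage sub-clusters into one
group. Erythrocyte-associated genes that are not themselves panel members
(Hba-a2, Hbb-bs, Alas2, Slc4a1 by default) can be excluded from the PCA
ranking, since non-erythroid fetal cells express hemoglobins at low level.

GO-style over-representation uses the hypergeometric upper tail with
Bonferroni correction over the tested terms; gene sets load from GMT.

## Trajectory

Stage ANOVA runs on hepatoblasts over genes detected in ≥ 3 cells; the
pipeline feeds it the QC'd matrix (not the noise-filtered gene subset) so
stage-dynamic genes of moderate abundance remain visible — the noise
filter's job is to clean the clustering, the trajectory has its own
eligibility rule. Trends use Spearman ρ of stage means vs stage ordinal
with |ρ| ≥ 0.8; stage ordinals are equally spaced by default (gestational
-day spacing is an option). Nearest-stage assignment correlates each query
cell with each stage centroid over the top-k genes on the log scale;
zero-variance queries are unassigned (variance compared against a 1e-12
floor — exact-constant vectors in floating point land at ~1e-16).

## TF networks

The DE screen is a two-sided Wilcoxon rank-sum at raw p < 0.01 — no
multiple-testing correction, matching a stated raw threshold; TFs constant
and identical in both groups are skipped. Edges require signed r > 0.35
strictly; the ≥ 3-partner node rule is evaluated once on the full
thresholded graph, so degrees within the final induced subgraph can drop
below 3 — the construction is deliberately non-iterative. Correlations are
computed within each group's cells separately when building group-specific
networks. Layout is force-directed (Fruchterman–Reingold) with a fixed
seed; it affects only exported coordinates.

## Marker assessment

Specificity here is positive-pool purity (precision), not the true-negative
rate: the operational question is what fraction of FACS-gated cells would
be the target type. The TNR is emitted as an extra column to avoid
confusion. Positivity is FPKM > 1 strictly; prediction requires both
scores > 0.5 (strict) at every required stage by default, with a
`min_stages` relaxation, and membership of a user-supplied membrane list
(a small demo list ships with the package).

## Problem sizes and determinism

The bundled demo is 2000 genes + 92 spike-ins × 400 cells over five
stages plus 52 sorted cells — a desk-scale design that exercises every
code path in seconds while keeping clustering unambiguous at the
configured effect sizes. The noise-recovery setting uses 2000 neutral
genes × 200 cells of a single type. All randomness flows from one integer
seed through per-operation derived streams; identical configuration and
seed reproduce every matrix and output byte-for-byte.

## Known limitations

- The gamma-compound noise family is a stand-in, not an inference about
  real fetal-liver data; only its mean–CV² law is matched to the model.
- The μ_th rule and the trimmed GLM assume strongly differential genes are
  a minority above the floor; transcriptomes dominated by signal (small
  targeted panels) will push μ_th high and starve the regression.
- The two-pass decomposition fixes the second-pass cluster count at six;
  it names what it finds from the supplied panels and cannot discover a
  type without a panel.
- Stage assignment is correlation to stage centroids — it orders cells by
  known stages and is not pseudotime inference.
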