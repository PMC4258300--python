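# Methods

This note documents the models, statistics, defaults and numerical choices
behind `coexmod`, and what the synthetic-data results do and do not show
about real data.

## Quality control and normalization

The QC chain runs in a fixed order: outlier-sample removal → (optional log2)
quantile normalization → probe missingness filter → probe-to-gene collapse →
cross-cohort gene intersection. No step reorders samples, and phenotype
alignment is maintained by sample id throughout.

**Inter-array correlation (IAC).** For each sample, the mean of its pairwise
Pearson correlations with all other samples of the same phenotype stratum
(tumors and controls are assessed separately, since the two classes differ
systematically), pairwise-complete over non-missing genes. Outlier arrays
are removed iteratively: in each round every sample whose stratum mean-IAC
z-score falls below −2 is dropped, IAC is recomputed, and the loop stops at a
fixed point; a stratum is never reduced below three samples. Because
empirical mean-IAC distributions are left-skewed, this rule removes the
natural low tail along with genuine artifacts — typically a further 5–12% of
arrays beyond the injected outliers in the synthetic design. That is the
documented behavior of iterative z-score peeling, not a defect; users who
want a purely conservative screen can raise `iac_z`.

**Quantile normalization.** The classical sorted-mean algorithm: each
sample's sorted values are mapped onto the across-sample mean of sorted
vectors. With missing data, each sample's empirical quantile function is
interpolated onto a common grid (the largest observed count), the reference
is the mean curve, and missing entries stay missing; ties receive the mean of
their targets. With equal per-sample counts this is exact and idempotent to
machine precision; the implementation is cross-checked against
`limma::normalizeQuantiles(ties = TRUE)` in the test suite.

**Probe handling.** Probes missing in strictly more than 30% of samples are
removed (a probe at exactly 30% is kept — the rule is "more than"). When a
probe-to-gene map is supplied, each gene keeps its single highest-mean probe
(ties break to the lexicographically smallest probe id); per-sample maxima
would mix probes within one gene row and are deliberately not used.

## Per-term networks

Networks are **unsigned**: `a_ij = |r_ij|^β` with unit diagonal. Pearson
correlation is pairwise-complete; a zero-variance gene gets missing
correlations, which become zero adjacency (with a warning) so term matrices
keep stable dimensions. The default power is **β = 6**, the long-standing
unsigned convention. Automatic selection (`auto_power`) is available: for
each candidate power 1–20, connectivities `k_i` are binned into ≤ 10
equal-count bins of log10 k, the empirical density of k per bin (count
normalized by total and by the bin's log10-width — with equal-count bins a
raw frequency would be constant by construction) is regressed on the bin mean
of log10 k, and the smallest power whose signed R² (negated when the slope is
positive) reaches 0.80 is chosen, falling back to the argmax with a warning.
Auto-selection is off by default because the scale-free criterion is noisy on
50–100-gene sub-networks; the fixed default keeps per-term networks
comparable.

TOM is computed vectorized (`L = A·A` with a zeroed diagonal) and is verified
against an O(n³) triple-loop oracle to 1e-10; entries are clipped to [0, 1]
and symmetrized against floating-point drift.

## Module detection

Average-linkage hierarchical clustering on `1 − TOM`, followed by a
**deterministic static-cut scan**: candidate cut heights run from 0.99 × the
maximum merge height downward on a 0.01 grid, and the retained cut maximizes
the number of clusters with ≥ `min_module_size` (10) genes, ties resolving to
the highest cut. The 1% margin below the root matters: TOM on soft-thresholded
noise is compressed so tightly toward dissimilarity 1 that background genes
only merge above the margin and remain unassigned ("grey"), while genuine
modules merge far lower. The scan is fully deterministic — there is no
randomness anywhere on the TOM → dendrogram → cut path.

Eigengenes are first principal components of gene-standardized module
submatrices (rows imputed to the gene mean, centered, unit variance), unit
norm over samples, sign-fixed so the correlation with the module's mean
standardized profile is non-negative — negating every input leaves the
reported eigengene orientation unchanged. Module order of operations is
detect → merge (eigengene dissimilarity `1 − cor`, average linkage, strict
cut at 0.25) → prune (kME ≤ 0.3 to grey, **single pass**: eigengene and kME
are recomputed once after pruning and survivors are not re-checked). A module
left with fewer than two genes has no defined eigengene and is deleted.
Labels are size-ranked integers with the conventional color aliases
(turquoise, blue, brown, ...); 0/grey is unassigned.

The K-means baseline clusters standardized gene profiles (Euclidean, 10
restarts, fixed seed) with k set to the network-based module count, and
applies the same minimum-size rule.

## Preservation: permutation Z_summary

For gene set G defined in the reference (training) cohort and evaluated in
the test cohort:

* **Density** — `meanCor` (mean off-diagonal test correlation), `meanAdj`
  (mean off-diagonal `|r|^β`), `propVarExplained` and `meanKME`. The latter
  two use the *reference-defined* eigengene re-projected into the test
  samples: the reference PC1 gene-loading vector is applied to the
  standardized test rows, and kME is each gene's correlation with that
  profile; `propVarExplained` is the mean squared kME (the variance fraction
  the reference component explains of the standardized test profiles).
* **Connectivity** — `cor_kIM` (intramodular connectivity per cohort,
  correlated across genes), `cor_cor` (vectorized off-diagonal correlation
  matrices, correlated across pairs), and `cor_kME`, where each cohort's kME
  is taken against that cohort's **own** eigengene. This last choice is
  deliberate: re-projecting reference loadings into the test data correlates
  every gene with its own contribution to the component, which drives the
  statistic toward 1 even for random gene sets and can push a genuinely
  preserved module *below* its null. Own-cohort eigengenes remove that
  self-projection bias; the null then centers at zero.

The null draws `n_perm` (default 200; 200 bounds the Monte-Carlo sd of a Z at
roughly 5%) random gene sets of equal size from the test cohort's gene
universe and recomputes all seven statistics. `Z = (obs − mean)/sd` per
statistic; a statistic whose null sd is degenerate (< 1e-12) is dropped from
its group median with a warning. `Z_summary` is the mean of the two group
medians; if an entire group is degenerate (e.g. the two cohorts are the same
matrix, making every cross-cohort correlation exactly 1 in every
permutation), the composite falls back to the remaining group. Permutation
draws can be retained (`keep_null=True`) for audit. Interpretation bands are
< 2 / 2–10 / > 10 with strict inequalities, and all selection gates
(`Z_summary > 5` for terms and for modules) are strict.

Null calibration is tested: for random gene sets each per-statistic Z has
mean within ±0.3 and sd within [0.7, 1.4] over 100 draws, and |Z_summary| < 2
in ≥ 90% of seeds. Scale invariance (all statistics are correlation-based)
and monotonicity in the planted loading are asserted as properties.

## Trait association, enrichment, candidates

Module–trait association is the Pearson correlation between the eigengene and
the 0/1 phenotype with the two-sided t-test p (df = n − 2); BH-FDR is taken
jointly across **all detected modules in one batch** (the family definition
is recorded in the manifest). The two-step gate — trait FDR < 0.05 in
training, then module Z_summary > 5 against testing — precedes any
enrichment.

Evidence enrichment is the hypergeometric upper tail `P(X ≥ k)` conditioned
on the **measured-gene universe** (the post-QC, intersected expression
matrix, not the whole genome), with one joint BH-FDR batch over all
(module × category) tests. A candidate needs FDR < 0.05 in ≥ 2 distinct
categories (cis- and trans-eQTL count separately); a stricter
`eqtl_plus_other` rule (at least one eQTL category plus at least one of
SCNA/mutation/prognostic) is available. Candidate pairs whose two-sided
Fisher exact overlap p survives Bonferroni at α = 0.01 are merged as graph
components (order-independent), gene sets are unioned, and enrichment is
recomputed on the unions. Regulator (TF/miRNA target-set) enrichment uses
FDR < 0.01 within each regulator collection per module, discards overlaps
< 2 genes before the FDR, and reports the top 5 with deterministic
tie-breaking (FDR, then p, then name). Raw p and FDR are both reported
everywhere.

## The synthetic two-cohort generator

Each planted module m has a latent factor `f_ms ~ N(case_shift · y_s, 1)`
per sample (y = 0/1 phenotype) and per-gene loadings drawn uniformly from
`[0.55 · loading, loading]`; gene g in m reads
`x_gs = μ_g + loading_g · f_ms + ε_gs` with `ε ~ N(0, noise_sd²)` and
baseline intercepts `μ_g ~ N(8, 1.5²)` shared by both cohorts. Defaults: 3000
genes, training 82 cases/40 controls, testing 60 cases/19 controls, ten
GO-like terms of 60–100 genes each hosting one module (sizes 20–32, loading
0.9, case shift 1.2), six preserved and four not, noise sd 0.5, 1% missing
completely at random, two outlier arrays per cohort.

Rationale for the non-obvious choices:

* **Baselines** make inter-array correlations realistically high (~0.85) so
  IAC-based QC has something to detect; they cancel out of every gene-gene
  correlation.
* **Heterogeneous loadings** give modules hub structure — variable kME and
  intramodular connectivity — without which the connectivity-preservation
  correlations have no dynamic range (real modules are ranked by kME for
  exactly this reason).
* **Universe size 3000** keeps planted module genes at ~8% of the universe;
  much denser designs contaminate the random-set permutation null with
  genuinely co-expressed genes.
* **Non-preserved modules** are displaced in the testing cohort by swapping
  their rows with genes outside every term: the named genes become noise
  there (permuting labels only within the module would leave them
  co-expressed and the module preserved), and the swap partners live outside
  all terms so no other term gains test-only structure. The per-cohort truth
  map records where the signal actually sits.
* **Outlier arrays** receive independent per-gene additive shifts of sd
  `4 · noise_sd`. A constant shift applied to all genes is invisible to
  correlation-based QC; the gene-wise shift is the additive artifact IAC can
  actually see.
* **Evidence and regulator sets** draw their designed fractions from the
  wired modules and their background only from non-module genes, so designed
  candidates are the only enriched modules by construction.

What the generator does **not** emulate: probe-level raw intensities, batch
or platform effects, correlated (informative) missingness, overlapping or
nested modules, negative loadings (anti-correlated module halves), and
non-Gaussian noise. Passing tests therefore demonstrate correctness of the
machinery and calibration of the statistics under a clean factor model — not
robustness to platform artifacts, which on real data is the role of the QC
stage and of the replication cohort itself.

## Pipeline, seeds, problem sizes

Every stage seed derives from the master seed by stable hashing of
`(master, stage, name)`, so results are independent of term iteration order
and below 2³¹. The manifest records the resolved configuration, per-stage
counts (the funnel is asserted monotone), removed samples, chosen powers,
FDR family definitions and all warnings. The expensive stage (term screen)
caches its table under `out_dir/cache` keyed by a content hash of the
matrices, the term collection and the screen parameters; other stages
recompute.

Default problem sizes (3000 genes, ~200 samples, 10 terms, 200 permutations)
were chosen so a full end-to-end run takes a few seconds on one CPU; the test
suite's 20-seed replication studies run in about 90 seconds total. Tolerances
used in tests: TOM vs oracle 1e-10, eigengene vs explicit eigendecomposition
1e-8, trait p vs numerically integrated t tail 1e-8, quantile-normalization
idempotency 1e-12.

## Known limitations

* The static-cut scan reproduces the observable contract of dynamic
  tree-cutting (minimum size, dissimilarity input, determinism) but not its
  adaptive per-branch behavior; very close module pairs may merge one cut
  earlier than an adaptive cutter would.
* kME pruning is single-pass by design; a pruned module's recomputed
  eigengene may leave a few members marginally at or below the cut.
* Preservation compares exactly two cohorts; composite ranks across many
  cohorts are out of scope.
* β is estimated (or fixed) once per term and never re-estimated after
  merging or pruning.
* Gene identifiers are matched as exact strings; symbol mapping across
  platforms is upstream of this package.
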