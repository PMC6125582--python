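# Methods

`coexmod` implements a module-level association analysis for bulk
RNA-Seq: instead of testing thousands of genes one at a time against a
quantitative trait, genes are first clustered into co-expression
modules, each sample is reduced to one enrichment score per module, and
the handful of module scores is tested under false-discovery-rate
control. This note records the model, the parameters that matter, the
numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Preprocessing

Raw gene-level counts (genes x samples) pass five stages, each recorded
in a provenance log so that the arithmetic
`genes in − low-count removals − high-COV removals = genes out` can be
audited for any run.

**Low-count filter.** A gene is kept when at least `min_samples`
(default 15) samples show at least `t_j` reads, where `t_j` rises
linearly with sample `j`'s library-size rank from 2 reads (smallest
library) to 7 (largest), rounded to the nearest integer. Tying the read
threshold to the library size means a fixed number of reads is not
treated as equally informative in a shallow and a deep library. Because
thresholds depend only on ranks, the filter is idempotent for fixed
library sizes.

**Normalization.** log2 counts per million with a prior count of 0.5:
`log2((c + 0.5) / (L + 1) * 1e6)`. No GC-content or gene-length
adjustment is attempted: the pipeline is deliberately annotation-free,
and every downstream stage consumes any normalized matrix. TMM scaling
factors are computed as a diagnostic only (samples that would need
extreme scaling are usually the geometric outliers) and never applied;
logCPM always uses raw library sizes.

**Angle-based outlier removal.** For sample `p`, the angle-based
outlier factor is the variance over all unordered pairs `(x, y)` of
other samples of `<p−x, p−y> / (‖p−x‖² ‖p−y‖²)`. A point inside the
cloud sees other points under widely varying angles; a far-outside
point sees everything in nearly one direction and gets a small factor.
All O(n³) pairs are used (n ≈ 160 makes the full computation trivial;
no k-nearest-neighbour approximation). Genes are z-scored first and the
matrix is scaled so the mean pairwise squared distance is 1, making the
factor dimensionless: the raw quantity decays like the inverse fourth
power of typical inter-sample distances, which grow with gene count.
The removal cutoff is `min(0.001, 0.1 × median factor)`. The absolute
part (0.001) flags "distinctly small" factors on structured data; the
relative guard exists because the factor's overall scale also tracks
the data's *effective* dimension — a cohort of mostly independent genes
sits entirely below any fixed absolute cutoff without containing a
single geometric outlier, and an absolute rule alone would discard
every sample. On simulated cohorts planted outliers sit at or below
0.06 × median while inliers stay above 0.27 × median at every scale we
tested, so the combined rule separates cleanly.

**Batch correction.** Per gene, expression is regressed by OLS on an
intercept, any kept covariates, and sum-to-zero batch contrasts; only
the fitted batch component is subtracted. The component is mean-centred
before subtraction so the per-gene grand mean is preserved exactly even
when batches are unbalanced (batch correction is defined only up to a
constant, so this is a free normalization). Exact confounding between
batch and a kept covariate raises a singular-design error naming the
columns.

**Coefficient-of-variation filter.** COV = sample standard deviation /
mean per gene, computed on the *unlogged* CPM scale (log-scale means
can sit near zero and make the ratio unstable); genes with COV > 0.8
are removed as dominated by technical variability, zero-mean genes are
removed with an explicit reason rather than crashing. The chosen order
is filter → normalize → outliers → batch → COV.

## Network construction and module detection

**Adjacency.** Unsigned weighted adjacency `a_ij = |pearson r|` between
gene expression profiles, zero diagonal. A hard threshold τ zeroes
entries below τ; surviving entries keep their weights by default (a
`binarize` flag yields the unweighted variant).

**Topological overlap.** For `i ≠ j`,

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),

with `l_ij = Σ_u a_iu a_uj` and connectivity `k_i = Σ_u a_iu`; the
clustering dissimilarity is `1 − TOM`. For any valid adjacency (entries
in [0,1], zero diagonal) the denominator is ≥ 1 because `k_i ≥ a_ij`; a
defensive guard still maps a non-positive denominator to maximal
dissimilarity with a warning.

**Clustering and dynamic tree cut.** Average-linkage (UPGMA)
agglomeration on the TOM dissimilarity, then a shape-based top-down
cut. Descending from the root, a branch is split into its children
when either

* its merge height exceeds the static cut height
  (`cut_height_quantile` × the maximum merge height, default 0.99 — the
  usual static-cut convention), or
* its *relative depth* `(h − median internal merge height) / h` exceeds
  `split_gap` (default 0.15).

The relative-depth rule is the shape criterion: two separated
sub-clusters, or stray genes chained onto a branch near its top, leave
the branch's merge height standing proud of the bulk of its internal
merges, while a tight homogeneous branch has its median internal height
hugging its own. The median (rather than the mean or the childrens'
heights) is the load-bearing choice: a handful of high chain merges
corrupts the maximum and shifts the mean, but not the median. Branches
smaller than `min_module_size` (default 30, below the smallest module
we expect to report) are folded into the nearest accepted branch by
average inter-branch dissimilarity — but only if joining at that height
would not itself trigger the split rule against the branch's top
internal merge — otherwise they are labeled 0 (unassigned). Labels are
renumbered by decreasing size. No expression-space reassignment (PAM)
stage is used.

**Threshold tuning.** The chain threshold → TOM → linkage → cut is run
over a τ grid, and the τ whose mean nonzero-module size is closest to
`target_mean_size` (default 200, a typical gene-set size for enrichment
testing) is kept, ties toward the smaller τ; a per-τ report (module
count, size mean/min/max, unassigned count) is retained. Soft-threshold
power selection by scale-free fit is intentionally not offered.

## Module scores (ssGSEA)

For one sample and one module, genes are ranked by expression
descending (ties broken by gene id for reproducibility). With
rank-from-bottom weights `r_i` raised to `alpha` (default 0.25, the
conventional exponent), the enrichment score is

    ES = Σ_i [ P_in(i) − P_out(i) ],
    P_in(i)  = Σ_{j≤i, g_j∈S} r_j^α / Σ_{g∈S} r_g^α,
    P_out(i) = |{j≤i : g_j∉S}| / (N − |S|).

The score is a pure function of within-sample ranks, so it transfers to
an external cohort without carrying anything over from discovery — the
property the replication stage relies on. Raw scores are divided by the
global (max − min) of the score matrix ("range-normalized"), computed
per transformed cohort for the same reason. Per-sample z-scoring was
rejected because it would tie external scores to discovery statistics.
Note that for `alpha > 0` the weighted in-set ECDF rises slightly
faster than the unweighted out-set ECDF in expectation, so the null ES
has a small positive offset; it is constant across samples and is
absorbed by the normalization and the regression intercept.

## Trait association

The severity trait is z-scored (sample SD). Per module, OLS of the
scaled trait on that module's score plus covariates (sex and smoking as
binary indicators, batch as indicator contrasts, age and BMI numeric;
listwise deletion for missing values). The per-module slope p-values
are Benjamini–Hochberg adjusted within the module family only;
`adj_(k) = min_{j≥k} min(1, p_(j)·m/j)`. A smoking-augmented model is
fit as a sensitivity analysis and compared to the base model by BIC
(−2 logL + k ln n, summed over the per-module fits on a common sample
set; smaller wins, ties keep the base model), and any sample subset
(e.g. a single self-reported ancestry) can be re-fit through the same
code path.

## Centrality and gene importance

Eigenvector centrality of the tuned, thresholded weighted adjacency:
the non-negative principal eigenvector, computed by power iteration
(relative tolerance 1e-10, at most 10⁴ iterations) on the largest
connected component with zeros elsewhere, normalized to unit Euclidean
norm. A diagonal shift by the maximum row sum is applied inside the
iteration — it leaves the principal eigenvector unchanged but prevents
the oscillation a bipartite spectrum (±λ) would otherwise cause.
Univariate gene importance is `s = −ln(BH-adjusted p)` from per-gene
logistic regressions of diagnosis on expression (Wald test; perfect
separation falls back to a likelihood-ratio test against the
intercept-only model and is flagged). Per module, the R² of `s` on
centrality summarizes whether hub genes carry more diagnostic signal,
and a hypergeometric upper tail `P(X ≥ x)` tests over-representation of
each module among the top-k (default 100) most significant genes.

## Replication

Discovered module gene sets are intersected with the external cohort's
post-filter gene universe (modules falling below 10 genes are flagged
and excluded); ssGSEA scores are computed within the external universe;
and diagnosis is regressed logistically on each module score with sex,
age and BMI as covariates (no batch — not assumed available externally;
no multiplicity adjustment across the small replication family).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
via a Gaussian latent-factor copula over negative-binomial counts:

* Each planted module `m` has a per-sample factor `f_m ~ N(0,1)`; a
  member gene's log-scale signal is `√ρ·f_m + √(1−ρ)·ε`, giving
  within-module latent correlation ρ with a single knob. Per-gene
  biological log-SDs are drawn from (0.35, 0.6) — large enough that
  within-module logCPM correlation survives count noise at ≈ 0.7ρ,
  small enough that a typical gene's CPM COV stays under the 0.8
  filter.
* Counts are gamma–Poisson with variance `μ + φμ²` (φ default 0.1);
  baseline abundances are log-normal around 30 CPM; library sizes are
  log-normal with CV 0.3 around 3·10⁶ reads so the rank-dependent
  low-count rule is actually exercised.
* The trait (a MADRS-like 0-to-60 integer score) is
  `12 + effect·Σ(trait-module factors) + covariate terms + N(0,6)`,
  truncated at 0 and rounded; diagnosis thresholds the same liability
  at its median, so trait and diagnosis are correlated as in a
  case–control cohort (simulated group means ≈ 21 vs ≈ 5).
* Nuisance structure: per-batch per-gene log-offsets (SD 0.1), a
  fraction of background genes at ~0.05 CPM (fails the low-count rule),
  a fraction with inflated per-sample noise (fails the COV rule), and
  `n_outliers` samples shifted by `outlier_shift` gene-SDs in half of
  all genes (geometric outliers for the angle-based detector).
  Low-count and high-COV genes are drawn from the background so the
  planted modules stay intact — the fractions describe nuisance genes,
  not degraded modules.
* One master seed; all sub-streams derive from a numpy `SeedSequence`,
  so cohorts are reproducible byte for byte.

Defaults (160 samples, 6000 genes, five modules of 100–200 genes,
ρ = 0.6, two trait-coupled modules with effect 6 trait points per
factor SD, 25% low-count genes, 8% high-COV genes, two outliers) are
the study conditions for the end-to-end checks; smaller gene universes
(600–1000 genes with the same module sizes and sample counts) are used
where a test repeats the pipeline over many seeds, chosen so the
quantities under test (correlation structure, ABOF separation,
module-size geometry per module) are unchanged while the gene-count
dimension, which enters only through background noise, is reduced.
The association calibration and power suites score the *planted* truth
modules (simulate → logCPM → ssGSEA → regression over 200 + 50 seeds)
rather than re-running network discovery per seed; module recovery is
itself verified separately (ARI ≈ 1.0 over seeds), so the factorization
tests each claim where it lives.

What the synthetic data does **not** emulate: GC-content and
gene-length biases (and hence any normalization that corrects them),
antisense/NAT read structure, cell-type composition shifts,
heavy-tailed library-size failures, or correlated module-module
structure beyond the shared trait coupling. Passing tests therefore
show the pipeline recovers the structure it assumes, at realistic
noise; they do not certify performance under biases the generator does
not contain.

## Numerical choices and degenerate inputs

* Correlations on fewer than 3 samples, zero-variance genes, empty or
  universe-sized gene sets, zero-variance traits, singular designs,
  empty subsets, graphs without edges, and non-2×2 tables for the
  Yates test all raise errors naming the offending object.
* ssGSEA ties break by gene id (stable sort); BH uses the stable sort
  order; tuning ties break toward the smaller τ; module labels are
  deterministic (decreasing size, then first gene position).
* The Yates-corrected χ² uses the `n(|ad−bc| − n/2)²/…` closed form
  clamped at zero; both corrected and uncorrected statistics are
  reported for 2×2 tables since published tables rarely state which
  was used.
* Adjusted p-values are floored at 1e-300 before `−ln` so importance
  stays finite.

## Known limitations

* The hard-threshold + TOM chain is O(g³) in gene count per grid point;
  ~6000 genes is comfortable, whole-transcriptome (20k+) would need
  blocking.
* The dynamic tree cut is the dendrogram-shape variant; it has no
  expression-space reassignment stage, so genes whose branch membership
  is ambiguous stay unassigned (label 0) rather than being rescued.
* With strongly coupled trait modules, ssGSEA scores of *other* modules
  acquire a small negative correlation with the trait (ranks are
  zero-sum within a sample); the FDR control under the global null is
  unaffected, but effect sizes of null modules are not exactly zero in
  coupled cohorts.
* Replication power depends on the overlap fraction of module genes in
  the external universe; degrading overlap measurably lowers power
  (tested), and modules reduced below 10 genes are not tested at all.
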