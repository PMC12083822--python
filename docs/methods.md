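# Methods

This note documents the models, statistics and numerical choices behind
`epidrugscreen`, and what the synthetic-data generators do and do not
emulate.

## The analysis chain

The package implements the analysis path of a chromatin-drug screen on
patient-derived tumor-sphere panels:

1. **Primary screen** (many compounds, few lines, two timepoints) →
   delta-AUC statistic → compound ranking → drug-class rank aggregation →
   top-class / best-in-class selection.
2. **Follow-up panel** (selected compounds, more lines, one timepoint,
   four doses) → 4PL IC-50 per (compound, line).
3. **Expression response** (one control + one treated RNA-seq sample per
   compound per line) → normalization → per-condition log2 fold changes →
   ≥2-fold up/down gene sets → overlap consistency analysis and regulator
   classification → target-count vs potency correlation.
4. **Baseline stratification** (untreated samples) → PCA + k-means(2) →
   per-drug cluster IC-50 comparison → cluster differential expression.
5. **Co-expression structure** (all samples) → soft-thresholded unsigned
   network → TOM → average-linkage modules (min size 30) → hub
   neighborhoods → module–drug effect scores.
6. **Chromatin accessibility** (scored peak sets per condition) → peak
   matching → global lost/gained counts → gene-linked score changes for a
   module gene set.

## Screening statistic: delta AUC

For one compound on one line, viability (fraction of vehicle control) is
measured at several doses at an early and a late timepoint. The **AUC** of
a timepoint is the *normalized* trapezoid of viability over log10 dose:
the trapezoid integral divided by the log10-dose span. A single-dose
timepoint degenerates to the viability itself. This definition was chosen
because the two timepoints may carry different dose sets (here two doses
early, one dose late): a raw dose integral would not be comparable across
timepoints, whereas the normalized trapezoid is a mean viability on a
common 0–1 scale. It is also invariant to uniform dose rescaling.

**delta AUC = AUC(early) − AUC(late).** A compound whose effect compounds
over prolonged exposure — the expected kinetics of epigenetic
reprogramming — scores positive; acute toxicity that the culture outgrows
scores negative; an inert compound scores zero.

Compounds are ranked by mean delta AUC across lines (rank 1 = best, ties
averaged). A drug class is summarized by the arithmetic mean of its
members' global ranks; classes are compared to a reference class — by
default the class with the *worst* average rank — with a Welch two-sample
t-test on member ranks. Testing ranks rather than raw delta AUCs makes
the comparison a Wilcoxon-type location test on the rank scale; a flag
(`on="delta"`) switches to raw values. Ranks are computed once on
line-averaged delta AUCs (not per line and then averaged); the class
table records the reference class and flags single-member classes whose
p-value is undefined.

The volcano statistic per compound is the mean per-line delta AUC (x)
against a Welch t-test between all pooled early and all pooled late
viability observations (y). Wherever a t-test is unspecified beyond
"t-test", the Welch (unequal-variance) form is used — it is never worse
than the pooled form and costs nothing. Two pooled groups that are both
exactly constant are degenerate: p = 1 by convention, with a flag.

## Dose–response: 4PL IC-50

Viability is modeled as the four-parameter logistic

    V(d) = bottom + (top − bottom) / (1 + (d / IC50)^hill),

fit by least squares on log10 dose with bounds 0 ≤ bottom ≤ top ≤ 1.5
(parameterized as `top, bottom/top` so the ordering is structural) and
hill ∈ [0.01, 20]. The fit multi-starts the IC-50 at every observed dose
and keeps the best residual sum of squares. Optimizer tolerances are
`ftol = xtol = 1e-6`: residuals are of assay-noise magnitude and the
(hill, log IC-50) valley is flat near the optimum, so machine-precision
termination criteria would report spurious non-convergence. Flat curves
(all-equal viabilities) are flagged, with hill undefined and the IC-50
reported at the maximum tested dose; `ic50_in_range` flags IC-50s outside
the tested dose range, which should be treated as censored. A helper
inverts the fitted curve at a target viability (e.g. 0.65) for choosing
sub-toxic working doses.

On noisy single-replicate 4-dose curves (noise sd 0.05) the median
absolute log10 IC-50 error is ≈ 0.15–0.17 (recomputed by
`scripts/acceptance.py`), i.e. recovery well within 2-fold.

## Expression

**Normalization.** Counts are library-size normalized and log2
transformed. The default is median-of-ratios (size factor = median over
all-nonzero genes of count / geometric mean) with a pseudocount of 1;
log2 CPM is the alternative. A regularized-log shrinkage transform is
deliberately not reimplemented: median-of-ratios captures the library-size
principle with a fully specified, dependency-free formula. All-zero gene
rows are retained.

**Fold changes and gene sets.** log2FC = norm(treated) − norm(control),
within line. The ≥ *t*-fold rule (default t = 2) is applied on this scale
with inclusive boundaries; up and down sets are disjoint by construction
for t > 1.

**Overlap analysis.** A gene is *consistent* for a compound if it moves in
the same direction in ≥ ceil(f·n_lines) lines; the default f = 0.75
quantifies "the vast majority of lines" and is configurable, since no
exact cutoff is canonical. A gene is *universal* ("stress response") for a
line if essentially every compound moves it there (default f = 1.0).
*Exclusive* genes occur in exactly one (line, compound) cell — the
dominant pattern in heterogeneous panels. Intersection regions follow
exclusive (UpSet) semantics, so region sizes partition the union.
Compounds are classified up-/down-regulators by a 2-fold ratio of the
medians (across lines) of their up- and down-set sizes; median rather than
mean keeps one extreme line from flipping the call.

**Baseline clusters.** Untreated samples only: the 2000 most variable
genes are centered, projected to 2 PCs, and k-means (k = 2, 10 restarts,
fixed seed) labels the lines. A deterministic rule replaces reading the
clusters off a PCA plot by eye. Cluster 1 is the larger cluster (tie: the
one containing the lexicographically first line). Cluster association
uses a per-drug Welch t-test on log10 IC-50; cluster DE uses a per-gene
Welch test on normalized control expression, with zero within-cluster
variances floored at the smallest nonzero gene variance (flagged), BH
FDR, and the ranking statistic |mean difference| × −log10 p. The ranking
statistic is a documented choice — "most differentially expressed" has no
unique definition — and is monotone in both effect size and significance.

## Co-expression modules (WGCNA-style, self-contained)

Unsigned adjacency a_ij = |cor(i,j)|^β across *all* samples; β is the
smallest tested power whose connectivity distribution is approximately
scale-free (R² ≥ 0.8 of log-frequency on log-connectivity over 10 bins).
If no power reaches the cut the best R² among powers with mean
connectivity ≥ 1 is used, flagged: strongly modular data (including the
planted-module benchmark) is *not* scale-free, and the fallback avoids
degenerate high powers that disconnect the network. Benchmarks on planted
modules therefore fix β = 6, the conventional unsigned default.

The topological overlap matrix is the standard unsigned form

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

with unit diagonal, checked against a triple-loop oracle to 1e-10.
Modules come from average-linkage hierarchical clustering on 1 − TOM with
a deterministic height scan (0.05…0.99, step 0.01): the cut maximizing the
number of clusters of at least the minimum size (30) wins; among ties the
cut assigning *more genes* to valid clusters is preferred, then the lower
height. The gene-count tie-break matters: a purely lower-height rule can
shatter a large module into fragments that each clear the size bar. This
deterministic scan is a documented replacement for dynamic tree cutting;
module eigengenes are not computed. Clusters below the minimum size map to
module 0 (unassigned); modules are numbered by decreasing size.

Hub neighborhoods are the k genes (default 20) most correlated with a hub
across all samples, with spoke length 1 − |r|. The module–drug effect is
the plain mean log2FC of the module genes under each drug across all
lines.

## ATAC peak comparison

Peaks are scored 0-based half-open intervals. Peak identity across
conditions uses greedy one-to-one matching on reciprocal overlap (the
shared span must cover ≥ 50% of *both* intervals, an ENCODE-style
convention): candidate pairs rank by reciprocal overlap, then overlap
length, then coordinates, with a ranking key symmetric in the two
conditions — swapping control and treated provably swaps lost and gained.
Unmatched control peaks are lost, unmatched treated peaks gained.

Peaks link to a gene when they overlap the ±50 kb TSS window (one peak
may serve several genes); chromosome names are normalized ("chr1" ≡ "1").
A matched peak's "significant height change" is |log2 score ratio| ≥ 1,
boundary inclusive — with no replicate structure in the inputs, a
fold-change rule is used instead of a statistical test, and the threshold
is configurable. Per-gene summaries count lost/gained linked peaks and
significant decreases/increases; both global per-condition counts and
matched lost/gained counts are reported, since either convention may be
wanted.

All interval operations are validated against O(n·m) brute-force oracles.

## Synthetic data: what is emulated

The generators plant known structure so every stage has a recovery test.

**Screen** (`ScreenTruth`): 4PL viability per (line, compound) with
compound kinetics. A *delayed* compound's IC-50 shrinks by a factor
(default 20×) at the latest timepoint — efficacy that builds with
exposure — giving positive delta AUC by construction; *acute* compounds
reverse the scaling; *inert* compounds sit at viability 1. Gaussian
viability noise (default sd 0.05, the scale of a careful MTS assay) is
truncated at 0, keeping fractions physical without materially biasing
means. The stock 106-compound screen has 36 classes: a strongly delayed
BET-like class with assay-range IC-50s (the planted winner), an inert
BRPF-like class (delta AUC 0, hence the worst class and the natural
auto-selected reference), and 34 weakly delayed classes with IC-50s well
above the tested doses. The stock 12×12 panel draws base IC-50s in
30–300 nM — inside the 10 nM–10 µM dose range so that even a planted 10×
resistance shift stays identifiable from the assay — with 10^N(0, 0.15)
per-line spread.

**Expression** (`ExpressionTruth`): negative-binomial counts via
Gamma–Poisson mixing. The `dispersion` argument is the biological
coefficient of variation of the Gamma (variance = μ + (dispersion·μ)²);
the default 0.1 means 10% extra-Poisson biological variability. Per-gene
baseline abundances are log-uniform with mean counts ≈ 100–4000 at the
default 1.5–3M library sizes, keeping shot noise below biological noise.
On the log2 mean scale each sample receives: (i) per-module latent factors
— genes in a module share a per-sample N(0,1) draw, with loadings
calibrated from the total non-factor variance so partner correlation is
`module_r` (default 0.7) in expectation, the hub carrying the largest
loading and signs alternating within the module so that the module's total
read mass is invariant to its factor (otherwise size-factor normalization
absorbs large modules' factors — a compositional artifact); (ii) cluster
markers elevated by the effect size in cluster-1 lines; (iii) planted
treatment effects of ±`effect_log2fc` (default 2, comfortably clearing
the 2-fold rule) on the consistent-down set of the one BET-like compound
(which also covers the first module — a BET inhibitor closing a
cell-cycle program), per-line stress-up sets, and per-cell line-specific
sets; and (iv) i.i.d. N(0, 0.15) log2 sample noise. One RNA-seq sample
per condition, matching the single-replicate design such screens use;
replicates are configurable upward.

**Peaks** (`PeakTruth`): every gene receives a few peaks near its TSS plus
uniform background peaks; under treatment each peak is lost independently
with a global probability, boosted near module-gene TSSs; retained scores
jitter by 2^N(0, 0.1).

What the generators do **not** emulate: batch and plate effects,
gene-length and GC bias, correlated library-size structure, per-line
baseline expression differences outside the planted markers, overlapping
gene sets between compounds, replicate structure for ATAC, and realistic
genomic peak clustering. Passing recovery tests therefore demonstrate the
*algorithms* recover planted structure under the stated noise — not that
real screens are free of the confounders above.

## Benchmark scales and reproduction

The recovery scenarios (in `epidrugscreen.benchmarks`, rerun by
`scripts/acceptance.py` and asserted in `tests/test_acceptance.py`) use:
106 compounds × 5 lines × 50 seeds for screen ranking; 200 four-dose
curves for IC-50 recovery; 12 lines × 12 compounds with 2000 genes for the
gene-set scenarios; modules of 30/60/120 genes plus 50 background genes
across 156 samples for module recovery; and 500-peak instances for the
interval oracles. These sizes mirror the study design the pipeline
addresses while keeping a full run in minutes.

## Known limitations

- The AUC definition (normalized log-dose trapezoid) is a documented
  convention, not a universal one; absolute delta-AUC values depend on it,
  though rankings are robust to monotone changes.
- IC-50s outside the tested dose range are extrapolations; they are
  flagged but not censored automatically.
- The exact-set version of the cluster–drug association (all six planted
  drugs flagged *and no others*) cannot reach high reliability with
  per-drug tests at α = 0.05: six null drugs at a ~2.5% directional
  false-positive rate give an expected exact-set rate of ≈ 0.86. The
  package reports both the recall-based and the exact-set rate.
- Module detection assumes modules are correlation-tight relative to
  background; overlapping or nested modules are out of scope, as are
  module eigengenes and dynamic tree cutting.
- The regulator classification and the "significant height change" rule
  are threshold conventions, exposed as parameters rather than inferred.
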