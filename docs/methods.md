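# Methods

This note records the models implemented in `tumorhet`, the parameter
choices that matter, and what the synthetic-data experiments do and do not
demonstrate.

## Data model

The universal input is a log2-scale expression matrix (genes × samples)
with a per-sample annotation of *case* (one tumor mass, sampled in several
spatially distinct regions/blocks) and *histotype* (histological tumor
type). The matrix is assumed normalized upstream; validation rejects
missing or non-finite entries, duplicate identifiers, unannotated samples
and cases mapped to more than one histotype, and warns when more than 1% of
entries are negative or above 30 (a hint of linear-scale input). Probe-level
matrices are collapsed to gene level by averaging the probes of each gene;
unmapped probes are dropped, because all downstream matching is on gene
identifiers (case-sensitive exact strings — alias resolution is deliberately
out of scope, as alias maps are annotation-version-dependent).

## PC-space heterogeneity

PCA treats samples as observations and genes as variables, centering each
gene and (by default) not scaling to unit variance: the data share a log2
scale, and unit-variance scaling would overweight flat genes. A
`scale_genes` flag exposes the alternative. Component signs are fixed so
each component's largest-|loading| gene loads positively, making
coordinates reproducible.

The number of retained components K can be a fixed integer, a
cumulative-variance target, or the scree-plot elbow. The elbow convention
used here: find the scree point with maximum perpendicular distance to the
straight line joining the first and last scree points, and retain the
components *strictly before* it (so a scree of [0.5, 0.3, 0.05, 0.05,
0.05, 0.05] retains 2 components). Retaining the pre-elbow components
matches the usual reading of "components before the elbow"; conventions
that retain the elbow point itself differ by one component.

Distances are euclidean on the K retained coordinates only. Per group
(histotype or case) the report carries the mean and maximum of d(i, j) over
unordered distinct pairs i < j — including zero self-distances would
deflate the means — and the mean and maximum of d(i, c) to the group's own
centroid, the componentwise mean of its members. Singleton groups report
zeros with a warning rather than NaN, keeping reports numeric. These
summaries satisfy max ≥ mean within each family and
max_pairwise ≤ 2·max_centroid (triangle inequality through the centroid).

A retention caveat the simulations make visible: with a small K, the
retained components capture only the *largest* case-separation directions.
If one histotype's cases are far more spread than the others', its
between-case distances dominate the retained space and the other
histotypes' between-case structure is partly projected away. Intra-case
distances are unaffected (within-case noise is isotropic, so its projection
onto any K directions preserves per-direction variance), which is why the
intra-case ranking is the robust heterogeneity readout.

## Single-sample gene-set scores

The z-score method standardizes each gene (mean 0, sd 1, unbiased n−1
denominator) and scores set S in sample s as Σ_{g∈S} z[g,s] / √|S|, with
|S| the number of set members matched in the matrix. Enrichment is score
strictly above zero (a score of exactly 0 is not enriched). Constant genes
get z = 0 but still count in √|S|: silently dropping them would change the
denominator between datasets. The standardization scope is `all_samples`
by default — scores are then comparable across histotypes, which the
commonly-enriched comparison requires — with `per_histotype` available to
judge each histotype against its own distribution.

The commonality rule: a set is commonly enriched in a histotype when the
enriched fraction reaches `min_fraction` (default 0.8, the "at least 16 of
19–20 samples" rule; 16/20 = 0.80 passes, 15/20 fails, 16/19 passes).
`shared_pathways` reports sets commonly enriched in ≥ 2 histotypes, sorted
by subset size then name.

ssGSEA (for signature scores such as CIN70): per sample, genes are ranked
by decreasing expression with ties broken by gene-id lexicographic order;
the gene at rank r carries rank statistic N − r + 1 and in-set weight
|N − r + 1|^α (α = 0.25); the score is the sum over rank positions of the
difference between the weighted in-set cumulative distribution and the
uniform out-of-set cumulative distribution. This is the *un-normalized*
enrichment score; normalisation variants (dividing by the score range)
change the scale but not the per-sample ordering, which a test confirms by
rank-agreement against an independent ssGSEA implementation. At α = 0 the
score depends on ranks only and is invariant under any strictly monotone
transform of a sample's expression vector.

## Druggable-target calls

Expressed = log2 value ≥ threshold. The threshold is inclusive so a value
exactly at the cut counts as expressed, and defaults to 6.0; with
`threshold="median"` it is the median over every matrix entry (computed on
the gene-level, post-collapse matrix; a probe-level median can be obtained
by thresholding before collapsing). Within a histotype each target is
classified, in order of precedence: expressed in all samples; expressed in
none; *heterogeneous within a case* if any case has mixed calls; otherwise
*heterogeneous between cases*. The within-case class takes precedence
because mixed calls inside one tumor mass are the clinically decisive
pattern. The classes partition the targets, and raising the threshold can
only remove calls (monotonicity).

## Consensus co-expression modules

A deliberately simplified consensus WGCNA:

- unsigned network, Pearson correlation: adjacency a_ij = |cor(x_i, x_j)|^β,
  β = 12 by default;
- topological overlap
  TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
  l_ij = Σ_{u≠i,j} a_iu a_uj, k_i = Σ_{u≠i} a_iu, diagonal 1;
- consensus across histotypes = elementwise minimum of per-histotype TOMs
  (the quantile-0 consensus; quantile scaling of inputs is out of scope);
- modules: average-linkage hierarchical clustering of 1 − TOM with a
  *static* cut (default height 0.995 of the maximum merge height) in place
  of the dynamic hybrid tree cut, which is an algorithm of its own;
  clusters below `min_module_size` (default 30) genes are left unassigned
  (label 0); modules are numbered by decreasing size with ties broken by
  smallest member gene id, so runs are deterministic;
- module eigengene: first principal component of the module's standardized
  expression (samples × members), unit norm, sign-oriented to correlate
  positively with the module's mean standardized profile (tie broken toward
  the lexicographically first member gene); `variance_explained` is the
  first-eigenvalue fraction;
- merging: modules are clustered on 1 − cor(ME_a, ME_b) (average linkage);
  clusters joined below `merge_cut_height` (default 0.25) merge, eigengenes
  are recomputed, and the procedure iterates to a fixed point (cap 100
  rounds).

Gene count is capped at the `max_genes` most variable genes (default 5000)
so the dense TOM stays tractable; the full blockwise machinery of
large-scale consensus WGCNA is out of scope, as is reproducing any specific
module catalogue from real data with the dynamic cut.

## Synthetic data

The generator draws
x[g,s] = baseline_mean + b[g] + h[g,H(s)] + c[g,C(s)] + Σ_m λ[g,m] f[m,s]
+ ε[g,s] + δ·1{planted}, with independent Gaussian components on the log2
scale (additive log-intensity noise is the natural model for normalized
arrays). Planted sets shift the mean, not the variance — the z-score
statistic is a location test. Module loadings are uniform on [0.5, 1.0]
and positive, so planted modules are coherent under unsigned correlation.
One seed drives a hierarchical stream (one child per variance component),
so extending a configuration does not perturb existing draws.

`default_study_config` is the study design: 4 histotypes × 5 cases × 4
samples with one NB case at 3 (79 samples), 2000 genes, baseline mean 6.0
(so the matrix-wide median lands at the default expression threshold),
baseline sd 1.0, histotype sd 1.0 > case sd 0.5 > within-case sd, the
latter ordered NB 0.9 > HB 0.5 = RMS 0.5 > WT 0.2. HB and RMS are an exact
tie ("mildly heterogeneous"), so ordering recovery is judged on the strict
relations only: NB on top, WT at the bottom, HB/RMS in between. Planted
signals: +1.0 log2 on 30-gene sets per histotype scope (one HB-specific,
one NB-specific, one shared WT+RMS), one case-scoped and one sample-scoped
set, and three weak latent modules (factor sd 0.6). The module factors are
kept weak on purpose: per-sample factor variance adds equally to every
histotype's within-case spread, and strong factors (norm comparable to the
case-separation directions) would enter the retained PC subspace and mask
the configured noise ordering. A back-of-envelope check guided the
defaults: the planted histotype set scores shift by roughly
δ(1−p)√30/sd_g ≈ 3 standardized units (p the targeted sample fraction)
against score-level noise of sd ≈ 0.9, giving near-certain on-target calls
and an expected off-target enrichment around 13%.

Two dedicated scenario factories keep the recovery experiments clean:
`set_recovery_config` (moderate background: histotype sd 0.5, case/sample
sd 0.3, 800 genes) for planted-enrichment and shared-pathway recovery, and
`module_recovery_config` (modules plus iid noise only: 3 × 40-gene modules,
factor sd 1.5, noise sd 0.5, 300 genes, 60 samples; optionally a 0.9
factor correlation between two modules) for module detection and merging.
Module recovery with loadings as low as 0.5 and noise sd 0.5 needs a
factor sd above 1: at β = 12 the adjacency of a weak-loading pair decays
like cor^12, and at factor sd 1 the weakest module genes join their cluster
above the static cut.

What the generator does *not* emulate: FFPE degradation and batch effects,
probe-level structure, copy-number-driven expression, non-Gaussian
heavy-tailed noise, and correlated planted signals. Passing recovery tests
therefore show the estimators are correct and well-calibrated under the
assumed variance structure — not that real FFPE microarray data meet those
assumptions.

## Problem sizes and numerical choices

The replicated experiments use 20 seeds each; the study design is 2000
genes × 79 samples and the module scenario 300 genes × 60 samples, sizes at
which every stage runs in milliseconds while leaving the planted effects at
realistic magnitudes. Tolerances: exact oracles (TOM brute force, pairwise
enumeration) are checked at 1e-10–1e-12; PCA against the eigendecomposition
oracle at 1e-8 (sign-matched). Degenerate inputs are contracts, not
crashes: constant matrices are rejected by PCA, constant genes get z = 0
(scoring) and zero adjacency (networks), singleton groups report zero
distances with a warning, and sets without matched genes are flagged
missing rather than scored.

## Known limitations

- The elbow selector is a heuristic; on flat scree curves it can select
  very few components. The fixed-K and variance-target selectors are the
  stable alternatives.
- The static tree cut is coarser than the dynamic hybrid cut: nested or
  partially overlapping modules that the dynamic cut separates may be
  merged or dropped here.
- The commonly-enriched rule is a fixed-fraction decision with no
  multiplicity control; it is a screening device, not a test.
- ssGSEA scores are un-normalized; compare them across sets only after a
  normalisation of your choosing.
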