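# Methods

This note documents the models, conventions and design choices behind
`skincorrect`, in the order the pipeline runs them.

## Background correction

**Model.** Each swab community is treated as a mixture of an indigenous
skin community and the ambient water community.  The correction is a
feature-selection rule on the ASV table: keep an ASV if it has zero reads
in every water sample ("unique to swab"), or if its per-sample relative
abundances are stochastically greater in swabs than in water by a
one-sided Mann–Whitney U test, Benjamini–Hochberg corrected across all
tested ASVs, at FDR threshold α.

**Choices made where the procedure is under-determined.**

* *Sidedness* — one-sided ("greater"), because the rule targets ASVs
  over-represented in swabs; a two-sided option is exposed
  (`alternative="two-sided"`).
* *α* — 0.05 by default, configurable; it is an FDR threshold on
  BH-adjusted q-values.
* *Comparison group* — all water samples are pooled into a single
  comparison group regardless of site.  A per-site pairing would
  confound the test with site effects given one water sample per site.
* *BH family* — only the tested ASVs enter the correction (m = number of
  tested features); unique-to-swab ASVs are retained by rule, not tested.
* *Mann–Whitney p-values* — exact enumeration when the two groups hold at
  most 12 observations with no ties, otherwise the normal approximation
  with tie correction (scipy's implementation in both regimes).

**Properties.** The corrected table's features are a subset of the input,
so Faith PD can only decrease per sample (subset monotonicity).  Because
the test runs on relative abundances, uniformly rescaling any library
leaves the result unchanged.  When swabs are statistically identical to
water (simulated contamination fraction ρ = 1), BH keeps the retained
fraction of tested water ASVs at or below α.

## QC filtering

Fixed order: organelle/eukaryote exclusion → feature-prevalence filter →
sample-depth filter; each step is idempotent.

* The feature rule "≥ 100 copies in ≥ 2 samples" is read *per sample*: an
  ASV is kept when its count is ≥ 100 in each of at least two samples
  (not a 100-reads-total rule).  Both thresholds are inclusive.
* Organelle matching is a case-insensitive substring test of the keywords
  (Chloroplast, Mitochondria, Eukaryota by default) against each rank
  token of the lineage, because database lineages vary in case and rank
  placement.  ASVs missing from the taxonomy are kept and reported.
* Rarefaction curves subsample without replacement (multivariate
  hypergeometric) and report mean Shannon diversity in natural log;
  the log base only rescales curves and is fixed for determinism.
  Depths above a sample's total are reported as undefined, not truncated.

## Phylogenetic diversity

Both metrics run on a branch/leaf incidence structure built once per
tree.  The root's own branch is treated as subtending every ASV — the
rooted convention of the QIIME toolchain — so:

* **Faith PD** is the total length of branches on the minimal subtree
  connecting a sample's observed ASVs to the root; the empty community
  has PD 0.
* **Unweighted UniFrac** is (branch length subtended by exactly one of
  the two presence sets) / (branch length subtended by either).
  Presence means count ≥ 1.  The implementation computes all pairs with
  one matrix product and agrees with scikit-bio's reference values to
  float precision (checked in the tests).

No rarefaction is applied before diversity computation; counts are used
as filtered.  UniFrac depends only on presence, so this matters mainly
for Faith PD interpretation at uneven depths — a known caveat, not a
correction the pipeline applies silently.

## Ordination and tests

* **PCoA** is classical metric scaling: double-centre −D²/2 and
  eigendecompose.  Negative eigenvalues are excluded from both axes and
  the explained-variance denominator (no Cailliez/Lingoes correction).
  Axis orientation is fixed deterministically by making each axis's
  largest-magnitude loading positive.  Requesting more axes than the
  positive spectrum supports truncates with a warning.
* **Biplots**: a feature's arrow is the mean of sample coordinates
  weighted by the feature's per-sample proportions normalised over
  samples; "effect size" is the arrow's Euclidean length; top-k selection
  breaks ties lexicographically by feature id.
* **PERMANOVA** uses the within/between sum-of-squared-distances
  pseudo-F and a label-permutation null with the +1 correction,
  p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), so p is never exactly 0.
  If every group is internally identical the pseudo-F is infinite; that
  is deliberate and still orders correctly against permuted values.
  Pairwise PERMANOVA applies BH across group pairs.
* **Kruskal–Wallis** (tie-corrected, χ² reference) returns H = 0, p = 1
  when all values are identical.  **Pearson R²** is the squared sample
  correlation over complete pairs; missing measurements drop the pair;
  zero variance on either side is reported as undefined (NaN) rather
  than 0.

## Linearity audit

Kernel PCA (linear or RBF) on relative-abundance rows, then ε-SVR of each
principal component on each water measurement, with in-sample
R² = 1 − SSE/SST.  The linear kernel reproduces classical PCA scores
exactly (tested to 1e−8), so the audit isolates the kernel choice.
Unstated hyperparameters are fixed and logged in every report: RBF γ by
the median heuristic (1 / median nonzero pairwise squared distance),
C = 1, ε = 0.1; R² is in-sample (descriptive, not cross-validated).

## Bayesian group means

Per group, y ~ Normal(μ, σ) with priors μ ~ Normal(ȳ, 10s) and
σ ~ HalfNormal(10s), where ȳ and s are the group's sample mean and SD.
The prior mean is data-centred by design; the prior *scale* is a choice —
10 × sample SD keeps it weakly informative so the posterior is dominated
by the likelihood.  Groups with fewer than 3 values or zero variance are
rejected with an explicit error.

Sampling is Metropolis-within-Gibbs: the μ conditional is conjugate
Normal and drawn exactly; log σ is updated by univariate slice sampling
(stepping-out and shrinkage), which requires no step-size tuning.  The
default budget keeps 2,800 draws per chain in four chains (11,200
retained draws per parameter) after 1,000 warmup iterations, and each
parameter's split R-hat must be < 1.01 or the summary is flagged
non-converged.  Runs are deterministic for a fixed seed on one platform.

The standardised difference between groups is computed per draw as
(μ₁ − μ₂) / ((s₁ + s₂)/2).  The pooled SD is the *plain average* of the
two sample SDs — the definition this workflow standardises on — and the
s's are fixed sample SDs, not posterior σ draws.  A zero pooled SD flags
the effect as undefined instead of propagating infinities.

Calibration (tests): 95% credible intervals cover a simulated true mean
95% ± 3% of the time over 200 replicates, and a true standardised
difference of 1 is recovered within [0.8, 1.2] in ≥ 90% of replicates.

## Composition analysis

* **Collapse** sums counts over features sharing a rank label and then
  normalises per sample; unassigned ranks (or ASVs missing from the
  taxonomy) pool into `Unassigned`.  Reads are conserved before
  normalisation.
* **Dysbiosis ratio**: per site, the mean relative abundance of
  Proteobacteria and of Bacteroidetes over that site's samples, and
  their ratio.  A zero Bacteroidetes mean yields an explicitly marked
  infinite ratio.  Phylum labels match case-insensitively.
* **ANCOM** adds pseudocount 1, tests every pairwise log-ratio between
  features with a two-sided Mann–Whitney U across the two groups,
  BH-adjusts within each feature's row of m − 1 p-values, counts
  rejections at level τ = 0.05 into W, and detects features with
  W ≥ 0.7 (m − 1).  These are the canonical ANCOM defaults; both τ and
  the 0.7 cut are configurable.  With the pseudocount, scaling a
  sample's counts is no longer *exactly* neutral, but detection
  decisions are stable under scaling at realistic depths (tested).

## Functional shift

Pathway abundances are counts × genome-content weights (copies of a
pathway per ASV genome), normalised per sample.  The raw-vs-corrected
comparison is a **paired** Wilcoxon signed-rank per pathway term — the
same swab sample appears in both datasets, so pairing is the natural
model; an unpaired option exists.  The exact distribution is used for
≤ 25 pairs, the normal approximation beyond.  BH runs across terms;
per-category tallies split significant terms by direction.  Terms that
are constant zero in both datasets are skipped and reported.

## Synthetic community generator

The generator emulates a stream-survey design: four streams in two
basins, five sites on a temperature gradient (16–28 °C, with
conductivity, pH and dissolved oxygen covarying plus noise), one water
sample and four fish swabs per site, two fish taxa, a ~200-ASV universe
(120 water, 40 indigenous per taxon, disjoint by default), mean read
depth 3,000 (Poisson), Dirichlet overdispersion θ = 50, contamination
fraction ρ = 0.3, and one flagged eutrophic site with Bacteroidetes
enrichment δ = 3.

Mechanics: water pools are softmax of Normal(0, 1.5) base log-abundances
shifted by β · z_site · loading_f (β = `gradient_effect`); indigenous
pools are softmax of Normal(0, 1.5) per taxon; a swab draws
k ~ Binomial(depth, ρ) reads from the site's Dirichlet-perturbed water
pool and the rest from the taxon's perturbed indigenous pool, so the
realised per-sample contamination fraction k/depth is recorded as ground
truth.  At eutrophic sites indigenous Bacteroidetes probabilities are
multiplied by δ and renormalised.  The tree is a random bifurcation with
Exponential(1) branch lengths; lineages carry explicit phylum labels.
All randomness flows from one seed.

What it does **not** emulate: sequence-level error (chimeras, denoising
artifacts), taxon-shared ASVs between water and skin (configurable but
off by default), copy-number variation, and within-site environmental
heterogeneity.  Passing tests therefore demonstrate the statistical
machinery under a known mixture model, not robustness to those real-data
complications.

## Study-scale evaluation choices

* Recovery of indigenous ASVs is scored against generator truth as
  sensitivity (retained fraction of indigenous ASVs present in swabs)
  and specificity (removed fraction of water-only ASVs present in
  swabs).  A large-sample run of the same pipeline (100 swabs, 50 water
  samples, depth 10,000) attains sensitivity 1.0 and specificity ≈ 0.99,
  establishing consistency.  At the survey scale (20 swabs + 5 water,
  depth 3,000) about 18% of water ASVs escape all five water samples and
  are retained as unique-to-swab, capping attainable specificity near
  0.8; the test thresholds (sensitivity ≥ 0.95, specificity ≥ 0.70 on
  50-replicate means) encode exactly that water-coverage limit, which is
  a property of the sampling design, not of the test statistic (no
  tested water ASV is falsely retained in these runs).
* The raw-vs-corrected gradient contrast is evaluated in a single-taxon,
  no-dysbiosis condition with ρ = 0.6 and β = 2: with two host taxa the
  host split occupies PCoA axis 1 and pushes the water gradient to
  axis 2, so the single-taxon condition is what isolates the
  axis-1-versus-gradient comparison the contrast is about.
* Permutation-test calibration uses 1,000 null datasets (20 samples,
  199 permutations each); Bayesian coverage uses 200 replicates with a
  reduced draw budget (2 chains × 500 draws) — sizes chosen so each
  check finishes in seconds to minutes while keeping Monte-Carlo error
  well inside the asserted bands.

## Known limitations

* The correction cannot distinguish a genuinely shared taxon (alive both
  on skin and in water at similar relative abundance) from contamination;
  such taxa are removed by design.
* One water sample per site limits the "unique to swab" rule; more water
  replicates directly improve specificity (see above).
* ANCOM here is the two-group variant; multi-group comparisons must be
  run pairwise.
* The BIOM reader covers the minimal dense JSON dialect only (no HDF5).
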