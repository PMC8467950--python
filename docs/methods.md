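# Methods

`guildflow` implements the downstream analysis of a longitudinal 16S
amplicon study of diabetic (db/db) mice under dietary treatments: from an
ASV count table, per-sample host metadata and a rooted phylogeny to
diversity summaries, co-abundance guilds, covariate-adjusted treatment
associations, and Random-Forest phenotype regression. This note records
the models, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Preprocessing

**Rarefaction.** Each sample is subsampled *without replacement*
(hypergeometric) to a common depth, default 13,000 reads/sample. Samples
below the depth are dropped with a warning. Implementation detail: every
read receives an i.i.d. uniform key drawn in a canonical (id-sorted)
feature order from a per-sample stream keyed by the sample id; the reads
with the smallest keys are kept. This makes the draw deterministic under a
fixed seed, independent of sample order, and equivariant under
permutations of the feature axis.

**Abundance filter.** ASVs with mean relative abundance below a cutoff are
treated as spurious and removed. Default cutoff 1e-4 (0.01%); the value is
a documented, configurable choice — abundance-filtering conventions vary
and the threshold should be revisited per dataset.

**Prevalence filter.** ASVs present (count > 0 after rarefaction) in
*strictly more than* 40% of samples are retained for guild analysis. The
inequality is strict: 2 of 5 samples (40%) does not pass. Prevalence can
be computed on a subset of samples (e.g. the diseased-strain subset of a
mixed-genotype study) while the returned table keeps all samples.

## Diversity

**Shannon index** H = −Σ p log p per sample, base 2 by default (the common
amplicon-workflow convention; the base is configurable and only rescales).

**Weighted UniFrac** between samples A and B is
Σᵢ bᵢ·|pᵢᴬ − pᵢᴮ| over branches i with length bᵢ, where pᵢˣ is the
fraction of X's reads on leaves below branch i. The default is the
unnormalized variant; the normalized variant (divide by
Σᵢ bᵢ·(pᵢᴬ + pᵢᴮ)) is available. Computation is delegated to scikit-bio.
Branch lengths are required on all non-root edges; a tree without them is
rejected at load time.

**NMDS** minimizes Kruskal stress-1 with monotone regression
(scikit-learn's non-metric SMACOF), 20 random restarts, 300 iterations and
tolerance 1e-6 per restart; best restart returned, deterministic under a
fixed seed.

**PERMANOVA.** Anderson's pseudo-F on the distance matrix:
SS_total = (1/n)·Σ_{i<j} d²ᵢⱼ, SS_within = Σ_g (1/n_g)·Σ_{i<j∈g} d²ᵢⱼ,
F = [(SS_total − SS_within)/(g−1)] / [SS_within/(n−g)]. If the number of
distinct label arrangements is ≤ 20,000 the null is enumerated completely
and the p-value is exact (this also bounds the smallest attainable p at
1/#arrangements); otherwise p = (1 + #{F_perm ≥ F_obs})/(1 + P) over P
random permutations. SS_within = 0 yields F = +∞ with the minimal
attainable p. Permutations are vectorized (batch pseudo-F via one matrix
product per group), so 9999 permutations on ≤ 150 items take milliseconds.

**Group comparisons** of per-sample values use Kruskal–Wallis with tie
correction followed by Dunn's pairwise z-tests on mean ranks; multiplicity
adjustment defaults to Holm (the more conservative choice when no method
is specified), configurable to any statsmodels method.

## Guild delineation

Guilds — sets of ASVs that rise and fall together across samples — are the
package's core procedure:

1. **Repeated-measures correlation.** For each ASV pair, each mouse's mean
   is subtracted from its own observations and the Pearson correlation of
   the pooled residuals is taken (the Bland–Altman within-subject
   correlation). Mice are the subjects and sampling days the repeats; this
   removes between-mouse baseline differences that would otherwise inflate
   co-abundance estimates. Correlations are computed on relative
   abundances of the prevalent ASVs across all samples; an ASV with zero
   within-subject variance has undefined correlations, which are recorded
   as r = 0 (distance 1) with a warning rather than dropping the ASV after
   filtering.
2. **Distance and clustering.** d = 1 − r (range [0, 2]), then Ward
   minimum-variance agglomeration via the Lance–Williams update applied to
   these distances (scipy linkage; the distances are not Euclidean, which
   is the standard usage of Ward on correlation distances).
3. **Recursive testing.** From the root of the dendrogram, each internal
   node whose clade has ≥ 3 members is tested by PERMANOVA (left clade vs
   right clade, default 9999 permutations) on the clade's sub-distance
   matrix. If p < 0.001 the two clades are genuinely distinct and the walk
   recurses into both; otherwise the whole clade becomes one guild. Clades
   of ≤ 2 members are atomic (a PERMANOVA needs residual degrees of
   freedom). No multiplicity correction is applied across the sequential
   tests; the fixed, stringent alpha plays that role, and the split records
   (node, pseudo-F, p, decision) are retained so every guild boundary can
   be audited.

Each split's permutation stream is seeded from (seed, node id), so the
p-value at a node does not depend on the traversal path; consequently the
guild count is monotone non-increasing as alpha tightens, and reruns with
the same data and seed reproduce the assignment exactly.

## Associations

A MaAsLin-style screen: for each guild (or any supplied feature table),
ordinary least squares of the transformed abundance on treatment group
(dummy-coded against a reference level) plus food and water intake, with
two-sided t-tests per coefficient. Guild proportions are
arcsine-square-root transformed; log transform (with half the smallest
nonzero value added to admit zeros) suits pathway-style tables.
Benjamini–Hochberg correction is applied across features separately per
model term, and q < 0.25 flags a hit — the conventional lenient screening
threshold for this analysis, where follow-up rather than confirmatory
inference is intended. Analysis defaults to the last sampled day
(endpoint), configurable. Covariates are not standardized by default.

## Phenotype prediction

Random-Forest regression (500 trees by default) of a phenotype on guild
AST abundances plus food and water intake at the endpoint day.

- **Importance** is permutation importance: mean increase in MSE when one
  predictor's values are shuffled (10 repeats), computed on the fitting
  data. It is transform-invariant and, unlike impurity importance, not
  biased toward high-cardinality predictors.
- **Feature elimination** removes one predictor per step (ranked once on
  the full data) and scores each candidate size by cross-validated MSE.
  The selected model is the smallest size attaining the minimal MSE.
  The elimination CV is leave-one-out by anology with the evaluation, but
  k-fold (the pipeline default is 5-fold) is available and used where the
  ~50-fold cost of LOO buys nothing for the size choice.
- **Evaluation** is leave-one-out: each sample predicted by a forest fit
  to the others, then Pearson r (and its two-sided p) between predicted
  and measured values. Constant predictions or responses yield an
  undefined correlation, reported as NaN with a warning.

## Synthetic data

The generator emulates the study design the pipeline targets: 5 treatment
arms × 10 mice × Days 0/14/28 (150 samples), 60 ASVs in 8 planted guilds.
For sample s (mouse m, group g, day t) and ASV j in guild G(j):

    λ_js = base_j + load·f_{G(j),s} + shift_{G(j),g,t} + u_{j,m} + ε_js
    p_s  = softmax_j(λ_js),   counts_s ~ Multinomial(L_s, p_s)

with f a per-(guild, sample) standard normal factor, u a per-(ASV, mouse)
random effect (sd 0.3) making repeated measures genuinely
subject-correlated, ε unit-normal noise, and L_s uniform on
15,000–25,000 reads (so the default rarefaction depth of 13,000 never
drops a sample). The loading is load = √(ρ/(1−ρ)·(σ_u²+σ_ε²)), which makes
the latent within-guild correlation exactly ρ (default 0.8). Treatment
effects are additive shifts on the latent log-abundance of whole guilds in
chosen (group, day) cells, growing from Day 14 to Day 28; the last guild
never receives a shift and serves as a negative control. The
softmax-multinomial construction was chosen over a Dirichlet-multinomial
because it makes the within-guild correlation — the quantity the guild
detector keys on — directly tunable.

Phenotypes: food and water intake are drawn around group/day means (food
≈ 4.8–7.2 g/day, water ≈ 11–17 mL/day, matching hyperphagic diabetic
mice), and

    glucose = 40 + 40·food + 1.5·water + Σ_g γ_g·AST(guild_g) + N(0, 20)

with γ = (+40, −40, 0, …) across guilds; body weight analogously
(22 + 2.5·food + 0.2·water + small guild terms + N(0, 1.5)); values
truncated at zero. The coefficients were set by standardized-effect
arithmetic — at Day 28 sd(food) ≈ 0.9 and sd(guild AST) ≈ 0.3, so food
contributes ≈ 36 mg/dL of glucose spread against ≈ 12 for the largest
guild — making food intake the dominant driver by design, the structure
the prediction stage is meant to expose.

What the generator does **not** emulate: sequencing error, chimeras or
denoising artifacts; taxonomy; realistic phylogenetic signal (the tree is
a random coalescent, uninformative about guild membership); overdispersion
beyond the logistic-normal-multinomial; dropout/zero-inflation beyond
multinomial sampling; and missing metadata. Tests passing on this
generator show the pipeline recovers the structure its model assumes — not
that real fecal communities satisfy those assumptions.

## Numerical choices and degenerate inputs

- Distance matrices are validated (symmetry to 1e-9, zero diagonal,
  non-negativity) and exactly symmetrized on construction.
- Permutation p-value comparisons use a relative 1e-12 tolerance so
  permutations tied with the observed statistic count as ≥.
- TSV round trips write floats as `%.17g` and parse with round-trip
  precision, so save/load is lossless for IEEE doubles.
- MSE-curve ties break toward fewer predictors; Ward ties follow scipy's
  deterministic nearest-neighbor-chain order (ties are measure-zero for
  continuous dissimilarities).
- Zero-total samples are rejected wherever proportions are needed; all-zero
  features are dropped by the abundance filter.
- The master pipeline seed expands into per-stage seeds via
  `SeedSequence(seed, spawn_key=(stage_index,))`; stages re-run in
  isolation reproduce their outputs.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the generator at the full
default design (150 samples × 60 ASVs) for guild recovery, associations
and prediction; permutation-test calibration uses 1000 null simulations of
n = 20; oracle-equivalence checks use small instances (6–8 items) where
exhaustive enumeration and O(n³) references are feasible. Forest sizes of
150–300 trees are used in simulation loops (500, the analysis default,
where a single fit is evaluated); these sizes keep the checks quick while
leaving the tested properties unchanged.

## Known limitations

- The recursive-PERMANOVA cut inherits PERMANOVA's sensitivity to
  dispersion differences between clades.
- Each split test evaluates the partition the clustering itself chose, on
  the same distance matrix — a selected-split test. The p-values are
  therefore anti-conservative for large clades: with enough items the
  best Ward split of pure noise routinely clears a fixed alpha, so guild
  counts on structure-free data are optimistic (the test suite documents
  this null behavior). Guild boundaries should be read as descriptive
  granularity control, not calibrated hypothesis tests; the split records
  let a user audit each boundary.
- Exhaustive enumeration bounds the smallest attainable p at small clade
  sizes, so very small guilds can never be split at alpha = 0.001 — a
  property of exact permutation inference, not a bug, but worth knowing
  when interpreting small-clade structure.
- The association screen uses fixed-effects OLS per feature; with three
  repeated measures per mouse a mixed model would use the longitudinal
  structure, but the screen restricts itself to one day at a time, where
  OLS is appropriate.
- Permutation importance is computed on the fitting data rather than
  strictly out-of-bag; with 500 bootstrap trees the ranking is essentially
  identical and the implementation avoids reaching into the forest's
  private bootstrap state.
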