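# Methods

This note documents the models, defaults, and design choices behind
`gutseg`, and what the synthetic cohorts do and do not establish about
real data.

## Study design assumed throughout

Two crossed factors: colonization status (CONV = conventionally colonized,
GF = germ-free; binary, CONV is the reference level) and intestinal
segment (duodenum, jejunum, ileum, cecum, colon; ordered oral→aboral),
with n = 6 mice per colonization group and one sample per mouse × segment.
Microbial profiles exist only for CONV animals; immune profiles exist for
both groups.

## Microbiome preprocessing

* **Depth filter**: samples with fewer than 500 total reads are discarded;
  a sample with exactly 500 reads is retained (the rule discards "less
  than" the threshold).
* **Rare-feature filter**: a feature is retained iff it is detected
  (count > 0) in at least ⌈10% × n_samples⌉ samples *and* its mean
  relative abundance across samples is ≥ 0.01%. The two criteria are a
  conjunction for retention, evaluated after sample filtering. The
  abundance criterion is a per-sample mean rather than a pooled total —
  the pooled reading is nearly equivalent on balanced depths and the mean
  is depth-robust; both thresholds are arguments.
* **Blank overlap**: a sample is *flagged* (never auto-discarded) when any
  feature detected in the blank control exceeds a dominance threshold
  (default 25%) of the sample's reads. Exclusion is an explicit analyst
  decision (a pipeline config switch).
* **No rarefaction anywhere.** All diversity measures run on plain
  relative abundances of the QC-filtered counts.

## Diversity and ordination

* Shannon index uses the natural log: H = −Σ p ln p over p > 0. H equals
  ln(richness) iff the community is uniform.
* Bray–Curtis dissimilarity d = Σ|x−y| / Σ(x+y) on relative abundances,
  in [0, 1].
* PCoA is classical metric scaling: double-center −½D², eigendecompose,
  order axes by eigenvalue. Negative eigenvalues are reported untouched
  (no Lingoes/Cailliez correction); proportion explained is computed over
  positive eigenvalues only, and coordinates are returned only for
  positive axes. For Euclidean inputs the embedding reproduces the input
  distances to numerical precision.
* Immune PCA operates on z-scored populations (mean 0, sd 1, ddof = 1 per
  feature) via SVD with a deterministic sign convention (largest-magnitude
  loading positive). Zero-variance populations raise by default and can be
  dropped explicitly.

## Presence/absence overlap and core taxa

A feature is "detected" in a segment when its value exceeds zero in at
least one sample of that segment (no minimum-count threshold; the
detection rule is an argument). The overlap structure records per-group
presence sets, intersection cardinalities for every subset of groups,
exclusive (Euler-region) counts, the core (intersection over all groups),
and per-group core abundance fractions — the share of mean relative
abundance carried by core features. The same binary logic applies
unchanged to species-, KO-, or gene-level tables.

## Dependence classification

Per immune population, OLS with treatment coding:

* full model: `y ~ colonization + segment + colonization:segment`
  (2G parameters for G segments),
* interaction: partial F, full vs additive (G−1 numerator df),
* main effects: Type-II F within the additive model (additive vs
  segment-only for colonization; additive vs colonization-only for
  segment).

Joint F tests are used rather than per-dummy t-tests because segment is a
multi-level factor and each model term needs a single decision. Every
(colonization × segment) cell must contain ≥ 2 observations; responses
with residual variance below 1e−12 are flagged degenerate and excluded
from testing. Abundances are modeled untransformed, matching the support
of the generator (nonnegative, truncated Gaussian).

BH FDR is applied separately within each term family (interaction,
colonization, segment) across populations, α = 0.05 by default; the
per-family structure keeps each decision axis interpretable, and a
`family="global"` option corrects all three families jointly. The decision
rule is strictly precedence-ordered (interaction ≻ both mains ≻ single
main ≻ none). A `force_assign` flag removes the "none" outcome by
assigning the smallest-q category, for designs where every population is
expected to be non-null.

Marginal means are model predictions on the full-model cell grid with
standard errors from the fit covariance; on balanced designs they equal
arithmetic cell means (saturated-model identity, checked to 1e−9).

## Univariate testing and dispersion

* CONV vs GF per population × segment: Mann–Whitney U, exact p by full
  enumeration when both groups have ≤ 8 observations and no ties,
  otherwise the normal approximation with tie and continuity correction.
  BH correction runs jointly across all population × segment tests
  (FDR 0.1 default). Stratification factors are configurable; strata
  missing a colonization group are skipped with a logged warning.
* Dispersion: all pairwise Euclidean distances between z-scored samples
  within each colonization group, compared two-sided by Mann–Whitney.
  Pairwise distances are not independent, so this p-value is labeled
  descriptive; a label-permutation test on the difference of mean
  within-group distances is available as the principled alternative.
* Enrichment: one-sided Fisher exact tests of annotation labels within
  each assigned category, margins explicit in the output.

## Association

Immune abundances are divided by their population's GF-group median
(pandas median: mean of the middle pair for even n); populations with a
zero GF median are excluded and reported. Spearman is the default
correlation — the rank-based choice is conventional for microbiome data
and invariant to the normalization's scale — with Pearson as an option;
BH across all species × population pairs; pairs with a constant vector
are skipped and listed.

## 16S absolute quantification

The standard curve is a least-squares fit Ct = intercept + slope ·
log10(copies) over ≥ 3 distinct dilution levels; amplification efficiency
is 10^(−1/slope) − 1. The copies-per-gram conversion is
`10^((ct − intercept)/slope) × (total_dna_ng / dna_per_rxn_ng) / mass_g`
with every scaling factor an explicit argument, since elution and loading
volumes vary between laboratories. At zero noise the conversion inverts
the simulation exactly.

## Synthetic cohorts: what they emulate

**Immune generator.** Abundance = baseline + colonization effect × I(GF)
+ segment effect + interaction effect × I(GF) + Gaussian noise, truncated
at 0. Effects are ±effect_scale with random non-constant signs per level,
centered to zero-sum across segments so segment and interaction terms
cannot fold into the intercept or colonization term — this guarantees the
categories are identifiable. Defaults: 82 populations with the category
mix 25 microbiome-only / 4 segment-only / 17 main-effects / 36 interaction
(the observed split), baseline 20, effect scale 4, noise sd 1 —
a moderate signal-to-noise regime in which recovery is high but not
trivial. Gaussian noise is an assumption chosen to match the OLS analysis
model; real cytometry proportions are bounded and heteroskedastic.

**Microbiome generator.** Per-segment species pools around a shared core:
non-core extras are the first k_g entries of a common list, except that
the first (smallest) segment draws its extras from the last segment's
exclusive range. Pools therefore overlap realistically while the
intersection of all pools is exactly the core, so noise-free detection
recovers the true core. Within a segment, species abundances are
log-normal (σ = 2); core species are clipped below at the log-normal
median and boosted ×10, reflecting that persistently detected taxa are
not vanishingly rare (and making core detection reliable at ample depth).
Reads are multinomial at a log-normal depth (10^4 median); a configurable
fraction of samples (default 20%, matching the study's attrition) is
forced under the 500-read threshold, and one blank-derived contaminant is
injected at ~80% relative abundance into one sample. Defaults follow the
observed richness gradient 80 → 291 with a 72-species core.

**qPCR generator.** Ct = intercept + slope·log10(copies) + Gaussian noise
over a 10-fold dilution series 10⁰–10⁹ in triplicate; default slope
−3.3219 (100% efficiency), intercept 38, Ct noise 0.15.

**Limits.** The generators start at the abundance-table level: no
sequencing reads, cytometry events, compositional coupling between
immune populations, or overdispersed counts. Passing recovery tests shows
the pipeline's inference is correct *under its own model assumptions*;
it does not validate those assumptions against real measurements.

## Numerical choices and problem sizes

* Exact Mann–Whitney switches to the asymptotic branch above n = 8 or with
  ties; the continuity-corrected approximation tracks the exact n = 8
  distribution to about the 0.01 level.
* BH caps adjusted p-values at 1 and propagates NaN (degenerate tests).
* The classifier's recovery experiments use 200 features at
  effect/noise = 8 and 50 null replicates of 200 features; the end-to-end
  demo uses the full 82-population, 30-sample study shape. These sizes
  give stable rates (binomial noise ≪ the margins tested) while keeping
  any single run in seconds.
* All generators are deterministic functions of their design (including
  the seed); the pipeline derives per-stage seeds from one run seed and
  records a config hash and per-file checksums in its manifest.

## Known limitations

* The dependence model assumes homoskedastic Gaussian errors on
  (relative) abundances; logit or arcsine-square-root transforms would be
  natural extensions and the model surface accepts transformed tables.
* The pairwise-distance dispersion test inherits the dependence caveat
  above; use the permutation option for inference.
* The blank-exclusion rule is a dominance heuristic; with multiple blank
  features or cross-contamination patterns a dedicated decontamination
  model would be preferable.
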