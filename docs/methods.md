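# Methods

`floradisp` quantifies morphological disparity from a mixed-type trait
matrix and relates it to ecological factors and latitude. This note records
the statistical model, the choices made where the design was genuinely
open, and what the synthetic validation does and does not demonstrate.

## Dissimilarity and disparity

The pairwise dissimilarity is the *mean character difference*, a Gower-type
index. For taxa *i*, *j* and the set S(i,j) of characters scored in both:

D(i,j) = (1/|S|) Σ_{k∈S} d_k(i,j)

with d_k a 0/1 mismatch for binary and unordered characters, and
|x_i − x_j| / range_k for ordered (ranks within the stated state order) and
continuous characters. `range_k` is the span observed across the **whole
dataset**, not per group, so that distances live in one common morphospace
and are comparable between groups; a character with zero observed span
contributes 0. Characters missing in either taxon are excluded from both
numerator and denominator, so D ∈ [0, 1] always; a pair sharing no scored
character is *undefined* (NaN, never silently 0) and is excluded from all
averages with a warning.

Disparity of a group is the mean pairwise dissimilarity D̄ over all defined
within-group pairs. The ± value reported with D̄ is the sample (n−1)
standard deviation of those pairwise values — it describes the spread of
the distance distribution, not an uncertainty of the mean. Because the
expectation of D̄ over uniform subsamples of any size equals the full-group
D̄, the index is robust to unequal group sizes (verified by a dedicated
test); this is the reason it is preferred over range-type indices here.

Ordered multistate characters are scored by rank difference along the
declared ordering (not unit steps); this is a convention of this package
and is the main place where alternative Gower variants could differ.

## Polymorphism

Cells may hold several states (trait polymorphism, ~2% of cells in the kind
of data targeted) and factor cells several categories (~16%). The distance
index is defined for monomorphic data only, so every computation first
draws one state uniformly at random per polymorphic cell. For descriptive
disparity a species with multiple categories counts in **every** category;
for tests each species is resolved to exactly one category so groups are
disjoint. Each test is repeated over `n_resolutions` fresh resolutions of
both matrices — with the distance matrix recomputed every time — and
reported as mean ± SD. The permutation stream is deliberately **shared**
across resolutions, so the reported SD isolates resolution randomness and
is exactly 0 for polymorphism-free input.

## Permutation inference

Group effects on the distance matrix are tested with a one-way
distance-based F using the standard partition of squared distances

SS_total = (1/N) Σ_{i<j} d²_ij,  SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij,
F = (SS_among/(a−1)) / (SS_within/(N−a)),

whose null distribution comes from shuffling taxon identities without
replacement (9 999 permutations at full scale). For Euclidean distances on
univariate data this F equals the classical one-way ANOVA F (tested against
`scipy.stats.f_oneway`). Post-hoc comparisons use the central-tendency
statistic T = D̄_A − D̄_B, permuting taxa within the two categories only,
two-sided, Bonferroni-corrected over the pairs tested. Categories left with
fewer than 3 taxa after resolution are dropped from tests with a warning.

Numerical conventions:

* default p-value is the raw exceedance count #{stat_perm ≥ stat_obs}/B, so
  a never-exceeded statistic prints p = 0; the (count+1)/(B+1) variant is
  available via `p_convention="add-one"`;
* ties count toward the numerator, with a 1e-9 relative slack so exact ties
  survive floating-point noise;
* perfect separation (SS_within = 0 with SS_among > 0) reports F = inf; a
  permutation ties with it only by regenerating the same partition;
* all randomness flows from one user seed through `numpy` SeedSequence
  spawning, so every reported run is exactly reproducible.

Note that the F-ratio responds to *both* location (different modal
morphologies) and dispersion (different within-group spread) differences
between groups — a well-known property of distance-based ANOVA that users
should keep in mind when interpreting a significant result.

## Factor-category associations

Each factor pair is tested with a Pearson chi-squared test (no continuity
correction); association strength and direction per category pair come from
Pearson residuals PR = (O−E)/√E. Species with multi-valued cells contribute
one count to every category pair in the Cartesian product of their sets —
this keeps the table deterministic and mirrors the descriptive
"counts in every category" convention; a random-resolution alternative is
available (`counting="resolve"`). Sparse categories can be merged or
excluded before testing (e.g. folding a small 'polar' class into 'cold');
a zero marginal is a hard error with a merge hint.

For the association network, each category receives a profile of its PR
values against all categories of the other factors (same-factor entries,
which carry no test, are 0). Bray–Curtis dissimilarity requires
non-negative input, so profiles are shifted by the global minimum PR first;
this preserves the profile ordering. The exact vectorisation of PR into a
distance matrix is not uniquely determined by precedent, so it is isolated
in one function (`pr_profile_distance`) and easy to swap. The profiles are
embedded in 2-D by non-metric MDS (SMACOF, Kruskal stress-1, best of
`n_starts` random starts, deterministic given the seed; coordinates centred
and scaled to unit RMS). Edges connect category pairs from significant
tests (P < 0.05) with |PR| ≥ 2 (≈ the 5% two-sided standard-normal cutoff;
the threshold is a drawing convention, not an inference). Clusters of
mutually associated categories are the connected components of the
positive-edge graph; explicit cluster specifications are also accepted.

Cluster membership uses intersection-across-factors / union-within-factor
semantics: a species belongs to a cluster when, for every constrained
factor, its category-set meets the admissible set. Two clusters are
contrasted with the central-tendency permutation test (99 999 permutations
at full scale); overlapping species are removed from both sides first, and
the internal group order is canonicalised so the two-sided p is exactly
invariant to swapping the clusters.

## Latitudinal gradient

Species presence is scored in 18 half-open 10° bins [lower, lower+10) from
−90° (latitude 90 closes the last bin) from occurrence records; presence is
record-based by default, with an optional `range_fill` that marks all bins
between a species' extreme records (a coarse stand-in for curated range
maps — both behaviours are tested). Per-bin disparity is D̄ of the species
present. Gradients are summarised by Pearson r (two-sided t-transform p)
and OLS of the bin response on the **absolute** bin midpoint (distance from
the Equator); bins below an optional richness floor can be excluded, and a
constant response is returned flagged rather than given a meaningless r.

Because D̄ might in principle depend on how many species a bin holds, each
bin is also compared against a richness-matched null: `n_draws` uniform
subsets of the bin's size drawn from the full species pool, reporting the
null mean, 2.5%/97.5% quantiles and a two-sided empirical p. A disparity
peak that survives this control is not a richness artefact. This subset
resampling null is a reconstruction of that control-by-rarefaction idea,
chosen as the simplest exchangeable null that fixes richness exactly.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
the scale of a large ordinal-level floral dataset: 380 taxa × 36 characters
(16 binary, 10 unordered, 6 ordered, 4 continuous) with 13.4% missing and
2.2% polymorphic cells; four factors (growth form / habitat / climate /
region with the standard vocabularies) with 3.6% missing and 16.5%
multi-valued cells; and GBIF-style occurrence records.

* **Associations**: each taxon draws a latent block (e.g. block 1 =
  tropical forest trees of Africa/South America); with probability
  `association_strength` (default 0.75) each factor category comes from the
  block, else uniformly from the vocabulary. Strength 0 gives exact
  independence (used for chi-squared calibration tests).
* **Trait distributions**: per character one modal state (or mean) shared
  by all groups; the group of a taxon is its primary category of a driver
  factor (climate). A group with dispersion w ∈ [0, 1] uses state
  probabilities (1−w)·modal + w·uniform, so within-group D̄ grows
  monotonically with w, vanishes as w → 0, and — because all groups share
  the modal state — a latitude bin mixing several groups can never be more
  disparate than its highest-w group. Independent per-group state
  distributions were tried first and rejected: they make group-mixing
  mid-latitude bins out-disparate the planted tropical group through
  between-group distances alone. With probability `modal_shift` (default
  0.15) a group swaps a character's modal state for its own, which plants
  the between-group location differences the distance-based ANOVA detects.
  Defaults (tropical w = 0.35 vs 0.15–0.2 elsewhere) put D̄ near the ~0.2
  scale typical of floral trait matrices. `group_traits=False` gives every
  taxon one shared distribution — disparity then independent of every
  factor and of latitude, the control used with the richness-matched null.
* **Occurrences**: species ranges (default width 20°) are centred uniformly
  in a latitude band set by the primary climate category (tropical 0–20°,
  …, polar 60–80°, hemisphere random), records uniform within the range.

What the generator does **not** emulate: phylogenetic correlation among
taxa, longitudinal/spatial clustering of records, character correlation
beyond group structure, and non-uniform polymorphism (real polymorphism
concentrates in labile characters). Passing tests therefore demonstrate
that the machinery recovers effects under the model's own assumptions —
not that those assumptions hold for any particular empirical dataset.

## Problem sizes and defaults

Full-scale defaults follow the study design the package targets
(9 999 test permutations, 99 999 for the cluster contrast, 100
resolutions); the pipeline's desk-scale defaults (999 permutations, 20
resolutions, 1 000 null draws) are the sizes used by the test suite and the
acceptance script, chosen so Monte-Carlo error is small relative to every
tolerance asserted. The type-I calibration uses 2 000 null datasets of 40
taxa × 10 binary characters so that the binomial SD of the rejection rate
(≈0.005) is half the asserted ±0.01 band. Exhaustive-enumeration checks use
≤8 taxa where all label assignments can be listed.

## Known limitations

* The distance-based F confounds location and dispersion effects (above).
* Cartesian counting in contingency tables lets multi-membership species
  contribute several counts, mildly inflating totals; the random-resolution
  mode is the conservative alternative.
* NMDS stress depends on the PR-profile construction; coordinates should be
  read as a visual grouping aid, not as calibrated distances.
* Record-based presence underestimates ranges for sparsely recorded
  species; `range_fill` overestimates them. Both are provided.
* The richness-controlled null resamples from the sampled species pool and
  so conditions on the study's taxon sampling.
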