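# floradisp

Morphological disparity analysis for mixed-type trait matrices: Gower-type
distances, distance-based permutation ANOVA, factor-association networks,
and latitudinal disparity gradients.

## The problem

Species richness is only one axis of biodiversity. *Disparity* — the
morphological diversity of a set of taxa — captures a different one: how
much of the available morphospace a group actually occupies. For flowering
plants, floral disparity is a proxy for the diversity of reproductive
strategies and pollinator interactions, and comparing it across growth
forms, habitats, climate zones, regions and latitude bands asks which
ecological settings let lineages explore more of the morphospace.

`floradisp` is for botanists and macroevolution researchers who have
(1) a taxa × characters matrix of mixed binary / unordered / ordered /
continuous floral (or other morphological) characters, with missing and
polymorphic cells; (2) a taxa × factors table of ecological categories,
possibly multi-valued; and (3) occurrence records. It computes disparity
per grouping, tests group differences without distributional assumptions,
maps associations among factor categories, and profiles richness and
disparity along latitude with a richness-controlled null.

## The model

Pairwise dissimilarity is the **mean character difference**, a Gower-type
index over characters scored in both taxa:

    D(i,j) = (1/n_shared) Σ_k d_k,   d_k = 1{x_ik ≠ x_jk}            (binary/unordered)
                                     d_k = |x_ik − x_jk| / range_k   (ordered/continuous)

so D ∈ [0, 1]. **Disparity** of a group is the mean pairwise dissimilarity
D̄ (± SD of the pairwise values). Group effects are tested with a one-way
distance-based permutation ANOVA,

    F = (SS_among/(a−1)) / (SS_within/(N−a)),
    SS_total = (1/N) Σ_{i<j} d²_ij,   SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij,

against taxon-identity permutations, with post-hoc two-group permutation
tests on T = D̄_A − D̄_B (Bonferroni-corrected). Polymorphic cells are
resolved uniformly at random, and every test is aggregated over many
resolutions (reported mean ± SD). Category associations are chi-squared
tests with Pearson residuals (O−E)/√E, visualised as a non-metric MDS
embedding of residual profiles with signed edges; latitude profiles use 18
half-open 10° bins and Pearson/OLS fits on |latitude|, plus a null that
redraws equal-sized species sets from the full pool to show disparity is
not a richness artefact. Details and design choices: `docs/methods.md`.

## Worked example

The package ships a generator for synthetic datasets with the structure the
analysis assumes (planted associations, a high-dispersion tropical group,
climate-linked latitudinal ranges):

```python
import floradisp as fd

spec = fd.SynthSpec(seed=7, n_taxa=120)
ds = fd.simulate_dataset(spec)

res = fd.DisparityAnova(ds.morph, ds.factors, "climate").fit(
    n_perm=999, n_resolutions=10, seed=0)
print(res.summary())
```

```
Disparity by category of factor 'climate'
 category  disparity     sd  n_taxa  n_pairs  defined
 tropical     0.3048 0.0790      39      741     True
     arid     0.2102 0.0979      18      153     True
temperate     0.2864 0.0938      26      325     True
     cold     0.2249 0.1113      28      378     True
    polar     0.1649 0.1314      22      231     True

Permutation ANOVA (999 permutations, 10 polymorphism resolutions):
  F = 17.27 +- 1.03, P = 0 +- 0
```

Tropical species are the most disparate (D̄ = 0.305 vs 0.16–0.29
elsewhere) — the effect planted by the generator — and the permutation
ANOVA finds the climate categories significantly heterogeneous (no
permuted F reached the observed one, hence P = 0 under the raw count
convention; the ± values are spread over random polymorphism resolutions).

```python
lat = fd.LatitudinalDisparity(ds.occurrences, ds.morph).fit(seed=0, n_draws=500)
print(lat.summary())
```

```
richness ~ |latitude|: r = -0.893, P = 6.03e-07, slope = -0.2433, intercept = 28.12 (18 bins)
disparity ~ |latitude|: r = -0.883, P = 1.18e-06, slope = -0.002578, intercept = 0.3609 (18 bins)
```

Both richness and disparity decline toward the poles; the per-bin table
(`lat.profile_frame()`) also carries each bin's richness-matched null
envelope.

The same stages are available from the shell:

```sh
floradisp simulate --seed 7 --n-taxa 120 --out-dir data/
floradisp test --matrix data/morph_matrix.csv --chardefs data/chardefs.yaml \
    --factors data/factor_table.csv --factor climate --n-perm 999 \
    --n-resolutions 10 --seed 0
floradisp all --config config.yaml   # whole pipeline from a YAML config
```

Input formats are plain delimited text: taxa in the first column, `/` for
multi-state cells, `?` for missing, plus a YAML character-definition
sidecar (see `docs/methods.md`).

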