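# Methods

This note documents the statistical machinery in `herbpersist`, the choices
made where the underlying methods admit more than one reading, and what the
synthetic-data tests do and do not establish about real survey data.

## Weighted residence time

For one species in one quadrat observed over `Z` ordered surveys,
`WRT_pa = 100 · (P/T)/Z` with `P` = surveys present and `T` = the number of
**maximal runs of consecutive presences** (equivalently, absence→presence
transitions counting the start as absence). This runs-based reading of `T`
is the one under which the index's published worked examples are internally
consistent: the alternating pattern `10101010` gives `P = 4, T = 4`, hence
`100·(4/4)/8 = 12.5`, and the block pattern `11000000` gives
`100·(2/1)/8 = 25`. Two cells of that worked table do not follow from the
formula under any reading of `T` (the pattern `00110010` prints 18.6 where
the formula gives 18.75, and one abundance-weighted cell prints 18.7 where
`31.25 × 0.5 = 15.625`); we treat them as printing errors, exclude them
from verification, and do not adjust the formula to fit them.

Conventions: an all-absent pattern has `WRT = 0` (the formula's 0/0 is taken
as no persistence); consecutiveness is adjacency in the survey sequence, so
the irregular calendar spacing of surveys (gaps of 1–3 years) is
deliberately ignored; reports round to one decimal, computation is exact.
For any pattern with at least one presence, `100/Z ≤ WRT_pa ≤ 100`, with the
minimum at maximally fragmented patterns (`P = T`) and the maximum at full
presence — verified exhaustively over all 2⁸ patterns in the tests.

**Relative cover.** `WRT_abu = WRT_pa · Rel.cov`, where `Rel.cov` is the
species' mean share of summed quadrat cover. Two averaging modes are
provided because the definition is ambiguous when the species is absent:
`presence_only` (default) averages the share over the surveys where the
species occurred; `all_surveys` averages over all `Z` surveys with absences
contributing zero. The default avoids penalising absence twice — `WRT_pa`
already encodes it. Both modes agree on the worked examples' self-consistent
cells.

## PERMANOVA

One-way, Anderson's partition on squared distances:
`SS_total = (1/N)·Σ_{i<j} d²`, `SS_within = Σ_g (1/n_g)·Σ_{i<j∈g} d²`,
`pseudo-F = (SS_between/(a−1))/(SS_within/(N−a))`, `R² = SS_between/SS_total`.
Significance by unrestricted permutation of group labels; the add-one rule
`p = (b+1)/(m+1)` keeps p strictly positive. When the number of distinct
label assignments is ≤ 10,000 the test enumerates them all and reports the
exact p instead of sampling. Bray–Curtis is computed in-house (the pair of
all-zero rows, for which the index is undefined, is assigned distance 0 with
a warning so empty quadrats remain comparable) and cross-checked against
scipy and scikit-bio in the tests.

**Trait-abundance composition.** The construction of the unit × trait matrix
fed to the second PERMANOVA is not standardised anywhere; ours is: for each
binary/categorical attribute, the summed cover of species bearing it; for
each quantitative trait, the cover-weighted mean (CWM; 0 in an empty unit);
columns scaled to unit range before Bray–Curtis so cover sums and CWMs are
commensurable. This is a documented, configurable choice
(`standardise=False` disables the scaling), not a canonical definition.

## Functional and phylogenetic diversity

Gower distance over the five-trait schema: quantitative components
`|xi−xj|/range` with the range taken over the species pool handed in (per
site in the pipeline, since diversity is compared within sites); binary and
categorical components are 0/1 mismatches; missing traits are deleted
pairwise with weight renormalisation, and a species pair sharing no
non-missing trait is an error rather than a silent zero. A constant
quantitative trait contributes 0 for every pair. Equal weights by default;
per-trait weights are accepted. On complete tables with equal weights the
result is a metric (checked on random instances).

FD and PD per quadrat are unweighted mean pairwise distances among the
species present (undefined below two species; such quadrats are dropped from
the site-level correlation with a warning). Abundance weighting is
deliberately not applied. The FD–PD association per site is Spearman's rho;
the two-sided p is an exact permutation enumeration for n ≤ 9 and the
asymptotic t-approximation otherwise.

Neighbor joining is the classic Saitou–Nei agglomeration (Studier–Keppler
`Q(i,j) = (r−2)d_ij − R_i − R_j`, rate-corrected branch lengths, matrix
reduction by `d_uk = (d_ik + d_jk − d_ij)/2`). Negative branch-length
estimates are clamped to zero with the deficit moved to the sister branch so
path lengths are preserved where possible; clamps are logged. On additive
matrices the input patristic structure is recovered exactly (to 1e-9 over
random trees in the tests). Patristic distances on trees lacking branch
lengths fall back to nodal (edge-count) distances only when explicitly
requested. Species absent from the phylogeny are substituted only through an
explicit user-supplied alias map — never by silent genus matching.

## Conditional inference trees

A deliberately simplified, rank-based analogue of the conditional-inference
framework: at each node every candidate trait is tested for independence
from the response by a permutation test — ordered traits with the absolute
centred-rank cross-product (a Spearman-type linear statistic), categorical
traits with the between-group rank dispersion `Σ n_g (r̄_g − r̄)²` (a
Kruskal-type statistic) — using one shared stream of seeded Monte-Carlo
permutations per node and the add-one p. P-values are Bonferroni-adjusted
over the testable traits; the node splits on the trait with the smallest
adjusted p only if it is below `alpha`, otherwise it becomes a leaf. Ties in
(adjusted p, raw p) — which occur routinely once effects are strong enough to
saturate the attainable minimum p — are broken by the permutation z-score of
the statistic (observed minus permutation-null mean, over null sd), then by
declared trait order; the shared permutation stream makes duplicated traits
tie exactly and fall to declared order.

Splits: ordered traits take the cutpoint maximising the absolute
standardised two-sample rank-sum statistic with both children at least
`min_leaf`, and the reported threshold is the largest observed value of the
left group (the "≤ c" convention); categorical traits search all binary
level subsets (≤ 10 levels). Missing values are deleted casewise per test;
at split time observations missing the split variable follow the majority
child (logged). Defaults: `alpha = 0.05`, `n_perm = 9999`, `min_node = 20`,
`min_leaf = 7`, `max_depth = 4`.

Observation unit: one row per (species, quadrat) with at least one
occurrence, response = `WRT_pa` or `WRT_abu`, predictors = the species'
fixed trait values replicated across its quadrats. Trait values are
species-level constants, so these rows are pseudo-replicated; this mirrors
the analysis design the package supports but inflates apparent sample size,
which is exactly why p-value saturation (and the z-score tie-break above)
matters. Tests verify: nominal type-I error of the association test under
the null (within ±0.02 of 0.05 over 1000 replicates), ≥ 90% root recovery of
a planted 35-point median separation at n = 400 with noise sd 15, and ≥ 90%
single-leaf outcomes on pure noise.

## Synthetic data generator

The generator emulates the monitoring design the analyses assume: 4 sites ×
100 permanent quadrats × 8 surveys (labelled 1999–2011), ~35 species per
site, and 5% expected between-site pool sharing, which reproduces the
qualitative pattern that almost all species are confined to a single site.
Occupancy per (quadrat, species) is first-order Markov: initial presence
Bernoulli(`p_init = 0.15`), per-survey persistence probability
`sigmoid(logit(0.7) + Σ effects)`, colonisation 0.03. The baseline values
are our choice of a realistic quadrat-scale regime for forest understorey
herbs — quadrats hold a handful of species, established occupants usually
survive a one-to-three-year gap, and new arrivals at 0.25 m² grain are
rare; trait effects are expressed on the log-odds scale applied to
standardised trait values. Cover when present is log-normal (median ≈ 3%,
σ = 1 on the log scale) with ±20% survey-to-survey perturbation, clipped to
[0.01, 100].

Trait distributions: seed mass log-normal (median ≈ 2 mg with a long right
tail into the tens of mg, so splits in the 5–20 mg range arise naturally);
SLA normal (25 ± 8 mm²·mg⁻¹, truncated above 5); bud bank Bernoulli(0.6);
vegetative mobility none/slow/fast at 0.2/0.4/0.4; leaf anatomy over the
four water-economy levels. The stand-in phylogeny is a random binary tree
with exponential branch lengths, drawn independently of the traits — so the
generator's FD–PD correlations are near zero by construction, and the
pipeline's FD–PD stage demonstrates machinery, not a planted signal.

**What the generator does not emulate:** spatial autocorrelation among
quadrats (the emulated design spaces them to suppress it), climate forcing
or directional change, interspecific interactions, intraspecific trait
variability, observer error, and any trait–phylogeny signal. Passing tests
therefore show the estimators and tests behave correctly under a known
occupancy process — not that real understorey dynamics satisfy that process.

## Problem sizes in tests and the acceptance script

The acceptance script runs the full 4-site, 100-quadrat, 8-survey study
(≈ 1100 persistence observations per site), a 999-permutation PERMANOVA over
400 quadrats, 999-permutation tree tests, and a 500-replicate null
calibration at n = 40 with 499 permutations — the sizes at which each
quantity is stable enough to be meaningful while the whole script stays
fast. The heavier simulation-based tests use 100 replicates for recovery
rates and 1000 for test calibration.

## Known limitations

- The CIT module approximates ctree's quadratic-form conditional inference
  with rank statistics and Monte-Carlo p-values; trees on borderline effects
  can differ from ctree's, though stop/split behaviour and planted-effect
  recovery match the framework's description.
- WRT treats the survey sequence as equally spaced; designs with wildly
  uneven revisit intervals would need a time-weighted variant.
- Aboveground absence is taken as absence: dormant below-ground organs,
  seed banks and missed detections all count against persistence.
- PERMANOVA is one-way only; no strata, no multi-factor designs.
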