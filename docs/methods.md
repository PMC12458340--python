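# Methods

This note records the models, conventions and numerical choices behind
`strainbiogeo`, and what the synthetic-data validation does and does not
establish about real data.

## Distance layers

**Strain genetic distance** is 1 − conANI: for two samples' major-allele
profiles of the same SGB, restrict to genomic sites covered in both with
depth ≥ `min_depth` (default 1, the minimal reading of consensus-allele
comparison) and count disagreement of the major alleles. A pair with fewer
than `min_shared_sites` (default 50) qualifying shared sites is recorded as
*missing* rather than trusted as a distance — a floor that prevents
one-site "distances" from sparse co-coverage. Missing pairs propagate as NA
through the distance-matrix container and are dropped listwise per SGB in
every downstream regression.

**Geographic distance** is the haversine great-circle distance on a sphere
of radius 6371.0088 km (the IUGG mean Earth radius, fixed so results are
bit-reproducible across environments). Coordinates are decimal-degree
WGS84-style latitude/longitude.

**Host relatedness** enters as the mitochondrial 1 − conANI distance between
hosts, the maternal-lineage proxy: maternal transmission of gut microbes is
the mechanism by which isolation-by-host would be expected to act.

When a host was sampled repeatedly, one sample is retained: the one
maximizing the mean of the within-host ranks of (number of compared bases,
number of SNPs). Both criteria are stated as primary by the upstream
microdiversity profiling convention without a combination rule; mean rank
treats them symmetrically, and exact ties break to the lexicographically
smallest sample id so the choice is deterministic.

## Mantel and MRM permutation tests

Matrices are aligned on their common labels and vectorized in row-major
lower-triangle order. MRM regresses the z-scored response vector on z-scored
predictor vectors, so coefficients are standardized partial regression
coefficients — comparable across SGBs and interpretable as "correlation
coefficients" in the single-predictor case, where the Pearson MRM
coefficient equals Mantel's r exactly. Raw-scale coefficients (with
intercept) are retained in the result object for transparency.

The null distribution jointly permutes rows and columns of the *response*
matrix, holding predictors fixed — the standard exchangeability argument for
distance matrices. Per-coefficient MRM p-values are two-sided on |b| (the
cited MRM implementations do not document a tail; two-sided is the
conservative choice), while the Mantel test is one-sided upper-tail,
matching the directional "distances increase together" hypothesis. "Up to
`n_perm` permutations" is implemented as: enumerate all n! relabelings
exactly when n! ≤ `n_perm` (p = count/n!, the identity included), otherwise
sample `n_perm` relabelings and report p = (1 + #extreme)/(n_perm + 1).
Sampled p-values are bit-reproducible for a fixed seed; each SGB draws its
permutations from a substream keyed by a stable hash of its id, so adding or
removing SGBs never perturbs the others' p-values. Statistic comparisons use
an absolute tolerance of 1e-12 so exhaustive p-values equal exact rationals.

With missing response pairs, the permutation moves the missingness with the
matrix and the statistic is recomputed on the re-masked vector each time,
preserving label exchangeability. The Spearman variant rank-transforms
(average ranks) the vectorized response and predictors; in the complete-data
fast path ranks are precomputed once since a relabeling permutes the same
multiset.

Predictor pairs with |r| > 1 − 1e-10 raise a singularity error naming the
offending pair rather than returning unstable coefficients.

**FDR and calls.** Benjamini–Hochberg adjustment (statsmodels step-up) is
applied across SGBs separately within each method × predictor family (four
families) — the default because significance is reported per predictor
under both methods; a joint-family mode is available. `ibd_call = "both"`
requires the geographic q-value < α under Pearson *and* Spearman;
analogously for `ibh_call`. The screen is restricted to SGBs present in
≥ 3 hosts and ≥ 2 populations (sites).

**Residualization for visualization** uses identity-covariance least squares
(no correlation structure is imposed; the "GLS" here is OLS with an
intercept), returning residuals of strain distance on host-MT distance to
plot against geography.

## Phylogenetic trait analysis

IBD strength per SGB = the standardized Pearson MRM geographic coefficient.
The bacterial tree is midpoint rooted — implemented via the two-sweep
diameter walk with the root placed on the edge containing the path midpoint
(the two deepest tips end up equidistant to within 1e-9) — and pruned to the
analysed SGBs with additive merging of suppressed unifurcations, so pairwise
tip path lengths are preserved exactly.

Contrasts follow Felsenstein's pruning recursion: at an internal node with
child values x₁, x₂ on (extended) branch lengths b₁, b₂, the standardized
contrast is (x₁ − x₂)/√(b₁+b₂), the node value is the precision-weighted
mean, and the node's branch is extended by b₁b₂/(b₁+b₂). Polytomies are
resolved to arbitrary bifurcations with zero-length internal branches; a
zero b₁+b₂ raises by default, or is padded by 1e-8 × tree depth under the
epsilon policy (used in the pipeline, where resolution-induced zeros are
expected and the affected contrasts are 0/√ε = 0 for identical child
values).

Outlier contrasts beyond the Tukey fences (1.5 × IQR outside Q1/Q3,
quartiles by linear interpolation between order statistics — the default of
mainstream numerics stacks; borderline points can depend on this
convention) are removed, *pairwise*: a contrast pair is dropped when either
the trait or the IBD-strength member is an outlier, keeping the vectors
aligned. Outliers are interpreted at the contrast level (each contrast is
the natural observational unit after the PIC transform).

The association test is a through-origin regression of trait-abundance
contrasts on IBD-strength contrasts, slope = Σxy/Σx², one-sided for a
negative slope. Its permutation null flips the signs of the response
contrasts independently — exact under the PIC symmetry that contrast signs
depend only on arbitrary child ordering; all 2ⁿ sign patterns are enumerated
when 2ⁿ ≤ `n_perm` (default 100,000). Binary trait calls (e.g. consensus
classifier output; non-consensus SGBs arrive as missing) are tested by OLS
of IBD strength on the 0/1 indicator: the slope is the group mean
difference and the two-sided p comes from the t distribution, identical to
a pooled two-sample t-test. Trait analyses are restricted to SGBs with
completeness ≥ 0.90 present in ≥ 4 samples.

## Sympatric comparisons

Sympatry is operationalized as identical site code (a km-radius alternative
is a config option). Every retained pair belongs to exactly one pairing:
focal–focal pairs are conspecific (by default only at sites where a
comparator species was sampled, since the comparison concerns sympatric
sites; configurable), focal–comparator pairs take the pairing assigned to
the comparator species, and comparator–comparator pairs are excluded.
SGB × pairing entries need ≥ 2 pairs.

Per-SGB permutation t-tests (difference of means; exhaustive over
C(n_a+n_b, n_a) reassignments when feasible) compare conspecific vs
congeneric and congeneric vs heterogeneric distances, BH-corrected across
SGBs within each contrast. The across-SGB "mean of means" test takes
per-SGB mean distances as units and, because the same SGB appears in both
pairings, permutes pairing labels *within* SGB — a sign-flip test on
per-SGB differences (all 2^S flips enumerated when feasible); an unpaired
pooled-permutation variant is available by flag. Note that per-SGB mean
differences share the host-genetic and geographic layers across SGBs, so
the mean-of-means test responds to any systematic between-pairing
difference, not only to the pairing-specific inflation — which is exactly
the between-host-species divergence signal it is meant to capture.

## The synthetic world

`ScenarioConfig` defaults are the emulated study conditions; they are not
tuning knobs.

| parameter | default | meaning |
|---|---|---|
| `n_sites`, `hosts_per_site` | 13, 3 | continental sampling design (39 hosts) |
| `site_extent_km` | 4000 | side of the uniform site square, mapped to lat/lon around (39° N, 98° W) |
| `mt_intercept`, `mt_slope`, `mt_noise_sd` | 0.002, 2e-6/km, 0.003 | host MT distance = clip₀(a + b·geo + noise), symmetrized; the noise is chosen so the MT-vs-geography Mantel r lands near 0.5 — geography explains host relatedness only partially, which is what makes IBD and IBH separable |
| `n_sgbs`, `occupancy_prob` | 200, 0.6 | SGB panel with Bernoulli host occupancy (sparse detection) |
| `sgb_baseline` | 0.25 | baseline strain divergence between any two hosts |
| `beta_geo0`, `beta_host` | 0.4, 0.2 | effect sizes on the z-scored, [0,1]-rescaled geographic and MT layers |
| `sgb_noise_sd` | 0.1 | per-pair Gaussian noise of strain distances |
| `sporulation_coupling` (λ) | 1.0 | β_geo,s = β_geo0 · exp(−λ · spor_s / max spor) |
| `bm_sigma` | 1.0 | Brownian sd of log gene abundance over unit tree depth |
| `heterogeneric_delta` (δ), `congeneric_delta_fraction` | 0.1, 0.25 | additive cross-species inflation (congeneric = δ/4) |

Strain distances are generated directly at the matrix level —
clip₀₁(baseline + β_geo,s·geõ + β_host·mt̃ + noise) per pair — because every
downstream statistic consumes distances; an allele-profile mode
(`simulate_allele_profiles`) exercises the conANI machinery end to end by
solving the per-sample substitution rate q from 2q(1−q) + (2/3)q² = p so the
expected pairwise divergence equals the target p. The baseline intercept is
a deliberate addition to the mixture: without it, pairs with near-zero
predictors would clip at zero about half the time; with the default noise
the clipped fraction is below 1% (asserted in tests). Scenarios with larger
noise clip a few percent of pairs at the boundaries; clipping never breaks
the exchangeability the permutation tests rely on. Pairwise-generated
distances are not guaranteed metric; no downstream statistic assumes the
triangle inequality.

The bacterial tree is a pure-birth (Yule) tree rescaled to unit mean
root-to-tip depth, so `bm_sigma` reads directly as the root-to-tip sd of log
abundance (the usual normalisation in comparative simulations; without it
the exponential of a depth-ln(n) Brownian walk produces a trait distribution
dominated by a single clade). Zero-length cherries left by stopping at a
birth event are padded to 1e-3 so every branch carries positive Brownian
variance. Gene abundance is round(exp(BM)) with root log-abundance 3.4
(~30 genes, a realistic sporulation-gene count scale).

All randomness derives from a single scenario seed through SHA-256-keyed
substreams per component (sites, samples, tree, per-SGB matrices), making
worlds byte-for-byte reproducible and individual SGBs independent of panel
composition.

**What the generator does not emulate:** real conANI noise structure
(coverage-dependent, site-correlated), phylogenetic signal in *occupancy*,
non-additive host×geography interactions, multi-strain mixtures within a
host, and reference-genome bias. Passing the validation suite therefore
establishes that the estimators and tests are correct and calibrated under
the assumed generating process, not that the assumptions hold in any
particular real dataset.

## Validation problem sizes

The simulation-based checks run at the following sizes, chosen to make the
binomial error of each estimated rate small relative to its margin: null
calibration on 300 SGBs at 40 hosts with 1,000 permutations each;
power/recovery on 100 SGBs per single-effect world; trait-coupling recovery
over 100 replicate 150-SGB worlds at 5,000 sign-flip permutations;
sympatric recovery over 100 replicate 50-SGB worlds at 2,000 permutations
(the acceptance script uses 40 replicates for the δ = 0 sympatric null).
Interactive defaults remain 10,000 matrix permutations and 100,000
sign-flips.

## Known limitations

- The MRM permutation null tests full exchangeability of the response; with
  strongly collinear predictors the partial-coefficient test can be
  anticonservative. The default world keeps the geography–MT correlation
  near the realistic ~0.5, where calibration holds empirically (type-I
  tests in the suite).
- The pooled all-SGB analysis (stacking SGBs into one regression) is out of
  scope; no aggregation rule is defined here beyond the per-SGB screen. A
  stacked variant with SGB blocks would need block-aware permutations.
- PIC assumes Brownian trait evolution; no λ/OU transformations or
  phylogenetic GLS are provided.
- Quartile and tie conventions (linear interpolation; average ranks) are
  fixed and recorded; borderline outlier decisions can differ under other
  conventions.
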