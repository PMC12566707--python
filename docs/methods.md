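# Methods

`phyloresist` implements the analysis chain used to study how the expansion of
a dominant clonal invader (the motivating system is Moso bamboo,
*Phyllostachys edulis*, expanding into subtropical evergreen broadleaf forest)
reshapes plant community diversity, phylogenetic structure and species
dominance along a space-for-time gradient. This note documents the models,
conventions, parameters and known limitations; nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Study design the package assumes

Four expansion stages — bamboo-free (BF), low mixture (LM), high mixture (HM)
and monoculture (MB) — with 4 replicate 20 m × 20 m plots each (16 plots).
Expansion intensity is the invader's tree-layer cover fraction, scaled 0–1,
and is the gradient variable for every trend analysis. Vegetation is surveyed
in three strata: the tree layer at whole-plot grain, the shrub layer in five
5 m × 5 m subplots, the herb layer in twenty-five 1 m × 1 m quadrats. Soil
covariates per plot: pH, total organic carbon (TOC, g/kg), total nitrogen
(TN, g/kg), total phosphorus (TP, g/kg).

## Importance values

For species *i* in one plot layer,

    IV_i = (relative density + relative dominance + relative frequency) / 3,

each component in percent, so layer IVs sum to 100. Dominance is basal area
for trees and percent cover for the understory. Relative frequency divides
each species' subplot-occupancy fraction by the sum of those fractions.
Because the tree layer is surveyed at plot grain, every tree species present
has frequency 1 and the component reduces to 100/S — a structural property
with a visible consequence: a tree-layer species' IV lies between roughly
100/(3S) and (200 + 100/S)/3 no matter how rare or dominant it is. Species
occurring in both tree and shrub layers are distinct records per layer.

## Taxonomic α-diversity

Margalef (S−1)/ln N, Shannon–Wiener H′ = −Σ p_i ln p_i (natural log), Pielou
H′/ln S, and the finite-sample Simpson concentration
D = Σ n_i (n_i − 1) / (N (N − 1)). The *reported* Simpson index is the
complement 1 − D (Gini–Simpson): the complement form is the only reading
under which a monoculture scores 0 and more diverse communities score higher,
which is how the index behaves in the source tables this analysis emulates
(monoculture column 0, diverse stands ≈ 0.8). The raw concentration is also
exposed. Conventions for degenerate communities: Pielou is defined as 0 when
S = 1 (the 0/0 limit), Margalef as 0 when N = 1, Simpson complement 0 when
N = 1.

## Phylogenetic diversity and structure

Trees are rooted with branch lengths; no ultrametricity is assumed and
polytomies are kept as given. Any length attached above the root is ignored.

* **Faith's PD** is the branch-length sum of the minimal subtree spanning the
  community, *including the path to the root* (configurable). The inclusive
  convention is forced by the degenerate case: a one-species monoculture
  community must have positive PD (its root-to-tip distance), matching the
  nonzero monoculture PD the emulated tables report; the exclusive convention
  would give 0.
* **MPD / MNTD** are presence-based (unweighted) means of pairwise patristic
  distances and of nearest-taxon distances.
* **NRI / NTI** are −1 × the standardized effect size of MPD / MNTD against
  the taxa-labels null: community size fixed, species identities drawn
  uniformly without replacement from the pool — exactly the marginal
  distribution induced by uniformly permuting the label set of the distance
  matrix. Positive values mean phylogenetic clustering. The pool for each
  layer is every species observed in that layer across all plots. Default
  999 randomizations (configurable; the literature on this design uses both
  999 and 9999). Degenerate cases return 0 with a flag rather than NaN: a
  community of fewer than two species, or a point-mass null (community =
  pool), where "zero sd" is detected at a 1e-10 relative tolerance because a
  point mass still leaves float jitter in the sample sd.
* Reproducibility: one master seed; each (plot, layer) derives a child seed
  by CRC of its identifier, so results never depend on iteration order.

## Gradient and group statistics

* **Theil–Sen**: slope = median of all pairwise slopes over pairs with
  distinct x; intercept = median(y − slope·x) (the "joint" variant).
* **Mann–Kendall** against the cover gradient: S = Σ sgn(Δx)·sgn(Δy); τ is
  tie-corrected τ_b. For n ≤ 10 with no ties the p-value is the exact
  permutation probability; otherwise a normal approximation with Kendall's
  full both-variable tie-corrected variance and a continuity correction.
  Both-variable correction matters here because stage-replicated cover
  values tie in x.
* **Kruskal–Wallis + Dunn**: the KW p-value for pooled N ≤ 30 comes from the
  permutation null of H (9999 permutations, cached per rank configuration —
  the null depends only on group sizes and the pooled rank multiset). The χ²
  approximation is measurably conservative at 4 groups × 4 values and is
  retained only for larger samples. Dunn's z uses pooled-rank variance with
  tie correction; pairwise p-values are BH-adjusted, consistent with the
  global BH-FDR policy (applied within each layer × index family). A compact
  letter display is assigned greedily in stage order BF→MB.

## The Resistance Index

For each species occurring (stage-mean IV > 0) in at least 3 of the 4
stages,

    RI_i = β_i / D_i,

where β_i is the Theil–Sen slope of the species' IV against cover across all
16 plots (IV = 0 in plots where it is absent — required so monotone
disappearance yields a negative slope) and D_i is its patristic distance to
the invader (for two tips, the path length; identical to their mean pairwise
distance). Raw RI is z-standardized within each layer with sample sd
(ddof = 1; with ~20–30 species per layer the ddof choice is material and is
recorded in the output metadata); z ≥ +1 → Resistant, z ≤ −1 → Susceptible,
else Neutral. The invader itself is excluded (its distance is 0). Dividing
by D encodes the per-unit-effect expectation that an equal decline signals
stronger displacement in a close relative of the invader. A stage-means
variant of the slope (4 points) is available for sensitivity analysis;
all-plots is the default.

## Ordination and variance partitioning

RDA fits the response block (Shannon, PD, NTI per layer — complementary
taxonomic, basal-phylogenetic and tip-phylogenetic axes) on cover + soil
(pH, TOC, TN, TP) after z-standardizing both blocks (correlation-scale RDA;
the responses mix nats, branch-length units and z-scores). Constrained axes
are the SVD of the fitted values; eigenvalues use the n−1 denominator and
match `vegan::rda` exactly (verified against frozen vegan reference values in
the test suite). Explanatory power is Ezekiel-adjusted
R²aₙ = 1 − (1 − R²)(n − 1)/(n − m − 1), also matching `vegan::RsquareAdj`.
Significance: unrestricted row permutations of the predictors against the
pseudo-F (plots are the exchangeable unit; the design has no blocking);
per-term p-values permute one predictor column against its marginal R²
contribution. VIF is 1/(1 − R²_j) from regressing each predictor on the
rest; values < 5 are taken as acceptable collinearity.

VPA partitions the full model's adjusted R² into the fraction unique to
cover (full − adjR²(soil)), unique to soil (full − adjR²(cover)), and shared
(the remainder), with unexplained = 1 − full. Adjusted-R² fractions can be
slightly negative; machine output reports them raw, display clamps at 0, and
a normalized-to-explained view is provided because figure conventions in this
literature sometimes report percentages of *explained* variance.

## Synthetic gradient generator

The generator is the package's ground-truth instrument; its defaults are the
study conditions above.

* **Cover**: stage means (0, 0.30, 0.70, 1.0) with Gaussian jitter sd 0.03,
  clipped to [0, 1].
* **Phylogeny**: a pure-birth ultrametric tree over all species plus the
  invader (root depth 200 branch-length units); pendant edges are extended
  by 1% of depth (the simulator otherwise ends at a speciation event,
  leaving zero-length cherries). The invader tip is chosen as the candidate
  with the largest nearest-relative distance that still leaves a ≥ 4-fold
  spread of distances to the invader *within every layer* (layers are
  assigned by interleaving the distance ranks), keeping RI denominators
  well-conditioned while preserving the near/far contrast the RI needs.
* **Understory archetypes**: per 30-species layer, 3 decliners
  (target IV = A(1−c), A ≈ 20), 4 increasers (A·c, A ≈ 15) and 23 flat
  species sharing the remaining IV budget. Per-species heterogeneity
  (±25%) is renormalized within archetype so 3·20 = 4·15 keeps the layer
  total at exactly 100 for every cover. Archetype assignment is stratified
  over distance-to-invader quartiles so slope and distance are not
  confounded. Increasers are absent at BF and decliners at MB, so both pass
  the ≥3-stage filter.
* **Tree layer**: the invader's stem share equals cover; natives split the
  remainder in fixed proportions. Latent truth lives in stem-share space
  because plot-grain frequency makes IV = (200·share + 100/S)/3 — an IV
  target proportional to share alone is geometrically unrealizable there.
  MB native targets are exactly zero: the monoculture tree layer contains
  the invader only. True native IV slope is −2A/3 for baseline share A/100.
* **Realization**: plot-level Gaussian IV noise (sd 1 IV point) on the
  targets; species are recorded as integer counts (120/240/600 individuals
  per tree/shrub/herb layer) and integer subplot hits, while the continuous
  dominance column absorbs the discretization, so realized IV equals the
  noisy target wherever non-negativity allows. Below the integer floor
  (count ≥ 1, hits ≥ 1; in practice targets under ~1–2 IV points) dominance
  clamps at 0 and deviations stay bounded (< 0.5 IV points) — demonstrated
  exactly in tests at a reduced-richness configuration where no species sits
  below the floor.
* **Soil**: pH = 4.39 + 0.85·c, TOC = 30.74 − 13.67·c, TN = 2.13 − 0.65·c,
  TP = 0.225 (no trend), with Gaussian noise sds 0.13, 2.0, 0.18, 0.045 —
  anchored to the observed stage means and spreads of the motivating system
  so trend tests run at realistic effect sizes.
* **Truth record**: per species the archetype, true β, distance to the
  invader, true RI = β/D, its within-layer z-score and the implied class.
  "Strong-effect" species are those whose *true* standardized RI crosses the
  ±1 thresholds; recovery tests score the estimator against these labels, so
  they measure estimation error rather than the geometry of the archetype
  mix. Every dataset is a deterministic function of (config, seed).

### What the generator does not emulate

Spatial structure and autocorrelation between neighbouring plots; clonal
spread dynamics of the invader; observation error in the covariates;
non-monotone (hump-shaped) species responses; shared species between layers;
phylogenetic signal in the response archetypes beyond the stratified
assignment. Passing recovery tests therefore shows the estimators work under
the design's statistical assumptions, not that field data meet those
assumptions.

## Numerical choices and degenerate inputs

* IV totals are summed over species in sorted-name order so results are
  independent of record order; PD edge sums are collected in a fixed
  traversal order (float addition is not associative — this is what makes
  reruns byte-identical).
* All-identical gradient values raise a distinct degenerate-input signal;
  all-identical group values return H = 0, p = 1.
* A resistance layer with zero RI spread classifies everything Neutral with
  a degeneracy flag instead of dividing by zero.
* Negative VPA fractions are reported raw and clamped only for display.
* Problem sizes in tests are chosen to keep exhaustive oracles exact:
  null-model enumeration on pools ≤ 7 taxa, Mann–Kendall permutation
  enumeration at n ≤ 8, 2000-replicate calibration for the Kruskal–Wallis
  size, 200-replicate calibration for the RDA permutation test.

## Known limitations

* The taxa-labels null is the only null model; frequency- or
  occupancy-preserving randomizations are out of scope.
* Per-term RDA p-values use a simple column-permutation scheme; restricted
  permutation designs (blocks, strata) are not implemented.
* The herb layer's "abundance" is ramet counts; cover-based pseudo-counts
  are accepted input but no automatic conversion is attempted.
* RI assumes the IV–cover relationship is monotone enough for a single
  Theil–Sen slope to summarize; hump-shaped responders are misranked by
  construction.
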