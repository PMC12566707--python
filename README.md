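# phyloresist

Community-phylogenetics toolkit for **invader-expansion gradients**: who
loses, who persists, and what drives the change when a dominant clonal
invader (the motivating case is Moso bamboo, *Phyllostachys edulis*,
expanding into subtropical evergreen broadleaf forest) takes over a plant
community.

It is written for plant community ecologists working with stratified plot
surveys (tree/shrub/herb layers) along a space-for-time expansion gradient —
four stages from invader-free (BF) through low (LM) and high (HM) mixtures to
monoculture (MB), replicated plots per stage — plus a rooted community
phylogeny and plot-level soil covariates.

## What it computes

* **Importance values** per species, plot and layer:
  IV = (relative density + relative dominance + relative frequency)/3, in
  percent, summing to 100 per layer.
* **Taxonomic α-diversity**: richness, Margalef (S−1)/ln N, Shannon–Wiener
  H′ = −Σ pᵢ ln pᵢ, Gini–Simpson 1 − Σ nᵢ(nᵢ−1)/(N(N−1)), Pielou H′/ln S.
* **Phylogenetic diversity and structure**: root-inclusive Faith's PD, MPD,
  MNTD, and the null-model z-scores NRI = −(MPD_obs − MPD_null)/sd(MPD_null)
  and NTI (likewise from MNTD) under the taxa-labels randomization.
* **Gradient statistics**: Theil–Sen slopes with Mann–Kendall/τ_b tests
  against invader cover (scaled 0–1), Kruskal–Wallis + Dunn post hoc across
  stages, BH-FDR correction.
* **Resistance Index** (the headline statistic): for each species present in
  ≥ 3 of the 4 stages,

  RIᵢ = βᵢ / D(i, invader)

  — its Theil–Sen IV-vs-cover slope divided by its patristic distance to the
  invader, z-standardized within layer; z ≥ +1 Resistant, z ≤ −1 Susceptible,
  otherwise Neutral.
* **Drivers**: redundancy analysis (RDA) of (Shannon, PD, NTI) on cover +
  soil with permutation tests, Ezekiel-adjusted R² and VIF screening, and
  variance partitioning (VPA) into cover-unique, soil-unique and shared
  fractions.
* **Synthetic gradients**: a generator that emulates the full design (16
  plots, three response archetypes, soil trending with cover, a random
  ultrametric phylogeny with near and distant relatives of the invader) and
  ships ground truth for every quantity, so the whole chain is testable
  end to end. See `docs/methods.md` for the model details.

## Worked example

```python
import phyloresist as pr

surveys, tree, truth = pr.generate_dataset(pr.GeneratorConfig(seed=7))
results = pr.ResistanceModel(surveys, tree, pr.INVADER).fit()
print(results.summary())
```

```
Resistance Index results
  invader: Phyllostachys_edulis
  species scored: 80  (skipped: 1)
   tree:  20 species | Resistant 0, Neutral 18, Susceptible 2
  shrub:  30 species | Resistant 1, Neutral 27, Susceptible 2
   herb:  30 species | Resistant 1, Neutral 28, Susceptible 1
   species layer     beta  dist_to_invader  ri_raw    ri_z       class  ...
 herb_sp02  herb  19.3222          65.4226  0.2953  3.5036   Resistant  ...
 herb_sp12  herb  14.7869         304.1545  0.0486  0.5902     Neutral  ...
```

Reading it: `herb_sp02` gains ~19 IV points per unit of invader cover
(`beta`) *and* is a close relative of the invader (distance 65 vs ~300 for
its peers), so its per-unit-relatedness response `ri_raw = beta/dist` is an
order of magnitude above the layer's spread — z-score 3.5, classified
Resistant. Canopy species that vanish toward the monoculture come out with
negative β and, if related to the invader, strongly negative z → Susceptible.

The drivers analysis on the same data:

```python
from phyloresist.pipeline import diversity_table, phylo_table, ordination_per_layer

div = diversity_table(surveys)
phy = phylo_table(surveys, tree, n_randomizations=199, seed=7)
metrics = div.merge(phy[["plot_id", "layer", "pd", "nri", "nti"]],
                    on=["plot_id", "layer"])
ords = ordination_per_layer(metrics, surveys, n_permutations=199, seed=7)
print(ords["tree"]["rda"].summary())
print(ords["tree"]["vpa"].as_dict())
```

```
Redundancy analysis
  responses:  shannon, pd, nti
  predictors: cover, pH, TOC, TN, TP
  R^2 = 0.7273   adjusted R^2 = 0.5910   global p = 0.0050 (199 permutations)
  axis % of constrained variance: 83.9, 14.9, 1.2
  ...
{'unique_cover': -0.011, 'unique_soil': 0.057, 'shared': 0.545, 'unexplained': 0.409}
```

The tree-layer diversity block is well explained (adjusted R² 0.59, global
permutation p = 0.005), and the variance partition attributes most of the
explained variance to the *shared* cover×soil fraction (0.545) rather than to
either predictor set uniquely — the expected signature when soil change is
itself driven by the invader's expansion. (The small negative cover-unique
fraction is a normal property of adjusted-R² partitions; display output
clamps it at 0.)

## Command line

```bash
phyloresist generate --seed 7 --out data/          # synthetic dataset + truth
phyloresist all --seed 7 --out run/                # full pipeline
phyloresist all --survey s.csv --covariates c.csv --tree t.nwk --out run/
```

`run/` receives tidy CSV/JSON outputs for every stage (importance values,
diversity, phylogenetic structure, trends, Dunn letters, resistance records,
ordination and VPA) plus a `manifest.json` with the seed, configuration and
output checksums; reruns with the same configuration are byte-identical.

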