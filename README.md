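# copeind — copepod community / water-mass indicator analysis

`copeind` is a Python pipeline for the classic question in coastal
biological oceanography: *which zooplankton taxa mark which water mass?*
It targets station-by-taxon copepod surveys of the kind run off
northeastern Taiwan during the northeast monsoon, where monsoon-driven
cold surface water, Kuroshio intrusion water and their mixture meet, and
it bundles every statistical stage of that analysis:

* **Dominance statistics** — per-taxon mean abundance `MA_i`, relative
  abundance `RA_i = 100·MA_i / Σ_i MA_i` and occurrence rate `OR_i` (% of
  stations with the taxon present), plus order-level composition
  (Calanoida / Cyclopoida / Harpacticoida / Poecilostomatoida) in which
  copepodite categories count toward abundance but not species number.
* **Water-mass clustering** — Bray-Curtis dissimilarity
  `d(a,b) = Σ_v|a_v−b_v| / Σ_v(a_v+b_v)` on the four hydrographic
  variables (temperature, salinity, dissolved oxygen, pH), complete-
  linkage agglomeration cut into *k* groups, within-group percent
  similarity, and a Clarke-style similarity-profile (SIMPROF) permutation
  test with statistic `π = Σ_r |s_(r) − s̄_(r)|`.
* **Group tests** — one-way ANOVA on per-station total abundance and
  Tukey–Kramer pairwise comparisons via the studentized-range
  distribution.
* **Indicator values** (Dufrêne–Legendre) — specificity
  `A_ij = N̄individuals_ij / Σ_j N̄individuals_ij`, fidelity
  `B_ij = Nsite_ij / Nsite_j`, `IndVal_ij = 100·A_ij·B_ij`, indicator
  selection at IndVal > 50%, optional label-permutation p-values, and a
  consistency solver that reconstructs the unknown group sizes behind a
  *published* IndVal table by brute force.
* **Constrained ordination** — a DCA gradient-length gate (first-axis
  length < 3 SD of species turnover ⇒ linear methods) followed by RDA of
  dominant-taxon abundances on the standardized environmental variables,
  with deterministic sign conventions and correlation biplot scores.
* **A synthetic community generator** — ~25 stations in three water
  masses with group-specific environmental profiles, right-skewed
  lognormal abundances, and *planted* indicator species with chosen
  specificity `A*` and fidelity `B*`, so every downstream stage can be
  verified against ground truth.

The library follows a statsmodels-like shape: model classes
(`EnvClustering`, `AbundanceAnova`, `IndicatorValueModel`, `DCA`, `RDA`)
are built from validated data containers and `fit()` returns a results
object with estimates, diagnostics and a `summary()`.

## Worked example

```python
import copeind as ci

abund, env, taxa, truth = ci.generate(ci.SyntheticDesign(seed=5))
clust = ci.EnvClustering(env).fit(k=3, simprof_permutations=999, seed=5)
print(clust.summary())
```

```
Environmental Bray-Curtis clustering (complete linkage)
  stations: 25   groups: 3   standardized: False

 group    n  similarity %       pi        p
     A    6         99.43     0.54   0.4210
     B   11         99.64     0.60   0.5510
     C    8         99.58     0.48   0.5550
```

Groups are labelled A/B/C by descending mean dissolved oxygen, so A is
the cold, oxygen-rich monsoon water and C the warm Kuroshio intrusion;
within-group similarities in the high-90s are typical of raw-unit surface
hydrography. Continuing with the indicator analysis:

```python
iv = ci.IndicatorValueModel(abund, clust.partition).fit()
print(iv.summary())
```

```
Indicator-value analysis (121 taxa, 3 groups)
indicators with IndVal > 50%:
  group A: Calanopia elliptica (72.22), Canthocalanus pauper (70.43), Temora turbinata (68.69), ...
  group B: Paracandacia truncata (61.63), Paracalanus aculeatus (60.99), Cyclopoid sp. 03 (60.93), Oncaea clevei (58.37)
  group C: Farranula concinna (95.73), Copilia mirabilis (83.33), Candacia aethiopica (65.21)
```

All nine planted indicator species are recovered in their true water
masses (the `Calanoid sp. 06`-style extras are background taxa that
concentrate in one group by chance — expected at 25 stations). The
numbers in parentheses are IndVal percentages: e.g. *Farranula concinna*
at 95.73 is present at nearly every group-C station and almost nowhere
else.

The same objects drive the rest of the pipeline (`ci.AbundanceAnova`,
`ci.DCA`, `ci.RDA`), or run everything at once from a shell:

```sh
copeind simulate --out survey --seed 5
copeind run-all --abundance survey/abundance.csv \
    --environment survey/environment.csv --taxa survey/taxa.csv \
    --out results --seed 5
```

which writes per-stage CSVs, a dendrogram in Newick text, and a
`summary.json` with group sizes, indicator lists and the RDA proportion
constrained.

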