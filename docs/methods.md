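# Methods

This note documents the statistical machinery in `copeind`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not establish about real surveys.

## Data model

A survey is three tables: a station × taxon abundance matrix in
individuals m⁻³, a station × environment table (temperature °C, salinity
PSU, dissolved oxygen mg/L, pH), and a taxon → order map with a
copepodite flag. Validation is strict: finite non-negative abundances,
unique case-sensitive identifiers, physically sensible environmental
ranges, a four-order copepod vocabulary, and identical station sets
across tables used jointly. Missing cells are errors — the analyses have
no missingness model, and silent imputation would bias every downstream
rate. CSV is the only interchange format (comma, UTF-8, `.` decimal,
mandatory header); numeric parsing goes through Python's
correctly-rounded float parser so that write→read round-trips
bit-exactly.

## Dominance statistics

`RA_i` is defined as the ratio of station-averaged abundances,
`100·MA_i/Σ MA_i`, *not* as the station-wise RA averaged over stations.
The two differ whenever station totals vary; the ratio-of-means form is
the one consistent with published community tables (e.g. a taxon with
MA 217.24 in a community totalling 774.24 ind m⁻³ has RA 28.06%), and it
makes `Σ RA = 100` an exact identity. Presence for `OR` means abundance
strictly > 0. The dominance cut defaults to RA ≥ 2.0%, the conventional
boundary between listed dominants and the unlisted tail.

## Environmental clustering

Bray-Curtis is computed on the four variables in **raw units** by
default. This is deliberate: with salinity ≈ 34 PSU dominating the
denominator, realistic coastal surface data yield within-group
similarities of 97–99%, the scale on which published water-mass
dendrograms report. A `standardize` option applies min–max range scaling
(keeping values non-negative, as Bray-Curtis requires) for data where
variables should contribute equally; z-scoring is refused because it
produces negative values for which the coefficient is undefined.

Agglomeration is complete linkage on the dissimilarity matrix, cut into
`k` groups (`k = 3` by default; no automatic selection). A phrase such
as "complete linkage for k-means cluster analysis" in survey reports is
internally contradictory — k-means cannot consume a Bray-Curtis matrix —
and is resolved here as agglomerative complete linkage cut at `k`.
Stations are sorted lexicographically before linkage so equal-height
merges resolve deterministically. Merge heights equal the maximum
within-cluster dissimilarity by construction. Group labels A, B, C, …
are assigned by descending group-mean dissolved oxygen, putting the
cold, oxygenated monsoon-derived water first and the warm oxygen-poor
intrusion last.

SIMPROF follows Clarke's construction: the observed ordered similarity
profile is compared with its rank-wise mean over permutations that
shuffle **each environmental variable independently across stations**;
`π` is the summed absolute departure on the percent-similarity scale and
the p-value uses the `(1 + #{π_perm ≥ π_obs})/(1 + n_perm)` correction,
making it valid (conservative) under the null. The exact permutation
scheme behind published π values is rarely stated; this one is the
standard interpretation, and its p-values are verified to be uniform
under an i.i.d.-columns null. π magnitudes depend on the similarity
scale and profile length, so published π values are not comparable
across implementations and are not reproduction targets.

## Group tests

One-way ANOVA uses the classical between/within decomposition
(`SSB + SSW = SST` is asserted to 1e-9 relative). Pairwise comparisons
use the Tukey–Kramer statistic
`q = |ȳ_j − ȳ_k| / sqrt(MSW(1/n_j + 1/n_k)/2)` — the unbalanced-groups
form, since water-mass groups are rarely equal-sized — with adjusted
p-values from the studentized-range distribution (scipy evaluates its
CDF by direct numerical quadrature; agreement with a 10,000-draw
Monte-Carlo check and with the `k = 2` t-test identity to 1e-4 is part
of the suite). Zero within-group variance with unequal means yields a
flagged boundary p of 0.

## Indicator values

`IndVal_ij = 100·A_ij·B_ij` with specificity
`A_ij = N̄_ij / Σ_j N̄_ij`, where `N̄_ij` is the arithmetic mean abundance
of taxon *i* over **all** sites of group *j* — zero-abundance sites
included. This is the standard Dufrêne–Legendre definition, and it is
the only reading that reproduces published values exactly (e.g. group
means (8.74, 21.31, 8.56) with full fidelity give 100·21.31/38.61 =
55.19). Fidelity counts sites with abundance strictly > 0; there is no
minimum-abundance presence threshold. Indicator selection is strictly
greater-than the threshold (default 50%). Taxa absent everywhere get
IndVal 0 and a flag rather than NaN. Permutation inference shuffles
station labels and compares each observed value against the permuted
distribution of the taxon's maximum group IndVal, again with the +1
correction.

The consistency solver inverts a *published* IndVal table: given printed
per-group mean abundances and IndVal percentages but unknown group
sizes, it enumerates every composition of the station total and every
integer presence count, scoring each composition by the worst absolute
residual between recomputed and printed IndVal. On the reference table
shipped with the package the unique best composition over 25 stations is
(6, 11, 8) with max residual 0.204 — within the ≤ 0.25 budget implied by
2-decimal rounding of the printed abundances, with the runner-up at
2.65. The (6, 11, 8) split used throughout the defaults is *derived*
this way, not printed in any source; single-taxon tables with fidelity 1
are correctly reported as unidentifiable.

## Ordination

**DCA.** Correspondence-analysis axes are extracted by reciprocal
averaging (tolerance 1e-10, ≤ 1000 iterations); axes ≥ 2 are detrended
against earlier axes by 26-segment running-mean subtraction. Hill-style
nonlinear rescaling puts axes on the species-turnover scale: the axis is
locally stretched by the inverse of the within-site weighted SD of
species scores (26 segments, 4 iterations), so one unit ≈ one SD of
turnover and the axis length is the site-score range. With detrending
and rescaling off, the run reduces exactly to CA (verified against an
independent CA implementation). On noise-free Gaussian coenoclines the
first-axis length recovers a 4-SD gradient within 25% and keeps a 1.5-SD
gradient below the gate; the method runs ~15–60% *high*, especially on
short gradients where weighted-average species scores are compressed
toward the ends — a conservative bias for the gate, since short
gradients are what the gate must detect, but worth remembering when
comparing absolute lengths across implementations.

**Gate semantics.** The pipeline computes the DCA first-axis length and
proceeds to RDA when it is < 3 SD; otherwise it warns rather than
errors, because the unimodal alternative (CCA) is out of scope.

**RDA.** Species columns are centred (optionally unit-scaled, or
Hellinger-transformed first); predictors are standardized, with a
condition-number guard (> 1e10 ⇒ error) against collinearity. Canonical
axes come from the SVD of the least-squares fitted species matrix;
eigenvalues use the 1/(n−1) convention so canonical + residual
eigenvalues equal the total species variance (asserted to 1e-8
relative). Scores follow a correlation-biplot (scaling 2) convention:
linear-combination site scores have unit variance per axis, species
scores carry the √eigenvalue magnitude (so `lc @ speciesᵀ` reconstructs
the fitted matrix), weighted-average site scores are the species-space
projections, and environmental biplot scores are plain correlations
with the lc scores (all in [−1, 1]). Axis signs are fixed so each
axis's largest-magnitude species loading is positive — eigenvector sign
ambiguity otherwise breaks regression tests. The default species
transformation is none (centring only), matching analyses that report
direct abundance–environment correlations; Hellinger is a flag.

## Synthetic community generator

The generator emulates a late-autumn 25-station survey in three water
masses, with defaults taken from the emulated survey wherever it prints
a value and chosen once otherwise:

* **Design.** Group sizes (6, 11, 8) — the solver-derived split (see
  above; the total of 25 follows from all published occurrence rates
  being multiples of 4%). Environmental profiles per group are the
  published means ± SDs (e.g. group A 22.78 ± 0.58 °C and 7.07 ± 0.08
  mg/L dissolved oxygen; group C 26.52 ± 0.63 °C); each station draws
  independently and normally from its group profile.
* **Planted indicators.** Nine defaults patterned on the survey's
  indicator species, three per water mass, with `A*`, `B*` and mean
  abundances in the published range. A planted taxon occurs at each
  target-group station with probability `B*`, lognormal about its mean
  when present; its expected off-group group-mean is set to
  `B*·m·(1−A*)/(A*·(G−1))` per other group (occupancy 0.7 there), so
  the *expected* specificity equals `A*`. `A* = 0` with positive
  in-group abundance is rejected as infeasible.
* **Background community.** 108 species + 13 copepodite categories in
  the published 68/33/4/3 order split; a dominant "Calanoid copepodites"
  category at 217.24 ind m⁻³; remaining mean abundances drawn from a
  heavy-tailed lognormal (σ = 1.6 across taxa) scaled so the expected
  survey-wide total is 774.24 ind m⁻³. Abundance is density, not counts,
  so noise is lognormal (σ = 0.6 per station-taxon) rather than
  negative-binomial; occupancy rises with abundance
  (`0.6 + 0.2·log10(mean)`, clipped to [0.2, 1]); a station-level
  lognormal factor (σ = 0.25) reproduces the observed spread of station
  totals (≈ 280–1500 ind m⁻³).
* **Seeding.** One integer seed drives one `numpy` generator; identical
  seeds give byte-identical files. Ground truth (true partition,
  realized A/B/IndVal recomputed with the package's own IndVal
  machinery) is emitted alongside.

**What passing tests show — and do not.** The generator draws each
station independently; real hydrography is spatially autocorrelated,
real communities have taxon–taxon covariance, and real abundances carry
sub-sampling (counting) error, none of which is modelled. Ground-truth
recovery on synthetic data therefore demonstrates the *correctness of
the statistics*, not field performance. One consequence is worth
stating explicitly: under independent normal draws from the published
group profiles, the group A and B temperature distributions
(22.78 ± 0.58 vs 24.31 ± 0.37 °C, a 2.6-SD gap) interleave in roughly a
quarter of realisations, so exact recovery of the planted partition by
clustering happens in only ~36% of seeds. With profiles separated by
≥ 3 SD on temperature the same pipeline recovers the partition in
≥ 95% of seeds. Real water masses are spatially coherent, which is why
the field survey's stations clustered cleanly while the independence
assumption here cannot guarantee it.

## Problem sizes

Validation suites run at desk scale by choice: 25-station default
surveys; a (60, 70, 70)-station, 20-indicator design for parameter
recovery; 100 seeds for recovery rates; 200 replicates × 199
permutations for the uniformity checks of both permutation tests; RDA
oracles at 20 × 8. These sizes give stable pass/fail behaviour under
the fixed seeds used.

## Known limitations

* No CCA, partial RDA, variance partitioning, or permutation tests of
  RDA axes; no diversity indices; no multi-group (site-combination)
  IndVal.
* DCA lengths are implementation-sensitive at the ±20% level (segment
  counts, smoothing, rescaling iterations); treat the <3 gate, not the
  absolute length, as the decision output.
* The consistency solver assumes the printed table used the same IndVal
  definitions as this package (it did, to within 2-decimal rounding, on
  the shipped reference) and that every group size is at least 1.
* Bray-Curtis on raw units weights variables by their physical scale;
  that is faithful to the emulated analysis but means temperature
  dominates the clustering signal for surface seawater.
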