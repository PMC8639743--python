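# Methods

This note documents the statistical model behind `lifegaps`, the defaults
and their rationale, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Outcome definitions

Age at death is fractional: exact day count between birth and death
divided by 365.25. Cohort life expectancy at birth (LEB) is attributed by
(birth year, gender) from a user-supplied life table; lookups are strict —
a missing (year, gender) key raises rather than interpolating, because the
life tables this pipeline expects span every relevant birth year and a gap
signals malformed input. YPLLG is `age − LEB` (signed years); YPLL is
`max(0, 75 − age)`. Fractional ages are deliberate: published YPLLG
summaries carry one-decimal precision, which integer ages cannot produce.

## Spatial weights

Distance-band weights with a 1200 m radius, boundary inclusive, binary and
row-standardized (`w_ij = 1/|N(i)|`), so the spatial lag is the unweighted
mean over neighbors — the convention of the GeoDa/rgeoda family, and the
reading of "the mean of this variable in a given neighborhood".
Coincident coordinates (shared buildings) are valid neighbors at distance
zero. Points without a neighbor in the band are excluded from the
analysis: they receive no statistic and the label `NEIGHBORLESS`. The
1200 m radius follows the epidemiological precedent for the urban region
that motivated the pipeline; it is a parameter (`radius_m`) everywhere.

## Local Moran and conditional permutation inference

The centering mean and the moment `m2` are computed over analyzed
(non-neighborless) points only, since neighborless points take no part in
the analysis. The algebraic identity `mean(I_i) = global Moran's I`
(row-standardized) is enforced by test to 1e-12.

For inference, each point holds its own value fixed and draws its `|N(i)|`
neighbor values uniformly without replacement from the other `n−1`
observed values, M times (the study-scale default is 99,999). The pseudo
p-value `(R+1)/(M+1)` counts permutations at least as extreme as the
observed statistic *in the tail matching the sign of the observed I_i*:
concordant clusters (HH and LL both have positive I) are tested in the
upper tail, discordant outliers in the lower. Two consequences worth
knowing:

- **The directional p behaves two-sidedly under the null**: because the
  tail is chosen after seeing the sign, P(p ≤ t) ≈ 2t for iid data, so
  Bonferroni control at overall α gives an effective family-wise level of
  at most 2α. This matches the referenced implementation's behavior; the
  test suite asserts the 2t bound empirically.
- **The permutation floor**: p can never fall below `1/(M+1)`. Any point
  can reach Bonferroni significance only if `M+1 > n/α`. With n = 10,000
  and α = 0.1 that requires M ≥ 99,999 — the reason the study-scale
  protocol uses that many permutations, and the reason desk-scale runs in
  the tests use smaller n with M chosen to keep the floor below α/n.

The conditional expectation of the permuted statistic is
`−z_i²/(m2·(n−1))` for row-standardized weights (the mean of the remaining
n−1 deviations is `−z_i/(n−1)`); the engine's Monte-Carlo mean is checked
against this closed form. Permutations are independent across points;
each point gets its own substream spawned from the master seed and keyed
by point index, so results do not depend on evaluation order. The inner
sampling loop is a numba-compiled partial Fisher–Yates shuffle, O(M·k) per
point.

The number of Bonferroni tests is the number of observations passed to
the run (not the analyzed subset), matching the published convention
α/n-observations; with α = 0.1 and n = 10,000 the per-test level is 1e-5.
Significance is strict (`p < threshold`); a significant point with exactly
zero deviation or lag (a measure-zero tie) falls back to `NS`. Quadrant
labels follow the conventional orientation — first letter the point,
second its neighborhood — so `LH` is a short-lived individual among
long-lived neighbors.

## Median-regression adjustment

Adjusted YPLLG is the raw residual of a τ = 0.5 quantile (LAD) regression
of YPLLG on: Swiss-nationality indicator, neighborhood median household
income (kCHF — pure conditioning rescale; residuals are invariant to it),
and neighborhood median population age. Gender and age are excluded
because they already define LEB. Income enters untransformed. Residuals
are not re-centered. The fit minimizes Σ|y − Xβ| exactly via linear
programming (HiGHS), which is deterministic given the data; when the LAD
solution is non-unique (degenerate LP ties) any optimal vertex is
accepted. Rank-deficient designs raise an error naming the collinear
columns. The first-order condition puts the residual median at numerical
zero, and roughly half the residuals at or below zero (within about
⌈k/2⌉ of n/2); both are asserted in tests, along with coefficient
agreement with an independent quantile-regression implementation.

## Neighborhood covariates

Median population age per (subsector, year) comes from 5-year grouped
counts via the classical interpolation `L + ((N/2 − CF)/f)·h`, with the
open 100+ class folded to [100, 105) under the assumption that nobody
lives past 105 (equal class widths are required by the formula).
Covariates attach at the record's subsector for the year of death. A
missing (subsector, year) cell borrows the nearest subsector *for the
same year* by centroid Euclidean distance — spatial, not temporal,
fallback, since the source description says "nearest neighborhood" —
with equidistant ties broken by the lexicographically smallest subsector
id for determinism. A provenance flag records every fallback.

## Exclusion cascade

Filtering applies, in order: death year inside the study window;
duplicates and records missing birth date, death date, or nationality
(one combined step — the published accounting reports them jointly);
outside the region boundary (boundary-inclusive point-in-polygon);
no coordinates; unresolved gender. A duplicate is an identical (gender,
birth date, death date, location) tuple, first occurrence kept. The
ledger stores (step, removed, remaining) and enforces the telescoping
identity; filtering the kept set again removes nothing. Gender may arrive
as a column or from a user-supplied given-name lookup; unmatched names
stay missing and are removed by the cascade, never guessed.

## The synthetic-data generator

The generator emulates the statistical shape of the urban death-notice
dataset the pipeline was designed for, with defaults calibrated once to
its printed profile:

- **YPLLG noise**: skew-normal with shape −50 (≈ negated half-normal),
  location/scale solved in closed form from target mean 5.19 and sd 20.12
  years; the implied median (≈ 9.3) and left skew match the observed
  distribution. A negated log-normal was considered and rejected: its
  hard upper bound (≈ +10.8 y at these moments) contradicts the observed
  maximum of ≈ +50 y.
- **Life table**: linear in birth year (base 68.7 y at 1900 for men,
  +0.1 y/birth-year, women +4 y), which puts the mean realized lifespan
  near 79.4 y for deaths in 2009–2016.
- **Demographics**: 53.3% women; Swiss share 79.6% with a west–east
  gradient (±0.15).
- **Neighborhoods**: a subsector grid with income rising west to east
  (mean 128,012 CHF, spread ≈ ±40 kCHF across subsectors) and median
  population age rising south to north (mean ≈ 43 y, sd ≈ 10 y);
  5-year age-group counts are drawn from a capped normal age profile.
- **Planted structure**: circular clusters whose members live
  `cluster_effect_years` longer (high) or shorter (low) than expected;
  cluster membership is geometric (within the disc), and truth labels
  plus the exact planted deviation are returned for recovery testing.
- **Covariate effects** act on deviations from the population mean of
  each covariate, so they reshape the spatial field without shifting the
  overall YPLLG level. During generation they use the subsector's
  year-averaged panel values (the death year is not yet known at that
  point); downstream attachment uses the actual death year — the
  within-subsector year-to-year variation is ~1%, so the mismatch is
  negligible against the noise scale.

Dates are generated by rejection: birth dates are drawn uniformly, ages
set to LEB + deviation (resampled if negative, capped at 105), and the
pair kept only when the death year lands in the study window — so birth
date, death date, gender and LEB are exactly consistent by construction.
Because calendar dates have day granularity, the recomputed fractional
age differs from the generated one by up to half a day; with all effects
and noise off, YPLLG is zero to within 1/365.25 years rather than exactly.

What the generator does **not** emulate: real street-network geography,
within-subsector income heterogeneity, cause-of-death structure,
migration (the last residence standing in for lifetime exposure), or
non-Swiss life-table mismatch. Passing tests therefore demonstrate the
statistical machinery — recovery of planted spatial structure under a
realistic outcome distribution — not epidemiological validity on any
particular real dataset.

## Study protocol and problem sizes

Subsets are simple random draws without replacement, independent across
subsets (a record may appear in several subsets). The median regression
is refitted within each subset so every subset's adjusted analysis is
self-contained. Cluster summaries report range/mean/sd across subsets per
label; a subset where a label is absent contributes a zero count and is
excluded from that label's mean-characteristic aggregation. Tukey's HSD
(Tukey–Kramer for unequal group sizes, family level 0.05) compares all
label pairs; groups with fewer than two observations are dropped with a
warning. Footprint reduction is `100·(n_raw − n_adj)/n_raw` per label
from mean counts across subsets; a single-subset basis is available as an
option because a reduction can legitimately be quoted from one
representative subset as well as from the mean.

Adjustment does not always shrink planted clusters: removing
covariate-explained variance lowers the residual scale, which *raises*
the relative size of a purely location-driven effect — footprints shrink
when covariates partially explain the clusters, and can persist or
sharpen when they do not. The acceptance scenario therefore mixes a
moderate location-only planted effect with strong covariate gradients.

The test suite and the acceptance script run everything at desk scale —
populations of 300–22,751, subsets of ~1,000, permutation counts of
999–20,000 chosen so the permutation floor stays below the Bonferroni
threshold — sizes selected to exercise each property with adequate power
while keeping a full run to a few minutes on one CPU. The study-scale
defaults (10 × 10,000 subsets, 99,999 permutations) remain the
package defaults for real analyses.

## Known limitations

- The directional pseudo p doubles the nominal family-wise level (see
  above); users wanting strict α control should halve `alpha`.
- No FDR alternatives to Bonferroni, and no other LISA statistics
  (Getis–Ord G*, local Geary) — out of scope by design.
- LEB attribution requires a complete life table over all observed birth
  years; there is deliberately no interpolation.
- The covariate fallback searches within the death year only; if an
  entire year is absent from the panel, attachment fails loudly.
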