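# lifegaps

Spatial cluster detection for life-expectancy inequality from individual,
georeferenced death records.

National life expectancy can hide large disparities between neighborhoods.
`lifegaps` implements an individual-level (point-based) analysis of those
disparities, avoiding the zoning sensitivity of aggregated small-area
studies (the modifiable areal unit problem): each deceased person is scored
by how much longer or shorter they lived than their birth cohort's
expectation, and local concentrations of unusually short- or long-lived
individuals are mapped with a local spatial-autocorrelation statistic.

## The method

**Outcome.** For individual *i* with age at death *aᵢ* and cohort life
expectancy at birth *LEBᵢ* (looked up by birth year and gender),

- YPLLG (years of potential life lost or gained): `yᵢ = aᵢ − LEBᵢ`
  (signed; positive means the person outlived their cohort expectation);
- YPLL (classical premature-mortality indicator): `max(0, 75 − aᵢ)`.

**Spatial structure.** With distance-band weights `w_ij = 1/|N(i)|` over
neighbors within 1200 m of each residence (boundary inclusive), the Local
Moran statistic at location *i* is

```
I_i = (z_i / m2) * Σ_j w_ij z_j,   z_i = y_i − ȳ,   m2 = Σ z_i² / n
```

Significance comes from conditional permutations: `y_i` stays fixed while
its neighbor positions receive M random draws (without replacement) from
the other observed values; the pseudo p-value is `(R+1)/(M+1)` with R the
number of permuted statistics at least as extreme as the observed one, in
the tail matching the sign of the observed `I_i`. Multiple testing is
Bonferroni-controlled (per-test level `α/n`, default `α = 0.1`), and
significant points are labeled by Moran-scatterplot quadrant: `HH`
(long-lived among long-lived), `LL` (short-lived among short-lived), and
the spatial-outlier types `LH`/`HL`. Points with no neighbor inside the
band are flagged `NEIGHBORLESS` and excluded.

**Adjustment.** To ask how much of the footprint is explained by who lives
where, the same analysis is re-run on adjusted YPLLG: residuals of a
median (least-absolute-deviations, τ = 0.5) regression of YPLLG on a Swiss
nationality indicator, neighborhood median household income, and
neighborhood median population age (gender and age are already inside
LEB, so they are not covariates). The LAD fit is solved exactly as a
linear program.

**Robustness.** The full protocol repeats both runs on k random subsets
(defaults: 10 subsets of 10,000), summarizes the population inside each
cluster type as range/mean/sd across subsets, compares cluster-type means
with Tukey's HSD, and reports the percent shrinkage of the LL and HH
footprints after adjustment.

A synthetic-data generator produces georeferenced death records with
planted high-/low-longevity clusters, covariate gradients, a cohort life
table, and a neighborhood panel (income plus 5-year age-group counts, from
which median age is derived by grouped-data interpolation with a 105-year
cap), so every stage is testable against known truth without the original
data.

## Worked example

```python
import pandas as pd
from lifegaps import (SyntheticConfig, generate_population, attach_indicators,
                      attach_covariates, LocalMoran)
from lifegaps.synthetic import SkewedNoise

config = SyntheticConfig(
    n_individuals=1500, region_extent=(0, 0, 12_000, 12_000),
    n_high_clusters=1, n_low_clusters=1,
    cluster_radius_m=1000.0, cluster_point_share=0.3,
    cluster_effect_years=14.0, skew_params=SkewedNoise(mean=5.19, sd=12.0),
    seed=7,
)
records, truth, life_table, panel = generate_population(config)
data = attach_covariates(attach_indicators(records, life_table), panel)
print(f"mean YPLLG: {data['yplg'].mean():.2f}  mean lifespan: {data['age_at_death'].mean():.2f}")

model = LocalMoran(radius_m=1200, n_permutations=19_999, alpha=0.1, random_state=0)
labels = model.fit_predict(data[["x_m", "y_m"]].to_numpy(), data["yplg"].to_numpy())
print(f"Bonferroni threshold: {model.threshold_:.2e}")
print(pd.Series(labels).value_counts().to_string())
```

prints

```
mean YPLLG: 5.27  mean lifespan: 79.40
Bonferroni threshold: 6.67e-05
NS    910
HH    245
LL    194
HL     78
LH     73
```

The population lives, on average, 5.3 years longer than its cohort
expectation (the left-skewed YPLLG distribution is calibrated to an
observed urban mortality profile). At the per-test level 0.1/1500 the
analysis flags 245 individuals inside the planted long-lived cluster
region (`HH`, mean YPLLG ≈ +18.9 years) and 194 inside the short-lived one
(`LL`, mean YPLLG ≈ −6.9), with a sprinkling of discordant spatial
outliers at the cluster rims; the remaining 910 points show no spatial
dependence. Note the permutation floor: a point can only reach
significance if `1/(n_permutations+1)` is below the Bonferroni threshold,
so small studies need enough permutations.

The same pipeline is scriptable from a shell:

```
lifegaps simulate --n 22751 --seed 0 --outdir synthetic/
lifegaps prepare --records synthetic/death_records.csv \
    --life-table synthetic/life_table.csv --panel synthetic/neighborhood_panel.csv \
    --out prepared.csv --ledger-out ledger.csv
lifegaps cluster --prepared prepared.csv --variable raw --permutations 99999 --seed 1
lifegaps study --prepared prepared.csv --k 10 --m 10000 --seed 1 --outdir study/
lifegaps report --studydir study/
```

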