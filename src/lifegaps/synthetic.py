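"""Synthetic georeferenced death records with planted spatial structure.

The generator emulates the statistical shape of an urban death-notice
dataset: individual records with gender, nationality, birth/death dates and
projected planar residential coordinates; a cohort life table linear in
birth year with a gender gap; and a neighborhood panel (statistical
subsectors on a grid) carrying median household income and 5-year
age-group counts with spatial gradients. Spatial structure is planted as
circular clusters whose members live ``cluster_effect_years`` longer (high
clusters) or shorter (low clusters) than their cohort expectation, on top
of covariate-linked deviations and a negatively skewed noise term, so that
cluster-detection stages can be validated against known truth labels.

Default parameters are calibrated to the observed profile of the Geneva
2009–2016 death records: YPLLG mean 5.19, sd 20.12, median ~9.3 (left
skew), mean lifespan ~79.4 years, 53.3% women, 79.6% Swiss, neighborhood
income 128,012 ± ~41,000 CHF and median population age ~43 ± ~10 years.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import AGE_CAP, AGE_COUNT_COLUMNS, N_AGE_BINS, grouped_median_age
from .indicators import DAYS_PER_YEAR, LifeTable

MAX_AGE_YEARS = 105.0


@dataclass
class SkewedNoise:
    """Skew-normal lifespan-deviation noise, parameterized by target moments.

    ``shape`` is the skew-normal slant: large negative values approach a
    negated half-normal, whose mean/median offset reproduces the observed
    left skew of YPLLG. ``mean`` and ``sd`` are the target first two
    moments; location and scale are solved from them in closed form.
    """

    shape: float = -50.0
    mean: float = 5.19
    sd: float = 20.12

    @property
    def _delta(self) -> float:
        return self.shape / math.sqrt(1.0 + self.shape**2)

    @property
    def scale(self) -> float:
        if self.sd == 0:
            return 0.0
        return self.sd / math.sqrt(1.0 - 2.0 * self._delta**2 / math.pi)

    @property
    def loc(self) -> float:
        return self.mean - self.scale * self._delta * math.sqrt(2.0 / math.pi)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(size, self.mean)
        return stats.skewnorm.rvs(self.shape, loc=self.loc, scale=self.scale,
                                  size=size, random_state=rng)


@dataclass
class CovariateEffects:
    """Linear lifespan-deviation effects of covariates (years per unit).

    Effects act on deviations from the population mean of each covariate,
    so nonzero coefficients shift local but not overall expectation.
    """

    swiss: float = 6.0  # years, Swiss vs non-Swiss
    income_per_kchf: float = 0.1  # years per 1000 CHF neighborhood income
    nbh_age_per_year: float = 0.3  # years per year of neighborhood median age

    def all_zero(self) -> bool:
        return self.swiss == 0 and self.income_per_kchf == 0 and self.nbh_age_per_year == 0


@dataclass
class SyntheticConfig:
    """Full specification of a synthetic study region and population."""

    n_individuals: int = 22_751
    region_extent: tuple[float, float, float, float] = (0.0, 0.0, 20_000.0, 20_000.0)
    n_high_clusters: int = 3
    n_low_clusters: int = 3
    cluster_radius_m: float = 1_500.0
    cluster_effect_years: float = 12.0
    cluster_point_share: float = 0.2
    skew_params: SkewedNoise = field(default_factory=SkewedNoise)
    frac_women: float = 0.533
    frac_swiss: float = 0.796
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    n_subsectors: int = 100
    year_range: tuple[int, int] = (2009, 2016)
    seed: int = 0
    # life-table construction
    lt_base_year: int = 1900
    lt_base_leb: float = 68.7
    lt_annual_gain: float = 0.1
    lt_gender_gap: float = 4.0  # women minus men, years
    # neighborhood panel construction
    income_mean_chf: float = 128_012.0
    income_gradient: float = 1.1  # relative east-west span of subsector income
    nbh_age_mean: float = 42.96
    nbh_age_gradient: float = 33.6  # north-south span of subsector mean age, years
    nationality_gradient: float = 0.15
    missing_cell_frac: float = 0.0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be at least 1")
        x0, y0, x1, y1 = self.region_extent
        if not (x1 > x0 and y1 > y0):
            raise ValueError("region_extent must be a non-degenerate rectangle")
        for name in ("frac_women", "frac_swiss", "cluster_point_share"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cluster_radius_m <= 0:
            raise ValueError("cluster_radius_m must be positive")
        if self.year_range[1] < self.year_range[0]:
            raise ValueError("year_range is empty")
        if self.n_subsectors < 1:
            raise ValueError("n_subsectors must be at least 1")


def generate_life_table(
    year_range: tuple[int, int],
    gender_levels: tuple[str, ...] = ("F", "M"),
    base_leb: float = 68.7,
    annual_gain: float = 0.1,
    gender_offsets: dict[str, float] | None = None,
) -> LifeTable:
    """Linear synthetic cohort life table over a birth-year range.

    ``LEB(year, gender) = base_leb + annual_gain * (year - first_year)
    + gender_offsets[gender]``. A positive ``annual_gain`` makes LEB
    monotone non-decreasing in birth year, mimicking secular gains.
    """
    if year_range[1] < year_range[0]:
        raise ValueError("year_range is empty")
    if annual_gain < 0:
        raise ValueError("annual_gain must be non-negative")
    offsets = gender_offsets or {g: 0.0 for g in gender_levels}
    rows = []
    for year in range(year_range[0], year_range[1] + 1):
        for gender in gender_levels:
            rows.append(
                {
                    "birth_year": year,
                    "gender": gender,
                    "leb_years": base_leb
                    + annual_gain * (year - year_range[0])
                    + offsets.get(gender, 0.0),
                }
            )
    return LifeTable(pd.DataFrame(rows))


def _subsector_grid(config: SyntheticConfig) -> pd.DataFrame:
    """Grid of subsector ids and centroids covering the region."""
    x0, y0, x1, y1 = config.region_extent
    gx = int(math.ceil(math.sqrt(config.n_subsectors)))
    gy = int(math.ceil(config.n_subsectors / gx))
    cells = []
    k = 0
    for iy in range(gy):
        for ix in range(gx):
            if k >= config.n_subsectors:
                break
            cells.append(
                {
                    "subsector_id": f"S{k:04d}",
                    "ix": ix,
                    "iy": iy,
                    "centroid_x_m": x0 + (ix + 0.5) * (x1 - x0) / gx,
                    "centroid_y_m": y0 + (iy + 0.5) * (y1 - y0) / gy,
                }
            )
            k += 1
    frame = pd.DataFrame(cells)
    frame.attrs["grid_shape"] = (gx, gy)
    return frame


def _assign_subsector(config: SyntheticConfig, grid: pd.DataFrame, x, y) -> np.ndarray:
    x0, y0, x1, y1 = config.region_extent
    gx, gy = grid.attrs["grid_shape"]
    ix = np.clip(((np.asarray(x) - x0) / (x1 - x0) * gx).astype(int), 0, gx - 1)
    iy = np.clip(((np.asarray(y) - y0) / (y1 - y0) * gy).astype(int), 0, gy - 1)
    flat = iy * gx + ix
    # cells beyond n_subsectors (ragged last row) snap to the nearest valid id
    flat = np.minimum(flat, config.n_subsectors - 1)
    ids = grid["subsector_id"].to_numpy()
    return ids[flat]


def generate_neighborhood_panel(config: SyntheticConfig) -> pd.DataFrame:
    """Yearly neighborhood panel with income/age gradients and optional gaps.

    Income rises west-to-east and neighborhood mean age south-to-north;
    age-group counts are multinomial draws from a normal age profile capped
    at 105. A ``missing_cell_frac`` share of (subsector, year) cells is
    dropped to exercise the nearest-neighborhood fallback downstream.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    grid = _subsector_grid(config)
    x0, y0, x1, y1 = config.region_extent

    rel_x = (grid["centroid_x_m"].to_numpy() - x0) / (x1 - x0) - 0.5
    rel_y = (grid["centroid_y_m"].to_numpy() - y0) / (y1 - y0) - 0.5
    base_income = config.income_mean_chf * (1.0 + config.income_gradient * rel_x)
    base_income = np.maximum(base_income + rng.normal(0, 3_000, len(grid)), 20_000.0)
    mean_age = np.clip(
        config.nbh_age_mean + config.nbh_age_gradient * rel_y + rng.normal(0, 1.5, len(grid)),
        20.0,
        70.0,
    )

    rows = []
    for s_idx, row in grid.iterrows():
        for year in range(config.year_range[0], config.year_range[1] + 1):
            total = int(rng.poisson(900))
            ages = np.clip(rng.normal(mean_age[s_idx], 18.0, total), 0.0, AGE_CAP - 1e-9)
            counts, _ = np.histogram(ages, bins=np.arange(0.0, AGE_CAP + 5.0, 5.0))
            entry = {
                "subsector_id": row["subsector_id"],
                "year": year,
                "median_income": float(base_income[s_idx] * (1.0 + rng.normal(0, 0.01))),
                "centroid_x_m": row["centroid_x_m"],
                "centroid_y_m": row["centroid_y_m"],
            }
            entry.update({col: int(c) for col, c in zip(AGE_COUNT_COLUMNS, counts)})
            rows.append(entry)
    panel = pd.DataFrame(rows)

    if config.missing_cell_frac > 0:
        drop = rng.random(len(panel)) < config.missing_cell_frac
        # never drop every subsector for a year
        for year, group in panel.groupby("year"):
            if drop[group.index].all():
                drop[group.index[0]] = False
        panel = panel[~drop].reset_index(drop=True)
    return panel


def _place_cluster_centers(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Cluster centers inside the region, separated by >= 2.2 radii."""
    n = config.n_high_clusters + config.n_low_clusters
    if n == 0:
        return np.empty((0, 2))
    x0, y0, x1, y1 = config.region_extent
    r = config.cluster_radius_m
    centers: list[np.ndarray] = []
    for _ in range(20_000):
        if len(centers) == n:
            break
        cand = np.array(
            [rng.uniform(x0 + r, x1 - r), rng.uniform(y0 + r, y1 - r)]
        )
        if all(np.hypot(*(cand - c)) >= 2.2 * r for c in centers):
            centers.append(cand)
    if len(centers) < n:
        raise ValueError("could not place cluster centers: region too small for the requested layout")
    return np.vstack(centers)


def generate_population(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, LifeTable, pd.DataFrame]:
    """Generate death records with known planted structure.

    Returns ``(records, truth, life_table, panel)``. ``truth`` carries, per
    record, the planted cluster id (-1 outside any cluster), the cluster
    type (high/low/none) and the exact planted lifespan deviation, for
    recovery testing. Ages are truncated to [0, 105]: deviations that would
    imply death before birth are resampled, longer lifespans capped at 105.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_individuals
    x0, y0, x1, y1 = config.region_extent

    birth_span = (config.year_range[0] - int(MAX_AGE_YEARS) - 1, config.year_range[1])
    life_table = generate_life_table(
        birth_span,
        base_leb=config.lt_base_leb + config.lt_annual_gain * (birth_span[0] - config.lt_base_year),
        annual_gain=config.lt_annual_gain,
        gender_offsets={"F": config.lt_gender_gap, "M": 0.0},
    )
    panel = generate_neighborhood_panel(config)
    grid = _subsector_grid(config)

    # --- locations: a share of points concentrated in planted cluster discs
    centers = _place_cluster_centers(config, rng)
    n_clusters = len(centers)
    cluster_types = np.array(
        ["high"] * config.n_high_clusters + ["low"] * config.n_low_clusters, dtype=object
    )
    xs = rng.uniform(x0, x1, n)
    ys = rng.uniform(y0, y1, n)
    if n_clusters > 0 and config.cluster_point_share > 0:
        n_in = int(round(config.cluster_point_share * n))
        assignment = rng.integers(0, n_clusters, n_in)
        radius = config.cluster_radius_m * np.sqrt(rng.random(n_in))
        angle = rng.uniform(0, 2 * np.pi, n_in)
        xs[:n_in] = centers[assignment, 0] + radius * np.cos(angle)
        ys[:n_in] = centers[assignment, 1] + radius * np.sin(angle)
    order = rng.permutation(n)  # decouple row order from placement mechanism
    xs, ys = xs[order], ys[order]

    # --- truth labels by geometric membership (nearest center within radius)
    cluster_id = np.full(n, -1, dtype=int)
    if n_clusters > 0:
        d2 = (xs[:, None] - centers[None, :, 0]) ** 2 + (ys[:, None] - centers[None, :, 1]) ** 2
        nearest = np.argmin(d2, axis=1)
        within = np.sqrt(d2[np.arange(n), nearest]) <= config.cluster_radius_m
        cluster_id[within] = nearest[within]
    if n_clusters > 0:
        cluster_type = np.where(cluster_id >= 0, cluster_types[np.maximum(cluster_id, 0)], "none")
    else:
        cluster_type = np.full(n, "none", dtype=object)

    # --- demographics
    gender = np.where(rng.random(n) < config.frac_women, "F", "M").astype(object)
    p_swiss = np.clip(
        config.frac_swiss + config.nationality_gradient * 2 * ((xs - x0) / (x1 - x0) - 0.5),
        0.0,
        1.0,
    )
    nationality = np.where(rng.random(n) < p_swiss, "swiss", "non_swiss").astype(object)
    subsector = _assign_subsector(config, grid, xs, ys)

    # --- covariate-linked deviation (year-averaged panel values per subsector)
    eff = config.covariate_effects
    deviation = np.zeros(n)
    if not eff.all_zero():
        by_sub = panel.groupby("subsector_id")
        sub_income = by_sub["median_income"].mean()
        sub_age = panel.groupby("subsector_id")[AGE_COUNT_COLUMNS].sum().apply(
            lambda row: grouped_median_age(row.to_numpy()), axis=1
        )
        income_k = sub_income.reindex(subsector).to_numpy() / 1000.0
        nbh_age = sub_age.reindex(subsector).to_numpy()
        deviation += eff.swiss * ((nationality == "swiss").astype(float) - config.frac_swiss)
        deviation += eff.income_per_kchf * (income_k - np.nanmean(income_k))
        deviation += eff.nbh_age_per_year * (nbh_age - np.nanmean(nbh_age))
    effect_sign = np.where(cluster_type == "high", 1.0, np.where(cluster_type == "low", -1.0, 0.0))
    deviation += effect_sign * config.cluster_effect_years

    noise = config.skew_params.rvs(n, rng)

    # --- dates: rejection sampling so death year lands in range and ages stay valid
    epoch = pd.Timestamp("1970-01-01")
    lo_day = (pd.Timestamp(f"{birth_span[0]}-01-01") - epoch).days
    hi_day = (pd.Timestamp(f"{config.year_range[1]}-12-31") - epoch).days
    birth_day = np.zeros(n, dtype=np.int64)
    death_day = np.zeros(n, dtype=np.int64)
    age_years = np.zeros(n)
    pending = np.arange(n)
    for _ in range(5_000):
        if pending.size == 0:
            break
        cand_birth = rng.integers(lo_day, hi_day + 1, pending.size)
        birth_year = pd.to_datetime(cand_birth, unit="D").year.to_numpy()
        leb = np.asarray(life_table.lookup(birth_year, gender[pending]), dtype=float)
        d = deviation[pending] + noise[pending]
        negative = leb + d < 0
        if negative.any():  # resample the noise of would-be negative ages
            noise_new = config.skew_params.rvs(int(negative.sum()), rng)
            noise[pending[negative]] = noise_new
            d = deviation[pending] + noise[pending]
        age = np.minimum(leb + d, MAX_AGE_YEARS)
        ok = age >= 0
        cand_death = cand_birth + np.round(age * DAYS_PER_YEAR).astype(np.int64)
        death_year = pd.to_datetime(np.clip(cand_death, lo_day, hi_day + 10_000), unit="D").year
        death_year = np.asarray(death_year)
        ok &= (death_year >= config.year_range[0]) & (death_year <= config.year_range[1])
        ok &= cand_death <= hi_day
        accepted = pending[ok]
        birth_day[accepted] = cand_birth[ok]
        death_day[accepted] = cand_death[ok]
        age_years[accepted] = age[ok]
        pending = pending[~ok]
    if pending.size:
        raise RuntimeError("date sampling failed to converge; check configuration")

    records = pd.DataFrame(
        {
            "id": [f"D{i:06d}" for i in range(n)],
            "gender": gender,
            "nationality": nationality,
            "birth_date": pd.to_datetime(birth_day, unit="D"),
            "death_date": pd.to_datetime(death_day, unit="D"),
            "x_m": xs,
            "y_m": ys,
            "subsector_id": subsector,
        }
    )
    truth = pd.DataFrame(
        {
            "id": records["id"],
            "cluster_id": cluster_id,
            "cluster_type": cluster_type,
            "planted_deviation": deviation + noise,
        }
    )
    return records, truth, life_table, panel


def write_outputs(
    records: pd.DataFrame,
    truth: pd.DataFrame,
    life_table: LifeTable,
    panel: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write records, truth labels, life table, panel and centroid GeoJSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": outdir / "death_records.csv",
        "truth": outdir / "truth_labels.csv",
        "life_table": outdir / "life_table.csv",
        "panel": outdir / "neighborhood_panel.csv",
        "centroids": outdir / "subsector_centroids.geojson",
    }
    out = records.copy()
    out["birth_date"] = out["birth_date"].dt.strftime("%Y-%m-%d")
    out["death_date"] = out["death_date"].dt.strftime("%Y-%m-%d")
    out.to_csv(paths["records"], index=False)
    truth.to_csv(paths["truth"], index=False)
    life_table.to_frame().to_csv(paths["life_table"], index=False)
    panel.to_csv(paths["panel"], index=False)

    centroids = panel.drop_duplicates("subsector_id")
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [float(r["centroid_x_m"]), float(r["centroid_y_m"])],
            },
            "properties": {"subsector_id": str(r["subsector_id"])},
        }
        for _, r in centroids.iterrows()
    ]
    paths["centroids"].write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return paths
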