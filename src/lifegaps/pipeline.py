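"""Full-study orchestration: subsets, raw/adjusted cluster runs, summaries.

The robustness protocol draws k random subsets (default 10 of size 10,000)
without replacement from the prepared records, runs the Local Moran
analysis per subset on raw YPLLG and on adjusted YPLLG (median-regression
residuals refitted within each subset), summarizes the population inside
each cluster type as range/mean/sd across subsets, compares cluster-type
means with Tukey's HSD, and quantifies how much the cluster footprints
shrink after adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .adjust import adjusted_yplg, build_design, fit_median_regression
from .moran import CLUSTER_LABELS, LABEL_NS, LocalMoran

ALL_LABELS = (LABEL_NS, *CLUSTER_LABELS)

CHARACTERISTICS = (
    "n",
    "pct_women",
    "pct_swiss",
    "mean_yplg",
    "mean_ypll",
    "mean_income",
    "mean_nbh_age",
)


@dataclass
class SubsetPlan:
    """Random-subset resampling plan: k subsets of size m, no replacement."""

    k: int = 10
    m: int = 10_000
    seed: int | None = None

    def validate(self, population_size: int) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.m < 1 or self.m > population_size:
            raise ValueError(f"subset size m={self.m} exceeds population size {population_size}")


def draw_subsets(records: pd.DataFrame, plan: SubsetPlan) -> list[pd.DataFrame]:
    """k independent simple-random subsets of size m, each without replacement."""
    plan.validate(len(records))
    rng = np.random.default_rng(plan.seed)
    subsets = []
    for _ in range(plan.k):
        idx = rng.choice(len(records), size=plan.m, replace=False)
        subsets.append(records.iloc[np.sort(idx)].reset_index(drop=True))
    return subsets


def run_model(
    subset: pd.DataFrame,
    variable: str = "raw",
    radius_m: float = 1200.0,
    n_permutations: int = 99_999,
    alpha: float = 0.1,
    seed: int | None = None,
) -> pd.DataFrame:
    """One Local Moran run on a prepared subset.

    ``variable='raw'`` analyzes the yplg column; ``variable='adjusted'``
    first fits a median regression of yplg on (swiss, income, neighborhood
    median age) within the subset and analyzes its residuals. Returns the
    subset with analysis columns appended (analysis_value, z, lag, I,
    pseudo_p, label).
    """
    if variable not in ("raw", "adjusted"):
        raise ValueError("variable must be 'raw' or 'adjusted'")
    for col in ("yplg", "x_m", "y_m"):
        if col not in subset.columns:
            raise ValueError(f"subset is missing prepared column {col!r}")
    if variable == "adjusted":
        fit = fit_median_regression(subset["yplg"].to_numpy(), build_design(subset))
        values = adjusted_yplg(fit)
    else:
        values = subset["yplg"].to_numpy(dtype=float)

    coords = subset[["x_m", "y_m"]].to_numpy(dtype=float)
    model = LocalMoran(
        radius_m=radius_m, n_permutations=n_permutations, alpha=alpha, random_state=seed
    ).fit(coords, values)

    out = subset.copy()
    out["analysis_value"] = values
    out["z"] = model.z_
    out["lag"] = model.lag_
    out["I"] = model.I_
    out["pseudo_p"] = model.pseudo_p_
    out["label"] = model.labels_
    return out


def _subset_label_stats(result: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for label in ALL_LABELS:
        group = result[result["label"] == label]
        row = {"label": label, "n": len(group)}
        if len(group):
            row["pct_women"] = 100.0 * (group["gender"] == "F").mean()
            row["pct_swiss"] = 100.0 * (group["nationality"].astype(str) == "swiss").mean()
            row["mean_yplg"] = group["analysis_value"].mean()
            row["mean_ypll"] = group["ypll"].mean() if "ypll" in group else np.nan
            row["mean_income"] = group["income"].mean() if "income" in group else np.nan
            row["mean_nbh_age"] = (
                group["nbh_median_age"].mean() if "nbh_median_age" in group else np.nan
            )
        else:
            row.update({c: np.nan for c in CHARACTERISTICS if c != "n"})
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_clusters(results: list[pd.DataFrame]) -> pd.DataFrame:
    """Range/mean/sd of per-cluster population characteristics across subsets.

    Counts include subsets where a label is absent (contributing n = 0);
    the other characteristics aggregate only over subsets where the label
    occurs. Output is tidy: one row per (label, characteristic) with
    columns min, max, mean, sd (sd is 0 for a single subset).
    """
    if not results:
        raise ValueError("no subset results to summarize")
    per_subset = pd.concat(
        [_subset_label_stats(r).assign(subset=i) for i, r in enumerate(results)],
        ignore_index=True,
    )
    rows = []
    for label in ALL_LABELS:
        block = per_subset[per_subset["label"] == label]
        for characteristic in CHARACTERISTICS:
            values = block[characteristic].to_numpy(dtype=float)
            if characteristic != "n":
                values = values[~np.isnan(values)]
            if values.size == 0:
                rows.append(
                    {
                        "label": label,
                        "characteristic": characteristic,
                        "min": np.nan,
                        "max": np.nan,
                        "mean": np.nan,
                        "sd": np.nan,
                    }
                )
                continue
            rows.append(
                {
                    "label": label,
                    "characteristic": characteristic,
                    "min": float(values.min()),
                    "max": float(values.max()),
                    "mean": float(values.mean()),
                    "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def tukey_hsd(groups: dict[str, np.ndarray], family_alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs mean comparison via the studentized range (Tukey–Kramer).

    Groups with fewer than two observations are excluded with a warning.
    Returns one row per pair: group names, mean difference, adjusted
    p-value, and significance at ``family_alpha``.
    """
    usable = {}
    for name, values in groups.items():
        values = np.asarray(values, dtype=float)
        values = values[~np.isnan(values)]
        if values.size < 2:
            warnings.warn(f"group {name!r} has fewer than 2 observations; excluded", stacklevel=2)
            continue
        usable[name] = values
    if len(usable) < 2:
        raise ValueError("need at least two groups with >= 2 observations")
    names = list(usable)
    res = stats.tukey_hsd(*[usable[n] for n in names])
    rows = []
    for i, j in combinations(range(len(names)), 2):
        diff = float(np.mean(usable[names[i]]) - np.mean(usable[names[j]]))
        p = float(res.pvalue[i, j])
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "mean_difference": diff,
                "p_adjusted": p,
                "significant": p < family_alpha,
            }
        )
    return pd.DataFrame(rows)


def footprint_reduction(
    raw_results: list[pd.DataFrame],
    adjusted_results: list[pd.DataFrame],
    basis: str = "mean",
    subset_index: int | None = None,
) -> dict[str, float | None]:
    """Percent shrinkage of LL and HH cluster membership after adjustment.

    ``basis='mean'`` compares mean cluster counts across subsets;
    ``basis='subset'`` compares the counts of a single subset
    (``subset_index``). A label with zero raw count yields ``None``.
    """
    if basis not in ("mean", "subset"):
        raise ValueError("basis must be 'mean' or 'subset'")

    def counts(results: list[pd.DataFrame], label: str) -> float:
        per = np.array([(r["label"] == label).sum() for r in results], dtype=float)
        if basis == "subset":
            if subset_index is None:
                raise ValueError("subset_index is required with basis='subset'")
            return float(per[subset_index])
        return float(per.mean())

    out: dict[str, float | None] = {}
    for label in ("LL", "HH"):
        raw_n = counts(raw_results, label)
        adj_n = counts(adjusted_results, label)
        out[label] = None if raw_n == 0 else 100.0 * (raw_n - adj_n) / raw_n
    return out


@dataclass
class StudyResult:
    """Everything the k-subset protocol produces."""

    raw_results: list[pd.DataFrame]
    adjusted_results: list[pd.DataFrame]
    raw_summary: pd.DataFrame
    adjusted_summary: pd.DataFrame
    tukey_raw: pd.DataFrame
    tukey_adjusted: pd.DataFrame
    footprints: dict[str, float | None] = field(default_factory=dict)


def run_study(
    records: pd.DataFrame,
    plan: SubsetPlan,
    radius_m: float = 1200.0,
    n_permutations: int = 99_999,
    alpha: float = 0.1,
    seed: int | None = None,
) -> StudyResult:
    """Run the complete raw + adjusted subset protocol on prepared records."""
    subsets = draw_subsets(records, plan)
    seeds = np.random.SeedSequence(seed).generate_state(2 * plan.k) % (2**31)
    raw_results = [
        run_model(s, "raw", radius_m, n_permutations, alpha, int(seeds[i]))
        for i, s in enumerate(subsets)
    ]
    adjusted_results = [
        run_model(s, "adjusted", radius_m, n_permutations, alpha, int(seeds[plan.k + i]))
        for i, s in enumerate(subsets)
    ]

    def tukey_of(results: list[pd.DataFrame]) -> pd.DataFrame:
        pooled = pd.concat(results, ignore_index=True)
        groups = {
            label: pooled.loc[pooled["label"] == label, "analysis_value"].to_numpy()
            for label in ALL_LABELS
        }
        groups = {k: v for k, v in groups.items() if len(v) >= 2}
        empty = pd.DataFrame(
            columns=["group_a", "group_b", "mean_difference", "p_adjusted", "significant"]
        )
        if len(groups) < 2:  # e.g. every point non-significant
            return empty
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return tukey_hsd(groups)

    return StudyResult(
        raw_results=raw_results,
        adjusted_results=adjusted_results,
        raw_summary=summarize_clusters(raw_results),
        adjusted_summary=summarize_clusters(adjusted_results),
        tukey_raw=tukey_of(raw_results),
        tukey_adjusted=tukey_of(adjusted_results),
        footprints=footprint_reduction(raw_results, adjusted_results),
    )
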