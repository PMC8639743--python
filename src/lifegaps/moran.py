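"""Local Moran's I with conditional-permutation inference and cluster labels.

For an analysis variable :math:`y` observed at point locations with
row-standardized distance-band weights :math:`w_{ij}`, the local statistic
at location *i* is

.. math::

    I_i = \\frac{z_i}{m_2} \\sum_j w_{ij} z_j,
    \\qquad z_i = y_i - \\bar y, \\quad m_2 = \\frac{1}{n}\\sum_i z_i^2,

where the mean and second moment run over the analyzed (non-neighborless)
points. Significance uses conditional permutations: the focal value
:math:`y_i` is held fixed while its neighbor positions receive values
drawn without replacement from the remaining observations; the pseudo
p-value is :math:`(R+1)/(M+1)` with R the number of permuted statistics at
least as extreme as the observed one, in the tail matching the sign of the
observed :math:`I_i` (so that both concordant-high and concordant-low
clusters, which share positive :math:`I_i`, are detected in the upper
tail, and spatial outliers with negative :math:`I_i` in the lower tail).
Multiple testing is controlled with a Bonferroni bound
``alpha / n_observations``; significant points are labeled by their Moran
scatterplot quadrant (HH, LL, LH, HL — first letter the point, second its
neighborhood).
"""

from __future__ import annotations

import json
from pathlib import Path

import numba as nb
import numpy as np
import pandas as pd

from .weights import DistanceBandWeights, build_distance_band

LABEL_NS = "NS"
LABEL_NEIGHBORLESS = "NEIGHBORLESS"
CLUSTER_LABELS = ("HH", "LL", "LH", "HL")

#: Map-palette names mirroring the conventional LISA cluster colors.
LABEL_COLORS = {
    "HH": "dark green",
    "LL": "dark purple",
    "LH": "light purple",
    "HL": "light green",
    LABEL_NS: "white",
    LABEL_NEIGHBORLESS: "grey",
}


class DegenerateInputError(ValueError):
    """The analysis variable has zero variance; the statistic is undefined."""


def local_moran_statistic(
    values: np.ndarray, weights: DistanceBandWeights
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compute (z, lag, I) per point; NaN at neighborless points.

    The centering mean and the moment ``m2`` are taken over analyzed
    (non-neighborless) points only, since neighborless points are excluded
    from the analysis.
    """
    y = np.asarray(values, dtype=float)
    if y.shape[0] != weights.n:
        raise ValueError("values and weights describe different numbers of points")
    analyzed = ~weights.neighborless
    n = int(analyzed.sum())
    if n < 2:
        raise ValueError("fewer than two non-neighborless points")
    ya = y[analyzed]
    z_full = np.full(y.shape, np.nan)
    z_full[analyzed] = ya - ya.mean()
    m2 = float(np.sum(z_full[analyzed] ** 2) / n)
    if m2 == 0.0:
        raise DegenerateInputError("analysis variable has zero variance")
    lag = weights.lag(z_full)
    stat = np.where(analyzed, z_full / m2 * lag, np.nan)
    return z_full, lag, stat


@nb.njit(cache=True)
def _permuted_lag_means(pool: np.ndarray, k: int, n_draws: int, seed: int) -> np.ndarray:
    """Means of ``n_draws`` samples of ``k`` pool values drawn without
    replacement (partial Fisher-Yates per draw)."""
    n = pool.shape[0]
    idx = np.arange(n)
    out = np.empty(n_draws)
    np.random.seed(seed)
    for t in range(n_draws):
        total = 0.0
        for j in range(k):
            r = j + int(np.random.random() * (n - j))
            idx[j], idx[r] = idx[r], idx[j]
            total += pool[idx[j]]
        out[t] = total / k
    return out


def permutation_pvalues(
    values: np.ndarray,
    weights: DistanceBandWeights,
    n_permutations: int = 99_999,
    seed: int | None = None,
    return_moments: bool = False,
):
    """Conditional-permutation pseudo p-values per point; NaN at neighborless.

    Each point uses its own random substream spawned from the master seed
    and keyed by point index, so results are invariant to evaluation order
    and reproducible from the seed alone. With ``return_moments=True`` also
    returns the Monte-Carlo mean and standard deviation of the permuted
    statistic per point (useful for validating the permutation null, whose
    conditional expectation is ``-z_i^2 / (m2 (n-1))`` under
    row-standardized weights).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    z, _, stat = local_moran_statistic(values, weights)
    analyzed_idx = np.flatnonzero(~weights.neighborless)
    n = analyzed_idx.size
    # dense z over analyzed points; position of each analyzed point inside it
    z_a = z[analyzed_idx]
    pos = {int(i): a for a, i in enumerate(analyzed_idx)}

    m2 = float(np.sum(z_a**2) / n)
    children = np.random.SeedSequence(seed).spawn(weights.n)
    pvals = np.full(weights.n, np.nan)
    perm_mean = np.full(weights.n, np.nan)
    perm_sd = np.full(weights.n, np.nan)
    for i in analyzed_idx:
        point_seed = int(children[int(i)].generate_state(1, dtype=np.uint32)[0])
        pool = np.delete(z_a, pos[int(i)])
        k = int(weights.cardinalities[i])
        lag_perm = _permuted_lag_means(pool, k, n_permutations, point_seed)
        stat_perm = (z[i] / m2) * lag_perm
        observed = stat[i]
        if observed >= 0:
            r = int(np.sum(stat_perm >= observed))
        else:
            r = int(np.sum(stat_perm <= observed))
        pvals[i] = (r + 1) / (n_permutations + 1)
        if return_moments:
            perm_mean[i] = stat_perm.mean()
            perm_sd[i] = stat_perm.std(ddof=1)
    if return_moments:
        return pvals, perm_mean, perm_sd
    return pvals


def bonferroni_threshold(alpha_overall: float, n_tests: int) -> float:
    """Per-test significance level alpha / n under Bonferroni control."""
    if not (0 < alpha_overall < 1):
        raise ValueError("alpha_overall must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha_overall / n_tests


def classify_clusters(
    z: np.ndarray, lag: np.ndarray, pseudo_p: np.ndarray, threshold: float
) -> np.ndarray:
    """Moran-scatterplot quadrant labels for significant points.

    Non-significant points (``pseudo_p >= threshold``, strict inequality
    for significance) get ``NS``; neighborless points (NaN statistics) get
    ``NEIGHBORLESS``; exact zero z or lag at a significant point falls back
    to ``NS`` (measure-zero tie).
    """
    z = np.asarray(z, dtype=float)
    lag = np.asarray(lag, dtype=float)
    p = np.asarray(pseudo_p, dtype=float)
    labels = np.full(z.shape, LABEL_NS, dtype=object)
    labels[np.isnan(z) | np.isnan(lag) | np.isnan(p)] = LABEL_NEIGHBORLESS
    significant = (p < threshold) & (labels == LABEL_NS)
    labels[significant & (z > 0) & (lag > 0)] = "HH"
    labels[significant & (z < 0) & (lag < 0)] = "LL"
    labels[significant & (z < 0) & (lag > 0)] = "LH"
    labels[significant & (z > 0) & (lag < 0)] = "HL"
    return labels


class LocalMoran:
    """Local Moran cluster detector over point data (estimator interface).

    Parameters
    ----------
    radius_m : float, default 1200
        Distance-band radius in meters for the spatial lag.
    n_permutations : int, default 999
        Conditional permutations per point (the full-study protocol uses
        99,999; the pseudo p-value floor is ``1/(n_permutations+1)``, which
        must sit below the Bonferroni threshold for any point to reach
        significance).
    alpha : float, default 0.1
        Overall (family-wise) significance level, Bonferroni-divided by the
        number of observations passed to :meth:`fit`.
    random_state : int or None
        Master seed for the permutation substreams.

    Attributes (after :meth:`fit`)
    ------------------------------
    weights_ : DistanceBandWeights
    z_, lag_, I_, pseudo_p_ : arrays aligned with the input points
        (NaN at neighborless points)
    labels_ : object array in {HH, LL, LH, HL, NS, NEIGHBORLESS}
    threshold_ : float — the Bonferroni per-test level actually applied
    neighborless_ : boolean mask
    """

    def __init__(
        self,
        radius_m: float = 1200.0,
        n_permutations: int = 999,
        alpha: float = 0.1,
        random_state: int | None = None,
    ):
        self.radius_m = radius_m
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "radius_m": self.radius_m,
            "n_permutations": self.n_permutations,
            "alpha": self.alpha,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "LocalMoran":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r} for LocalMoran")
            setattr(self, key, value)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LocalMoran":
        """Fit on (n, 2) coordinates ``X`` and analysis variable ``y``."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) coordinate array")
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y must have the same number of rows")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")
        self.weights_ = build_distance_band(X, radius_m=self.radius_m)
        self.z_, self.lag_, self.I_ = local_moran_statistic(y, self.weights_)
        self.pseudo_p_ = permutation_pvalues(
            y, self.weights_, n_permutations=self.n_permutations, seed=self.random_state
        )
        self.n_tests_ = X.shape[0]
        self.threshold_ = bonferroni_threshold(self.alpha, self.n_tests_)
        self.labels_ = classify_clusters(self.z_, self.lag_, self.pseudo_p_, self.threshold_)
        self.neighborless_ = self.weights_.neighborless
        return self

    def fit_predict(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.fit(X, y).labels_

    def results_frame(self, ids=None) -> pd.DataFrame:
        """Tidy per-point results table (id, z, lag, I, pseudo_p, label)."""
        if not hasattr(self, "labels_"):
            raise RuntimeError("LocalMoran is not fitted")
        n = len(self.labels_)
        frame = pd.DataFrame(
            {
                "id": np.arange(n) if ids is None else np.asarray(ids),
                "z": self.z_,
                "lag": self.lag_,
                "I": self.I_,
                "pseudo_p": self.pseudo_p_,
                "label": self.labels_,
            }
        )
        return frame


def export_cluster_geojson(
    coords: np.ndarray, results: pd.DataFrame, path: str | Path
) -> None:
    """Write labeled points as a GeoJSON FeatureCollection with palette names."""
    coords = np.asarray(coords, dtype=float)
    features = []
    for (x, y_), (_, row) in zip(coords, results.iterrows()):
        props = {
            "id": str(row["id"]),
            "label": row["label"],
            "color": LABEL_COLORS.get(row["label"], "white"),
        }
        if np.isfinite(row.get("pseudo_p", np.nan)):
            props["pseudo_p"] = float(row["pseudo_p"])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(x), float(y_)]},
                "properties": props,
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))
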