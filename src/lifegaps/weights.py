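"""Fixed-radius (distance-band) spatial weights over point locations.

Every point within ``radius_m`` meters of a focal point (boundary inclusive)
is a neighbor; weights are binary, row-standardized to ``1/|N(i)|`` so that
the spatial lag is the unweighted mean over neighbors. Points with no
neighbor inside the band are flagged *neighborless* and excluded from the
local autocorrelation analysis downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class DistanceBandWeights:
    """Row-standardized distance-band neighbor structure.

    Attributes
    ----------
    neighbors : list of int arrays
        ``neighbors[i]`` holds the indices of the points within
        ``radius_m`` of point ``i`` (excluding ``i`` itself), sorted.
    radius_m : float
        Band radius in meters.
    """

    neighbors: list[np.ndarray]
    radius_m: float
    cardinalities: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.cardinalities = np.array([len(nb) for nb in self.neighbors], dtype=np.int64)

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def neighborless(self) -> np.ndarray:
        """Boolean mask of points with no neighbor in the band."""
        return self.cardinalities == 0

    def lag(self, values: np.ndarray) -> np.ndarray:
        """Spatial lag: mean of ``values`` over each point's neighbors.

        Neighborless points get NaN.
        """
        values = np.asarray(values, dtype=float)
        out = np.full(self.n, np.nan)
        for i, nb in enumerate(self.neighbors):
            if len(nb):
                out[i] = values[nb].mean()
        return out

    def to_triplets(self) -> pd.DataFrame:
        """Sparse (i, j, w) representation with row-standardized weights."""
        rows, cols, w = [], [], []
        for i, nb in enumerate(self.neighbors):
            if len(nb):
                rows.extend([i] * len(nb))
                cols.extend(nb.tolist())
                w.extend([1.0 / len(nb)] * len(nb))
        return pd.DataFrame({"i": rows, "j": cols, "w": w})


def build_distance_band(points: np.ndarray, radius_m: float = 1200.0) -> DistanceBandWeights:
    """Build a distance-band neighbor structure over planar points.

    Parameters
    ----------
    points : (n, 2) array
        Coordinates in a planar metric frame (meters).
    radius_m : float
        Band radius; a pair at exactly ``radius_m`` counts as neighbors.

    Raises
    ------
    ValueError
        If fewer than two points are given or coordinates are not finite.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of planar coordinates")
    if points.shape[0] < 2:
        raise ValueError("at least two points are required to build spatial weights")
    if not np.all(np.isfinite(points)):
        raise ValueError("coordinates must be finite")
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")

    tree = cKDTree(points)
    raw = tree.query_ball_point(points, r=radius_m)
    neighbors = []
    for i, nb in enumerate(raw):
        arr = np.array([j for j in nb if j != i], dtype=np.int64)
        arr.sort()
        neighbors.append(arr)
    return DistanceBandWeights(neighbors=neighbors, radius_m=float(radius_m))
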