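"""Row-normalized truncated inverse-distance spatial weight matrix.

Raw weights are 1/d_ij for centroid pairs strictly closer than the cutoff
(161 km by default, the assumed limit of spatial autocorrelation) and zero
otherwise; the diagonal is zero.  Each nonzero row is divided by its sum.
Rows of isolated units (no neighbour within the cutoff) are kept as zero
rows, so their disturbances reduce to their own innovations.  The matrix is
time-invariant across panel periods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geoscape import haversine_matrix

CUTOFF_KM = 161.0


@dataclass(frozen=True)
class WeightMatrix:
    W: np.ndarray          # N×N row-normalized
    raw: np.ndarray        # N×N truncated inverse distances (symmetric)
    d: np.ndarray          # N×N great-circle distances (km)
    cutoff_km: float

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def isolated(self) -> np.ndarray:
        """Boolean mask of units with no neighbour inside the cutoff."""
        return ~self.raw.any(axis=1)


def build_weight_matrix(
    lon: np.ndarray,
    lat: np.ndarray,
    cutoff_km: float = CUTOFF_KM,
    floor_km: Optional[float] = None,
) -> WeightMatrix:
    """Build the weight matrix over landscape centroids.

    Parameters
    ----------
    lon, lat
        Centroid coordinates, one entry per landscape (N >= 2).
    cutoff_km
        Strict truncation distance: pairs at exactly the cutoff get zero.
    floor_km
        Optional floor applied to co-located centroids (d == 0 off the
        diagonal).  Without it, duplicate coordinates are rejected.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = lon.shape[0]
    if n < 2:
        raise ValueError("need at least 2 landscapes to build weights")
    d = haversine_matrix(lon, lat)
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0.0):
        if floor_km is None:
            raise ValueError(
                "duplicate centroid coordinates; pass floor_km to assign a floor distance"
            )
        d = d.copy()
        d[off & (d == 0.0)] = floor_km

    raw = np.zeros_like(d)
    mask = off & (d < cutoff_km)
    raw[mask] = 1.0 / d[mask]

    row_sums = raw.sum(axis=1)
    W = np.zeros_like(raw)
    nz = row_sums > 0
    W[nz] = raw[nz] / row_sums[nz, None]
    return WeightMatrix(W=W, raw=raw, d=d, cutoff_km=cutoff_km)


def write_weights_csv(wm: WeightMatrix, dense_path, triplet_path) -> None:
    """Write the dense matrix and a sparse (i, j, w) triplet CSV, both with
    12 significant digits."""
    import csv

    n = wm.n
    with open(dense_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([f"u{j}" for j in range(n)])
        for i in range(n):
            w.writerow([f"{x:.12g}" for x in wm.W[i]])
    with open(triplet_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["i", "j", "weight"])
        for i, j in zip(*np.nonzero(wm.W)):
            w.writerow([i, j, f"{wm.W[i, j]:.12g}"])
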