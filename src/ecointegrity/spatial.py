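"""Spatial statistics and regional (microbasin) aggregation.

Global Moran's I with analytic expectation, variance and Z score, plus
site-to-microbasin assignment and zonal averaging of surfaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial.distance import cdist
from shapely.geometry import box

from .grids import GridSpec

__all__ = [
    "SpatialWeightSpec",
    "weight_matrix",
    "morans_i",
    "make_rect_microbasins",
    "assign_sites_to_microbasins",
    "aggregate_microbasins",
]


@dataclass(frozen=True)
class SpatialWeightSpec:
    """How to build the spatial weight matrix from site coordinates.

    ``inverse_distance`` is the desktop-GIS default: w_ij = 1/d_ij with a
    minimum distance floor against coincident points.  ``distance_band``
    gives binary weights within ``band`` meters; ``rook`` is the lattice
    special case (band = smallest observed inter-point distance).
    """

    scheme: str = "inverse_distance"
    band: float | None = None
    min_distance: float = 1e-9
    row_standardize: bool = False

    def __post_init__(self) -> None:
        if self.scheme not in ("inverse_distance", "distance_band", "rook"):
            raise ValueError(f"unknown weight scheme {self.scheme!r}")
        if self.scheme == "distance_band" and (self.band is None or self.band <= 0):
            raise ValueError("distance_band scheme needs a positive band")


def weight_matrix(coords, spec: SpatialWeightSpec = SpatialWeightSpec()) -> np.ndarray:
    """Dense spatial weight matrix with zero diagonal."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    d = cdist(coords, coords)
    off = ~np.eye(n, dtype=bool)
    if spec.scheme == "inverse_distance":
        with np.errstate(divide="ignore"):
            w = 1.0 / np.maximum(d, spec.min_distance)
        w[~off] = 0.0
    else:
        band = spec.band
        if spec.scheme == "rook":
            band = d[off].min() * (1 + 1e-9)
        w = ((d <= band) & off).astype(float)
    if spec.row_standardize:
        sums = w.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        w = w / sums
    return w


def morans_i(
    values,
    coords=None,
    spec: SpatialWeightSpec = SpatialWeightSpec(),
    W: np.ndarray | None = None,
    variance: str = "normality",
) -> dict[str, float]:
    """Global Moran's I with expectation, variance and Z score.

    ``variance`` is computed under the ``"normality"`` assumption by
    default, or ``"randomization"`` (kurtosis-corrected).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]):
        raise ValueError("values are constant; Moran's I undefined")
    if W is None:
        if coords is None:
            raise ValueError("pass coordinates or an explicit weight matrix")
        W = weight_matrix(coords, spec)
    W = np.asarray(W, dtype=float)
    if W.shape != (n, n):
        raise ValueError(f"weight matrix shape {W.shape} != ({n}, {n})")
    if np.any(np.diag(W) != 0):
        raise ValueError("weight matrix must have a zero diagonal")

    z = x - x.mean()
    s0 = W.sum()
    if s0 == 0:
        raise ValueError("all spatial weights are zero")
    num = z @ W @ z
    den = z @ z
    I = (n / s0) * (num / den)
    expected = -1.0 / (n - 1)

    s1 = 0.5 * np.sum((W + W.T) ** 2)
    s2 = np.sum((W.sum(axis=1) + W.sum(axis=0)) ** 2)
    if variance == "normality":
        var = (n * n * s1 - n * s2 + 3 * s0 * s0) / (s0 * s0 * (n * n - 1)) - expected**2
    elif variance == "randomization":
        b2 = n * np.sum(z**4) / (np.sum(z**2) ** 2)
        a = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
        b = b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0)
        var = (a - b) / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - expected**2
    else:
        raise ValueError(f"unknown variance assumption {variance!r}")
    zscore = (I - expected) / np.sqrt(var)
    return {"I": float(I), "expected": float(expected), "variance": float(var), "z": float(zscore)}


# ---------------------------------------------------------------------------
# microbasins


def make_rect_microbasins(grid: GridSpec, nx: int, ny: int):
    """Rectangular tiling of the grid extent into nx*ny 'microbasins'."""
    if nx < 1 or ny < 1:
        raise ValueError("need at least one tile per axis")
    ids, polys = [], []
    dx = grid.width / nx
    dy = grid.height / ny
    for j in range(ny):
        for i in range(nx):
            ids.append(f"mb_{j * nx + i:03d}")
            polys.append(
                box(
                    grid.origin_x + i * dx,
                    grid.origin_y + j * dy,
                    grid.origin_x + (i + 1) * dx,
                    grid.origin_y + (j + 1) * dy,
                )
            )
    return ids, polys


def assign_sites_to_microbasins(
    site_coords, ids: Sequence, polygons: Sequence
) -> tuple[dict[int, object], list[int]]:
    """Map each site index to the id of the polygon covering it.

    Returns ``(membership, unassigned)`` where ``membership[i]`` is the
    polygon id for site ``i`` and ``unassigned`` lists site indices in no
    polygon.  Boundary points count as inside; a site covered by several
    (overlapping) polygons goes to the first and triggers a warning.
    """
    coords = np.atleast_2d(np.asarray(site_coords, dtype=float))
    pts = shapely.points(coords[:, 0], coords[:, 1])
    membership: dict[int, object] = {}
    unassigned: list[int] = []
    overlap_hits = 0
    polys = list(polygons)
    for i, pt in enumerate(pts):
        covering = [pid for pid, poly in zip(ids, polys) if shapely.covers(poly, pt)]
        if not covering:
            unassigned.append(i)
            continue
        if len(covering) > 1:
            overlap_hits += 1
        membership[i] = covering[0]
    if overlap_hits:
        warnings.warn(
            f"{overlap_hits} site(s) covered by overlapping polygons; "
            "assigned to the first match",
            stacklevel=2,
        )
    return membership, unassigned


def aggregate_microbasins(
    site_values: Mapping[int, float] | Sequence[float],
    membership: Mapping[int, object],
    ids: Sequence,
    polygons: Sequence,
    grid: GridSpec,
    rasters: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Per-microbasin means: response over member sites, rasters over the
    pixels whose centers the polygon covers.

    Microbasins without member sites carry predictor means but a missing
    response.  A polygon covering no pixel center is an error.
    """
    X, Y = grid.center_mesh()
    pts = shapely.points(X.ravel(), Y.ravel())
    rows = []
    site_values = dict(enumerate(site_values)) if not isinstance(site_values, Mapping) else site_values
    for pid, poly in zip(ids, polygons, strict=True):
        inside = shapely.covers(poly, pts)
        if not inside.any():
            raise ValueError(f"microbasin {pid!r} covers no pixel centers")
        row: dict = {"microbasin_id": pid, "n_pixels": int(inside.sum())}
        for name, raster in rasters.items():
            row[name] = float(np.asarray(raster).ravel()[inside].mean())
        members = [i for i, mid in membership.items() if mid == pid]
        row["n_sites"] = len(members)
        row["eii"] = (
            float(np.mean([site_values[i] for i in members])) if members else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
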