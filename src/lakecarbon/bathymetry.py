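"""Lake hypsometry from depth soundings.

Sounding points (GPS + echo-sounder) and shoreline zero-depth points are
interpolated onto a planar grid, from which the depth-area-volume
(hypsographic) relationship is tabulated in fixed-thickness strata.  The
winter hypsometry removes the ice slab from the top, which is how
under-ice water volumes are obtained for gas inventories.

The interpolator is inverse-distance weighting (power 2) clipped to the
convex hull of the points; it is pluggable, so a geostatistical method
can be substituted without touching the hypsometry math.  Coordinates are
planar metres; depth is positive downward; strata are half-open
``[top, bottom)`` intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree

DEFAULT_STRATUM_M = 0.5
DEFAULT_IDW_POWER = 2.0


@dataclass
class DepthPointSet:
    """Sounding + shoreline points for one lake."""

    lake_id: str
    x: np.ndarray
    y: np.ndarray
    depth: np.ndarray
    is_shoreline: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.is_shoreline = np.asarray(self.is_shoreline, dtype=bool)
        if np.any(self.depth < 0):
            raise ValueError("depths must be >= 0")
        if np.any(self.depth[self.is_shoreline] != 0):
            raise ValueError("shoreline points must have depth 0")

    def __len__(self) -> int:
        return len(self.depth)

    @classmethod
    def from_csv(cls, path) -> "DepthPointSet":
        df = pd.read_csv(path)
        (lake_id,) = df["lake_id"].unique()
        return cls(
            lake_id=lake_id,
            x=df["x_m"].to_numpy(),
            y=df["y_m"].to_numpy(),
            depth=df["depth_m"].to_numpy(),
            is_shoreline=df["is_shoreline"].to_numpy(dtype=bool),
        )


@dataclass
class DepthRaster:
    """Gridded depth field; NaN outside the lake."""

    lake_id: str
    depth: np.ndarray  # 2-D, m, NaN = land
    cell_size_m: float

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size_m**2


@dataclass
class Hypsometry:
    """Depth-area-volume table for one lake.

    ``area_m2[i]`` is the planar lake area at the top of stratum i (the
    area of water at or below that depth); areas are nonincreasing with
    depth and ``sum(volume_m3)`` is the total lake volume.
    """

    lake_id: str
    depth_top_m: np.ndarray
    depth_bottom_m: np.ndarray
    area_m2: np.ndarray
    volume_m3: np.ndarray
    frozen_solid: bool = False

    def __post_init__(self) -> None:
        self.depth_top_m = np.asarray(self.depth_top_m, dtype=float)
        self.depth_bottom_m = np.asarray(self.depth_bottom_m, dtype=float)
        self.area_m2 = np.asarray(self.area_m2, dtype=float)
        self.volume_m3 = np.asarray(self.volume_m3, dtype=float)
        if len(self.area_m2) and np.any(np.diff(self.area_m2) > 1e-9):
            raise ValueError("stratum areas must be nonincreasing with depth")

    @property
    def surface_area_m2(self) -> float:
        return float(self.area_m2[0]) if len(self.area_m2) else 0.0

    @property
    def total_volume_m3(self) -> float:
        return float(self.volume_m3.sum())

    @property
    def max_depth_m(self) -> float:
        return float(self.depth_bottom_m[-1]) if len(self.depth_bottom_m) else 0.0

    def area_at_depth(self, z: float) -> float:
        """Planar lake area at depth ``z`` (piecewise constant per stratum)."""
        if len(self.area_m2) == 0 or z >= self.max_depth_m:
            return 0.0
        i = int(np.searchsorted(self.depth_top_m, z, side="right")) - 1
        return float(self.area_m2[max(i, 0)])

    def zone_area_weights(self, edges: list[float]) -> dict[str, float]:
        """Planar area fraction per depth zone delimited by ``edges`` (m)."""
        bounds = [0.0, *edges, np.inf]
        weights: dict[str, float] = {}
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            sel = (self.depth_top_m >= lo) & (self.depth_top_m < hi)
            if not sel.any():
                continue
            top_area = self.area_m2[sel][0]
            below = self.area_m2[self.depth_top_m >= hi]
            bottom_area = below[0] if len(below) else 0.0
            label = f"{lo:g}-{hi:g}m" if np.isfinite(hi) else f">{lo:g}m"
            weights[label] = (top_area - bottom_area) / self.surface_area_m2
        return weights

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lake_id": self.lake_id,
                "depth_top_m": self.depth_top_m,
                "depth_bottom_m": self.depth_bottom_m,
                "area_m2": self.area_m2,
                "volume_m3": self.volume_m3,
            }
        )


def interpolate_depth_grid(
    points: DepthPointSet,
    cell_size_m: float | None = None,
    power: float = DEFAULT_IDW_POWER,
    n_neighbors: int = 12,
    min_points: int = 20,
) -> DepthRaster:
    """Inverse-distance-weighted depth raster clipped to the point hull.

    Each cell takes the weight-1/d^power mean of its ``n_neighbors``
    nearest points (neighborhood IDW, the usual GIS default — global IDW
    over-smooths toward the basin mean).  Cells outside the convex hull
    of all points (shoreline included) are NaN, and a cell centred
    exactly on a sounding takes that sounding's depth.  When
    ``cell_size_m`` is omitted it is chosen so the bounding box holds at
    least 4x10^4 cells.
    """
    if len(points) < min_points:
        raise ValueError(f"need >= {min_points} points for interpolation")
    xy = np.column_stack([points.x, points.y])
    try:
        tri = Delaunay(xy)
    except QhullError as exc:  # collinear or duplicate geometry
        raise ValueError("degenerate point geometry (collinear hull)") from exc

    x0, x1 = points.x.min(), points.x.max()
    y0, y1 = points.y.min(), points.y.max()
    if cell_size_m is None:
        cell_size_m = max(np.sqrt((x1 - x0) * (y1 - y0) / 4e4), 1e-6)
    gx = np.arange(x0 + cell_size_m / 2, x1, cell_size_m)
    gy = np.arange(y0 + cell_size_m / 2, y1, cell_size_m)
    gxx, gyy = np.meshgrid(gx, gy)
    cells = np.column_stack([gxx.ravel(), gyy.ravel()])
    inside = tri.find_simplex(cells) >= 0

    depth = np.full(len(cells), np.nan)
    if inside.any():
        k = min(n_neighbors, len(points))
        dist, idx = cKDTree(xy).query(cells[inside], k=k)
        dist = np.atleast_2d(dist)
        idx = np.atleast_2d(idx)
        exact = dist < 1e-9
        w = 1.0 / np.maximum(dist, 1e-9) ** power
        w = np.where(exact.any(axis=1)[:, None], exact.astype(float), w)
        vals = points.depth[idx]
        depth[inside] = (w * vals).sum(axis=1) / w.sum(axis=1)
    depth = np.maximum(depth, 0.0)
    return DepthRaster(lake_id=points.lake_id, depth=depth.reshape(gxx.shape), cell_size_m=cell_size_m)


def hypsometry_from_raster(
    raster: DepthRaster,
    stratum_thickness_m: float = DEFAULT_STRATUM_M,
) -> Hypsometry:
    """Tabulate per-stratum planar area and water volume by cell counting.

    Volume conservation is exact: the stratum volumes sum to the raster's
    cell-integrated volume.
    """
    d = raster.depth[np.isfinite(raster.depth)]
    if d.size == 0:
        raise ValueError("empty raster")
    zmax = float(d.max())
    n = max(int(np.ceil(zmax / stratum_thickness_m)), 1)
    tops = np.arange(n) * stratum_thickness_m
    bottoms = np.minimum(tops + stratum_thickness_m, zmax)
    ca = raster.cell_area_m2
    areas = np.array([(d > t).sum() * ca if t > 0 else d.size * ca for t in tops])
    volumes = np.array(
        [np.clip(d - t, 0.0, b - t).sum() * ca for t, b in zip(tops, bottoms)]
    )
    return Hypsometry(
        lake_id=raster.lake_id,
        depth_top_m=tops,
        depth_bottom_m=bottoms,
        area_m2=areas,
        volume_m3=volumes,
    )


def winter_volume(hyps: Hypsometry, ice_thickness_m: float) -> Hypsometry:
    """Hypsometry of the water remaining below a flat ice slab.

    Strata shallower than the ice are removed and the partially frozen
    stratum is pro-rated (a flat-ice approximation: every water column
    loses its top ``ice_thickness_m``).  Ice at or beyond the maximum
    depth returns an empty hypsometry flagged ``frozen_solid``.
    """
    if ice_thickness_m < 0:
        raise ValueError("ice thickness must be >= 0")
    if ice_thickness_m == 0:
        return hyps
    if ice_thickness_m >= hyps.max_depth_m:
        empty = np.array([])
        return Hypsometry(hyps.lake_id, empty, empty, empty, empty, frozen_solid=True)
    keep = hyps.depth_bottom_m > ice_thickness_m
    tops = np.maximum(hyps.depth_top_m[keep], ice_thickness_m)
    bottoms = hyps.depth_bottom_m[keep]
    # pro-rate the straddled stratum assuming uniform volume density in depth
    frac = (bottoms - tops) / (bottoms - hyps.depth_top_m[keep])
    volumes = hyps.volume_m3[keep] * frac
    return Hypsometry(hyps.lake_id, tops, bottoms, hyps.area_m2[keep], volumes)
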