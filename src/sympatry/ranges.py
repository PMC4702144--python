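"""Foraging-range estimation in the horizontal plane.

Tracks are speed-filtered, foraging locations are turned into a 2-D kernel
utilization distribution (product Gaussian kernel, per-axis normal-reference
bandwidth), highest-density regions are extracted as mass contours (50% =
core area, 95% = overall range by convention), overlaps are polygon
intersections, and every dive is labelled by the region its position falls
in.  All geometry is planar (local metric frame); areas are km².
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union
from skimage import measure

from .exceptions import InputError

CORE_LEVEL = 0.50
RANGE_LEVEL = 0.95
DEFAULT_CELL = 250.0     # m
LINK_TOLERANCE = 3600.0  # s, dive-to-fix matching


# ---------------------------------------------------------------------------
# speed filter

def speed_filter(points: pd.DataFrame, v_max: float = 3.0) -> pd.DataFrame:
    """Iteratively drop the fix implying the largest over-limit speed.

    The first and last fix of each individual are never removed.  Returns
    the retained rows (original order preserved).
    """
    keep_parts = []
    for _, grp in points.groupby("individual", sort=False):
        grp = grp.sort_values("time")
        if len(grp) < 2:
            keep_parts.append(grp)
            continue
        t = grp["time"].to_numpy(float)
        x = grp["x"].to_numpy(float)
        y = grp["y"].to_numpy(float)
        alive = np.ones(t.size, dtype=bool)
        while True:
            idx = np.flatnonzero(alive)
            dt = np.diff(t[idx])
            dist = np.hypot(np.diff(x[idx]), np.diff(y[idx]))
            with np.errstate(divide="ignore"):
                v = np.where(dt > 0, dist / dt, np.inf)
            if v.size == 0 or v.max() <= v_max:
                break
            seg = int(np.argmax(v))
            a, b = idx[seg], idx[seg + 1]
            candidates = [c for c in (a, b) if c not in (idx[0], idx[-1])]
            if not candidates:
                break
            if len(candidates) == 1:
                drop = candidates[0]
            else:
                # drop whichever endpoint leaves the slower bridged segment
                def bridged(c):
                    pos = np.searchsorted(idx, c)
                    lo, hi = idx[pos - 1], idx[pos + 1]
                    d = np.hypot(x[hi] - x[lo], y[hi] - y[lo])
                    return d / (t[hi] - t[lo]) if t[hi] > t[lo] else np.inf
                drop = min(candidates, key=bridged)
            alive[drop] = False
        keep_parts.append(grp[alive])
    return pd.concat(keep_parts).sort_index() if keep_parts else points


# ---------------------------------------------------------------------------
# kernel density surface

@dataclass
class DensitySurface:
    """Normalized 2-D kernel density on a regular grid (cell mass sums
    to 1)."""

    gx: np.ndarray           # cell-centre x coordinates (nx,)
    gy: np.ndarray           # cell-centre y coordinates (ny,)
    density: np.ndarray      # (ny, nx), probability density per m^2
    cell: float              # cell edge length, m
    bandwidths: tuple[float, float]
    n_points: int

    @property
    def cell_area(self) -> float:
        return self.cell ** 2

    @property
    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area)


def _normal_reference_bw(v: np.ndarray) -> float:
    # Scott's rule per axis for a 2-D product kernel
    return float(v.std(ddof=1) * v.size ** (-1.0 / 6.0))


def kde2d(x, y, cell: float = DEFAULT_CELL, pad_bw: float = 3.0,
          bounds: tuple[float, float, float, float] | None = None
          ) -> DensitySurface:
    """Product-Gaussian kernel density with per-axis normal-reference
    bandwidths, normalized to unit mass over the grid."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise InputError("kernel density needs at least 10 points")
    hx, hy = _normal_reference_bw(x), _normal_reference_bw(y)
    if hx < cell:
        warnings.warn("x bandwidth floored at one grid cell", stacklevel=2)
        hx = cell
    if hy < cell:
        warnings.warn("y bandwidth floored at one grid cell", stacklevel=2)
        hy = cell
    if bounds is None:
        bounds = (x.min() - pad_bw * hx, x.max() + pad_bw * hx,
                  y.min() - pad_bw * hy, y.max() + pad_bw * hy)
    x0, x1, y0, y1 = bounds
    gx = np.arange(x0, x1 + cell, cell) + cell / 2.0
    gy = np.arange(y0, y1 + cell, cell) + cell / 2.0
    ax = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / hx) ** 2)
    ay = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / hy) ** 2)
    dens = (ay @ ax.T) / (x.size * 2 * np.pi * hx * hy)
    mass = dens.sum() * cell * cell
    if mass <= 0:
        raise InputError("degenerate density surface")
    dens /= mass
    return DensitySurface(gx=gx, gy=gy, density=dens, cell=cell,
                          bandwidths=(hx, hy), n_points=x.size)


# ---------------------------------------------------------------------------
# highest-density-region contours

def _rings_to_geometry(rings: list[np.ndarray]) -> MultiPolygon:
    polys = []
    for r in rings:
        if len(r) < 4:
            continue
        p = Polygon(r)
        if not p.is_valid:
            p = p.buffer(0)
        if not p.is_empty and p.area > 0:
            polys.append(p)
    if not polys:
        return MultiPolygon([])
    polys.sort(key=lambda p: p.area, reverse=True)
    depth = []
    for i, p in enumerate(polys):
        d = sum(1 for j in range(i) if polys[j].contains(p))
        depth.append(d)
    parts = []
    for i, p in enumerate(polys):
        if depth[i] % 2 != 0:
            continue
        holes = [q for j, q in enumerate(polys)
                 if depth[j] == depth[i] + 1 and p.contains(q)]
        part = p.difference(unary_union(holes)) if holes else p
        parts.append(part)
    geom = unary_union(parts)
    if isinstance(geom, Polygon):
        geom = MultiPolygon([geom])
    return geom


def hdr_level(surface: DensitySurface, mass: float) -> float:
    """Density level whose superlevel set holds the requested mass
    (grid-cell accumulation over descending density)."""
    if not 0.0 < mass < 1.0:
        raise InputError("mass fraction must be in (0, 1)")
    flat = np.sort(surface.density.ravel())[::-1]
    cum = np.cumsum(flat) * surface.cell_area
    k = int(np.searchsorted(cum, mass))
    return float(flat[min(k, flat.size - 1)])


def hdr_contour(surface: DensitySurface, mass: float
                ) -> tuple[MultiPolygon, float, float]:
    """Highest-density-region polygons at the given mass fraction.

    Returns (geometry, area in km^2, density level).  The surface is
    zero-padded so contours touching the data bounding box still close.
    """
    level = hdr_level(surface, mass)
    padded = np.pad(surface.density, 1, mode="constant")
    rings = []
    for c in measure.find_contours(padded, level):
        xs = np.interp(c[:, 1] - 1, np.arange(surface.gx.size), surface.gx)
        ys = np.interp(c[:, 0] - 1, np.arange(surface.gy.size), surface.gy)
        rings.append(np.column_stack([xs, ys]))
    geom = _rings_to_geometry(rings)
    return geom, geom.area / 1e6, level


# ---------------------------------------------------------------------------
# range estimates and overlap

@dataclass
class RangeEstimate:
    """A species x tide-regime utilization distribution with its core (50%)
    and overall (95%) highest-density contours."""

    species: str
    tide: str | None
    surface: DensitySurface
    contours: dict = field(default_factory=dict)   # level -> geometry
    areas_km2: dict = field(default_factory=dict)  # level -> area

    def geometry(self, level: float) -> MultiPolygon:
        return self.contours[level]


def estimate_range(points: pd.DataFrame, species: str, tide: str | None = None,
                   cell: float = DEFAULT_CELL,
                   levels: tuple[float, ...] = (CORE_LEVEL, RANGE_LEVEL),
                   bounds=None) -> RangeEstimate:
    surf = kde2d(points["x"], points["y"], cell=cell, bounds=bounds)
    est = RangeEstimate(species=species, tide=tide, surface=surf)
    for lev in levels:
        geom, area, _ = hdr_contour(surf, lev)
        est.contours[lev] = geom
        est.areas_km2[lev] = area
    return est


def overlap(range_a, range_b, level: float = RANGE_LEVEL
            ) -> tuple[MultiPolygon, float]:
    """Polygon intersection of two range contours and its area in km^2."""
    geom_a = range_a.geometry(level) if isinstance(range_a, RangeEstimate) \
        else range_a
    geom_b = range_b.geometry(level) if isinstance(range_b, RangeEstimate) \
        else range_b
    inter = geom_a.intersection(geom_b)
    return inter, inter.area / 1e6


# ---------------------------------------------------------------------------
# dive positions and region labels

def link_dives_to_positions(dives: pd.DataFrame, tracks: pd.DataFrame,
                            tolerance: float = LINK_TOLERANCE
                            ) -> pd.DataFrame:
    """Attach the nearest-in-time track fix (within tolerance seconds) to
    every dive; dives with no fix in range get NaN positions."""
    out = []
    for ind, grp in dives.groupby("individual", sort=False):
        fixes = tracks[tracks["individual"] == ind].sort_values("time")
        grp = grp.sort_values("start")
        if fixes.empty:
            grp = grp.assign(x=np.nan, y=np.nan)
        else:
            merged = pd.merge_asof(
                grp, fixes[["time", "x", "y"]].rename(
                    columns={"time": "fix_time"}),
                left_on="start", right_on="fix_time",
                direction="nearest", tolerance=tolerance)
            grp = grp.assign(x=merged["x"].to_numpy(),
                             y=merged["y"].to_numpy())
        out.append(grp)
    result = pd.concat(out)
    n_miss = int(result["x"].isna().sum())
    if n_miss:
        warnings.warn(f"{n_miss} dives have no track fix within "
                      f"{tolerance:.0f} s; labelled outside", stacklevel=2)
    return result


def assign_region(dives: pd.DataFrame, geom_a, geom_b,
                  label_a: str = "A_only", label_b: str = "B_only"
                  ) -> pd.Series:
    """Label each dive by point-in-polygon tests against two range
    polygons: overlap if inside both, outside if inside neither."""
    x = dives["x"].to_numpy(float)
    y = dives["y"].to_numpy(float)
    valid = np.isfinite(x) & np.isfinite(y)
    in_a = np.zeros(len(dives), dtype=bool)
    in_b = np.zeros(len(dives), dtype=bool)
    in_a[valid] = shapely.contains_xy(geom_a, x[valid], y[valid])
    in_b[valid] = shapely.contains_xy(geom_b, x[valid], y[valid])
    labels = np.where(in_a & in_b, "overlap",
                      np.where(in_a, label_a,
                               np.where(in_b, label_b, "outside")))
    return pd.Series(labels, index=dives.index, name="region")
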