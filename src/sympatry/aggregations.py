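"""Prey-aggregation detection in gridded volume-backscattering fields.

Cells exceeding the background Sv by a configurable margin are grouped into
8-connected components; components of at least ``min_cells`` cells become
aggregations, classified dense or diffuse by their linear-domain mean Sv,
and measured: height (deepest minus shallowest cell edge), length (last
minus first along-track cell edge), occupied area, length:height ratio and
mean Sv.  Components touching the grid edge are kept but flagged truncated.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from .profiles import to_db, to_linear

DETECT_DB_ABOVE = 6.0      # dB above background
DENSE_THRESHOLD_DB = -64.0  # linear-domain mean Sv split
MIN_CELLS = 4
_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class Aggregation:
    """One detected aggregation and its morphometrics."""

    agg_id: str
    type: str                  # dense | diffuse
    day: int
    mean_depth: float          # m, cell-weighted
    height: float              # m
    length: float              # m
    area: float                # m^2
    lh_ratio: float
    mean_sv: float             # dB, linear-domain mean
    x_center: float
    x_min: float
    x_max: float
    n_cells: int
    truncated: bool

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def estimate_background(echo: xr.Dataset) -> float:
    """Global background Sv estimate: the median cell value (aggregations
    are sparse, so the median is robust to them)."""
    return float(np.median(echo["sv"].to_numpy()))


def detect(echo: xr.Dataset, detect_db_above: float = DETECT_DB_ABOVE,
           min_cells: int = MIN_CELLS,
           background: float | None = None) -> list[dict]:
    """Candidate aggregation cell clusters (8-connected components of
    cells exceeding background + threshold, with >= min_cells cells)."""
    sv = echo["sv"].to_numpy()
    if sv.size == 0:
        return []
    if background is None:
        background = estimate_background(echo)
    mask = sv > background + detect_db_above
    labels, n = ndimage.label(mask, structure=_EIGHT)
    clusters = []
    for k in range(1, n + 1):
        iz, ix = np.nonzero(labels == k)
        if iz.size < min_cells:
            continue
        clusters.append({
            "iz": iz, "ix": ix, "sv": sv[iz, ix],
            "truncated": bool(
                iz.min() == 0 or iz.max() == sv.shape[0] - 1 or
                ix.min() == 0 or ix.max() == sv.shape[1] - 1),
        })
    return clusters


def classify_type(cluster: dict,
                  dense_threshold_db: float = DENSE_THRESHOLD_DB) -> str:
    """dense if the linear-domain mean Sv reaches the threshold."""
    mean_db = to_db(to_linear(cluster["sv"]).mean())
    return "dense" if mean_db >= dense_threshold_db else "diffuse"


def morphometrics(cluster: dict, echo: xr.Dataset, day: int = 0,
                  agg_id: str = "a000",
                  dense_threshold_db: float = DENSE_THRESHOLD_DB
                  ) -> Aggregation:
    """Morphometrics of one cluster; single-row or single-column clusters
    get one cell extent for height or length (never zero)."""
    z = echo["depth"].to_numpy()
    x = echo["distance"].to_numpy()
    dz = float(echo.attrs.get("depth_res", np.median(np.diff(z))))
    dx = float(echo.attrs.get("distance_res", np.median(np.diff(x))))
    iz, ix = cluster["iz"], cluster["ix"]
    height = (iz.max() - iz.min() + 1) * dz
    length = (ix.max() - ix.min() + 1) * dx
    mean_sv = float(to_db(to_linear(cluster["sv"]).mean()))
    return Aggregation(
        agg_id=agg_id, type=classify_type(cluster, dense_threshold_db),
        day=day,
        mean_depth=float(z[iz].mean()),
        height=float(height), length=float(length),
        area=float(iz.size * dx * dz),
        lh_ratio=float(length / height),
        mean_sv=mean_sv,
        x_center=float(x[ix].mean()),
        x_min=float(x[ix.min()] - dx / 2), x_max=float(x[ix.max()] + dx / 2),
        n_cells=int(iz.size), truncated=cluster["truncated"],
    )


def detect_aggregations(echo: xr.Dataset,
                        detect_db_above: float = DETECT_DB_ABOVE,
                        min_cells: int = MIN_CELLS,
                        dense_threshold_db: float = DENSE_THRESHOLD_DB,
                        background: float | None = None
                        ) -> tuple[pd.DataFrame, np.ndarray]:
    """Full detection pass: aggregation table plus the boolean cell mask of
    all detected aggregations (for background-Sv masking)."""
    day = int(echo.attrs.get("day", 0))
    clusters = detect(echo, detect_db_above, min_cells, background)
    mask = np.zeros(echo["sv"].shape, dtype=bool)
    rows = []
    for k, cl in enumerate(clusters):
        mask[cl["iz"], cl["ix"]] = True
        rows.append(morphometrics(
            cl, echo, day=day, agg_id=f"d{day}a{k:03d}",
            dense_threshold_db=dense_threshold_db).as_dict())
    cols = [f.name for f in Aggregation.__dataclass_fields__.values()] \
        if rows == [] else None
    return pd.DataFrame(rows, columns=cols), mask


def attach_presence(profiles: pd.DataFrame, aggregations: pd.DataFrame,
                    ) -> pd.DataFrame:
    """Flag each profile present for a type if any aggregation of that type
    overlaps the profile's along-track span (same mission day)."""
    out = profiles.copy()
    for tname in ("dense", "diffuse"):
        col = f"{tname}_present"
        out[col] = False
        if aggregations.empty:
            continue
        sub = aggregations[aggregations["type"] == tname]
        if sub.empty:
            continue
        x0 = out["x_start"].to_numpy(float)
        x1 = out["x_end"].to_numpy(float)
        a0 = sub["x_min"].to_numpy(float)
        a1 = sub["x_max"].to_numpy(float)
        hit = (a0[None, :] < x1[:, None]) & (a1[None, :] > x0[:, None])
        if "day" in out.columns and "day" in sub.columns:
            same_day = (sub["day"].to_numpy()[None, :] ==
                        out["day"].to_numpy()[:, None])
            hit &= same_day
        out[col] = hit.any(axis=1)
    return out
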