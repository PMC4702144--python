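"""AUV mission segmentation and water-column feature extraction.

Each monotone descent or ascent leg of the see-saw mission is one vertical
profile.  Profiles are binned to 1 m and characterised by nine features:
CHL maximum and its depth, integrated CHL over the upper 50 m, mixed layer
depth (maximum density gradient), density at the MLD, surface PAR (mean of
the upper 2 m), depth of the 1 W/m^2 isolume (log-linear interpolation,
shallowest crossing), thermocline depth (maximum temperature gradient) and
the mean temperature above/below the thermocline.  Background acoustic
profiles average Sv in the linear domain after masking all detected
aggregations, restricted to cells within 3 m of the vehicle.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

from .exceptions import InputError

MIN_LEG_SPAN = 10.0        # m vertical; shorter legs merge into neighbours
ISOLUME_LEVEL = 1.0        # W/m^2
SURFACE_PAR_DEPTH = 2.0    # m
CHL_INTEGRATION_DEPTH = 50.0
CHL_MIN_COVERAGE = 40.0    # m of the upper 50 covered, else flagged missing
BACKGROUND_RANGE = 3.0     # m from the vehicle


def to_linear(sv_db: np.ndarray) -> np.ndarray:
    return 10.0 ** (np.asarray(sv_db, dtype=float) / 10.0)


def to_db(linear: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(linear)


# ---------------------------------------------------------------------------
# segmentation

def segment_profiles(sensor: pd.DataFrame, day: int | None = None,
                     min_span: float = MIN_LEG_SPAN) -> pd.DataFrame:
    """Split the mission at local extrema of vehicle depth; each monotone
    leg becomes one profile.  Legs spanning less than ``min_span`` metres
    vertically are merged into their predecessor.  Returns the sensor table
    with a ``profile_id`` column (every sample belongs to exactly one
    profile)."""
    if "depth" not in sensor.columns:
        raise InputError("sensor table needs a 'depth' column")
    d = sensor["depth"].to_numpy(float)
    n = d.size
    if day is None:
        day = int(sensor["day"].iloc[0]) if "day" in sensor.columns else 0
    diffs = np.diff(d)
    sign = np.sign(diffs)
    # carry direction through flat stretches
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    turns = np.flatnonzero(sign[1:] != sign[:-1]) + 1
    boundaries = [0, *turns.tolist(), n]
    if len(boundaries) == 2:
        warnings.warn("mission does not undulate; single profile",
                      stacklevel=2)
    # merge short legs
    merged = [boundaries[0]]
    for b0 in boundaries[1:-1]:
        if abs(d[b0] - d[merged[-1]]) < min_span:
            continue   # leg too short vertically; absorb into predecessor
        merged.append(b0)
    merged.append(n)
    ids = np.empty(n, dtype=object)
    for k, (b0, b1) in enumerate(zip(merged[:-1], merged[1:])):
        ids[b0:b1] = f"d{day}p{k:03d}"
    out = sensor.copy()
    out["profile_id"] = ids
    return out


# ---------------------------------------------------------------------------
# feature extraction

def _bin_1m(profile: pd.DataFrame) -> pd.DataFrame:
    bins = np.floor(profile["depth"].to_numpy(float)).astype(int)
    g = profile.assign(_bin=bins).groupby("_bin").mean(numeric_only=True)
    g = g.sort_index()
    g["depth_bin"] = g.index + 0.5
    return g


def extract_features(profile: pd.DataFrame) -> dict:
    """The nine water-column features of one vertical profile.

    Features that cannot be computed (light never reaching the isolume,
    constant density, short coverage) come back as NaN rather than being
    extrapolated.
    """
    binned = _bin_1m(profile)
    depths = binned["depth_bin"].to_numpy(float)
    if binned.shape[0] < 5 or depths.max() - depths.min() < 20.0:
        raise InputError("profile too short: need >= 5 bins spanning 20 m")
    feats: dict = {"n_bins": int(binned.shape[0])}

    chl = binned["chl"].to_numpy(float)
    k_max = int(np.nanargmax(chl))
    feats["chl_max"] = float(chl[k_max])
    feats["depth_chl_max"] = float(depths[k_max])
    upper = depths <= CHL_INTEGRATION_DEPTH
    if upper.sum() >= 2 and (depths[upper].max() - depths[upper].min()
                             >= CHL_MIN_COVERAGE):
        feats["integrated_chl_0_50"] = float(
            np.trapezoid(chl[upper], depths[upper]))
    else:
        feats["integrated_chl_0_50"] = np.nan

    dens = binned["density"].to_numpy(float)
    if np.ptp(dens) < 1e-6:
        feats["mld"] = np.nan
        feats["density_at_mld"] = np.nan
    else:
        grad = np.abs(np.gradient(dens, depths))
        j = int(np.argmax(grad))
        feats["mld"] = float(depths[j])
        feats["density_at_mld"] = float(dens[j])

    par = profile["par"].to_numpy(float)
    pdep = profile["depth"].to_numpy(float)
    shallow = pdep <= SURFACE_PAR_DEPTH
    feats["surface_par"] = float(par[shallow].mean()) if shallow.any() \
        else np.nan

    feats["isolume_1wm2"] = _isolume(
        depths, binned["par"].to_numpy(float), ISOLUME_LEVEL)

    temp = binned["temperature"].to_numpy(float)
    tgrad = np.abs(np.gradient(temp, depths))
    jt = int(np.argmax(tgrad))
    feats["thermocline_depth"] = float(depths[jt])
    above = depths < depths[jt]
    below = depths > depths[jt]
    feats["mean_temp_above"] = float(temp[above].mean()) if above.any() \
        else np.nan
    feats["mean_temp_below"] = float(temp[below].mean()) if below.any() \
        else np.nan
    return feats


def _isolume(depths: np.ndarray, par: np.ndarray, level: float) -> float:
    """Shallowest depth where PAR crosses ``level``, interpolating linearly
    in log-PAR (light decays exponentially)."""
    order = np.argsort(depths)
    z, p = depths[order], par[order]
    ok = p > 0
    z, p = z[ok], p[ok]
    if z.size < 2 or p.max() < level or p.min() > level:
        return np.nan
    below = np.flatnonzero(p < level)
    if below.size == 0:
        return np.nan
    j = below[0]
    if j == 0:
        return float(z[0])
    lp0, lp1 = np.log(p[j - 1]), np.log(p[j])
    frac = (lp0 - np.log(level)) / (lp0 - lp1)
    return float(z[j - 1] + frac * (z[j] - z[j - 1]))


def profile_features(sensor_with_ids: pd.DataFrame) -> pd.DataFrame:
    """Feature table for every profile of a segmented mission."""
    rows = []
    for pid, grp in sensor_with_ids.groupby("profile_id", sort=False):
        row = {"profile_id": pid,
               "day": int(grp["day"].iloc[0]) if "day" in grp else 0,
               "x_start": float(grp["distance"].min()),
               "x_end": float(grp["distance"].max())}
        try:
            row.update(extract_features(grp))
        except InputError:
            continue
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# background Sv

def background_sv(echo: xr.Dataset, sensor_with_ids: pd.DataFrame,
                  agg_mask: np.ndarray | None = None,
                  vehicle_range: float = BACKGROUND_RANGE) -> pd.DataFrame:
    """Per-profile background backscatter: mask all aggregation cells,
    keep cells within ``vehicle_range`` m of the vehicle, then average Sv in
    the linear domain within 1 m depth bins.

    Returns a long table (profile_id, depth_bin, sv_background); bins whose
    cells are all masked are absent (flagged missing by omission).
    """
    sv = echo["sv"].to_numpy()
    z = echo["depth"].to_numpy()
    x = echo["distance"].to_numpy()
    vd = echo["vehicle_depth"].to_numpy()
    lin = to_linear(sv)
    keep = np.abs(z[:, None] - vd[None, :]) <= vehicle_range
    if agg_mask is not None:
        keep &= ~agg_mask
    dz = float(echo.attrs.get("depth_res", np.median(np.diff(z))))
    bins = np.floor(z).astype(int)
    rows = []
    for pid, grp in sensor_with_ids.groupby("profile_id", sort=False):
        x0, x1 = grp["distance"].min(), grp["distance"].max()
        cols = (x >= x0) & (x <= x1)
        for b in np.unique(bins):
            sel = keep[:, cols][bins == b, :]
            vals = lin[np.ix_(bins == b, cols)][sel]
            if vals.size == 0:
                continue
            rows.append({"profile_id": pid, "depth_bin": b + 0.5 * dz,
                         "sv_background": float(to_db(vals.mean()))})
    return pd.DataFrame(rows)
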