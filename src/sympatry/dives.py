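"""Dive extraction, shape metrics and behavioural classification.

A depth trace is reduced to surface-to-surface dives; each dive gets the
three krill-foraging signatures — bottom time (time between the first and
last sample within 80% of the maximum depth), wiggles (complete vertical
oscillations of at least 2 m inside the bottom phase) and plateaus (slow
shelves of at least 5 s outside it) — and is classified as a foraging dive
if any signature is present, otherwise as transit (< 10 m) or search.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from . import _shape
from .exceptions import InputError, SchemaError, UndefinedResultError


def _require_columns(df: pd.DataFrame, cols, table: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(c, table)

log = logging.getLogger(__name__)

DIVE_THRESHOLD = 1.0    # m, wet/dry boundary for dive delimitation
MIN_DEPTH = 3.0         # m, minimum max depth of a retained dive
MIN_DURATION = 10.0     # s
TRANSIT_MAX_DEPTH = 10.0
HAS_BOTTOM_MIN = 5.0    # s of bottom time needed to count as a signature


# ---------------------------------------------------------------------------
# drift correction

def _surface_mode(depths: np.ndarray) -> float:
    """Modal near-surface depth (m) from a 0.1 m histogram below 6 m."""
    shallow = depths[depths < 6.0]
    if shallow.size == 0:
        return np.nan
    bins = np.arange(-4.0, 6.05, 0.1)
    hist, edges = np.histogram(shallow, bins=bins)
    mode = 0.5 * (edges[hist.argmax()] + edges[hist.argmax() + 1])
    near = shallow[np.abs(shallow - mode) <= 0.3]
    return float(near.mean()) if near.size else float(mode)


def correct_drift(trace: pd.DataFrame, window: float = 1800.0,
                  return_offsets: bool = False):
    """Remove the slowly drifting depth-zero offset.

    Within sliding windows the modal near-surface depth is estimated and
    subtracted (linearly interpolated between window centres); residual
    negative depths are set to 0.
    """
    if trace.empty:
        raise InputError("empty trace")
    out = trace.copy()
    offsets_all = []
    for ind, grp in trace.groupby("individual", sort=False):
        t = grp["time"].to_numpy(float)
        d = grp["depth"].to_numpy(float)
        span = t[-1] - t[0]
        if span <= window:
            warnings.warn(
                f"{ind}: correction window longer than trace; using a "
                "single global offset", stacklevel=2)
            centers = np.array([0.5 * (t[0] + t[-1])])
            modes = np.array([_surface_mode(d)])
        else:
            edges = np.arange(t[0], t[-1] + window, window)
            centers, modes = [], []
            for lo, hi in zip(edges[:-1], edges[1:]):
                sel = (t >= lo) & (t < hi)
                if sel.sum() < 10:
                    continue
                m = _surface_mode(d[sel])
                if np.isfinite(m):
                    centers.append(0.5 * (lo + hi))
                    modes.append(m)
            centers, modes = np.asarray(centers), np.asarray(modes)
        if centers.size == 0:
            continue
        offset = np.interp(t, centers, modes)
        corrected = d - offset
        corrected[corrected < 0] = 0.0
        out.loc[grp.index, "depth"] = corrected
        offsets_all.append(pd.DataFrame(
            {"individual": ind, "time": centers, "offset": modes}))
    if return_offsets:
        return out, (pd.concat(offsets_all, ignore_index=True)
                     if offsets_all else pd.DataFrame())
    return out


# ---------------------------------------------------------------------------
# dive delimitation

def _segments(times: np.ndarray, dt: float):
    """Index bounds of contiguous uniformly sampled blocks."""
    gaps = np.nonzero(np.diff(times) > 1.5 * dt)[0]
    starts = np.concatenate([[0], gaps + 1])
    stops = np.concatenate([gaps + 1, [times.size]])
    return zip(starts, stops)


def detect_dives(trace: pd.DataFrame, min_depth: float = MIN_DEPTH,
                 min_duration: float = MIN_DURATION,
                 dive_threshold: float = DIVE_THRESHOLD) -> pd.DataFrame:
    """Maximal wet intervals (depth > threshold) that reach ``min_depth``
    and last ``min_duration``; non-overlapping and time-ordered."""
    rows = []
    for ind, grp in trace.groupby("individual", sort=False):
        t = grp["time"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise InputError(f"{ind}: time not strictly increasing")
        d = grp["depth"].to_numpy(float)
        dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
        meta = grp.iloc[0]
        base = grp.index[0]
        for s0, s1 in _segments(t, dt):
            wet = d[s0:s1] > dive_threshold
            padded = np.concatenate([[False], wet, [False]])
            edges = np.flatnonzero(np.diff(padded.astype(int)))
            for a, b in zip(edges[::2], edges[1::2]):
                seg = d[s0 + a:s0 + b]
                dur = seg.size * dt
                if seg.max() < min_depth or dur < min_duration:
                    continue
                rows.append({
                    "individual": ind, "species": meta.get("species"),
                    "sex": meta.get("sex"),
                    "start": t[s0 + a], "end": t[s0 + b - 1],
                    "i0": int(base + s0 + a), "i1": int(base + s0 + b),
                    "duration": dur, "max_depth": float(seg.max()),
                    "dt": dt,
                })
    cols = ["individual", "species", "sex", "start", "end", "i0", "i1",
            "duration", "max_depth", "dt"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# shape metrics and classification

def extract_shape(depths: np.ndarray, dt: float) -> dict:
    """Bottom time, wiggle and plateau counts for one dive segment."""
    i0, i1, bottom_time = _shape.bottom_phase(depths, dt)
    n_wiggles = _shape.count_wiggles(depths, i0, i1)
    plateaus = _shape.find_plateaus(depths, dt, i0, i1)
    return {
        "bottom_time": bottom_time,
        "n_wiggles": n_wiggles,
        "n_plateaus": len(plateaus),
        "has_bottom": bottom_time >= HAS_BOTTOM_MIN,
        "has_wiggle": n_wiggles > 0,
        "has_plateau": len(plateaus) > 0,
    }


def classify(dive: pd.Series | dict) -> str:
    """transit / search / forage from the signature flags and max depth."""
    if dive["has_bottom"] or dive["has_wiggle"] or dive["has_plateau"]:
        return "forage"
    return "transit" if dive["max_depth"] < TRANSIT_MAX_DEPTH else "search"


def analyze(trace: pd.DataFrame, drift_window: float = 1800.0,
            min_depth: float = MIN_DEPTH, min_duration: float = MIN_DURATION,
            correct: bool = True) -> pd.DataFrame:
    """Full per-trace dive table: drift correction, delimitation, shape
    extraction and classification."""
    _require_columns(trace, ("individual", "time", "depth"), "depth trace")
    corrected = correct_drift(trace, window=drift_window) if correct else trace
    dives = detect_dives(corrected, min_depth=min_depth,
                         min_duration=min_duration)
    depth_arr = corrected["depth"].to_numpy(float)
    shapes = [extract_shape(depth_arr[r.i0:r.i1], r.dt)
              for r in dives.itertuples(index=False)]
    if shapes:
        dives = pd.concat([dives, pd.DataFrame(shapes, index=dives.index)],
                          axis=1)
        dives["behavior"] = [classify(r) for _, r in dives.iterrows()]
    else:
        for c in ("bottom_time", "n_wiggles", "n_plateaus", "has_bottom",
                  "has_wiggle", "has_plateau", "behavior"):
            dives[c] = []
    dives["day"] = (dives["start"] // 86400).astype(int) if len(dives) else []
    return dives


# ---------------------------------------------------------------------------
# summaries

def foraging_depth_mode(depths, grid_step: float = 0.5) -> float:
    """Most frequent foraging depth: argmax of a 1-D Gaussian kernel density
    (normal-reference bandwidth) over foraging-dive max depths, evaluated on
    a regular grid.  Ties break to the shallowest depth."""
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise UndefinedResultError("no foraging dives")
    sd = depths.std(ddof=1) if depths.size > 1 else 0.0
    iqr = np.subtract(*np.percentile(depths, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        return float(depths.min())
    bw = 1.06 * scale * depths.size ** (-0.2)
    grid = np.arange(max(depths.min() - 3 * bw, 0.0),
                     depths.max() + 3 * bw + grid_step, grid_step)
    dens = np.exp(-0.5 * ((grid[:, None] - depths[None, :]) / bw) ** 2).sum(
        axis=1)
    return float(grid[np.argmax(dens)])


def at_sea_hours(trace: pd.DataFrame, dry_gap: float = 3600.0,
                 surface_threshold: float = DIVE_THRESHOLD) -> pd.Series:
    """At-sea hours per individual: total recorded span minus continuous
    surface intervals longer than ``dry_gap`` (haul-outs)."""
    out = {}
    for ind, grp in trace.groupby("individual", sort=False):
        t = grp["time"].to_numpy(float)
        d = grp["depth"].to_numpy(float)
        dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
        total = 0.0
        for s0, s1 in _segments(t, dt):
            seg_d = d[s0:s1]
            span = (s1 - s0) * dt
            dry = seg_d <= surface_threshold
            padded = np.concatenate([[False], dry, [False]])
            edges = np.flatnonzero(np.diff(padded.astype(int)))
            for a, b in zip(edges[::2], edges[1::2]):
                run = (b - a) * dt
                if run > dry_gap:
                    span -= run
            total += span
        out[ind] = total / 3600.0
    return pd.Series(out, name="at_sea_hours")


def summarize(dives: pd.DataFrame, hours: pd.Series | None = None
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual and per-species behavioural summary.

    Signature proportions are computed per individual over its foraging
    dives, then averaged (mean +- SD) across the individuals of a species.
    Dive frequency is foraging dives per at-sea hour.
    """
    per_ind = []
    for ind, grp in dives.groupby("individual", sort=False):
        forage = grp[grp["behavior"] == "forage"]
        if forage.empty:
            log.warning("%s has no foraging dives; excluded from "
                        "proportion averaging", ind)
            continue
        row = {
            "individual": ind, "species": grp["species"].iloc[0],
            "n_forage": len(forage),
            "p_bottom": forage["has_bottom"].mean(),
            "p_wiggle": forage["has_wiggle"].mean(),
            "p_plateau": forage["has_plateau"].mean(),
            "depth_mode": foraging_depth_mode(forage["max_depth"]),
            "mean_duration": forage["duration"].mean(),
        }
        if hours is not None and ind in hours.index and hours[ind] > 0:
            row["dive_frequency"] = len(forage) / hours[ind]
        per_ind.append(row)
    per_ind = pd.DataFrame(per_ind)
    if per_ind.empty:
        return per_ind, pd.DataFrame()
    metrics = [c for c in ("p_bottom", "p_wiggle", "p_plateau", "depth_mode",
                           "mean_duration", "dive_frequency")
               if c in per_ind.columns]
    agg = per_ind.groupby("species")[metrics].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return per_ind, agg.reset_index()
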