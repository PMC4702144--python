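"""Synthetic-data generators with known ground truth.

Three generators emulate the field campaign: central-place-foraging tracks
around two colonies, time-depth-recorder traces with planted transit /
search / foraging dive shapes, and see-saw AUV missions over a stratified
water column with planted elliptical prey aggregations.  Every generated
entity carries exactly one ground-truth record, so each downstream stage can
be validated round-trip without any external data.

All three generators derive their randomness from ``SimConfig.seed``; the
same config yields byte-identical outputs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import Point, Polygon

from . import _shape
from .config import (ADELIE, GENTOO, SPECIES, DiveShapeParams, SimConfig)
from .exceptions import ConfigError

TRANSIT, SEARCH, FORAGE = "transit", "search", "forage"


# ---------------------------------------------------------------------------
# ground truth container

@dataclass
class GroundTruth:
    """One truth record per generated entity."""

    individuals: pd.DataFrame | None = None
    dives: pd.DataFrame | None = None
    aggregations: pd.DataFrame | None = None
    profiles: pd.DataFrame | None = None
    overlap_polygon: Polygon | None = None
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        doc = {"params": self.params}
        for name in ("individuals", "dives", "aggregations", "profiles"):
            df = getattr(self, name)
            if df is not None:
                doc[name] = df.to_dict(orient="records")
        if self.overlap_polygon is not None:
            doc["overlap_polygon_wkt"] = self.overlap_polygon.wkt
        with open(path, "w") as fh:
            json.dump(doc, fh, default=str)


def overlap_polygon(config: SimConfig) -> Polygon:
    """The designated overlap zone (a disk in the local frame)."""
    cx, cy = config.tracks.overlap_center
    return Point(cx, cy).buffer(config.tracks.overlap_radius, quad_segs=64)


# ---------------------------------------------------------------------------
# planted dive profiles

def _ramp(depth: float, rate: float, dt: float) -> np.ndarray:
    step = rate * dt
    return np.arange(step, depth - 1e-9, step)


def build_v_dive(depth: float, rate: float, dt: float) -> np.ndarray:
    down = _ramp(depth, rate, dt)
    return np.concatenate([down, [depth], down[::-1]])


def build_nonforage_v_dive(depth: float, rate: float, dt: float) -> np.ndarray:
    """V-dive guaranteed to stay below 5 s of bottom-band time, so it can
    never be classified as foraging.  Sample-grid alignment can push a plain
    V over the band-time threshold; nudge the depth until it cannot."""
    best = None
    for _ in range(40):
        prof = build_v_dive(depth, rate, dt)
        _, _, bt = _shape.bottom_phase(prof, dt)
        if bt <= 2.0 * dt + 1e-9:
            return prof
        if best is None or bt < best[0]:
            best = (bt, prof)
        depth -= 0.2 * rate * dt / 1.5
    if best[0] < 4.5:
        return best[1]
    raise ConfigError("cannot build a non-foraging V-dive at this depth")


_DIP_SHAPE = np.array([0.343, 0.686, 1.0, 0.686, 0.343])


def build_bottom_dive(depth: float, bottom_s: float, n_wiggles: int,
                      with_plateau: bool, p: DiveShapeParams,
                      dt: float) -> np.ndarray:
    """Foraging dive with a flat bottom phase, planted wiggle oscillations
    and optionally an ascent plateau shelf."""
    down = _ramp(depth, p.descent_rate, dt)
    per_wiggle = _DIP_SHAPE.size + 4
    flat0 = max(int(round(bottom_s / dt)) - n_wiggles * per_wiggle, 4)
    bottom = [np.full(flat0, depth)]
    dip = depth - p.wiggle_amp * _DIP_SHAPE
    for _ in range(n_wiggles):
        bottom.append(dip)
        bottom.append(np.full(4, depth))
    up = down[::-1]
    if with_plateau:
        up = _insert_shelf(up, p.plateau_depth_frac * depth,
                           int(round(p.plateau_duration / dt)))
    return np.concatenate([down, *bottom, up])


def _insert_shelf(up: np.ndarray, shelf_depth: float, n: int) -> np.ndarray:
    idx = int(np.argmin(np.abs(up - shelf_depth)))
    return np.concatenate([up[:idx], np.full(n, up[idx]), up[idx:]])


def build_shallow_plateau_dive(depth: float, p: DiveShapeParams,
                               dt: float) -> np.ndarray:
    """Shallow foraging dive whose only signature is an ascent plateau
    (too brief near the maximum to accrue bottom time)."""
    down = _ramp(depth, p.descent_rate, dt)
    up = _insert_shelf(down[::-1], p.plateau_depth_frac * depth,
                       int(round(p.plateau_duration / dt)))
    return np.concatenate([down, [depth], up])


# ---------------------------------------------------------------------------
# itinerary: individuals, trips and the dive schedule

def _make_individuals(config: SimConfig, rng: np.random.Generator,
                      poly: Polygon) -> pd.DataFrame:
    tp = config.tracks
    rows = []
    for sp in SPECIES:
        n = config.n_individuals.get(sp, 0)
        n_overlap = int(round(tp.overlap_fraction.get(sp, 0.0) * n))
        cx, cy = tp.foraging_centers[sp]
        ox, oy = tp.overlap_center
        for i in range(n):
            uses_overlap = i < n_overlap
            # every individual's home centre sits in its species' area;
            # overlap users additionally make day-trips into the shared
            # zone (handled by the itinerary planner)
            for _ in range(200):
                fx = cx + rng.normal(0, tp.center_scatter_sd)
                fy = cy + rng.normal(0, tp.center_scatter_sd)
                if not poly.contains(Point(fx, fy)):
                    break
            rows.append({
                "individual": f"{sp[:2]}{i + 1:02d}", "species": sp,
                "sex": "F" if i % 2 == 0 else "M",
                "colony_x": tp.colony_centers[sp][0],
                "colony_y": tp.colony_centers[sp][1],
                "forage_x": fx, "forage_y": fy,
                "overlap_user": uses_overlap,
            })
    return pd.DataFrame(rows)


def _plan(config: SimConfig):
    """Deterministic itinerary shared by the track and depth-trace
    generators: who goes where and which dives they perform when."""
    config.validate()
    rng = config.rng("plan")
    poly = overlap_polygon(config)
    individuals = _make_individuals(config, rng, poly)
    tides = config.tide_for_days()
    dt = config.sampling_interval
    eff_sp = config.overlap_effect_species

    tp = config.tracks
    ox, oy = tp.overlap_center
    dives, trips = [], []
    for ind in individuals.itertuples(index=False):
        p: DiveShapeParams = config.dive_params[ind.species]
        colony = np.array([ind.colony_x, ind.colony_y])
        home = np.array([ind.forage_x, ind.forage_y])
        if ind.overlap_user and config.days > 1:
            # overlap users split their days between the shared zone and
            # the home area (always at least one of each, so the
            # within-individual contrast exists by design)
            n_zone = int(np.clip(round(tp.p_zone_trip * config.days),
                                 1, config.days - 1))
            zone_days = set(rng.choice(config.days, n_zone, replace=False))
        elif ind.overlap_user:
            zone_days = {0}
        else:
            zone_days = set()
        for day in range(config.days):
            if day in zone_days:
                r = tp.overlap_radius * np.sqrt(rng.uniform(0.02, 0.2))
                theta = rng.uniform(0, 2 * np.pi)
                center = np.array([ox + r * np.cos(theta),
                                   oy + r * np.sin(theta)])
            else:
                center = home
            t_leg = float(np.linalg.norm(center - colony)) / tp.swim_speed
            depart = day * 86400.0 + 6 * 3600.0 + rng.uniform(0, 3600.0)
            t = depart
            trip_dives = []

            def leg(t0, a, b, outbound):
                for k in range(p.n_transit_dives):
                    frac = (k + 0.5) / p.n_transit_dives
                    start = t0 + frac * t_leg
                    d = rng.uniform(*p.transit_range)
                    prof = build_nonforage_v_dive(d, p.transit_rate, dt)
                    pos = a + frac * (b - a)
                    trip_dives.append((start, prof, TRANSIT, pos, 0, 0))

            leg(t, colony, center, True)
            t += t_leg
            # dive sites follow a mean-reverting random walk around the trip
            # target so successive fixes imply realistic swim speeds
            sc = config.tracks.site_scatter_sd
            site = center + rng.normal(0, sc / 4.0, 2)
            prev_t = t
            for _ in range(p.dives_per_trip):
                t += max(rng.normal(p.surface_mean, p.surface_sd), 8.0)
                gap = max(t - prev_t, 8.0)
                prev_t = t
                step_sd = min(sc / 6.0, 0.7 * gap)
                site = center + 0.97 * (site - center) + \
                    rng.normal(0, step_sd, 2)
                in_ov = poly.contains(Point(*site))
                shift = (config.overlap_effect
                         if in_ov and ind.species == eff_sp else 0.0)
                if rng.random() < p.p_forage_at_site:
                    if rng.random() < p.p_bottom:
                        d = float(np.clip(rng.normal(p.depth_mean, p.depth_sd),
                                          p.depth_min, p.depth_max)) + shift
                        wig = rng.random() < p.p_wiggle / p.p_bottom
                        k = int(min(1 + rng.poisson(1.2), 4)) if wig else 0
                        extra = max(0.0, p.p_plateau - (1 - p.p_bottom))
                        plat = rng.random() < extra / p.p_bottom
                        bs = max(rng.normal(p.bottom_time_mean,
                                            p.bottom_time_sd),
                                 p.bottom_time_min)
                        if k:
                            bs = max(bs, 4.0 + 9.0 * k * dt)
                        prof = build_bottom_dive(d, bs, k, plat, p, dt)
                        trip_dives.append((t, prof, FORAGE, site, k, int(plat)))
                    else:
                        d = rng.uniform(*p.shallow_range) + shift
                        prof = build_shallow_plateau_dive(d, p, dt)
                        trip_dives.append((t, prof, FORAGE, site, 0, 1))
                else:
                    d = rng.uniform(*p.search_range)
                    prof = build_nonforage_v_dive(d, p.descent_rate, dt)
                    trip_dives.append((t, prof, SEARCH, site, 0, 0))
                t += len(trip_dives[-1][1]) * dt
            leg(t, site, colony, False)   # homeward from the last dive site
            t += t_leg
            arrival = t

            for start, prof, behavior, pos, k_wig, n_plat in trip_dives:
                i0, i1, bt = _shape.bottom_phase(prof, dt)
                in_ov = poly.contains(Point(*pos))
                dives.append({
                    "individual": ind.individual, "species": ind.species,
                    "sex": ind.sex, "day": day, "tide": tides[day],
                    "start": start,
                    "duration": float((prof > 1.0).sum()) * dt,
                    "behavior": behavior, "max_depth": float(prof.max()),
                    "bottom_time": bt,
                    "n_wiggles": k_wig, "n_plateaus": n_plat,
                    "has_bottom": bt >= 5.0,
                    "has_wiggle": k_wig > 0, "has_plateau": n_plat > 0,
                    "x": pos[0], "y": pos[1], "in_overlap": bool(in_ov),
                    "profile_samples": prof,
                })
            trips.append({
                "individual": ind.individual, "species": ind.species,
                "sex": ind.sex, "day": day, "tide": tides[day],
                "depart": depart, "arrival": arrival, "t_leg": t_leg,
                "colony": colony, "center": center,
                "return_from": site.copy(),
            })
    return individuals, pd.DataFrame(dives), trips, poly


# ---------------------------------------------------------------------------
# public generators

def generate_tracks(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Location records for every individual: colony fixes, travel fixes and
    one fix per dive, with additive position noise and optional planted
    outliers."""
    individuals, dives, trips, poly = _plan(config)
    rng = config.rng("tracks")
    tp = config.tracks
    rows = []
    for trip in trips:
        a, b = trip["colony"], trip["center"]
        def emit(t, pos, true_kind):
            noisy = np.asarray(pos, dtype=float) + rng.normal(
                0, tp.position_noise_sd, 2)
            rows.append({
                "individual": trip["individual"], "species": trip["species"],
                "sex": trip["sex"], "day": trip["day"], "tide": trip["tide"],
                "time": t, "x": noisy[0], "y": noisy[1],
                "quality": str(rng.integers(1, 4)), "kind": true_kind,
            })
        emit(trip["depart"] - 60.0, a, "colony")
        n_fix = max(int(trip["t_leg"] // tp.travel_fix_interval), 1)
        # fix phase deliberately differs from the transit-dive phase so no
        # two records ever share a timestamp
        for k in range(n_fix):
            frac = (k + 0.37) / n_fix
            emit(trip["depart"] + frac * trip["t_leg"],
                 a + frac * (b - a), "travel")
        mask = (dives["individual"] == trip["individual"]) & \
               (dives["day"] == trip["day"])
        for dv in dives.loc[mask].itertuples(index=False):
            emit(dv.start, (dv.x, dv.y), "dive")
        t_back = trip["arrival"] - trip["t_leg"]
        ret = trip["return_from"]
        for k in range(n_fix):
            frac = (k + 0.37) / n_fix
            emit(t_back + frac * trip["t_leg"], ret + frac * (a - ret),
                 "travel")
        emit(trip["arrival"] + 60.0, a, "colony")

    tracks = pd.DataFrame(rows).sort_values(
        ["individual", "time"], kind="stable").reset_index(drop=True)
    tracks["is_outlier"] = False
    if tp.outlier_fraction > 0:
        for ind, grp in tracks.groupby("individual"):
            idx = grp.index[1:-1]
            n_out = int(round(tp.outlier_fraction * len(idx)))
            if n_out:
                chosen = rng.choice(idx, size=n_out, replace=False)
                theta = rng.uniform(0, 2 * np.pi, n_out)
                tracks.loc[chosen, "x"] += tp.outlier_offset * np.cos(theta)
                tracks.loc[chosen, "y"] += tp.outlier_offset * np.sin(theta)
                tracks.loc[chosen, "is_outlier"] = True

    truth = GroundTruth(
        individuals=individuals, overlap_polygon=poly,
        params={"overlap_effect": config.overlap_effect,
                "overlap_effect_species": config.overlap_effect_species})
    return tracks, truth


def generate_tdr(config: SimConfig, truth_region: Polygon | None = None
                 ) -> tuple[pd.DataFrame, GroundTruth]:
    """Depth traces: per-trip contiguous blocks of surface and planted dives,
    with linear sensor drift and additive depth noise.

    ``truth_region`` defaults to the configured overlap zone and only affects
    which truth records are flagged in-overlap; the planted depth shift always
    follows the configured zone so tracks and traces stay consistent.
    """
    individuals, dives, trips, poly = _plan(config)
    if truth_region is not None:
        pts = [Point(x, y) for x, y in zip(dives["x"], dives["y"])]
        dives["in_overlap"] = [truth_region.contains(p) for p in pts]
        poly = truth_region
    rng = config.rng("tdr")
    dt = config.sampling_interval
    pad = 120.0

    frames = []
    drifts = {}
    for ind in individuals.itertuples(index=False):
        ind_trips = [t for t in trips if t["individual"] == ind.individual]
        ind_dives = dives[dives["individual"] == ind.individual]
        t_first = min(t["depart"] for t in ind_trips) - pad
        t_last = max(t["arrival"] for t in ind_trips) + pad
        drift = rng.uniform(-config.drift_max, config.drift_max)
        drifts[ind.individual] = drift
        for trip in ind_trips:
            t0 = trip["depart"] - pad
            n = int(round((trip["arrival"] + pad - t0) / dt)) + 1
            times = t0 + np.arange(n) * dt
            depth = np.zeros(n)
            day_dives = ind_dives[ind_dives["day"] == trip["day"]]
            for dv in day_dives.itertuples(index=False):
                i = int(round((dv.start - t0) / dt))
                prof = dv.profile_samples
                depth[i:i + prof.size] = prof
            depth = depth + drift * (times - t_first) / (t_last - t_first)
            if config.depth_noise_sd > 0:
                depth = depth + rng.normal(0, config.depth_noise_sd, n)
            frames.append(pd.DataFrame({
                "individual": ind.individual, "species": ind.species,
                "sex": ind.sex, "time": times, "depth": depth,
            }))

    tdr = pd.concat(frames, ignore_index=True)
    truth_dives = dives.drop(columns=["profile_samples"]).copy()
    truth_dives["date"] = truth_dives["day"]
    individuals = individuals.copy()
    individuals["drift_m"] = individuals["individual"].map(drifts)
    truth = GroundTruth(
        individuals=individuals, dives=truth_dives, overlap_polygon=poly,
        params={"overlap_effect": config.overlap_effect,
                "overlap_effect_species": config.overlap_effect_species,
                "depth_noise_sd": config.depth_noise_sd,
                "sampling_interval": dt})
    return tdr, truth


# ---------------------------------------------------------------------------
# AUV missions

def _along_track_fields(config: SimConfig, x: np.ndarray,
                        rng: np.random.Generator) -> dict[str, np.ndarray]:
    oc = config.ocean
    out = {}
    for name, base in (("mld", oc.mld), ("thermocline", oc.thermocline),
                       ("chl_max_depth", oc.chl_max_depth),
                       ("attenuation", oc.attenuation)):
        phase = rng.uniform(0, 2 * np.pi)
        out[name] = base * (1 + oc.variation_amp *
                            np.sin(2 * np.pi * x / oc.variation_length + phase))
    return out


def _vehicle_depth(config: SimConfig, x: np.ndarray) -> np.ndarray:
    m = config.mission
    cycle = 2 * m.leg_length_m
    phase = (x % cycle) / m.leg_length_m
    tri = np.where(phase <= 1.0, phase, 2.0 - phase)
    return m.min_depth + (m.max_depth - m.min_depth) * tri


def _sample_geometry(ag, rng: np.random.Generator, dense: bool
                     ) -> tuple[float, float]:
    """Full height and length (m) of one planted aggregation."""
    ln_h0 = np.log(ag.diffuse_height_median)
    ln_l0 = np.log(ag.diffuse_length_median)
    if not dense:
        h = np.exp(rng.normal(ln_h0, ag.height_sigma))
        length = np.exp(rng.normal(ln_l0, ag.length_sigma))
    elif rng.random() < ag.dense_layer_frac:
        h = np.exp(rng.normal(ln_h0 + np.log(ag.layer_height_mult),
                              ag.height_sigma))
        length = np.exp(rng.normal(ln_l0 + np.log(ag.layer_length_mult),
                                   ag.length_sigma))
    else:
        ln_h = rng.normal(ln_h0 + ag.dense_height_shift, ag.height_sigma)
        # compact swarms: longer ones are flatter (anti-correlated axes)
        ln_l = ln_l0 - (ln_h - (ln_h0 + ag.dense_height_shift)) + \
            rng.normal(0, ag.anticorr_eps_sd)
        h, length = np.exp(ln_h), np.exp(ln_l)
    return float(h), float(length)


def generate_auv_mission(config: SimConfig, day: int = 0
                         ) -> tuple[xr.Dataset, pd.DataFrame, GroundTruth]:
    """One see-saw mission: gridded echogram with planted elliptical
    aggregations, the along-track sensor record, and truth for every planted
    patch and every vertical profile (one per monotone leg)."""
    config.validate()
    m, oc, ag = config.mission, config.ocean, config.aggregations
    if ag.depth_range[1] > m.max_depth:
        raise ConfigError(
            "mission max depth is shallower than the deepest planted "
            "aggregation")
    rng = config.rng("auv", day)
    dx, dz = m.distance_res, m.depth_res
    x = (np.arange(int(m.length_m / dx)) + 0.5) * dx
    z = (np.arange(int(m.depth_extent / dz)) + 0.5) * dz
    fields = _along_track_fields(config, x, rng)
    Z = z[:, None]
    temp = oc.temp_below + (oc.temp_above - oc.temp_below) * 0.5 * (
        1 + np.tanh((fields["thermocline"][None, :] - Z) /
                    oc.transition_width))
    dens = oc.density_above + (oc.density_below - oc.density_above) * 0.5 * (
        1 + np.tanh((Z - fields["mld"][None, :]) / oc.transition_width))
    chl = oc.chl_background + oc.chl_peak * np.exp(
        -0.5 * ((Z - fields["chl_max_depth"][None, :]) / oc.chl_width) ** 2)
    par = oc.surface_par * np.exp(-fields["attenuation"][None, :] * Z)

    sv = np.full((z.size, x.size), ag.background_sv, dtype=float)
    if ag.background_depth_gradient:
        sv += ag.background_depth_gradient * Z
    if ag.background_sd > 0:
        sv += rng.normal(0, ag.background_sd, sv.shape)

    # aggregation placement: windows weighted by the local isolume depth
    # (shallower light penetration attracts more patches)
    cycle = 2 * m.leg_length_m
    n_win = max(int(m.length_m // cycle), 1)
    win_centers = (np.arange(n_win) + 0.5) * cycle
    iso_win = np.interp(win_centers, x, np.log(oc.surface_par) /
                        fields["attenuation"])
    iso_z = ((iso_win - iso_win.mean()) / iso_win.std()
             if iso_win.std() > 0 else np.zeros_like(iso_win))
    logw = ag.presence_isolume_slope * iso_z
    weights = np.exp(logw - logw.max())
    weights /= weights.sum()

    placed = []
    agg_rows = []
    types = [("dense", True)] * ag.n_dense + [("diffuse", False)] * ag.n_diffuse
    for i, (tname, dense) in enumerate(types):
        for _ in range(80):
            h, length = _sample_geometry(ag, rng, dense)
            a, b = length / 2.0, h / 2.0
            b = max(b, 0.55 * dz)
            a = max(a, 1.5 * dx)
            if np.pi * a * b / (dx * dz) < 6:
                continue
            win = rng.choice(n_win, p=weights)
            x0 = win * cycle + rng.uniform(a, cycle - a) if cycle > 2 * a \
                else win * cycle + cycle / 2.0
            z0 = rng.uniform(*ag.depth_range)
            z0 = float(np.clip(z0, b + dz, m.max_depth - b - dz))
            sep_x = ag.min_separation_cells * dx
            sep_z = ag.min_separation_cells * dz
            bbox = (x0 - a - sep_x, x0 + a + sep_x,
                    z0 - b - sep_z, z0 + b + sep_z)
            if any(bbox[0] < o[1] and bbox[1] > o[0] and
                   bbox[2] < o[3] and bbox[3] > o[2] for o in placed):
                continue
            placed.append(bbox)
            # rasterize on a local window around the ellipse
            jx0 = max(int((x0 - a) / dx) - 1, 0)
            jx1 = min(int((x0 + a) / dx) + 2, x.size)
            jz0 = max(int((z0 - b) / dz) - 1, 0)
            jz1 = min(int((z0 + b) / dz) + 2, z.size)
            sub = (((x[None, jx0:jx1] - x0) / a) ** 2 +
                   ((z[jz0:jz1, None] - z0) / b) ** 2) <= 1.0
            if not sub.any():
                continue
            mean_sv = (ag.sv_dense if dense else ag.sv_diffuse) + \
                rng.normal(0, ag.sv_patch_sd)
            vals = mean_sv + (rng.normal(0, ag.sv_cell_sd, int(sub.sum()))
                              if ag.sv_cell_sd > 0 else 0.0)
            window = sv[jz0:jz1, jx0:jx1]
            window[sub] = np.maximum(window[sub], vals)
            izs, ixs = np.nonzero(sub)
            iz, ix = izs + jz0, ixs + jx0
            mask_sum = int(sub.sum())
            agg_rows.append({
                "day": day, "agg_id": f"d{day}a{i:03d}", "type": tname,
                "x_center": x0, "depth_center": z0,
                "length": 2 * a, "height": 2 * b,
                "length_raster": (ix.max() - ix.min() + 1) * dx,
                "height_raster": (iz.max() - iz.min() + 1) * dz,
                "n_cells_raster": mask_sum,
                "area": np.pi * a * b, "lh_ratio": (2 * a) / (2 * b),
                "mean_sv": mean_sv, "n_cells": mask_sum,
                "x_min": x[ix.min()] - dx / 2, "x_max": x[ix.max()] + dx / 2,
                "truncated": bool(iz.min() == 0 or iz.max() == z.size - 1 or
                                  ix.min() == 0 or ix.max() == x.size - 1),
            })
            break

    vd = _vehicle_depth(config, x)
    sensor = pd.DataFrame({
        "day": day, "distance": x, "time": x / 1.5, "depth": vd,
        "temperature": _at_vehicle(temp, z, vd) +
        (rng.normal(0, oc.temp_noise, x.size) if oc.temp_noise else 0.0),
        "density": _at_vehicle(dens, z, vd) +
        (rng.normal(0, oc.density_noise, x.size) if oc.density_noise else 0.0),
        "chl": np.maximum(_at_vehicle(chl, z, vd) +
                          (rng.normal(0, oc.chl_noise, x.size)
                           if oc.chl_noise else 0.0), 0.0),
        "par": _at_vehicle(par, z, vd) *
        (np.exp(rng.normal(0, oc.par_noise_frac, x.size))
         if oc.par_noise_frac else 1.0),
    })

    # profile truth: one monotone leg per profile
    leg_edges = np.arange(0, m.length_m + 1e-9, m.leg_length_m)
    prof_rows = []
    aggs = pd.DataFrame(agg_rows)
    for k in range(len(leg_edges) - 1):
        x0, x1 = leg_edges[k], leg_edges[k + 1]
        cols = (x >= x0) & (x < x1)
        iso = np.log(oc.surface_par) / fields["attenuation"][cols]
        row = {
            "day": day, "profile_id": f"d{day}p{k:03d}",
            "x_start": x0, "x_end": x1,
            "mld": fields["mld"][cols].mean(),
            "thermocline": fields["thermocline"][cols].mean(),
            "chl_max_depth": fields["chl_max_depth"][cols].mean(),
            "chl_max": oc.chl_background + oc.chl_peak,
            "isolume": iso.mean(),
            # mean PAR over the sampled upper 2 m (vehicle apex region)
            "surface_par": oc.surface_par * float(np.exp(
                -fields["attenuation"][cols].mean() *
                0.5 * (m.min_depth + 2.0))),
        }
        for tname in ("dense", "diffuse"):
            if len(aggs):
                sub = aggs[aggs["type"] == tname]
                row[f"{tname}_present"] = bool(
                    ((sub["x_min"] < x1) & (sub["x_max"] > x0)).any())
            else:
                row[f"{tname}_present"] = False
        prof_rows.append(row)

    echo = xr.Dataset(
        {"sv": (("depth", "distance"), sv),
         "vehicle_depth": ("distance", vd)},
        coords={"depth": z, "distance": x},
        attrs={"day": day, "distance_res": dx, "depth_res": dz,
               "mission_max_depth": m.max_depth,
               "background_sv": ag.background_sv},
    )
    truth = GroundTruth(
        aggregations=aggs, profiles=pd.DataFrame(prof_rows),
        params={"n_placed": len(agg_rows)})
    return echo, sensor, truth


def _at_vehicle(field2d: np.ndarray, z: np.ndarray,
                vd: np.ndarray) -> np.ndarray:
    """Sample a (depth x distance) field along the vehicle path (linear
    interpolation in depth, vectorised over columns)."""
    idx = np.clip(np.searchsorted(z, vd), 1, z.size - 1)
    cols = np.arange(vd.size)
    z0, z1 = z[idx - 1], z[idx]
    f0 = field2d[idx - 1, cols]
    f1 = field2d[idx, cols]
    w = np.clip((vd - z0) / (z1 - z0), 0.0, 1.0)
    return f0 * (1 - w) + f1 * w


# ---------------------------------------------------------------------------
# convenience bundle

@dataclass
class SyntheticDataset:
    tracks: pd.DataFrame
    tdr: pd.DataFrame
    missions: list          # (echogram, sensor, truth) per day
    truth: GroundTruth
    tide_labels: list


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """All pipeline inputs for one synthetic study."""
    tracks, truth_tracks = generate_tracks(config)
    tdr, truth = generate_tdr(config)
    truth.individuals = truth_tracks.individuals.merge(
        truth.individuals[["individual", "drift_m"]], on="individual")
    missions = [generate_auv_mission(config, day)
                for day in range(config.days)]
    truth.aggregations = pd.concat(
        [t.aggregations for _, _, t in missions], ignore_index=True)
    truth.profiles = pd.concat(
        [t.profiles for _, _, t in missions], ignore_index=True)
    return SyntheticDataset(tracks=tracks, tdr=tdr, missions=missions,
                            truth=truth, tide_labels=config.tide_for_days())
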