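"""Full-study orchestration.

``run_pipeline`` executes the stages in dependency order — synthetic data
(or supplied inputs) → dive classification → foraging ranges and overlap →
AUV profiles → aggregation detection → the statistical battery — and
returns a result bundle whose tables mirror the study's result surfaces:

* a dense-vs-diffuse morphometrics table with Mann-Whitney columns,
* per-region and per-tide dive-depth comparisons (ICC-gated K-S / LMM),
* behaviour presence GLMMs and a foraging-dive-duration LMM,
* presence/absence model sets (dAIC) with cross-validation metrics,
* behavioural summaries per individual and species.

Every filter logs records in/out; one root seed drives all stages.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregations as agg_mod
from . import dives as dive_mod
from . import profiles as prof_mod
from . import ranges as range_mod
from . import stats as stats_mod
from .config import ADELIE, GENTOO, SimConfig
from .exceptions import PipelineError
from .simulate import SyntheticDataset, generate_dataset

log = logging.getLogger(__name__)

MORPHO_METRICS = ("mean_depth", "height", "length", "area", "lh_ratio",
                  "mean_sv")

DEFAULT_CANDIDATES = (
    "{resp} ~ isolume_1wm2 + (1|day)",
    "{resp} ~ depth_chl_max + integrated_chl_0_50 + isolume_1wm2 + (1|day)",
    "{resp} ~ mld + density_at_mld + (1|day)",
    "{resp} ~ chl_max + surface_par + (1|day)",
    "{resp} ~ depth_chl_max + integrated_chl_0_50 + isolume_1wm2 "
    "+ density_at_mld + (1|day)",
    "{resp} ~ 1 + (1|day)",
)

PRESENCE_PREDICTORS = ("chl_max", "depth_chl_max", "integrated_chl_0_50",
                       "mld", "density_at_mld", "surface_par",
                       "isolume_1wm2")


@dataclass
class RunConfig:
    """One pipeline run: a simulation config plus stage options."""

    sim: SimConfig = field(default_factory=SimConfig)
    include_auv: bool = True
    contour_level: float = range_mod.RANGE_LEVEL
    core_level: float = range_mod.CORE_LEVEL
    grid_cell: float = range_mod.DEFAULT_CELL
    v_max: float = 3.0
    detect_db_above: float = agg_mod.DETECT_DB_ABOVE
    dense_threshold_db: float = agg_mod.DENSE_THRESHOLD_DB
    min_cells: int = agg_mod.MIN_CELLS
    candidate_models: tuple = DEFAULT_CANDIDATES
    cv_folds: int = 10
    cv_repeats: int = 10
    forage_dives_only_for_kde: bool = True

    @property
    def seed(self) -> int:
        return self.sim.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    """Bundle of stage outputs and report tables."""

    config: RunConfig
    data: SyntheticDataset
    dive_table: pd.DataFrame
    range_estimates: dict                 # (species, tide) -> RangeEstimate
    overlap_areas: pd.DataFrame
    profile_table: pd.DataFrame
    aggregation_table: pd.DataFrame
    tables: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    filter_log: list = field(default_factory=list)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(
            json.dumps(self.config.to_dict(), indent=2, default=str))
        stages = {
            "dives/dive_table.csv": self.dive_table,
            "ranges/overlap_areas.csv": self.overlap_areas,
            "profiles/profile_table.csv": self.profile_table,
            "aggregations/aggregation_table.csv": self.aggregation_table,
        }
        for rel, df in stages.items():
            path = out / rel
            path.parent.mkdir(parents=True, exist_ok=True)
            df.to_csv(path, index=False)
        for name, df in self.tables.items():
            path = out / "report" / f"{name}.csv"
            path.parent.mkdir(parents=True, exist_ok=True)
            if isinstance(df, pd.DataFrame):
                df.to_csv(path, index=False)
        (out / "summary.json").write_text(
            json.dumps(self.summary, indent=2, default=_jsonify))
        (out / "filter_log.json").write_text(
            json.dumps(self.filter_log, indent=2, default=_jsonify))
        self.data.truth.to_json(out / "truth.json")


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    return str(o)


# ---------------------------------------------------------------------------
# stages

def _stage_dives(cfg: RunConfig, data: SyntheticDataset, flog: list
                 ) -> pd.DataFrame:
    dives = dive_mod.analyze(data.tdr)
    tide_map = {d: t for d, t in enumerate(data.tide_labels)}
    dives["tide"] = dives["day"].map(tide_map)
    dives["date"] = dives["day"]
    flog.append({"stage": "dives", "n_in": int(len(data.tdr)),
                 "n_out": int(len(dives))})
    return dives


def _stage_ranges(cfg: RunConfig, data: SyntheticDataset,
                  dives: pd.DataFrame, flog: list):
    tracks = range_mod.speed_filter(data.tracks, v_max=cfg.v_max)
    flog.append({"stage": "speed_filter", "n_in": int(len(data.tracks)),
                 "n_out": int(len(tracks))})
    dives = range_mod.link_dives_to_positions(dives, tracks)
    pos = dives if not cfg.forage_dives_only_for_kde else \
        dives[dives["behavior"] == "forage"]
    estimates = {}
    areas = []
    tides = sorted(set(data.tide_labels))
    for tide in tides:
        for sp in (ADELIE, GENTOO):
            pts = pos[(pos["species"] == sp) & (pos["tide"] == tide)
                      ].dropna(subset=["x", "y"])
            if len(pts) < 10:
                log.warning("too few foraging positions for %s/%s", sp, tide)
                continue
            estimates[(sp, tide)] = range_mod.estimate_range(
                pts, species=sp, tide=tide, cell=cfg.grid_cell,
                levels=(cfg.core_level, cfg.contour_level))
        key_a, key_g = (ADELIE, tide), (GENTOO, tide)
        if key_a in estimates and key_g in estimates:
            geom, area = range_mod.overlap(
                estimates[key_a], estimates[key_g], cfg.contour_level)
            areas.append({"tide": tide, "level": cfg.contour_level,
                          "overlap_km2": area,
                          "adelie_km2":
                          estimates[key_a].areas_km2[cfg.contour_level],
                          "gentoo_km2":
                          estimates[key_g].areas_km2[cfg.contour_level]})
    # tide-pooled ranges for region labelling (per-tide surfaces are kept
    # for the overlap-area report; pooled contours are far more stable at
    # a handful of days per regime)
    for sp in (ADELIE, GENTOO):
        pts = pos[pos["species"] == sp].dropna(subset=["x", "y"])
        if len(pts) >= 10:
            estimates[(sp, None)] = range_mod.estimate_range(
                pts, species=sp, tide=None, cell=cfg.grid_cell,
                levels=(cfg.core_level, cfg.contour_level))
    dives["region"] = "outside"
    key_a, key_g = (ADELIE, None), (GENTOO, None)
    if key_a in estimates and key_g in estimates:
        dives["region"] = range_mod.assign_region(
            dives,
            estimates[key_a].geometry(cfg.contour_level),
            estimates[key_g].geometry(cfg.contour_level),
            label_a="adelie_only", label_b="gentoo_only")
    return dives, estimates, pd.DataFrame(areas)


def _stage_acoustics(cfg: RunConfig, data: SyntheticDataset, flog: list):
    prof_frames, agg_frames = [], []
    for echo, sensor, _ in data.missions:
        day = int(echo.attrs.get("day", 0))
        seg = prof_mod.segment_profiles(sensor, day=day)
        feats = prof_mod.profile_features(seg)
        aggs, _mask = agg_mod.detect_aggregations(
            echo, detect_db_above=cfg.detect_db_above,
            min_cells=cfg.min_cells,
            dense_threshold_db=cfg.dense_threshold_db)
        feats = agg_mod.attach_presence(feats, aggs)
        prof_frames.append(feats)
        agg_frames.append(aggs)
    profile_table = pd.concat(prof_frames, ignore_index=True)
    aggregation_table = pd.concat(agg_frames, ignore_index=True)
    tide_map = {d: t for d, t in enumerate(data.tide_labels)}
    profile_table["tide"] = profile_table["day"].map(tide_map)
    aggregation_table["tide"] = aggregation_table["day"].map(tide_map)
    flog.append({"stage": "acoustics",
                 "n_profiles": int(len(profile_table)),
                 "n_aggregations": int(len(aggregation_table))})
    return profile_table, aggregation_table


# ---------------------------------------------------------------------------
# report tables

def table_morphometrics(aggs: pd.DataFrame) -> pd.DataFrame:
    """Dense vs diffuse morphometrics with Mann-Whitney Z and p."""
    rows = []
    dense = aggs[aggs["type"] == "dense"]
    diffuse = aggs[aggs["type"] == "diffuse"]
    for metric in MORPHO_METRICS:
        row = {"metric": metric,
               "n_dense": len(dense), "n_diffuse": len(diffuse)}
        for name, sub in (("dense", dense), ("diffuse", diffuse)):
            row[f"{name}_mean"] = sub[metric].mean() if len(sub) else np.nan
            row[f"{name}_sd"] = sub[metric].std() if len(sub) else np.nan
        if len(dense) >= 3 and len(diffuse) >= 3:
            res = stats_mod.mann_whitney(dense[metric], diffuse[metric])
            row["mw_z"] = res.extra["z"]
            row["mw_p"] = res.p_value
        else:
            row["mw_z"] = np.nan
            row["mw_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def table_depth_comparisons(dives: pd.DataFrame) -> pd.DataFrame:
    """Species and region dive-depth comparisons, ICC-gated."""
    forage = dives[dives["behavior"] == "forage"]
    rows = []

    def compare(name, a, b, tide):
        if len(a) < 3 or len(b) < 3:
            rows.append({"comparison": name, "tide": tide, "method": "none",
                         "n_x": len(a), "n_y": len(b),
                         "statistic": np.nan, "p": np.nan})
            return
        res = stats_mod.gated_comparison(
            a["max_depth"].to_numpy(), b["max_depth"].to_numpy(),
            a["individual"].to_numpy(), b["individual"].to_numpy())
        res.update({"comparison": name, "tide": tide})
        rows.append(res)

    for tide, sub in forage.groupby("tide"):
        compare("adelie_vs_gentoo",
                sub[sub["species"] == ADELIE],
                sub[sub["species"] == GENTOO], tide)
        ov = sub[sub["region"] == "overlap"]
        compare("adelie_vs_gentoo_in_overlap",
                ov[ov["species"] == ADELIE],
                ov[ov["species"] == GENTOO], tide)
    return pd.DataFrame(rows)


def overlap_contrast_lmm(dives: pd.DataFrame, species: str = GENTOO,
                         region_col: str = "region") -> dict:
    """The headline vertical-partitioning test: within one species, are
    foraging dives deeper inside the interspecific overlap region?
    Random-intercept LMM on sqrt max depth."""
    sub = dives[(dives["species"] == species) &
                (dives["behavior"] == "forage")].copy()
    sub["in_overlap"] = (sub[region_col] == "overlap").astype(float)
    n_in = int(sub["in_overlap"].sum())
    if n_in < 5 or n_in > len(sub) - 5:
        return {"species": species, "n_in_overlap": n_in,
                "n": len(sub), "estimate": np.nan, "stat": np.nan,
                "p": np.nan, "converged": False}
    fit = stats_mod.fit_mixed("max_depth ~ in_overlap + (1|individual)",
                              sub, family="gaussian", transform="sqrt")
    row = fit.coef("in_overlap")
    return {"species": species, "n_in_overlap": n_in, "n": len(sub),
            "estimate": float(row["estimate"]), "se": float(row["se"]),
            "stat": float(row["stat"]), "p": float(row["p"]),
            "converged": fit.converged}


def species_depth_lmm(dives: pd.DataFrame) -> dict:
    """Interspecific maximum-depth difference (LMM, sqrt transform)."""
    sub = dives[dives["behavior"] == "forage"].copy()
    fit = stats_mod.fit_mixed(
        "max_depth ~ species + tide + sex + (1|individual)", sub,
        family="gaussian", transform="sqrt")
    row = fit.coef(f"species[{GENTOO}]")
    means = sub.groupby("species")["max_depth"].mean()
    pct = np.nan
    if ADELIE in means and GENTOO in means and means[ADELIE] > 0:
        pct = 100.0 * (means[GENTOO] - means[ADELIE]) / means[ADELIE]
    return {"stat": float(row["stat"]), "p": float(row["p"]),
            "estimate": float(row["estimate"]),
            "pct_deeper": float(pct)}


def behavior_glmms(dives: pd.DataFrame) -> pd.DataFrame:
    """Presence/absence GLMMs of each foraging signature."""
    forage = dives[dives["behavior"] == "forage"].copy()
    forage, _ = stats_mod.standardize(forage, ["max_depth"])
    rows = []
    for sig in ("has_bottom", "has_wiggle", "has_plateau"):
        forage[sig] = forage[sig].astype(int)
        if forage[sig].nunique() < 2:
            continue
        fit = stats_mod.fit_mixed(
            f"{sig} ~ species + max_depth + tide + sex + (1|individual)",
            forage, family="binomial")
        for _, r in fit.params.iterrows():
            rows.append({"signature": sig, "term": r["term"],
                         "estimate": r["estimate"], "se": r["se"],
                         "z": r["stat"], "p": r["p"],
                         "converged": fit.converged})
    return pd.DataFrame(rows)


def duration_lmm(dives: pd.DataFrame) -> pd.DataFrame:
    forage = dives[dives["behavior"] == "forage"]
    fit = stats_mod.fit_mixed(
        "duration ~ species + tide + (1|individual)", forage,
        family="gaussian")
    return fit.params.assign(model="duration_lmm")


def presence_model_sets(profile_table: pd.DataFrame,
                        candidates=DEFAULT_CANDIDATES,
                        cv_folds: int = 10, cv_repeats: int = 10,
                        seed: int = 0) -> dict:
    """dAIC model sets + VIF screen + repeated CV per aggregation type."""
    out = {}
    for tname in ("dense", "diffuse"):
        resp = f"{tname}_present"
        df = profile_table.dropna(
            subset=list(PRESENCE_PREDICTORS)).copy()
        df[resp] = df[resp].astype(int)
        if df[resp].nunique() < 2:
            out[tname] = {"error": "response has a single class",
                          "model_set": pd.DataFrame(), "cv": {}}
            continue
        df, _ = stats_mod.standardize(df, list(PRESENCE_PREDICTORS))
        entry = {}
        try:
            entry["vif"] = stats_mod.vif(
                df[list(PRESENCE_PREDICTORS)]).to_dict()
        except Exception as e:
            entry["vif"] = {"error": str(e)}
        formulas = [c.format(resp=resp) for c in candidates]
        try:
            ms = stats_mod.model_set(formulas, df, family="binomial")
            entry["model_set"] = ms.table
            best_formula = ms.table.loc[ms.table["aic"].idxmin(), "formula"]
            entry["best_formula"] = best_formula
        except PipelineError as e:
            entry["model_set"] = pd.DataFrame()
            entry["error"] = str(e)
            out[tname] = entry
            continue
        y = df[resp]
        if min((y == 1).sum(), (y == 0).sum()) >= cv_folds:
            cv = stats_mod.cross_validate(
                best_formula, df, family="binomial", folds=cv_folds,
                repeats=cv_repeats, seed=seed)
            entry["cv"] = cv.summary()["mean"].to_dict()
            entry["cv_sd"] = cv.summary()["sd"].to_dict()
        else:
            entry["cv"] = {}
        out[tname] = entry
    return out


# ---------------------------------------------------------------------------
# orchestration

def run_pipeline(cfg: RunConfig, out_dir=None) -> PipelineResult:
    """Execute all stages; any stage failure raises a stage-named
    PipelineError."""
    flog: list = []
    try:
        data = generate_dataset(cfg.sim)
    except Exception as e:
        raise PipelineError(f"stage simulate failed: {e}") from e
    try:
        dive_table = _stage_dives(cfg, data, flog)
    except Exception as e:
        raise PipelineError(f"stage dives failed: {e}") from e
    try:
        dive_table, estimates, areas = _stage_ranges(
            cfg, data, dive_table, flog)
    except Exception as e:
        raise PipelineError(f"stage ranges failed: {e}") from e
    if cfg.include_auv and data.missions:
        try:
            profile_table, aggregation_table = _stage_acoustics(
                cfg, data, flog)
        except Exception as e:
            raise PipelineError(f"stage acoustics failed: {e}") from e
    else:
        log.info("no AUV input; acoustic stages skipped")
        profile_table = pd.DataFrame()
        aggregation_table = pd.DataFrame()

    result = PipelineResult(
        config=cfg, data=data, dive_table=dive_table,
        range_estimates=estimates, overlap_areas=areas,
        profile_table=profile_table, aggregation_table=aggregation_table,
        filter_log=flog)
    try:
        _stage_stats(cfg, result)
    except Exception as e:
        raise PipelineError(f"stage stats failed: {e}") from e
    if out_dir is not None:
        result.write(out_dir)
    return result


def _stage_stats(cfg: RunConfig, result: PipelineResult) -> None:
    dives = result.dive_table
    tables = result.tables
    hours = dive_mod.at_sea_hours(result.data.tdr)
    per_ind, per_species = dive_mod.summarize(dives, hours)
    tables["behavior_by_individual"] = per_ind
    tables["behavior_by_species"] = per_species
    tables["depth_comparisons"] = table_depth_comparisons(dives)
    tables["duration_lmm"] = duration_lmm(dives)
    tables["behavior_glmms"] = behavior_glmms(dives)
    contrast = overlap_contrast_lmm(dives)
    species_lmm = species_depth_lmm(dives)
    summary = {
        "n_dives": int(len(dives)),
        "n_forage_dives": int((dives["behavior"] == "forage").sum()),
        "overlap_areas_km2": result.overlap_areas.to_dict(orient="records"),
        "gentoo_overlap_contrast": contrast,
        "species_depth_lmm": species_lmm,
    }
    if cfg.include_auv and result.data.missions:
        tables["morphometrics"] = table_morphometrics(
            result.aggregation_table)
        summary["n_aggregations"] = {
            t: int((result.aggregation_table["type"] == t).sum())
            for t in ("dense", "diffuse")}
    if not result.profile_table.empty:
        sets = presence_model_sets(
            result.profile_table, candidates=cfg.candidate_models,
            cv_folds=cfg.cv_folds, cv_repeats=cfg.cv_repeats,
            seed=cfg.seed)
        for tname, entry in sets.items():
            if isinstance(entry.get("model_set"), pd.DataFrame):
                tables[f"model_set_{tname}"] = entry["model_set"]
        summary["presence_models"] = {
            t: {k: v for k, v in e.items() if k != "model_set"}
            for t, e in sets.items()}
    result.summary = summary
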