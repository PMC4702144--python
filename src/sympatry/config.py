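"""Simulation and run configuration.

All tunable constants of the synthetic study live here as dataclass fields so
that a configuration can be serialised next to the outputs it produced and a
run can be reproduced exactly from its snapshot.

Coordinates are a local planar (x, y) frame in metres centred between the two
breeding colonies; at the tens-of-kilometres extent of the study area the
planar distortion is negligible and areas are reported in km².
"""
from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError

ADELIE = "adelie"
GENTOO = "gentoo"
SPECIES = (ADELIE, GENTOO)

DIURNAL = "diurnal"
SEMIDIURNAL = "semidiurnal"


@dataclass
class DiveShapeParams:
    """Per-species parameters of the planted dive shapes.

    Depths are metres (positive down), times seconds.  ``p_bottom`` /
    ``p_wiggle`` / ``p_plateau`` are marginal probabilities over foraging
    dives; wiggles are only planted inside dives that carry bottom time
    (a wiggle lives in the bottom phase, so it necessarily contributes
    bottom time), and foraging dives without bottom time are shallow
    plateau-only dives, hence ``p_plateau >= 1 - p_bottom`` is enforced.
    """

    depth_mean: float = 35.0          # bottom-type foraging dives
    depth_sd: float = 10.0
    depth_min: float = 20.0
    depth_max: float = 80.0
    shallow_range: tuple[float, float] = (12.0, 18.0)   # plateau-only dives
    search_range: tuple[float, float] = (11.0, 18.0)
    transit_range: tuple[float, float] = (5.0, 8.0)
    p_bottom: float = 0.84
    p_wiggle: float = 0.17
    p_plateau: float = 0.16
    bottom_time_mean: float = 25.0
    bottom_time_sd: float = 8.0
    bottom_time_min: float = 10.0
    descent_rate: float = 1.5         # m/s, forage & search dives
    transit_rate: float = 0.7
    wiggle_amp: float = 3.5           # m, planted oscillation amplitude
    plateau_duration: float = 15.0    # s
    plateau_depth_frac: float = 0.5   # shelf depth as fraction of max depth
    dives_per_trip: int = 40          # foraging-site dives (forage + search)
    p_forage_at_site: float = 0.7
    n_transit_dives: int = 6          # per travel leg
    surface_mean: float = 30.0        # post-dive surface interval
    surface_sd: float = 8.0

    def validate(self) -> None:
        if self.dives_per_trip <= 0 or self.n_transit_dives < 0:
            raise ConfigError("dive counts must be positive")
        for name in ("depth_sd", "bottom_time_sd", "surface_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.p_plateau < 1.0 - self.p_bottom - 1e-9:
            raise ConfigError(
                "p_plateau must be >= 1 - p_bottom: foraging dives without "
                "bottom time are plateau-only by construction"
            )
        if not (0 < self.descent_rate and 0 < self.transit_rate):
            raise ConfigError("dive rates must be positive")


@dataclass
class TrackParams:
    """Central-place-foraging track geometry (metres)."""

    colony_centers: dict = field(default_factory=lambda: {
        ADELIE: (-8000.0, 0.0), GENTOO: (8000.0, 0.0)})
    foraging_centers: dict = field(default_factory=lambda: {
        ADELIE: (-5000.0, 2500.0), GENTOO: (5000.0, 2500.0)})
    overlap_center: tuple[float, float] = (0.0, 2500.0)
    overlap_radius: float = 2500.0
    overlap_fraction: dict = field(default_factory=lambda: {
        ADELIE: 0.2, GENTOO: 0.4})
    center_scatter_sd: float = 800.0   # individual center around species center
    site_scatter_sd: float = 1200.0    # per-dive site around the trip target
    p_zone_trip: float = 0.7           # overlap users: daily odds of a trip
                                       # to the shared zone vs the home area
    position_noise_sd: float = 50.0    # additive fix noise
    swim_speed: float = 1.2            # m/s travel speed
    travel_fix_interval: float = 300.0  # s between fixes while travelling
    outlier_fraction: float = 0.0      # fraction of fixes displaced far away
    outlier_offset: float = 20000.0

    def validate(self) -> None:
        if self.overlap_radius <= 0:
            raise ConfigError("overlap_radius must be positive")
        for frac in self.overlap_fraction.values():
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("overlap_fraction must be in [0, 1]")
        if self.swim_speed <= 0:
            raise ConfigError("swim_speed must be positive")


@dataclass
class OceanParams:
    """Water-column structure planted in the AUV missions.

    The column is two-layered with tanh transitions: density steps at the
    mixed layer depth, temperature at the thermocline; chlorophyll is a
    Gaussian bump; light decays exponentially from the surface.  Each depth
    scale varies smoothly along track (sinusoid of relative amplitude
    ``variation_amp``) so that presence models have a gradient to key off.
    """

    mld: float = 20.0                  # m
    thermocline: float = 24.0          # m
    chl_max_depth: float = 20.0        # m
    chl_peak: float = 5.0              # ug/L
    chl_width: float = 8.0             # m, Gaussian sigma
    chl_background: float = 0.3        # ug/L
    surface_par: float = 100.0         # W/m2
    attenuation: float = 0.1           # 1/m  -> 1 W/m2 isolume at ln(100)/0.1
    temp_above: float = 1.5            # degC
    temp_below: float = -0.5
    density_above: float = 26.8        # sigma-t
    density_below: float = 27.4
    transition_width: float = 2.0      # m
    variation_amp: float = 0.15        # relative along-track variation
    variation_length: float = 3000.0   # m wavelength
    temp_noise: float = 0.01
    density_noise: float = 0.005
    chl_noise: float = 0.05
    par_noise_frac: float = 0.02

    def validate(self) -> None:
        if self.attenuation <= 0 or self.surface_par <= 0:
            raise ConfigError("surface_par and attenuation must be positive")
        if not 0 <= self.variation_amp < 1:
            raise ConfigError("variation_amp must be in [0, 1)")

    def isolume_depth(self, level: float = 1.0) -> float:
        """Closed-form depth of the given irradiance level (m)."""
        return float(np.log(self.surface_par / level) / self.attenuation)


@dataclass
class AggregationParams:
    """Planted prey-aggregation field.

    Dense aggregations are a two-component mixture: compact swarms (taller
    than diffuse layers, with length anti-correlated to height so compact
    swarms are short and tall) plus a minority of thin elongated layers.
    This reproduces the characteristic skew of observed krill-patch
    morphometrics: heights, areas and internal backscatter separate the two
    types while lengths and length:height ratios largely do not.
    """

    n_dense: int = 12                  # per mission
    n_diffuse: int = 18
    sv_dense: float = -62.0            # dB, internal mean
    sv_diffuse: float = -66.0
    sv_patch_sd: float = 1.0           # patch-to-patch spread of the mean
    sv_cell_sd: float = 1.5            # cell noise inside a patch
    background_sv: float = -75.0
    background_sd: float = 2.0
    background_depth_gradient: float = 0.0   # dB per m, optional
    depth_range: tuple[float, float] = (10.0, 60.0)
    # geometry (heights/lengths are full extents, metres, lognormal)
    diffuse_height_median: float = 2.6
    diffuse_length_median: float = 15.0
    height_sigma: float = 0.38
    length_sigma: float = 0.55
    dense_height_shift: float = 0.6    # log-shift of swarm heights
    dense_layer_frac: float = 0.3
    layer_height_mult: float = 0.35
    layer_length_mult: float = 1.2
    anticorr_eps_sd: float = 0.25
    # placement coupling to the water column (softmax over windows)
    presence_isolume_slope: float = -1.2   # shallower isolume -> more patches
    min_separation_cells: int = 2

    def validate(self) -> None:
        if self.n_dense < 0 or self.n_diffuse < 0:
            raise ConfigError("aggregation counts must be >= 0")
        if self.sv_dense <= self.sv_diffuse:
            raise ConfigError(
                "dense internal Sv mean must exceed the diffuse mean")
        for name in ("sv_patch_sd", "sv_cell_sd", "background_sd",
                     "height_sigma", "length_sigma", "anticorr_eps_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class MissionParams:
    """REMUS-style see-saw mission geometry."""

    length_m: float = 6000.0
    leg_length_m: float = 300.0        # horizontal extent of one monotone leg
    min_depth: float = 1.0
    max_depth: float = 88.0
    distance_res: float = 2.0          # m, echogram + sensor sampling
    depth_res: float = 1.0             # m
    depth_extent: float = 100.0        # m, echogram vertical extent

    def validate(self) -> None:
        if self.distance_res <= 0 or self.depth_res <= 0:
            raise ConfigError("grid resolutions must be positive")
        if not 0 <= self.min_depth < self.max_depth <= self.depth_extent:
            raise ConfigError("mission depths must satisfy "
                              "0 <= min < max <= depth_extent")


@dataclass
class SimConfig:
    """Root configuration of one synthetic study.

    One seed drives everything; per-stage generators derive child seeds
    deterministically, so an identical config yields byte-identical outputs.
    """

    seed: int = 0
    n_individuals: dict = field(default_factory=lambda: {ADELIE: 5, GENTOO: 5})
    days: int = 3
    tide_labels: list | None = None     # per-day; default alternating blocks
    tide_block: int = 2
    sampling_interval: float = 1.0      # s, depth recorder
    depth_noise_sd: float = 0.15        # m, sensor noise
    drift_max: float = 2.0              # m, linear zero drift over the record
    overlap_effect: float = 30.0        # m added to in-overlap gentoo dives
    overlap_effect_species: str = GENTOO
    dive_params: dict = field(default_factory=lambda: {
        ADELIE: DiveShapeParams(),
        GENTOO: DiveShapeParams(
            depth_mean=53.0, depth_sd=13.0, depth_max=110.0,
            p_bottom=0.73, p_wiggle=0.28, p_plateau=0.27,
            bottom_time_mean=45.0, bottom_time_sd=12.0),
    })
    tracks: TrackParams = field(default_factory=TrackParams)
    ocean: OceanParams = field(default_factory=OceanParams)
    aggregations: AggregationParams = field(default_factory=AggregationParams)
    mission: MissionParams = field(default_factory=MissionParams)

    def validate(self) -> None:
        if self.days <= 0:
            raise ConfigError("days must be positive")
        for sp, n in self.n_individuals.items():
            if sp not in SPECIES:
                raise ConfigError(f"unknown species {sp!r}")
            if n <= 0:
                raise ConfigError("n_individuals must be positive")
        if self.sampling_interval <= 0:
            raise ConfigError("sampling_interval must be positive")
        if self.tide_labels is not None:
            if len(self.tide_labels) != self.days:
                raise ConfigError("tide_labels must have one label per day")
            bad = set(self.tide_labels) - {DIURNAL, SEMIDIURNAL}
            if bad:
                raise ConfigError(f"unknown tide labels: {bad}")
        for p in self.dive_params.values():
            p.validate()
        self.tracks.validate()
        self.ocean.validate()
        self.aggregations.validate()
        self.mission.validate()
        # planted dives must be resolvable at the sampling interval
        for sp, p in self.dive_params.items():
            min_dur = 2 * p.transit_range[0] / p.transit_rate
            if min_dur < 3 * self.sampling_interval:
                raise ConfigError(
                    f"{sp}: shortest planted dive spans fewer than 3 samples")

    def tide_for_days(self) -> list[str]:
        if self.tide_labels is not None:
            return list(self.tide_labels)
        labels = []
        for day in range(self.days):
            block = (day // self.tide_block) % 2
            labels.append(DIURNAL if block == 0 else SEMIDIURNAL)
        return labels

    def rng(self, *key: int | str) -> np.random.Generator:
        """Child generator for a named stage, derived from the root seed."""
        digest = [self.seed] + [
            zlib.crc32(k.encode()) if isinstance(k, str) else int(k)
            for k in key
        ]
        return np.random.default_rng(np.random.SeedSequence(digest))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
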