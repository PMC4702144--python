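import warnings

import pytest

from sympatry.config import ADELIE, GENTOO, SimConfig
from sympatry import simulate

warnings.filterwarnings("ignore", message="only .* groups")


def quiet_config(seed: int = 42, days: int = 2, dives_per_trip: int = 12
                 ) -> SimConfig:
    """Noise-free study: zero sensor noise, drift, patch noise and
    along-track variation, so recovery is exact."""
    cfg = SimConfig(seed=seed, days=days, depth_noise_sd=0.0, drift_max=0.0)
    for sp in cfg.dive_params:
        cfg.dive_params[sp].dives_per_trip = dives_per_trip
        cfg.dive_params[sp].n_transit_dives = 3
    cfg.tracks.position_noise_sd = 0.0
    oc = cfg.ocean
    oc.variation_amp = 0.0
    oc.temp_noise = oc.density_noise = oc.chl_noise = 0.0
    oc.par_noise_frac = 0.0
    ag = cfg.aggregations
    ag.background_sd = ag.sv_cell_sd = ag.sv_patch_sd = 0.0
    return cfg


@pytest.fixture(scope="session")
def quiet_cfg() -> SimConfig:
    return quiet_config()


@pytest.fixture(scope="session")
def quiet_tdr(quiet_cfg):
    return simulate.generate_tdr(quiet_cfg)


@pytest.fixture(scope="session")
def quiet_mission(quiet_cfg):
    return simulate.generate_auv_mission(quiet_cfg, day=0)


@pytest.fixture(scope="session")
def noisy_tdr():
    cfg = SimConfig(seed=7, days=2, depth_noise_sd=0.3, drift_max=2.0)
    for sp in cfg.dive_params:
        cfg.dive_params[sp].dives_per_trip = 15
        cfg.dive_params[sp].n_transit_dives = 4
    return simulate.generate_tdr(cfg)
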