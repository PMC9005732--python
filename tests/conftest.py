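"""Shared fixtures: a standard seeded synthetic world for integration tests.

The standard run uses the package's default configuration (a 10x20 grid at
0.5 degrees spanning aridity PET/P 0.3-3, 2000-2016) and performs the full
historical chain once per session: climate, forest gain, S1/S0 bucket
runs, true wetland parameters, observations, static calibration and the
period-change fields entering the sensitivity decomposition.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from afforwet import (
    RunConfig,
    attribution_diff,
    calibrate_static,
    climate_zone,
    bucket_soil_moisture,
    gen_climate,
    gen_forest_history,
    gen_observed_wetlands,
    gen_wetland_params,
    make_grid_domain,
    rice_filter,
    gen_rice_mask,
    soil_moisture_deficit,
    wetland_cell_mask,
    wetland_series,
)
from afforwet.io_cli import stage_seed
from afforwet.synthetic_data import ForestTrajectory


def build_standard_run(seed: int = 1) -> SimpleNamespace:
    """The default-configuration historical run, from a single seed."""
    cfg = RunConfig(seed=seed)
    domain = make_grid_domain(cfg.n_lat, cfg.n_lon, cfg.lat0, cfg.lon0, cfg.resolution)
    climate = gen_climate(
        domain, stage_seed(seed, "climate"), cfg.phi_range, cfg.p_base,
        cfg.interannual_cv, years=cfg.years,
    )
    forest = gen_forest_history(
        domain, stage_seed(seed, "forest"), cfg.forest_increase_km2,
        cfg.start_year, cfg.end_year,
    )
    control = ForestTrajectory(
        forest_frac=np.broadcast_to(forest.forest_frac[0], forest.forest_frac.shape).copy(),
        years=forest.years, domain=domain,
    )
    sm_s1 = bucket_soil_moisture(climate, forest)
    sm_s0 = bucket_soil_moisture(climate, control)
    true_params = gen_wetland_params(domain, stage_seed(seed, "wetland_params"))
    obs = gen_observed_wetlands(
        true_params, sm_s1, cfg.obs_noise_cv, stage_seed(seed, "observations")
    )
    params = calibrate_static(obs.static_max_frac, soil_moisture_deficit(sm_s1))
    wet_s1 = wetland_series(sm_s1, params, domain)
    wet_s0 = wetland_series(sm_s0, params, domain)
    rice = gen_rice_mask(domain, stage_seed(seed, "rice"), cfg.rice_prob)

    d_area = attribution_diff(wet_s1.area, wet_s0.area)
    d_sm_annual = attribution_diff(sm_s1.annual_mean, sm_s0.annual_mean)
    d_awet = d_area[-1] - d_area[0]
    d_sm = d_sm_annual[-1] - d_sm_annual[0]
    d_aforest = (forest.forest_frac[-1] - forest.forest_frac[0]) * domain.cell_area
    wet_mask = rice_filter(
        wetland_cell_mask(wet_s1.annual_max_frac, cfg.wetland_threshold),
        rice, cfg.rice_threshold,
    )
    filters = {
        "has_forest": forest.forest_frac.max(axis=0) > 0,
        "forest_changed": d_aforest != 0,
        "wetland_mask": wet_mask,
    }
    return SimpleNamespace(
        cfg=cfg, domain=domain, climate=climate, forest=forest, control=control,
        sm_s1=sm_s1, sm_s0=sm_s0, true_params=true_params, obs=obs, params=params,
        wet_s1=wet_s1, wet_s0=wet_s0, rice=rice, zones=climate_zone(climate.phi_mean),
        d_awet=d_awet, d_sm=d_sm, d_aforest=d_aforest, filters=filters,
    )


@pytest.fixture(scope="session")
def std():
    return build_standard_run(seed=1)


@pytest.fixture
def small_domain():
    return make_grid_domain(4, 6, lat0=35.0, lon0=100.0, resolution=0.5)
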