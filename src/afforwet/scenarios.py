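"""Near-term planting scenarios and wetland-loss projection.

Four scenario kinds share one national planting target over a projection
window: SA allocates proportionally to each cell's historical planting
(continuing the observed trajectory), while SA_dry / SA_mesic / SA_wet
place the entire target inside one PET/P climate zone, proportionally to
each cell's remaining plantable area.  Projection runs the bucket
soil-moisture surrogate under the scenario trajectory (S1) and under a
constant-forest control (S0) with the same recycled climate, applies the
wetland diagnostic to both, and attributes wetland change to planting as
S1 - S0.  Losses are reported as percentages of the baseline-year wetland
area and binned 2-4 / 4-6 / 6-8 / 8-10 / >10 %.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .budyko import BudykoParams
from .synthetic_data import (
    BucketParams,
    ClimateFields,
    ForestTrajectory,
    GridDomain,
    InfeasibleAllocationError,
    allocate_with_caps,
    bucket_soil_moisture,
)
from .trends_sensitivity import ZONE_DRY, ZONE_MESIC, ZONE_WET
from .wetland_diagnostic import WetlandParams, wetland_series

__all__ = [
    "SCENARIO_KINDS",
    "DEFAULT_LOSS_BIN_EDGES",
    "Scenario",
    "ProjectionResult",
    "build_scenario",
    "project",
    "loss_relative",
    "loss_bins",
]

SCENARIO_KINDS = ("SA", "SA_dry", "SA_mesic", "SA_wet")
_ZONE_OF_KIND = {"SA_dry": ZONE_DRY, "SA_mesic": ZONE_MESIC, "SA_wet": ZONE_WET}

DEFAULT_LOSS_BIN_EDGES = (2.0, 4.0, 6.0, 8.0, 10.0)


@dataclass
class Scenario:
    """A planting plan: forest trajectory plus allocation metadata."""

    name: str
    forest_traj: ForestTrajectory
    allocation_rule: str
    national_target_km2: float

    @property
    def planted_area_km2(self) -> np.ndarray:
        return self.forest_traj.planted_area_km2


def build_scenario(
    kind: str,
    domain: GridDomain,
    zones: np.ndarray,
    forest_now: np.ndarray,
    national_target_km2: float,
    years,
    historical_weights: np.ndarray | None = None,
    max_frac: float = 0.95,
) -> Scenario:
    """Allocate a national planting target and build a linear trajectory.

    ``zones`` is the per-cell climate-zone map, ``forest_now`` the forest
    fraction at the start of the window.  SA needs ``historical_weights``
    (per-cell historical planted area); zone variants weight by remaining
    plantable area, capped so no cell exceeds ``max_frac`` forest cover
    (the reserved non-plantable remainder).  Raises
    InfeasibleAllocationError with the shortfall when the zone cannot
    absorb the target.
    """
    if kind not in SCENARIO_KINDS:
        raise ValueError(f"unknown scenario kind {kind!r}; expected one of {SCENARIO_KINDS}")
    if national_target_km2 < 0:
        raise ValueError("national target must be >= 0")
    years = np.asarray(years)
    forest_now = np.asarray(forest_now, dtype=float)
    capacity = np.maximum(max_frac - forest_now, 0.0) * domain.cell_area

    if kind == "SA":
        if historical_weights is None:
            raise ValueError("SA allocation needs historical planting weights")
        weights = np.asarray(historical_weights, dtype=float)
        rule = "proportional to historical planting"
    else:
        zone = _ZONE_OF_KIND[kind]
        weights = np.where(np.asarray(zones) == zone, capacity, 0.0)
        rule = f"remaining plantable area within the {zone} zone"

    planted = allocate_with_caps(
        national_target_km2, weights.ravel(), capacity.ravel()
    ).reshape(forest_now.shape)
    ramp = np.linspace(0.0, 1.0, years.size)
    frac = forest_now[None] + ramp[:, None, None] * (planted / domain.cell_area)[None]
    traj = ForestTrajectory(forest_frac=frac, years=years, domain=domain)
    return Scenario(
        name=kind,
        forest_traj=traj,
        allocation_rule=rule,
        national_target_km2=float(national_target_km2),
    )


def recycle_climate(
    historical: ClimateFields, years, seed: int = 0
) -> ClimateFields:
    """"Constant climate" forcing: seeded resampling of historical years.

    The projection window is longer than the historical record, so years
    are drawn with replacement; the draw is part of the scenario
    configuration and fixed by ``seed``.
    """
    years = np.asarray(years)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, historical.years.size, size=years.size)
    return ClimateFields(
        P=historical.P[idx],
        PET=historical.PET[idx],
        years=years,
        domain=historical.domain,
    )


@dataclass
class ProjectionResult:
    """Attributed wetland outcome of a scenario.

    ``attributed_change`` is the per-cell S1-S0 wetland-area difference in
    the final year (km^2, negative = loss); ``loss_pct`` the loss as a
    percentage of the baseline-year wetland area (0 where the cell gained;
    NaN where the baseline is zero); ``national_loss_km2`` the net national
    attributed loss (positive = loss).
    """

    years: np.ndarray
    wetland_area_s1: np.ndarray  # (n_years, n_lat, n_lon), km^2
    wetland_area_s0: np.ndarray
    baseline_area: np.ndarray  # (n_lat, n_lon), km^2
    attributed_change: np.ndarray  # (n_lat, n_lon), km^2
    loss_pct: np.ndarray  # (n_lat, n_lon), %
    gain_flag: np.ndarray  # (n_lat, n_lon), bool
    national_loss_km2: float
    missing_cells: int  # wetland cells without calibrated parameters


def project(
    scenario: Scenario,
    climate: ClimateFields,
    wetland_params: WetlandParams,
    budyko_params: BudykoParams | None = None,
    bucket_params: BucketParams | None = None,
    baseline_year: int | None = None,
    recycle_seed: int = 0,
) -> ProjectionResult:
    """Project wetland change through the forest -> SM -> wetland chain.

    ``climate`` is the historical record to recycle over the scenario
    window.  Cells with missing (NaN) calibrated f_max are excluded from
    the national total and counted in ``missing_cells``.  A zero-target
    scenario is bit-identical to its control, hence exactly zero
    attributed change.
    """
    years = scenario.forest_traj.years
    domain = scenario.forest_traj.domain
    scen_climate = recycle_climate(climate, years, seed=recycle_seed)

    forest_now = scenario.forest_traj.forest_frac[0]
    control = ForestTrajectory(
        forest_frac=np.broadcast_to(forest_now, scenario.forest_traj.forest_frac.shape).copy(),
        years=years,
        domain=domain,
    )

    f_max = np.asarray(wetland_params.f_max, dtype=float)
    missing = ~np.isfinite(f_max)
    safe_params = wetland_params.replace(f_max=np.where(missing, 0.0, f_max))

    areas = {}
    for label, traj in (("s1", scenario.forest_traj), ("s0", control)):
        sm = bucket_soil_moisture(scen_climate, traj, budyko_params, bucket_params)
        areas[label] = wetland_series(sm, safe_params, domain).area

    baseline_year = int(years[0]) if baseline_year is None else int(baseline_year)
    if baseline_year not in years:
        raise ValueError(f"baseline year {baseline_year} outside the projection window")
    b_idx = int(np.nonzero(years == baseline_year)[0][0])
    baseline = areas["s0"][b_idx]

    d_final = areas["s1"][-1] - areas["s0"][-1]
    d_final = np.where(missing, np.nan, d_final)
    with np.errstate(divide="ignore", invalid="ignore"):
        loss_pct = np.where(baseline > 0, 100.0 * np.maximum(-d_final, 0.0) / baseline, np.nan)
    gain_flag = np.isfinite(d_final) & (d_final > 0)
    national_loss = float(-np.nansum(d_final))
    return ProjectionResult(
        years=years,
        wetland_area_s1=areas["s1"],
        wetland_area_s0=areas["s0"],
        baseline_area=baseline,
        attributed_change=d_final,
        loss_pct=loss_pct,
        gain_flag=gain_flag,
        national_loss_km2=national_loss,
        missing_cells=int(missing.sum()),
    )


def loss_relative(projection: ProjectionResult, baseline_year: int) -> np.ndarray:
    """Loss percentage against an arbitrary baseline year in the window.

    loss = 100 * (baseline - final) / baseline, floored at 0 for gains
    (gains carry the projection's gain flag instead of negative losses);
    missing where the baseline area is zero.
    """
    years = projection.years
    if baseline_year not in years:
        raise ValueError(f"baseline year {baseline_year} outside the projection window")
    b_idx = int(np.nonzero(years == baseline_year)[0][0])
    baseline = projection.wetland_area_s0[b_idx]
    d_final = projection.attributed_change
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(baseline > 0, 100.0 * np.maximum(-d_final, 0.0) / baseline, np.nan)


def loss_bins(loss_pct_values, edges=DEFAULT_LOSS_BIN_EDGES) -> dict[str, int]:
    """Histogram of loss percentages in [2,4), [4,6), [6,8), [8,10), (10,inf).

    Losses below the first edge are uncounted, as is a loss of exactly
    10% (the top bin is a strict ">"); NaNs are ignored.
    """
    vals = np.asarray(loss_pct_values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    edges = tuple(edges)
    counts: dict[str, int] = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        counts[f"{lo:g}-{hi:g}%"] = int(((vals >= lo) & (vals < hi)).sum())
    counts[f">{edges[-1]:g}%"] = int((vals > edges[-1]).sum())
    return counts
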