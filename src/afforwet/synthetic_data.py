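"""Synthetic gridded inputs with known ground truth.

Everything the analysis pipeline consumes is generated here: a lat-lon
grid with spherical cell areas, climate fields spanning an aridity
gradient, monotone forest-gain trajectories, a bucket soil-moisture
surrogate whose evapotranspiration responds to forest cover through the
Budyko curves, noisy "observed" wetland products generated from known
diagnostic parameters, contiguous basins with protection levels, and a
static rice-paddy mask.  All generators are pure functions of their
arguments and a seed.

The bucket surrogate stands in for a full land-surface model.  Its design
goal is not realism of any single process but a correct, analytically
transparent sign structure: planting trees raises the effective
plant-available water coefficient, which raises the evaporative fraction,
which lowers soil moisture — strongly where the climate is dry enough for
soils to sit below saturation, and not at all where abundant precipitation
keeps the bucket pinned at capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .budyko import BudykoParams, effective_w, et_ratio
from .wetland_diagnostic import (
    WetlandParams,
    annual_max_fraction,
    soil_moisture_deficit,
    wetland_fraction,
)

__all__ = [
    "EARTH_RADIUS_KM",
    "GridDomain",
    "ClimateFields",
    "ForestTrajectory",
    "BucketParams",
    "SoilMoistureSeries",
    "ObservedWetlands",
    "BasinTable",
    "InfeasibleAllocationError",
    "make_grid_domain",
    "gen_climate",
    "gen_forest_history",
    "bucket_soil_moisture",
    "gen_wetland_params",
    "gen_observed_wetlands",
    "gen_basins",
    "gen_rice_mask",
    "allocate_with_caps",
]

EARTH_RADIUS_KM = 6371.0


class InfeasibleAllocationError(ValueError):
    """Requested planting exceeds the available non-forest area."""

    def __init__(self, message: str, shortfall_km2: float = 0.0):
        super().__init__(message)
        self.shortfall_km2 = shortfall_km2


# ---------------------------------------------------------------------------
# Grid domain
# ---------------------------------------------------------------------------


@dataclass
class GridDomain:
    """Regular lat-lon grid with per-cell spherical areas (km^2)."""

    lat_centers: np.ndarray  # (n_lat,), degrees
    lon_centers: np.ndarray  # (n_lon,), degrees
    resolution: float  # degrees
    cell_area: np.ndarray  # (n_lat, n_lon), km^2

    @property
    def n_lat(self) -> int:
        return self.lat_centers.size

    @property
    def n_lon(self) -> int:
        return self.lon_centers.size

    @property
    def n_cells(self) -> int:
        return self.n_lat * self.n_lon

    @property
    def total_area_km2(self) -> float:
        return float(self.cell_area.sum())


def make_grid_domain(
    n_lat: int,
    n_lon: int,
    lat0: float = 30.0,
    lon0: float = 90.0,
    resolution: float = 0.5,
) -> GridDomain:
    """Build a regular grid; (lat0, lon0) is the center of the first cell.

    Cell areas use the spherical-quadrilateral formula
    A = R^2 * dlambda * (sin(lat_n) - sin(lat_s)), so area varies only
    with latitude.  At 0.5 deg a mid-latitude (36N) cell is ~2500 km^2.
    """
    if n_lat < 1 or n_lon < 1:
        raise ValueError("grid dimensions must be >= 1")
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    lat = lat0 + resolution * np.arange(n_lat)
    lon = lon0 + resolution * np.arange(n_lon)
    half = resolution / 2.0
    band = (
        EARTH_RADIUS_KM**2
        * np.deg2rad(resolution)
        * (np.sin(np.deg2rad(lat + half)) - np.sin(np.deg2rad(lat - half)))
    )
    area = np.repeat(band[:, None], n_lon, axis=1)
    if np.any(area <= 0):
        raise ValueError("grid extends beyond a pole: nonpositive cell area")
    return GridDomain(lat_centers=lat, lon_centers=lon, resolution=resolution, cell_area=area)


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------


@dataclass
class ClimateFields:
    """Annual P and PET (mm/yr) per cell-year with an aridity gradient."""

    P: np.ndarray  # (n_years, n_lat, n_lon)
    PET: np.ndarray
    years: np.ndarray
    domain: GridDomain

    @property
    def phi(self) -> np.ndarray:
        """Per cell-year aridity index PET/P."""
        return self.PET / self.P

    @property
    def phi_mean(self) -> np.ndarray:
        """Climatological aridity index: time-mean PET over time-mean P."""
        return self.PET.mean(axis=0) / self.P.mean(axis=0)


def gen_climate(
    domain: GridDomain,
    seed: int,
    phi_range: tuple[float, float] = (0.3, 3.0),
    p_base: float = 800.0,
    interannual_cv: float = 0.15,
    years=None,
) -> ClimateFields:
    """Climate with mean PET/P increasing monotonically along longitude.

    The west-to-east aridity gradient spans ``phi_range`` so all three
    climate zones (PET/P < 1, 1-2, > 2) are represented.  Interannual
    variability is multiplicative with the stated coefficient of
    variation, drawn independently for P and PET.  The precipitation base
    is spatially uniform: aridity is driven by atmospheric demand alone,
    a controlled-experiment design that isolates demand effects.
    """
    lo, hi = phi_range
    if not (0 < lo <= hi):
        raise ValueError("phi_range must be a nonempty interval within (0, inf)")
    if p_base <= 0:
        raise ValueError("p_base must be > 0")
    if interannual_cv < 0:
        raise ValueError("interannual_cv must be >= 0")
    years = np.arange(2000, 2017) if years is None else np.asarray(years)
    rng = np.random.default_rng(seed)
    phi_cols = np.linspace(lo, hi, domain.n_lon)
    phi_map = np.broadcast_to(phi_cols[None, :], (domain.n_lat, domain.n_lon))
    shape = (years.size, domain.n_lat, domain.n_lon)
    noise_p = 1.0 + interannual_cv * rng.standard_normal(shape)
    noise_pet = 1.0 + interannual_cv * rng.standard_normal(shape)
    P = p_base * np.clip(noise_p, 0.2, None)
    PET = phi_map[None, :, :] * p_base * np.clip(noise_pet, 0.2, None)
    return ClimateFields(P=P, PET=PET, years=years, domain=domain)


# ---------------------------------------------------------------------------
# Forest history
# ---------------------------------------------------------------------------


@dataclass
class ForestTrajectory:
    """Forest cover fraction per cell-year; remainder of each cell is grass."""

    forest_frac: np.ndarray  # (n_years, n_lat, n_lon), [0, 1]
    years: np.ndarray
    domain: GridDomain

    @property
    def planted_area_km2(self) -> np.ndarray:
        """Per-cell planted area over the window (km^2)."""
        return (self.forest_frac[-1] - self.forest_frac[0]) * self.domain.cell_area


def allocate_with_caps(
    target_km2: float, weights: np.ndarray, capacity_km2: np.ndarray
) -> np.ndarray:
    """Distribute an area target over cells proportionally to weights,
    capping each cell at its capacity and redistributing the excess.

    Raises InfeasibleAllocationError (with the shortfall) when the total
    capacity of cells with positive weight cannot absorb the target.
    """
    weights = np.asarray(weights, dtype=float).copy()
    capacity = np.asarray(capacity_km2, dtype=float)
    if target_km2 < 0:
        raise ValueError("allocation target must be >= 0")
    if np.any(weights < 0):
        raise ValueError("allocation weights must be >= 0")
    usable = capacity[weights > 0].sum()
    if target_km2 > usable * (1 + 1e-12):
        raise InfeasibleAllocationError(
            f"target {target_km2:.1f} km^2 exceeds plantable area "
            f"{usable:.1f} km^2",
            shortfall_km2=float(target_km2 - usable),
        )
    alloc = np.zeros_like(capacity)
    remaining = float(target_km2)
    active = weights > 0
    for _ in range(weights.size + 1):
        if remaining <= 1e-9 or not active.any():
            break
        share = np.where(active, weights, 0.0)
        share = share / share.sum() * remaining
        room = capacity - alloc
        add = np.minimum(share, room)
        alloc += add
        remaining -= float(add.sum())
        active = active & (alloc < capacity - 1e-12)
    return alloc


def gen_forest_history(
    domain: GridDomain,
    seed: int,
    national_increase_km2: float,
    start_year: int = 2000,
    end_year: int = 2016,
    spatial_weights: np.ndarray | None = None,
    initial_frac_range: tuple[float, float] = (0.0, 0.4),
    max_frac: float = 0.95,
) -> ForestTrajectory:
    """Monotone, piecewise-linear forest-gain trajectories.

    Initial fractions are drawn uniformly from ``initial_frac_range``; the
    national planting target is allocated across cells proportionally to
    ``spatial_weights`` (default: random weights scaled by remaining
    plantable area, concentrating planting in some cells as inventory-based
    maps do).  The summed area increase equals the target to within
    round-off; per-cell fractions never exceed ``max_frac``.
    """
    if national_increase_km2 < 0:
        raise ValueError("national_increase_km2 must be >= 0")
    rng = np.random.default_rng(seed)
    years = np.arange(start_year, end_year + 1)
    f0 = rng.uniform(*initial_frac_range, size=(domain.n_lat, domain.n_lon))
    capacity = (max_frac - f0) * domain.cell_area
    if spatial_weights is None:
        spatial_weights = rng.gamma(2.0, size=f0.shape) * capacity
    planted = allocate_with_caps(national_increase_km2, spatial_weights.ravel(), capacity.ravel())
    d_frac = (planted / domain.cell_area.ravel()).reshape(f0.shape)
    ramp = np.linspace(0.0, 1.0, years.size)
    frac = f0[None, :, :] + ramp[:, None, None] * d_frac[None, :, :]
    return ForestTrajectory(forest_frac=frac, years=years, domain=domain)


# ---------------------------------------------------------------------------
# Bucket soil-moisture surrogate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BucketParams:
    """Monthly bucket configuration.

    sm_sat: storage capacity (mm); drainage: linear drainage coefficient
    (fraction of storage per month); init_frac: initial storage as a
    fraction of capacity; spinup_years: repetitions of the first forcing
    year discarded before recording; seasonality: 'flat' splits annual
    totals evenly over months, 'sinusoidal' modulates them with a
    unit-mean annual cycle.
    """

    sm_sat: float = 300.0
    drainage: float = 0.06
    init_frac: float = 0.5
    spinup_years: int = 3
    seasonality: str = "flat"

    def monthly_weights(self) -> np.ndarray:
        if self.seasonality == "flat":
            return np.full(12, 1.0 / 12.0)
        if self.seasonality == "sinusoidal":
            m = np.arange(12)
            w = 1.0 + 0.6 * np.sin(2 * np.pi * (m - 3) / 12.0)
            return w / w.sum()
        raise ValueError(f"unknown seasonality {self.seasonality!r}")


@dataclass
class SoilMoistureSeries:
    """Monthly bucket output plus the fluxes that produced it (all mm)."""

    sm: np.ndarray  # (n_months, n_lat, n_lon), end-of-month storage
    sm_sat: float
    years: np.ndarray
    domain: GridDomain
    p_flux: np.ndarray = field(default=None, repr=False)  # monthly P
    et_flux: np.ndarray = field(default=None, repr=False)
    q_flux: np.ndarray = field(default=None, repr=False)
    sm_prev: np.ndarray = field(default=None, repr=False)  # storage before each step

    @property
    def annual_mean(self) -> np.ndarray:
        n_years = self.years.size
        return self.sm.reshape(n_years, -1, *self.sm.shape[1:]).mean(axis=1)


def bucket_soil_moisture(
    climate: ClimateFields,
    forest_traj: ForestTrajectory,
    budyko_params: BudykoParams | None = None,
    bucket_params: BucketParams | None = None,
    seed: int | None = None,
) -> SoilMoistureSeries:
    """Monthly water balance SM' = clamp(SM + P - ET - Q, 0, SM_sat).

    ET is the annual Budyko evaporative fraction — evaluated at the cell's
    climatological PET/P with the area-weighted forest/grass coefficient of
    that year — distributed over months and throttled by wetness
    (SM/SM_sat); drainage is linear in storage.  Off unclamped steps the
    budget closes exactly; clamping at the bounds represents saturation
    excess (discarded to fast runoff) and complete drying.  Deterministic:
    ``seed`` is accepted for generator-API symmetry but unused.
    """
    del seed
    budyko_params = budyko_params or BudykoParams()
    bp = bucket_params or BucketParams()
    if climate.P.shape != forest_traj.forest_frac.shape:
        raise ValueError(
            f"shape mismatch: climate {climate.P.shape} vs forest "
            f"{forest_traj.forest_frac.shape}"
        )
    if not np.array_equal(np.asarray(climate.years), np.asarray(forest_traj.years)):
        raise ValueError("climate and forest trajectory cover different years")

    n_years = climate.years.size
    grid_shape = climate.P.shape[1:]
    phi = climate.phi_mean
    month_w = bp.monthly_weights()

    sm = np.full(grid_shape, bp.init_frac * bp.sm_sat)
    n_months = n_years * 12
    out_sm = np.empty((n_months,) + grid_shape)
    out_p = np.empty_like(out_sm)
    out_et = np.empty_like(out_sm)
    out_q = np.empty_like(out_sm)
    out_prev = np.empty_like(out_sm)

    def step(sm, p_m, et_pot_m):
        et = et_pot_m * (sm / bp.sm_sat)
        q = bp.drainage * sm
        sm_new = np.clip(sm + p_m - et - q, 0.0, bp.sm_sat)
        return sm_new, et, q

    # spin-up on the first forcing year
    a0 = et_ratio(phi, effective_w(forest_traj.forest_frac[0], budyko_params))
    for _ in range(bp.spinup_years):
        for m in range(12):
            p_m = climate.P[0] * month_w[m]
            sm, _, _ = step(sm, p_m, a0 * p_m)

    for y in range(n_years):
        a = et_ratio(phi, effective_w(forest_traj.forest_frac[y], budyko_params))
        for m in range(12):
            t = y * 12 + m
            p_m = climate.P[y] * month_w[m]
            out_prev[t] = sm
            sm, et, q = step(sm, p_m, a * p_m)
            out_sm[t] = sm
            out_p[t] = p_m
            out_et[t] = et
            out_q[t] = q

    return SoilMoistureSeries(
        sm=out_sm,
        sm_sat=bp.sm_sat,
        years=np.asarray(climate.years),
        domain=climate.domain,
        p_flux=out_p,
        et_flux=out_et,
        q_flux=out_q,
        sm_prev=out_prev,
    )


# ---------------------------------------------------------------------------
# Wetland truth and observations
# ---------------------------------------------------------------------------


def gen_wetland_params(
    domain: GridDomain,
    seed: int,
    f_max_range: tuple[float, float] = (0.05, 0.4),
    zero_prob: float = 0.3,
    k: float = 0.15,
    d0: float = 45.0,
    v: float = 1.0,
) -> WetlandParams:
    """Ground-truth diagnostic parameters for the synthetic world.

    f_max is a topographic attribute: uniform within ``f_max_range`` with a
    ``zero_prob`` share of cells that host no wetlands at all.  The shape
    parameters (k, d0, v) are spatially uniform — the half-saturation
    deficit is a property of topography, not climate — which makes the
    dry-zone vulnerability an emergent outcome rather than an input.
    """
    rng = np.random.default_rng(seed)
    shape = (domain.n_lat, domain.n_lon)
    f_max = rng.uniform(*f_max_range, size=shape)
    f_max[rng.random(shape) < zero_prob] = 0.0
    return WetlandParams(
        f_max=f_max,
        k=np.full(shape, k),
        d0=np.full(shape, d0),
        v=np.full(shape, v),
    )


@dataclass
class ObservedWetlands:
    """Synthetic satellite-like wetland products.

    ``static_max_frac`` emulates a static long-term maximum extent map;
    ``annual_max_frac`` a dynamic per-year maximum product with
    multiplicative observation noise.
    """

    static_max_frac: np.ndarray  # (n_lat, n_lon)
    annual_max_frac: np.ndarray  # (n_years, n_lat, n_lon)
    noise_cv: float


def gen_observed_wetlands(
    true_params: WetlandParams,
    sm_series: SoilMoistureSeries,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> ObservedWetlands:
    """Apply the true diagnostic to the SM series and add observation noise.

    The static product is the noiseless long-term maximum; the dynamic
    product is the per-year maximum times (1 + cv*N(0,1)), clipped to
    [0, 1].
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    deficit = soil_moisture_deficit(sm_series)
    frac = wetland_fraction(deficit, true_params)
    n_years = sm_series.years.size
    annual = annual_max_fraction(frac, n_years)
    static = frac.max(axis=0)
    rng = np.random.default_rng(seed)
    noisy = annual * (1.0 + noise_cv * rng.standard_normal(annual.shape))
    return ObservedWetlands(
        static_max_frac=static,
        annual_max_frac=np.clip(noisy, 0.0, 1.0),
        noise_cv=noise_cv,
    )


# ---------------------------------------------------------------------------
# Basins and rice
# ---------------------------------------------------------------------------

PROTECTION_LEVELS = ("national", "provincial", "municipal_county", "unprotected")
DEFAULT_LEVEL_SHARES = {
    "national": 0.15,
    "provincial": 0.20,
    "municipal_county": 0.25,
    "unprotected": 0.40,
}


@dataclass
class BasinTable:
    """Cell->basin membership plus per-basin protection levels."""

    basin_id: np.ndarray  # (n_lat, n_lon), int
    levels: dict[int, str]  # basin_id -> protection level
    domain: GridDomain

    def to_frame(self):
        import pandas as pd

        ids = self.basin_id.ravel()
        return pd.DataFrame(
            {
                "cell_index": np.arange(ids.size),
                "basin_id": ids,
                "protection_level": [self.levels[int(b)] for b in ids],
            }
        )

    def basin_ids(self) -> np.ndarray:
        return np.unique(self.basin_id)

    def basin_area_km2(self):
        import pandas as pd

        area = pd.Series(self.domain.cell_area.ravel()).groupby(self.basin_id.ravel()).sum()
        area.index.name = "basin_id"
        return area


def gen_basins(
    domain: GridDomain,
    n_basins: int,
    level_shares: dict[str, float] | None = None,
    seed: int = 0,
) -> BasinTable:
    """Partition the grid into contiguous basins by seeded region growing.

    ``n_basins`` seed cells are drawn at random; unassigned cells join a
    random already-assigned 4-neighbor until the grid is covered, which
    guarantees contiguity and a full partition.  Protection levels are
    assigned per basin from ``level_shares``.
    """
    if n_basins < 1:
        raise ValueError("n_basins must be >= 1")
    if n_basins > domain.n_cells:
        raise ValueError("more basins than cells")
    shares = level_shares or DEFAULT_LEVEL_SHARES
    if any(level not in PROTECTION_LEVELS for level in shares):
        raise ValueError(f"protection levels must be among {PROTECTION_LEVELS}")
    rng = np.random.default_rng(seed)
    n_lat, n_lon = domain.n_lat, domain.n_lon
    basin = np.full((n_lat, n_lon), -1, dtype=int)
    flat_seeds = rng.choice(domain.n_cells, size=n_basins, replace=False)
    for b, s in enumerate(flat_seeds):
        basin[np.unravel_index(s, (n_lat, n_lon))] = b
    while np.any(basin < 0):
        ii, jj = np.nonzero(basin < 0)
        order = rng.permutation(ii.size)
        grew = False
        for idx in order:
            i, j = ii[idx], jj[idx]
            neigh = []
            if i > 0 and basin[i - 1, j] >= 0:
                neigh.append(basin[i - 1, j])
            if i < n_lat - 1 and basin[i + 1, j] >= 0:
                neigh.append(basin[i + 1, j])
            if j > 0 and basin[i, j - 1] >= 0:
                neigh.append(basin[i, j - 1])
            if j < n_lon - 1 and basin[i, j + 1] >= 0:
                neigh.append(basin[i, j + 1])
            if neigh:
                basin[i, j] = neigh[rng.integers(len(neigh))]
                grew = True
        if not grew:  # pragma: no cover - cannot happen on a connected grid
            raise RuntimeError("region growing stalled")
    names = list(shares)
    probs = np.asarray([shares[n] for n in names], dtype=float)
    probs = probs / probs.sum()
    levels = {b: names[rng.choice(len(names), p=probs)] for b in range(n_basins)}
    return BasinTable(basin_id=basin, levels=levels, domain=domain)


def gen_rice_mask(
    domain: GridDomain,
    seed: int,
    rice_prob: float = 0.12,
    rice_frac_range: tuple[float, float] = (0.02, 0.5),
) -> np.ndarray:
    """Static per-cell rice-paddy fraction; zero with probability 1-rice_prob."""
    if not 0 <= rice_prob <= 1:
        raise ValueError("rice_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    shape = (domain.n_lat, domain.n_lon)
    frac = rng.uniform(*rice_frac_range, size=shape)
    frac[rng.random(shape) >= rice_prob] = 0.0
    return frac
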