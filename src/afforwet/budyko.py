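"""Budyko water-balance partitioning and forest-change runoff attribution.

Annual precipitation P is split between evapotranspiration ET and runoff Q
according to the aridity index phi = PET/P and a vegetation parameter w, the
plant-available water coefficient (deep-rooted forest ~2, shallow-rooted
grass ~0.5):

    ET/P = (1 + w*phi) / (1 + w*phi + 1/phi)
    Q/P  = (1/phi)     / (1 + w*phi + 1/phi)

The two ratios share a denominator, so ET/P + Q/P = 1 exactly (annual
storage change neglected).  Converting grass to forest raises w, raising
ET/P and lowering Q/P; the runoff change attributable to a forest-cover
change from fraction f_prev to f_curr is

    deltaQ = P * (f_curr - f_prev) * [Q/P(phi, w_grass) - Q/P(phi, w_forest)]

with the sign convention that forest gain gives deltaQ <= 0.

All functions broadcast over numpy arrays and preserve python scalars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BudykoParams",
    "DeltaRunoffField",
    "et_ratio",
    "runoff_ratio",
    "delta_runoff",
    "effective_w",
    "budyko_curve_table",
    "grid_delta_runoff",
    "min_fractional_runoff_reduction",
]


@dataclass(frozen=True)
class BudykoParams:
    """Two-class plant-available water coefficients (dimensionless, > 0)."""

    w_forest: float = 2.0
    w_grass: float = 0.5

    def __post_init__(self) -> None:
        if self.w_forest <= 0 or self.w_grass <= 0:
            raise ValueError("plant-available water coefficients must be > 0")


@dataclass
class DeltaRunoffField:
    """Gridded runoff change attributed to forest-cover change.

    ``delta_q`` holds per-year deltaQ (mm/yr) for years[1:], computed from
    consecutive-year forest fractions; ``total`` is the accumulated change
    over the period and ``normalized`` is total divided by climatological
    annual P (dimensionless deltaQ/P).
    """

    delta_q: np.ndarray  # (n_years-1, n_lat, n_lon), mm/yr
    years: np.ndarray  # (n_years-1,) labels, the later year of each pair
    total: np.ndarray  # (n_lat, n_lon), mm
    normalized: np.ndarray  # (n_lat, n_lon), deltaQ/P
    params: BudykoParams = field(default_factory=BudykoParams)


def _validate_phi_w(phi, w) -> tuple[np.ndarray, np.ndarray]:
    phi = np.asarray(phi, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(phi <= 0):
        raise ValueError("aridity index phi = PET/P must be > 0")
    if np.any(w <= 0):
        raise ValueError("plant-available water coefficient w must be > 0")
    return phi, w


def _maybe_scalar(x: np.ndarray):
    return x.item() if np.ndim(x) == 0 else x


def et_ratio(phi, w):
    """Evaporative fraction ET/P on the Budyko curve with parameter w.

    Strictly increasing in both phi and w; tends to 0 as phi -> 0 (energy
    limit) and to 1 as phi -> inf (water limit).
    """
    phi, w = _validate_phi_w(phi, w)
    num = 1.0 + w * phi
    return _maybe_scalar(num / (num + 1.0 / phi))


def runoff_ratio(phi, w):
    """Runoff fraction Q/P = 1 - ET/P (shared denominator, exact)."""
    phi, w = _validate_phi_w(phi, w)
    inv = 1.0 / phi
    return _maybe_scalar(inv / (1.0 + w * phi + inv))


def effective_w(forest_frac, params: BudykoParams | None = None):
    """Area-weighted plant-available water coefficient for a forest/grass mix.

    The non-forest remainder of a cell is grass by construction, so
    w = f*w_forest + (1-f)*w_grass; endpoints return the pure coefficients.
    """
    params = params or BudykoParams()
    f = np.asarray(forest_frac, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("forest fraction must lie in [0, 1]")
    return _maybe_scalar(f * params.w_forest + (1.0 - f) * params.w_grass)


def delta_runoff(P, phi, f_prev, f_curr, params: BudykoParams | None = None):
    """Annual runoff change (mm/yr) due to a forest-fraction change.

    deltaQ = P * (f_curr - f_prev) * [Q/P(phi, w_f) - Q/P(phi, w_g)];
    negative for forest gain when w_forest > w_grass.
    """
    params = params or BudykoParams()
    P = np.asarray(P, dtype=float)
    if np.any(P <= 0):
        raise ValueError("annual precipitation must be > 0")
    f_prev = np.asarray(f_prev, dtype=float)
    f_curr = np.asarray(f_curr, dtype=float)
    if np.any((f_prev < 0) | (f_prev > 1) | (f_curr < 0) | (f_curr > 1)):
        raise ValueError("forest fractions must lie in [0, 1]")
    dq = (
        P
        * (f_curr - f_prev)
        * (runoff_ratio(phi, params.w_forest) - runoff_ratio(phi, params.w_grass))
    )
    return _maybe_scalar(np.asarray(dq))


def budyko_curve_table(phi_values, w_values, params: BudykoParams | None = None):
    """Tabulate (phi, w, ET/P, Q/P) for every (phi, w) combination.

    Returns a pandas DataFrame with one row per pair; used for curve plots
    and regression surfaces.
    """
    import pandas as pd

    phi_values = np.atleast_1d(np.asarray(phi_values, dtype=float))
    w_values = np.atleast_1d(np.asarray(w_values, dtype=float))
    phi_grid, w_grid = np.meshgrid(phi_values, w_values, indexing="ij")
    phi_flat, w_flat = phi_grid.ravel(), w_grid.ravel()
    return pd.DataFrame(
        {
            "phi": phi_flat,
            "w": w_flat,
            "et_ratio": np.atleast_1d(et_ratio(phi_flat, w_flat)),
            "runoff_ratio": np.atleast_1d(runoff_ratio(phi_flat, w_flat)),
        }
    )


def grid_delta_runoff(
    climate,
    forest,
    params: BudykoParams | None = None,
    use_annual_phi: bool = False,
) -> DeltaRunoffField:
    """Apply the forest-change runoff attribution per cell-year on a grid.

    Uses each year's P with the long-term mean aridity index per cell
    (per-year phi behind ``use_annual_phi``) and consecutive-year forest
    fractions.  ``climate`` and ``forest`` must share domain and years.
    """
    params = params or BudykoParams()
    if climate.P.shape != forest.forest_frac.shape:
        raise ValueError(
            f"shape mismatch: climate {climate.P.shape} vs forest "
            f"{forest.forest_frac.shape}"
        )
    if not np.array_equal(np.asarray(climate.years), np.asarray(forest.years)):
        raise ValueError("climate and forest trajectories cover different years")

    phi = climate.phi if use_annual_phi else climate.phi_mean[None, :, :]
    d_frac = forest.forest_frac[1:] - forest.forest_frac[:-1]
    diff = runoff_ratio(phi, params.w_forest) - runoff_ratio(phi, params.w_grass)
    if not use_annual_phi:
        diff = np.broadcast_to(diff, climate.P.shape)
    dq = climate.P[1:] * d_frac * diff[1:]
    total = dq.sum(axis=0)
    normalized = total / climate.P.mean(axis=0)
    return DeltaRunoffField(
        delta_q=dq,
        years=np.asarray(climate.years)[1:],
        total=total,
        normalized=normalized,
        params=params,
    )


def min_fractional_runoff_reduction(
    delta_f: float = 0.20,
    phi_range: tuple[float, float] = (0.6, 2.2),
    step: float = 0.01,
    params: BudykoParams | None = None,
) -> float:
    """Minimum of |deltaQ|/P over an aridity range for a given forest gain.

    Evaluates delta_f * [Q/P(phi, w_grass) - Q/P(phi, w_forest)] on a grid
    of phi values (inclusive endpoints) and returns the minimum as a
    positive fraction of annual P.
    """
    params = params or BudykoParams()
    lo, hi = phi_range
    if not (0 < lo < hi):
        raise ValueError("phi_range must satisfy 0 < lo < hi")
    n = int(round((hi - lo) / step)) + 1
    phi = np.linspace(lo, hi, n)
    reduction = delta_f * (
        runoff_ratio(phi, params.w_grass) - runoff_ratio(phi, params.w_forest)
    )
    return float(reduction.min())
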