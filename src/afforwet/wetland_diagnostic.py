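"""Soil-moisture-deficit wetland-fraction diagnostic and its calibration.

A TOPMODEL-style subgrid parametrization: the saturated (flooded) fraction
of a grid cell is a decreasing function of the grid-mean soil-moisture
deficit D = SM_sat - SM.  We use a generalized (asymmetric) sigmoid of the
deficit,

    f(D) = f_max * (1 + v * exp(k * (D - d0)))**(-1/v)

with f_max the attainable maximum wetland fraction (a topographic
property), d0 a half-saturation deficit (mm), k a deficit sensitivity
(1/mm) and v an asymmetry exponent (v = 1 gives a symmetric logistic with
f(d0) = f_max/2).  The form is CDF-like and saturating, mirroring the
cumulative topographic-index distributions used by subgrid saturation
schemes, is invertible for static calibration, and keeps the parameter
count identifiable from ~16 annual maxima.

Two calibration modes:

* static  — a single long-term maximum extent observation (an RFW-like
  map) pins f_max with the shape parameters held at defaults;
* dynamic — a per-year annual-maximum series (a GIEMS-2-like product)
  constrains (f_max, k, d0) by bounded nonlinear least squares, v fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "WetlandParams",
    "WetlandSeries",
    "CalibrationResult",
    "soil_moisture_deficit",
    "wetland_fraction",
    "calibrate_static",
    "calibrate_dynamic",
    "calibrate_dynamic_grid",
    "annual_max_fraction",
    "annual_max_wetland_area",
    "wetland_series",
]

DEFAULT_K = 0.15  # 1/mm
DEFAULT_D0 = 45.0  # mm
DEFAULT_V = 1.0


@dataclass
class WetlandParams:
    """Per-cell (or scalar) parameters of the saturated-fraction diagnostic."""

    f_max: np.ndarray | float  # attainable max wetland fraction, [0, 1]
    k: np.ndarray | float = DEFAULT_K  # deficit sensitivity, 1/mm, > 0
    d0: np.ndarray | float = DEFAULT_D0  # half-saturation deficit, mm, >= 0
    v: np.ndarray | float = DEFAULT_V  # asymmetry, > 0

    def __post_init__(self) -> None:
        for name, val, lo_ok in (
            ("f_max", self.f_max, lambda x: (x >= 0) & (x <= 1)),
            ("k", self.k, lambda x: x > 0),
            ("d0", self.d0, lambda x: x >= 0),
            ("v", self.v, lambda x: x > 0),
        ):
            arr = np.asarray(val, dtype=float)
            finite = np.isfinite(arr)
            if not np.all(lo_ok(arr[finite])):
                raise ValueError(f"invalid wetland parameter {name}")

    def replace(self, **kw) -> "WetlandParams":
        return replace(self, **kw)


@dataclass
class WetlandSeries:
    """Diagnosed wetland fractions and areas on a grid.

    ``wet_frac`` is per timestep (monthly), ``annual_max_frac`` the within-
    year maximum and ``area`` the annual-maximum wetland area per cell
    (fraction times full cell area, km^2).
    """

    wet_frac: np.ndarray  # (n_steps, n_lat, n_lon)
    annual_max_frac: np.ndarray  # (n_years, n_lat, n_lon)
    area: np.ndarray  # (n_years, n_lat, n_lon), km^2
    years: np.ndarray


@dataclass
class CalibrationResult:
    """Outcome of a dynamic calibration; non-convergence is reported here."""

    params: WetlandParams
    sse: float
    converged: bool
    message: str = ""


def soil_moisture_deficit(sm) -> np.ndarray:
    """Deficit D = SM_sat - SM (mm) per cell-timestep; zero at saturation."""
    sm_arr = np.asarray(sm.sm, dtype=float)
    sm_sat = np.asarray(sm.sm_sat, dtype=float)
    if np.any(sm_arr > sm_sat + 1e-9) or np.any(sm_arr < -1e-9):
        raise ValueError("soil moisture outside [0, SM_sat]")
    return sm_sat - sm_arr


def _unit_shape(deficit, k, d0, v):
    """Shape factor in (0, 1]: the diagnostic with f_max factored out."""
    z = np.asarray(k, dtype=float) * (np.asarray(deficit, dtype=float) - np.asarray(d0, dtype=float))
    v = np.asarray(v, dtype=float)
    # exp overflow is harmless: 1/inf -> 0, the correct dry asymptote
    with np.errstate(over="ignore"):
        return (1.0 + v * np.exp(z)) ** (-1.0 / v)


def wetland_fraction(deficit, params: WetlandParams):
    """Wetland (saturated) fraction from the deficit; decreasing in D."""
    deficit = np.asarray(deficit, dtype=float)
    if np.any(deficit < 0):
        raise ValueError("soil-moisture deficit must be >= 0")
    out = np.asarray(params.f_max, dtype=float) * _unit_shape(
        deficit, params.k, params.d0, params.v
    )
    return out.item() if np.ndim(out) == 0 else out


def calibrate_static(
    obs_max_frac,
    deficit_series,
    shape_defaults: tuple[float, float, float] = (DEFAULT_K, DEFAULT_D0, DEFAULT_V),
) -> WetlandParams:
    """Pin f_max so the modeled long-term maximum matches an observed one.

    With the shape (k, d0, v) fixed, the diagnostic's maximum over the
    calibration period occurs at the minimum deficit, so
    f_max = obs / shape(D_min).  Cells observed at zero get f_max = 0.

    ``deficit_series`` has time on axis 0; ``obs_max_frac`` matches the
    spatial shape (both may be scalar for a single cell).
    """
    obs = np.asarray(obs_max_frac, dtype=float)
    if np.any((obs < 0) | (obs > 1)):
        raise ValueError("observed max wetland fraction must lie in [0, 1]")
    deficit = np.asarray(deficit_series, dtype=float)
    if deficit.size == 0 or not np.any(np.isfinite(deficit)):
        raise ValueError("insufficient data: empty or all-missing deficit series")
    k, d0, v = shape_defaults
    d_min = np.nanmin(deficit, axis=0)
    f_max = np.where(obs > 0, obs / _unit_shape(d_min, k, d0, v), 0.0)
    f_max = np.minimum(f_max, 1.0)
    return WetlandParams(f_max=f_max if f_max.ndim else f_max.item(), k=k, d0=d0, v=v)


def annual_max_fraction(wet_frac: np.ndarray, n_years: int) -> np.ndarray:
    """Within-year maxima of a per-timestep fraction series (axis 0)."""
    steps = wet_frac.shape[0]
    if steps % n_years:
        raise ValueError("series length is not a whole number of years")
    per_year = steps // n_years
    return wet_frac.reshape((n_years, per_year) + wet_frac.shape[1:]).max(axis=1)


def calibrate_dynamic(
    obs_annual_max: np.ndarray,
    deficit_series: np.ndarray,
    init: WetlandParams | None = None,
    bounds: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None,
    max_nfev: int = 400,
) -> CalibrationResult:
    """Fit (f_max, k, d0) of one cell to an annual-maximum series.

    Minimizes the sum of squared errors between modeled and observed annual
    maxima by bounded nonlinear least squares (trust-region reflective);
    v is held at its default.  Needs more years than free parameters
    (>= 4).  A deficit series without interannual variability leaves k and
    d0 unidentifiable; such degenerate fits are flagged, not raised.
    """
    obs = np.asarray(obs_annual_max, dtype=float)
    deficit = np.asarray(deficit_series, dtype=float)
    n_years = obs.size
    if n_years < 4:
        raise ValueError("dynamic calibration needs at least 4 years of observations")
    annual_min_d = annual_max_fraction(-deficit, n_years) * -1.0  # yearly min deficit

    if init is None:
        init = WetlandParams(
            f_max=float(np.clip(2.0 * obs.max(), 1e-6, 1.0)),
            k=DEFAULT_K,
            d0=float(np.median(annual_min_d)),
        )
    v = float(np.asarray(init.v))
    if bounds is None:
        bounds = ((0.0, 1e-4, 0.0), (1.0, 2.0, float(deficit.max()) + 100.0))

    def residuals(theta):
        f_max, k, d0 = theta
        return f_max * _unit_shape(annual_min_d, k, d0, v) - obs

    x0 = np.clip(
        [float(np.asarray(init.f_max)), float(np.asarray(init.k)), float(np.asarray(init.d0))],
        bounds[0],
        bounds[1],
    )
    sol = least_squares(residuals, x0, bounds=bounds, max_nfev=max_nfev)
    sse = float(np.sum(sol.fun**2))
    params = WetlandParams(f_max=float(sol.x[0]), k=float(sol.x[1]), d0=float(sol.x[2]), v=v)

    degenerate = np.ptp(annual_min_d) < 1e-9 or np.ptp(obs) < 1e-12
    converged = bool(sol.success) and not degenerate
    message = sol.message
    if degenerate:
        message = "degenerate fit: no interannual variability, k/d0 unidentifiable"
    return CalibrationResult(params=params, sse=sse, converged=converged, message=message)


def calibrate_dynamic_grid(
    obs_annual_max: np.ndarray,
    deficit_series: np.ndarray,
    **kwargs,
):
    """Per-cell dynamic calibration over a grid.

    ``obs_annual_max`` is (n_years, n_lat, n_lon), ``deficit_series``
    (n_steps, n_lat, n_lon).  Cells whose observations are all zero get
    f_max = 0 without fitting.  Returns (WetlandParams of arrays, sse
    array, converged bool array).
    """
    _, n_lat, n_lon = obs_annual_max.shape
    f_max = np.zeros((n_lat, n_lon))
    k = np.full((n_lat, n_lon), DEFAULT_K)
    d0 = np.full((n_lat, n_lon), DEFAULT_D0)
    sse = np.zeros((n_lat, n_lon))
    converged = np.ones((n_lat, n_lon), dtype=bool)
    for i in range(n_lat):
        for j in range(n_lon):
            obs_ij = obs_annual_max[:, i, j]
            if not np.any(obs_ij > 0):
                continue
            res = calibrate_dynamic(obs_ij, deficit_series[:, i, j], **kwargs)
            f_max[i, j] = res.params.f_max
            k[i, j] = res.params.k
            d0[i, j] = res.params.d0
            sse[i, j] = res.sse
            converged[i, j] = res.converged
    return WetlandParams(f_max=f_max, k=k, d0=d0, v=DEFAULT_V), sse, converged


def annual_max_wetland_area(wet_frac_series: np.ndarray, domain, n_years: int) -> np.ndarray:
    """Annual-maximum wetland area per cell-year (km^2).

    Per-year maximum fraction times full cell area; the national total is
    the sum over cells.
    """
    if wet_frac_series.shape[1:] != domain.cell_area.shape:
        raise ValueError("wetland fraction series does not match the domain grid")
    return annual_max_fraction(wet_frac_series, n_years) * domain.cell_area[None, :, :]


def wetland_series(sm, params: WetlandParams, domain, years=None) -> WetlandSeries:
    """Run the diagnostic over a soil-moisture series and aggregate annually."""
    deficit = soil_moisture_deficit(sm)
    frac = wetland_fraction(deficit, params)
    years = np.asarray(sm.years if years is None else years)
    n_years = years.size
    ann = annual_max_fraction(frac, n_years)
    area = ann * domain.cell_area[None, :, :]
    return WetlandSeries(wet_frac=frac, annual_max_frac=ann, area=area, years=years)
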