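"""Trend estimation, masks, climate zones, attribution and sensitivity.

Implements the statistical layer of the analysis: per-cell least-squares
trends with t-tests, the wetland-cell (>1% mean annual maximum fraction)
and rice-paddy (>10% coverage) exclusion rules, quadrant classification of
forest-vs-wetland trends, PET/P climate zones, factorial S1-S0 attribution
differences, the chain decomposition of the wetland sensitivity to forest
change

    dAwet/dAforest = (dAwet/dSM) * (dSM/dAforest)

and the 5th-95th percentile outlier rule with per-zone box statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendResult",
    "SensitivityResult",
    "ZONE_WET",
    "ZONE_MESIC",
    "ZONE_DRY",
    "linear_trend",
    "trend_field",
    "classify_quadrant",
    "climate_zone",
    "wetland_cell_mask",
    "rice_filter",
    "attribution_diff",
    "sensitivity_ratios",
    "drop_outliers",
    "zone_box_stats",
]

ZONE_WET = "wet"  # PET/P < 1
ZONE_MESIC = "mesic"  # 1 <= PET/P <= 2
ZONE_DRY = "dry"  # PET/P > 2

QUADRANT_BOUNDARY = 0


@dataclass
class TrendResult:
    """OLS slope against calendar year and two-sided t-test p-value."""

    slope: np.ndarray | float
    p_value: np.ndarray | float


def trend_field(field: np.ndarray, years) -> TrendResult:
    """Per-cell least-squares trend of a (time, ...) field vs calendar year.

    The p-value is the two-sided t-test on the slope.  Fewer than 3 finite
    time points yields missing (NaN) results rather than an exception; a
    constant series has slope 0 and p = 1 by convention; a noiseless
    nonconstant linear series has p = 0.
    """
    y = np.asarray(field, dtype=float)
    t = np.asarray(years, dtype=float)
    n = t.size
    if y.shape[0] != n:
        raise ValueError("time axis of field does not match years")
    if n < 3:
        nan = np.full(y.shape[1:], np.nan)
        return TrendResult(slope=nan, p_value=nan.copy())
    tc = t - t.mean()
    sxx = float((tc**2).sum())
    ymean = y.mean(axis=0)
    slope = np.tensordot(tc, y, axes=(0, 0)) / sxx
    resid = y - ymean - slope[None] * tc.reshape((n,) + (1,) * (y.ndim - 1))
    ss_res = (resid**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(ss_res / (n - 2) / sxx)
        tstat = np.abs(slope) / se
    p = 2.0 * stats.t.sf(tstat, df=n - 2)
    # exact fits: zero residual variance
    exact = ss_res <= 1e-300
    p = np.where(exact & (slope == 0), 1.0, p)
    p = np.where(exact & (slope != 0), 0.0, p)
    return TrendResult(slope=slope, p_value=p)


def linear_trend(series, years) -> TrendResult:
    """Single-cell trend; same conventions as :func:`trend_field`."""
    y = np.asarray(series, dtype=float)
    finite = np.isfinite(y)
    if finite.sum() < 3:
        return TrendResult(slope=np.nan, p_value=np.nan)
    res = trend_field(y[finite][:, None], np.asarray(years)[finite])
    return TrendResult(slope=float(res.slope[0]), p_value=float(res.p_value[0]))


def classify_quadrant(forest_trend, wetland_trend):
    """Quadrant of (forest trend, wetland trend); 0 marks a boundary (a zero).

    Quadrant 4 — forest increasing while wetlands shrink — is the
    afforestation-pressure signature.
    """
    f = np.asarray(forest_trend, dtype=float)
    w = np.asarray(wetland_trend, dtype=float)
    q = np.select(
        [
            (f > 0) & (w > 0),
            (f < 0) & (w > 0),
            (f < 0) & (w < 0),
            (f > 0) & (w < 0),
        ],
        [1, 2, 3, 4],
        default=QUADRANT_BOUNDARY,
    )
    return q.item() if np.ndim(f) == 0 and np.ndim(w) == 0 else q


def climate_zone(phi_mean):
    """Classify mean PET/P into wet (<1), mesic (1-2, closed) or dry (>2)."""
    phi = np.asarray(phi_mean, dtype=float)
    if np.any(phi <= 0):
        raise ValueError("mean PET/P must be > 0")
    zone = np.where(phi < 1.0, ZONE_WET, np.where(phi <= 2.0, ZONE_MESIC, ZONE_DRY))
    return zone.item() if np.ndim(phi) == 0 else zone


def wetland_cell_mask(annual_max_frac: np.ndarray, threshold: float = 0.01) -> np.ndarray:
    """Cells whose mean annual maximum wetland fraction exceeds the threshold.

    Strict inequality: a mean of exactly 1% is excluded.
    """
    return np.asarray(annual_max_frac, dtype=float).mean(axis=0) > threshold


def rice_filter(mask: np.ndarray, rice_frac: np.ndarray, threshold: float = 0.10) -> np.ndarray:
    """Remove cells with rice-paddy coverage strictly above the threshold."""
    return np.asarray(mask, dtype=bool) & ~(np.asarray(rice_frac, dtype=float) > threshold)


def attribution_diff(field_s1: np.ndarray, field_s0: np.ndarray) -> np.ndarray:
    """Factorial attribution S1 - S0: the change due to the driver."""
    a = np.asarray(field_s1, dtype=float)
    b = np.asarray(field_s0, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: S1 {a.shape} vs S0 {b.shape}")
    return a - b


@dataclass
class SensitivityResult:
    """Chain-decomposed sensitivities with inclusion bookkeeping.

    ``included`` flags cells that pass all filters, have finite ratios and
    fall inside the outlier band; ``passes_filters`` is the pre-outlier
    filter mask; ``n_nonfinite`` counts cells excluded for a residual
    nonfinite ratio despite passing the filters.
    """

    dAwet_dAforest: np.ndarray  # km^2 per km^2
    dAwet_dSM: np.ndarray  # km^2 per mm
    dSM_dAforest: np.ndarray  # mm per km^2
    included: np.ndarray  # bool
    passes_filters: np.ndarray  # bool
    outlier_band: tuple[float, float] | None
    n_nonfinite: int


def sensitivity_ratios(
    dAwet: np.ndarray,
    dAforest: np.ndarray,
    dSM: np.ndarray,
    filters: dict[str, np.ndarray],
    outlier_pct: tuple[float, float] | None = (5.0, 95.0),
) -> SensitivityResult:
    """Per-cell sensitivities from period changes, with filters and outliers.

    ``dAwet`` and ``dSM`` are end-minus-start changes of the S1-S0
    attribution differences (km^2 and mm); ``dAforest`` the raw forest-area
    change (km^2).  ``filters`` provides boolean masks ``has_forest``,
    ``forest_changed`` and ``wetland_mask`` (rice exclusion folded into the
    wetland mask upstream); only cells passing all three are considered.
    Ratios where the denominator vanishes are left nonfinite and excluded.

    The 5th-95th percentile outlier band on dAwet/dAforest is computed over
    every finite-ratio cell — a pool independent of the filter masks, so
    filter choices do not shift the band — and intersected with the filter
    mask to give the final inclusion flag.
    """
    dAwet = np.asarray(dAwet, dtype=float)
    dAforest = np.asarray(dAforest, dtype=float)
    dSM = np.asarray(dSM, dtype=float)
    required = ("has_forest", "forest_changed", "wetland_mask")
    missing = [k for k in required if k not in filters]
    if missing:
        raise ValueError(f"missing filter masks: {missing}")
    filt = np.ones(dAwet.shape, dtype=bool)
    for k in required:
        filt &= np.asarray(filters[k], dtype=bool)

    with np.errstate(divide="ignore", invalid="ignore"):
        r_fa = np.where(dAforest != 0, dAwet / dAforest, np.nan)
        r_ws = np.where(dSM != 0, dAwet / dSM, np.nan)
        r_sf = np.where(dAforest != 0, dSM / dAforest, np.nan)

    finite = np.isfinite(r_fa) & np.isfinite(r_ws) & np.isfinite(r_sf)
    band = None
    in_band = np.ones_like(filt)
    if outlier_pct is not None and finite.any():
        lo, hi = np.percentile(r_fa[finite], outlier_pct)
        band = (float(lo), float(hi))
        in_band = (r_fa >= lo) & (r_fa <= hi)
    included = filt & finite & in_band
    n_nonfinite = int((filt & ~finite).sum())
    return SensitivityResult(
        dAwet_dAforest=r_fa,
        dAwet_dSM=r_ws,
        dSM_dAforest=r_sf,
        included=included,
        passes_filters=filt,
        outlier_band=band,
        n_nonfinite=n_nonfinite,
    )


def drop_outliers(
    values, lower_pct: float = 5.0, upper_pct: float = 95.0
) -> tuple[np.ndarray, int]:
    """Retain values inside the [P_lower, P_upper] band (inclusive).

    Percentiles use linear interpolation between order statistics.  NaNs
    are discarded before the band is computed; an empty input returns an
    empty array.  Returns (retained values, number dropped as outliers).
    """
    vals = np.asarray(values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return vals, 0
    lo, hi = np.percentile(vals, [lower_pct, upper_pct])
    keep = (vals >= lo) & (vals <= hi)
    return vals[keep], int((~keep).sum())


def zone_box_stats(values_by_zone: dict[str, np.ndarray]) -> pd.DataFrame:
    """Box-plot statistics per climate zone (outliers dropped beforehand).

    Columns: min, Q0.2, Q0.4, Q0.5, Q0.6, Q0.8, max, mean, n.  An empty
    zone yields an all-missing row with n = 0.
    """
    rows = {}
    for zone, vals in values_by_zone.items():
        v = np.asarray(vals, dtype=float).ravel()
        v = v[np.isfinite(v)]
        if v.size == 0:
            rows[zone] = {c: np.nan for c in
                          ("min", "q20", "q40", "q50", "q60", "q80", "max", "mean")}
            rows[zone]["n"] = 0
            continue
        q20, q40, q50, q60, q80 = np.percentile(v, [20, 40, 50, 60, 80])
        rows[zone] = {
            "min": v.min(),
            "q20": q20,
            "q40": q40,
            "q50": q50,
            "q60": q60,
            "q80": q80,
            "max": v.max(),
            "mean": v.mean(),
            "n": v.size,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "zone"
    return out
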