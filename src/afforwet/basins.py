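"""Basin aggregation, basin-scale Budyko attribution and protection stats.

Cells are aggregated to contiguous basins (sum or area-weighted mean), the
forest-change runoff attribution is re-applied at the basin scale, yearly
cumulative wetland-vs-forest change is regressed per protection group
(national / provincial / municipal-county / unprotected reserves), and
basins exceeding a loss threshold are counted overall and by level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .budyko import BudykoParams, runoff_ratio
from .synthetic_data import BasinTable, PROTECTION_LEVELS

__all__ = [
    "aggregate_to_basins",
    "basin_budyko_delta_q",
    "group_regression",
    "count_basins_exceeding",
    "summarize_basins",
]


def aggregate_to_basins(field: np.ndarray, basin_table: BasinTable, mode: str) -> pd.Series:
    """Aggregate a per-cell field to basins.

    ``mode`` is 'sum' or 'area_weighted_mean'; sums over basins equal the
    domain sum exactly.  Returns a Series indexed by basin_id.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != basin_table.basin_id.shape:
        raise ValueError("field does not match the basin table's grid")
    ids = basin_table.basin_id.ravel()
    vals = field.ravel()
    if mode == "sum":
        out = pd.Series(vals).groupby(ids).sum()
    elif mode == "area_weighted_mean":
        w = basin_table.domain.cell_area.ravel()
        num = pd.Series(vals * w).groupby(ids).sum()
        out = num / pd.Series(w).groupby(ids).sum()
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    out.index.name = "basin_id"
    return out


def basin_budyko_delta_q(
    climate, forest, basin_table: BasinTable, params: BudykoParams | None = None
) -> pd.DataFrame:
    """Forest-change runoff attribution applied at the basin scale.

    P, PET and forest fractions are area-weighted to basins first, then
    deltaQ uses each year's basin P, the basin climatological PET/P and
    consecutive-year basin forest fractions.  Returns per-basin annual
    deltaQ columns plus a 'total' (mm over the period).
    """
    params = params or BudykoParams()
    ids = basin_table.basin_ids()
    n_years = climate.years.size
    P_b = np.empty((n_years, ids.size))
    PET_b = np.empty_like(P_b)
    f_b = np.empty_like(P_b)
    for y in range(n_years):
        P_b[y] = aggregate_to_basins(climate.P[y], basin_table, "area_weighted_mean").loc[ids]
        PET_b[y] = aggregate_to_basins(climate.PET[y], basin_table, "area_weighted_mean").loc[ids]
        f_b[y] = aggregate_to_basins(
            forest.forest_frac[y], basin_table, "area_weighted_mean"
        ).loc[ids]
    phi_b = PET_b.mean(axis=0) / P_b.mean(axis=0)
    diff = runoff_ratio(phi_b, params.w_forest) - runoff_ratio(phi_b, params.w_grass)
    dq = P_b[1:] * (f_b[1:] - f_b[:-1]) * diff[None, :]
    out = pd.DataFrame(dq.T, index=pd.Index(ids, name="basin_id"), columns=climate.years[1:])
    out["total"] = dq.sum(axis=0)
    return out


def group_regression(
    dAwet_by_year: pd.DataFrame,
    dAforest_by_year: pd.DataFrame,
    levels: pd.Series,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Regress cumulative wetland change on cumulative forest change by group.

    Inputs are (years x basin) tables of cumulative changes since the
    first year (km^2); ``levels`` maps basin_id to protection level.  Per
    group the basin columns are summed and the yearly points regressed by
    ordinary least squares.  Degenerate x-variance yields a missing slope.
    Significance is starred at ``alpha`` (0.01: the 99% confidence level).
    """
    if dAwet_by_year.shape[0] < 3:
        raise ValueError("group regression needs at least 3 yearly points")
    rows = {}
    groups = {level: levels.index[levels == level] for level in PROTECTION_LEVELS}
    groups["all_protected"] = levels.index[levels != "unprotected"]
    groups["all"] = levels.index
    for name, basins in groups.items():
        basins = [b for b in basins if b in dAwet_by_year.columns]
        if not basins:
            rows[name] = {"slope": np.nan, "p_value": np.nan, "n_years": 0,
                          "significant": False}
            continue
        x = dAforest_by_year[basins].sum(axis=1).to_numpy()
        y = dAwet_by_year[basins].sum(axis=1).to_numpy()
        if np.ptp(x) < 1e-12:
            rows[name] = {"slope": np.nan, "p_value": np.nan, "n_years": x.size,
                          "significant": False}
            continue
        res = stats.linregress(x, y)
        p = 0.0 if np.isnan(res.pvalue) and res.stderr == 0 else float(res.pvalue)
        rows[name] = {
            "slope": float(res.slope),
            "p_value": p,
            "n_years": x.size,
            "significant": bool(p < alpha),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    return out


def count_basins_exceeding(
    basin_loss_pct: pd.Series,
    threshold: float = 10.0,
    levels: pd.Series | None = None,
) -> pd.Series:
    """Count basins with loss strictly above the threshold, overall and by level."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    exceed = basin_loss_pct > threshold
    counts = {"overall": int(exceed.sum())}
    if levels is not None:
        for level in PROTECTION_LEVELS:
            ids = levels.index[levels == level]
            counts[level] = int(exceed.reindex(ids).fillna(False).sum())
    return pd.Series(counts, name="n_basins")


def summarize_basins(
    basin_table: BasinTable,
    forest_area_by_year: pd.DataFrame,
    wetland_area_by_year: pd.DataFrame,
    delta_q_total: pd.Series,
    loss_pct: pd.Series,
) -> pd.DataFrame:
    """Assemble the per-basin summary table (areas, deltaQ, loss).

    Yearly inputs are (years x basin) km^2 tables; the summary keeps the
    final year.  A basin's protection level is the one assigned in the
    basin table (highest-wins for multi-reserve basins is resolved
    upstream at generation time).
    """
    ids = basin_table.basin_ids()
    area = basin_table.basin_area_km2()
    out = pd.DataFrame(
        {
            "protection_level": [basin_table.levels[int(b)] for b in ids],
            "area_km2": area.loc[ids],
            "forest_area_km2": forest_area_by_year.iloc[-1].loc[ids],
            "wetland_area_km2": wetland_area_by_year.iloc[-1].loc[ids],
            "delta_q_mm": delta_q_total.loc[ids],
            "loss_pct": loss_pct.loc[ids],
        },
        index=pd.Index(ids, name="basin_id"),
    )
    return out
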