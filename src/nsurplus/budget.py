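"""Soil-surface nitrogen budgets: surplus, NUE, aggregation and phase summaries.

The budget follows the soil-surface (gross balance) convention: nitrogen
inputs to the soil–plant system are synthetic fertilizer, animal manure
(as applied, i.e. net of storage losses), atmospheric deposition and
biological fixation; outputs are removals via harvested crops and via
grazing/cutting of grass.  The surplus is the plain balance

    surplus = (in_fert + in_man + in_dep + in_bnf) - (out_crops + out_past)

per region, year and ensemble member, and nitrogen use efficiency is
``NUE = 100 * outputs / inputs`` (%).  All per-hectare fluxes are
kgN ha^-1 yr^-1 on the area basis of their sector (agricultural fluxes
per hectare of agricultural area, non-agricultural per hectare of
non-agricultural area); mass totals are TgN yr^-1.

Negative surpluses are retained (the budget is a pure balance, soil N
mining is a real signal) and can be located with :func:`flag_negative`.
"""

from __future__ import annotations

from itertools import product
from typing import Mapping

import numpy as np
import pandas as pd

#: N input components (kgN per ha of sector area per yr)
INPUT_COMPONENTS = ["in_fert", "in_man", "in_dep", "in_bnf"]
#: N removal components (kgN per ha of sector area per yr)
OUTPUT_COMPONENTS = ["out_crops", "out_past"]
COMPONENTS = INPUT_COMPONENTS + OUTPUT_COMPONENTS
AREA_COLUMNS = ["ag_area", "nonag_area"]

KEY_COLUMNS = ["region_id", "country", "year", "member_id", "sector"]

SECTORS = ("agricultural", "non-agricultural")

#: kg -> Tg
KG_PER_TG = 1e9

#: Default development phases (inclusive year windows).
PHASES = {"early": (1940, 1985), "intensification": (1986, 2019)}


def ensemble_members() -> pd.DataFrame:
    """Enumerate the 16-member ensemble (2 fertilizer x 4 manure x 2 pasture).

    Member ids are 1..16 in lexicographic order of
    (fert_variant, manure_variant, pasture_variant).
    """
    rows = [
        {"member_id": 1 + i, "fert_variant": f, "manure_variant": m, "pasture_variant": p}
        for i, (f, m, p) in enumerate(product((1, 2), (1, 2, 3, 4), (1, 2)))
    ]
    return pd.DataFrame(rows)


def _check_components(records: pd.DataFrame) -> None:
    missing = [c for c in COMPONENTS if c not in records.columns]
    if missing:
        raise ValueError(f"missing component columns: {missing}")
    sub = records[COMPONENTS]
    if sub.isna().any().any():
        bad = records.loc[sub.isna().any(axis=1), KEY_COLUMNS[:1] + ["year", "member_id"]]
        raise ValueError(
            "missing component values for "
            + "; ".join(
                f"region={r.region_id} year={r.year} member={r.member_id}"
                for r in bad.head(10).itertuples()
            )
        )
    neg = (sub < 0).any(axis=1)
    if neg.any():
        bad = records.loc[neg, ["region_id", "year", "member_id"]]
        raise ValueError(
            "negative component values for "
            + "; ".join(
                f"region={r.region_id} year={r.year} member={r.member_id}"
                for r in bad.head(10).itertuples()
            )
        )


def compute_surplus(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``total_in``, ``total_out``, ``surplus`` and ``nue`` columns.

    ``nue`` (in %) is NaN where total inputs are zero.  Input records are one
    row per (region, year, member, sector) in the wide component layout.
    """
    _check_components(records)
    out = records.copy()
    out["total_in"] = out[INPUT_COMPONENTS].sum(axis=1)
    out["total_out"] = out[OUTPUT_COMPONENTS].sum(axis=1)
    out["surplus"] = out["total_in"] - out["total_out"]
    with np.errstate(divide="ignore", invalid="ignore"):
        nue = 100.0 * out["total_out"] / out["total_in"]
    out["nue"] = nue.where(out["total_in"] > 0)
    return out


def flag_negative(series: pd.DataFrame) -> pd.DataFrame:
    """Rows with a negative surplus (soil N mining); never clipped upstream."""
    return series.loc[series["surplus"] < 0]


def sector_area(records: pd.DataFrame, sector: str) -> pd.Series:
    """Weighting area for a sector: its own area, or the total for 'total'."""
    if sector == "agricultural":
        return records["ag_area"]
    if sector == "non-agricultural":
        return records["nonag_area"]
    if sector == "total":
        return records["ag_area"] + records["nonag_area"]
    raise ValueError(f"unknown sector {sector!r}")


def combine_sectors(records: pd.DataFrame) -> pd.DataFrame:
    """Merge the two sector records into per-ha-of-total-area records.

    Every flux is converted from its sector area basis to the total-area
    basis (mass-conserving), so the result is a sector='total' record set.
    """
    value_cols = COMPONENTS
    ag = records[records["sector"] == "agricultural"].set_index(
        ["region_id", "country", "year", "member_id"]
    )
    na = records[records["sector"] == "non-agricultural"].set_index(
        ["region_id", "country", "year", "member_id"]
    )
    if len(ag) != len(na):
        raise ValueError("sectors are not paired per (region, year, member)")
    na = na.reindex(ag.index)
    total_area = ag["ag_area"] + na["nonag_area"]
    out = ag[["ag_area"]].copy()
    out["nonag_area"] = na["nonag_area"]
    for c in value_cols:
        out[c] = (ag[c] * ag["ag_area"] + na[c] * na["nonag_area"]) / total_area
    out["sector"] = "total"
    return out.reset_index()


def aggregate(
    records: pd.DataFrame,
    scope: str,
    groups: Mapping[str, str] | pd.Series | None = None,
    sector: str = "agricultural",
) -> pd.DataFrame:
    """Area-weighted aggregation of per-ha component fluxes.

    Parameters
    ----------
    scope
        ``'region'`` (identity), ``'country'``, ``'EU27'`` (one group), or
        ``'typology'`` (requires ``groups`` mapping region_id -> label).
    groups
        region_id -> group label, required for scope='typology'.
    sector
        Which sector rows to aggregate; the sector's area is the weight
        (total area for sector='total' records).

    Per-ha fluxes are area-weighted means; the group area is the summed
    weight, so mass closure (flux x area) holds exactly at every scope.
    """
    sub = records[records["sector"] == sector].copy()
    if sub.empty:
        raise ValueError(f"no records for sector {sector!r}")
    if scope == "region":
        key = sub["region_id"]
    elif scope == "country":
        key = sub["country"]
    elif scope == "EU27":
        key = pd.Series("EU27", index=sub.index)
    elif scope == "typology":
        if groups is None:
            raise ValueError("scope='typology' requires a region_id -> label mapping")
        mapping = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
        key = sub["region_id"].map(mapping)
        if key.isna().any():
            orphans = sorted(sub.loc[key.isna(), "region_id"].unique())
            raise ValueError(f"regions without a scope assignment: {orphans[:10]}")
    else:
        raise ValueError(f"unknown scope {scope!r}")

    w = sector_area(sub, sector)
    if (w <= 0).any():
        raise ValueError("non-positive aggregation weights")
    sub = sub.assign(_group=key.values, _w=w.values)
    for c in COMPONENTS:
        sub[c] = sub[c] * sub["_w"]
    g = sub.groupby(["_group", "year", "member_id"], sort=True)
    agg = g[COMPONENTS].sum()
    wsum = g["_w"].sum()
    for c in COMPONENTS:
        agg[c] = agg[c] / wsum
    agg["area"] = wsum
    agg = agg.reset_index().rename(columns={"_group": "scope_id"})
    agg["scope"] = scope
    agg["sector"] = sector
    agg["country"] = agg["scope_id"]  # harmless alias for downstream column access
    agg["region_id"] = agg["scope_id"]
    agg["ag_area"] = agg["area"] if sector == "agricultural" else np.nan
    agg["nonag_area"] = agg["area"] if sector == "non-agricultural" else np.nan
    return compute_surplus(agg)


def member_mean(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse the ensemble dimension to the member-mean (member_id=0)."""
    keys = [c for c in ["scope", "scope_id", "region_id", "country", "year", "sector"] if c in records.columns]
    num = [c for c in records.columns if c not in keys + ["member_id"] and pd.api.types.is_numeric_dtype(records[c])]
    out = records.groupby(keys, sort=True, as_index=False)[num].mean()
    out["member_id"] = 0
    return out


def ensemble_stats(series: pd.DataFrame, value: str = "surplus") -> pd.DataFrame:
    """Per-year ensemble mean / min / max / sd (ddof=1) of one column.

    With a single member the sd is reported absent (NaN).
    """
    keys = [c for c in ["scope", "scope_id", "sector", "year"] if c in series.columns]
    if not keys:
        keys = ["year"]
    g = series.groupby(keys, sort=True)[value]
    out = g.agg(mean="mean", min="min", max="max", sd=lambda v: v.std(ddof=1), n="size")
    out.loc[out["n"] < 2, "sd"] = np.nan
    return out.reset_index()


def mass_totals(records: pd.DataFrame, sector: str = "agricultural") -> pd.DataFrame:
    """Per-year, per-member component mass fluxes (TgN yr^-1) over all regions.

    Uses year-specific areas: flux (kgN/ha) x sector area (ha) x 1e-9.
    """
    sub = records[records["sector"] == sector].copy()
    if sub.empty:
        raise ValueError(f"no records for sector {sector!r}")
    w = sector_area(sub, sector)
    for c in COMPONENTS:
        sub[c] = sub[c] * w / KG_PER_TG
    g = sub.groupby(["year", "member_id"], sort=True)[COMPONENTS].sum().reset_index()
    g["total_in"] = g[INPUT_COMPONENTS].sum(axis=1)
    g["total_out"] = g[OUTPUT_COMPONENTS].sum(axis=1)
    g["surplus"] = g["total_in"] - g["total_out"]
    return g


def phase_summary(
    records: pd.DataFrame,
    phases: Mapping[str, tuple[int, int]] | None = None,
    sector: str = "agricultural",
) -> pd.DataFrame:
    """Mean component mass fluxes, input shares and NUE per development phase.

    For each phase window (inclusive years) the component masses are summed
    over regions per year (year-specific areas), averaged over the window and
    the ensemble, and expressed both as TgN yr^-1 and as % of total inputs.
    """
    phases = PHASES if phases is None else phases
    years = records["year"]
    masses = mass_totals(records, sector=sector)
    rows = []
    for name, (y0, y1) in phases.items():
        if y0 < years.min() or y1 > years.max():
            raise ValueError(f"phase {name!r} window {y0}-{y1} outside data range")
        sel = masses[(masses["year"] >= y0) & (masses["year"] <= y1)]
        mean = sel[COMPONENTS + ["total_in", "total_out"]].mean()
        row = {"phase": name, "year_start": y0, "year_end": y1}
        for c in COMPONENTS:
            row[f"{c}_tg"] = mean[c]
        for c in INPUT_COMPONENTS:
            row[f"{c}_share_pct"] = 100.0 * mean[c] / mean["total_in"]
        row["total_in_tg"] = mean["total_in"]
        row["total_out_tg"] = mean["total_out"]
        row["surplus_tg"] = mean["total_in"] - mean["total_out"]
        row["nue_pct"] = 100.0 * mean["total_out"] / mean["total_in"]
        rows.append(row)
    return pd.DataFrame(rows)


def moving_average(series: pd.Series, window: int = 3) -> pd.Series:
    """Centered moving average over years (index = year)."""
    return series.sort_index().rolling(window, center=True, min_periods=window).mean()


def percent_change(
    series: pd.Series,
    window_start: tuple[int, int],
    window_end: tuple[int, int],
) -> float:
    """Endpoint-vs-start percent change on 3-year window means.

    ``series`` is a per-year series (index = year).  Each window is an
    inclusive 3-year interval; the change is
    ``100 * (mean(end) - mean(start)) / mean(start)``.
    """
    s = series.sort_index()
    for y0, y1 in (window_start, window_end):
        if y0 < s.index.min() or y1 > s.index.max():
            raise ValueError(f"window {y0}-{y1} outside data range")
    start = s.loc[window_start[0] : window_start[1]].mean()
    end = s.loc[window_end[0] : window_end[1]].mean()
    if start == 0:
        raise ValueError("start-window mean is zero; percent change undefined")
    return float(100.0 * (end - start) / start)
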