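"""Anomaly products: GDD differences and percent yield change vs. baselines.

The season-condition products compare a current year against either the
previous year or the five-year reference mean: cumulative GDD at a fixed
cutoff date (end of July for winter crops, end of September for maize) and
yield as a percent change, where -20 % means the year reached 80 % of the
reference yield and +20 % means 120 %.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from shapely.geometry import mapping

from .thermal_time import GddParams, accumulate_gdd

CUTOFF_WINTER_CROPS = (7, 31)  # end of July
CUTOFF_MAIZE = (9, 30)  # end of September

REFERENCE_MODES = ("previous_year", "five_year_mean")


def yield_change_percent(current, reference):
    """Percent change of ``current`` vs ``reference``: 100 * (cur/ref - 1).

    Non-positive references make the ratio meaningless; those entries come
    back NaN with a warning.
    """
    current = np.asarray(current, dtype=float)
    reference = np.asarray(reference, dtype=float)
    bad = ~(reference > 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} non-positive reference values -> missing")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(bad, np.nan, 100.0 * (current / reference - 1.0))
    return float(out) if out.ndim == 0 else out


def reference_values(
    values: pd.DataFrame, year: int, mode: str = "five_year_mean"
) -> pd.Series:
    """Per-unit reference value for ``year``: previous year or 5-year mean.

    ``values`` has columns unit_id, year, value.  The five-year window is
    the five years preceding ``year``; units observed in fewer than five of
    them get the mean over what exists (warning), and below three the unit
    is flagged missing (NaN).
    """
    if mode not in REFERENCE_MODES:
        raise ValueError(f"mode must be one of {REFERENCE_MODES}")
    piv = values.pivot_table(index="unit_id", columns="year", values="value")
    if mode == "previous_year":
        if year - 1 not in piv.columns:
            raise ValueError(f"no data for previous year {year - 1}")
        return piv[year - 1]
    window = [y for y in range(year - 5, year) if y in piv.columns]
    if not window:
        raise ValueError(f"no reference years in [{year - 5}, {year - 1}]")
    sub = piv[window]
    counts = sub.notna().sum(axis=1)
    if (counts < 5).any():
        warnings.warn(
            f"{int((counts < 5).sum())} units have < 5 reference years; "
            "averaging over what exists"
        )
    ref = sub.mean(axis=1)
    ref[counts < 3] = np.nan
    return ref


def gdd_at_cutoff(
    weather: pd.DataFrame, params: GddParams, cutoff: tuple[int, int]
) -> pd.DataFrame:
    """Cumulative GDD on the cutoff date, per unit and year.

    Returns columns unit_id, year, value.
    """
    weather = weather.copy()
    weather["year"] = pd.DatetimeIndex(weather["date"]).year
    rows = []
    for (uid, year), grp in weather.groupby(["unit_id", "year"], sort=True):
        tt = accumulate_gdd(grp, params, unit_id=uid)
        cut = pd.Timestamp(int(year), *cutoff)
        upto = tt.gdd[tt.gdd.index <= cut]
        rows.append(
            {
                "unit_id": uid,
                "year": int(year),
                "value": float(upto.iloc[-1]) if len(upto) else 0.0,
            }
        )
    return pd.DataFrame(rows)


def gdd_difference(
    weather: pd.DataFrame,
    params: GddParams,
    year: int,
    *,
    cutoff: tuple[int, int] = CUTOFF_WINTER_CROPS,
    mode: str = "five_year_mean",
) -> pd.Series:
    """Per-unit GDD difference at the cutoff date vs. the reference.

    Positive values mean the current season ran thermally ahead of the
    reference (previous year or five-year mean).
    """
    table = gdd_at_cutoff(weather, params, cutoff)
    current = table[table["year"] == year].set_index("unit_id")["value"]
    ref = reference_values(table, year, mode)
    return (current - ref).rename("gdd_difference")


def yield_anomaly_table(
    yields: pd.DataFrame, year: int, mode: str = "five_year_mean"
) -> pd.DataFrame:
    """Per-unit percent yield change for ``year`` vs. the chosen reference.

    ``yields`` has columns unit_id, year, yield_dt_ha.  Output columns:
    unit_id, value_current, value_reference, percent_change.
    """
    values = yields.rename(columns={"yield_dt_ha": "value"})[
        ["unit_id", "year", "value"]
    ]
    current = values[values["year"] == year].set_index("unit_id")["value"]
    ref = reference_values(values, year, mode)
    current, ref = current.align(ref, join="inner")
    return pd.DataFrame(
        {
            "unit_id": current.index,
            "value_current": current.to_numpy(),
            "value_reference": ref.to_numpy(),
            "percent_change": yield_change_percent(
                current.to_numpy(), ref.to_numpy()
            ),
        }
    )


def write_choropleth_geojson(units, table: pd.DataFrame, path, key="unit_id") -> None:
    """Unit polygons with the table's columns as feature properties."""
    indexed = table.set_index(key)
    features = []
    for uid, poly in units.items():
        props = {"unit_id": uid}
        if uid in indexed.index:
            rec = indexed.loc[uid]
            props.update(
                {
                    c: (None if pd.isna(v) else float(v) if np.isreal(v) else v)
                    for c, v in rec.items()
                }
            )
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(poly)}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
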