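"""Growing degree days and thermal-time resampling.

Thermal time (cumulative growing degree days, GDD) re-indexes a calendar
time series by accumulated heat above a crop-specific base temperature, so
that the same coordinate value refers to the same crop development stage in
every year.  The daily increment is

    max(0, (min(Tx, 30) + max(Tn, Tb)) / 2 - Tb)

with Tb = 5 degC for winter wheat and winter rapeseed and Tb = 10 degC for
maize, Tn floored at Tb and Tx capped at 30 degC before averaging.  Yield
predictors are read off a fixed milestone grid of GDD levels
(150, 300, ..., 1200 degC day by default, i.e. eight levels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UPPER_CAP_C = 30.0
DEFAULT_LEVELS = tuple(float(v) for v in range(150, 1201, 150))


@dataclass(frozen=True)
class GddParams:
    """Base temperature, upper cap and accumulation origin for one crop.

    ``accumulation_origin`` is a (month, day) pair; accumulation starts on
    that date of the harvest year.  Default 1 January.
    """

    base_temperature: float
    upper_cap: float = UPPER_CAP_C
    accumulation_origin: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if self.upper_cap <= self.base_temperature:
            raise ValueError(
                f"upper_cap ({self.upper_cap}) must exceed base temperature "
                f"({self.base_temperature})"
            )


#: base temperatures of the three target crops (degC)
CROP_BASE_TEMPERATURE = {
    "winter wheat": 5.0,
    "winter rapeseed": 5.0,
    "maize": 10.0,
}


@dataclass(frozen=True)
class MilestoneGrid:
    """Ordered GDD levels (degC day) at which predictors are sampled."""

    levels: tuple[float, ...] = DEFAULT_LEVELS

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        if lv.ndim != 1 or len(lv) == 0:
            raise ValueError("levels must be a non-empty 1-d sequence")
        if not np.all(np.diff(lv) > 0):
            raise ValueError("levels must be strictly increasing")

    def __len__(self) -> int:
        return len(self.levels)

    def __iter__(self):
        return iter(self.levels)


@dataclass
class ThermalTimeSeries:
    """Cumulative GDD per calendar day for one unit and crop.

    ``gdd`` is indexed by day (DatetimeIndex, daily, gap free) and is
    non-decreasing; the value on a day includes that day's increment.
    """

    unit_id: str
    crop: str
    gdd: pd.Series

    def __post_init__(self) -> None:
        if not self.gdd.index.is_monotonic_increasing:
            raise ValueError("thermal time index must be sorted by date")

    @property
    def max_gdd(self) -> float:
        return float(self.gdd.iloc[-1]) if len(self.gdd) else 0.0


def daily_gdd_increment(t_max, t_min, params: GddParams):
    """Daily GDD increment (degC day) from max/min air temperature.

    Accepts scalars or arrays.  Tn is floored at the base temperature and
    Tx is capped at ``params.upper_cap`` before averaging; days whose capped
    mean falls below the base contribute zero.
    """
    t_max = np.asarray(t_max, dtype=float)
    t_min = np.asarray(t_min, dtype=float)
    if np.any(t_max < t_min):
        raise ValueError("t_max < t_min encountered")
    tx = np.minimum(t_max, params.upper_cap)
    tn = np.maximum(t_min, params.base_temperature)
    inc = np.maximum(0.0, (tx + tn) / 2.0 - params.base_temperature)
    return float(inc) if inc.ndim == 0 else inc


def accumulate_gdd(
    weather: pd.DataFrame,
    params: GddParams,
    *,
    unit_id: str = "",
    crop: str = "",
) -> ThermalTimeSeries:
    """Accumulate daily GDD from the configured origin onwards.

    ``weather`` needs columns ``date``, ``tmax``, ``tmin`` for a single unit
    and year.  Days before the accumulation origin are ignored.  Missing
    calendar days or missing temperatures between origin and the last date
    raise, listing the gaps: thermal time cannot be accumulated across holes.
    """
    df = weather.sort_values("date")
    dates = pd.DatetimeIndex(df["date"])
    if len(dates) == 0:
        raise ValueError("empty weather series")
    year = dates[0].year
    origin = pd.Timestamp(year, *params.accumulation_origin)
    mask = dates >= origin
    df = df.loc[mask.tolist()]
    dates = dates[mask]
    if len(dates) == 0:
        raise ValueError(f"no weather on or after accumulation origin {origin.date()}")
    expected = pd.date_range(dates[0], dates[-1], freq="D")
    missing_days = expected.difference(dates)
    nan_rows = df["tmax"].isna() | df["tmin"].isna()
    if len(missing_days) or nan_rows.any():
        gaps = [str(d.date()) for d in missing_days] + [
            str(pd.Timestamp(d).date()) for d in dates[nan_rows.to_numpy()]
        ]
        raise ValueError(f"missing Tx/Tn for days: {sorted(gaps)}")
    inc = daily_gdd_increment(df["tmax"].to_numpy(), df["tmin"].to_numpy(), params)
    gdd = pd.Series(np.cumsum(inc), index=dates, name="gdd")
    return ThermalTimeSeries(unit_id=unit_id, crop=crop, gdd=gdd)


def milestone_dates(
    tt: ThermalTimeSeries, grid: MilestoneGrid
) -> dict[float, pd.Timestamp | None]:
    """First calendar date on which each milestone level is reached.

    Levels never attained map to ``None``.  Dates are non-decreasing with
    level because cumulative GDD is non-decreasing.
    """
    if len(tt.gdd) == 0:
        raise ValueError("empty thermal-time series")
    values = tt.gdd.to_numpy()
    out: dict[float, pd.Timestamp | None] = {}
    for level in grid:
        idx = int(np.searchsorted(values, level, side="left"))
        out[level] = tt.gdd.index[idx] if idx < len(values) else None
    return out


def resample_to_thermal_time(
    obs: pd.Series, tt: ThermalTimeSeries, grid: MilestoneGrid
) -> dict[float, float]:
    """Resample a dated observation series onto the GDD milestone grid.

    ``obs`` is indexed by date and may contain NaN (cloud gaps).  Each
    observation is placed at the cumulative GDD of its date; values at the
    milestone levels are linear interpolations *in the GDD coordinate*
    between the nearest non-missing observations bracketing the level.  No
    extrapolation: levels outside the observed GDD range, or never attained,
    come back as NaN.
    """
    obs = obs.dropna()
    if len(obs) == 0:
        raise ValueError("all observations missing")
    common = obs.index.intersection(tt.gdd.index)
    obs = obs.loc[common]
    if len(obs) == 0:
        raise ValueError("observations do not overlap the thermal-time span")
    x = tt.gdd.loc[obs.index].to_numpy(dtype=float)
    y = obs.to_numpy(dtype=float)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    max_gdd = tt.max_gdd
    out: dict[float, float] = {}
    for level in grid:
        if level > max_gdd or level < x[0] or level > x[-1]:
            out[level] = float("nan")
        else:
            out[level] = float(np.interp(level, x, y))
    return out
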