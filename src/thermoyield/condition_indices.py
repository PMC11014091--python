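"""Kogan condition indices (VCI/TCI) on the thermal-time grid.

The Vegetation Condition Index scales the current NDVI against the
multi-year minimum and maximum observed *at the same GDD level*:

    VCI = 100 * (NDVI - NDVI_min) / (NDVI_max - NDVI_min)

and the Temperature Condition Index inverts the scale for LST (hot = bad):

    TCI = 100 * (LST_max - LST) / (LST_max - LST_min)

Envelopes are built from reference years only, so a forecast year never
contributes to its own denominators.  Out-of-envelope values are clamped to
[0, 100] (a record year beats the historical extremes); a degenerate
envelope (max == min) yields a missing index rather than a fabricated one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_REFERENCE_YEARS = 2


@dataclass
class ClimatologyEnvelope:
    """Per-level min/max of NDVI and LST over the reference years.

    ``ndvi`` and ``lst`` are DataFrames indexed by GDD level with columns
    ``min`` and ``max``; rows where fewer than two reference years had data
    are NaN.
    """

    unit_id: str
    ndvi: pd.DataFrame
    lst: pd.DataFrame
    reference_years: tuple[int, ...]


def _minmax(values_by_year: pd.DataFrame) -> pd.DataFrame:
    """Element-wise min/max over years; NaN where < 2 years observed."""
    counts = values_by_year.notna().sum(axis=0)
    env = pd.DataFrame(
        {"min": values_by_year.min(axis=0), "max": values_by_year.max(axis=0)}
    )
    env.loc[counts < MIN_REFERENCE_YEARS] = np.nan
    return env


def build_envelope(
    ndvi_by_year: pd.DataFrame,
    lst_by_year: pd.DataFrame,
    *,
    unit_id: str = "",
) -> ClimatologyEnvelope:
    """Build the reference envelope from resampled per-year values.

    Both inputs are DataFrames with reference years as the index and GDD
    levels as columns (NaN where a level was unattained or cloud-hidden).
    """
    if len(ndvi_by_year) == 0 or len(lst_by_year) == 0:
        raise ValueError("no reference years supplied")
    return ClimatologyEnvelope(
        unit_id=unit_id,
        ndvi=_minmax(ndvi_by_year),
        lst=_minmax(lst_by_year),
        reference_years=tuple(int(y) for y in ndvi_by_year.index),
    )


def vci(ndvi, env_min, env_max):
    """Vegetation Condition Index in [0, 100]; NaN for degenerate envelopes."""
    ndvi = np.asarray(ndvi, dtype=float)
    env_min = np.asarray(env_min, dtype=float)
    env_max = np.asarray(env_max, dtype=float)
    span = env_max - env_min
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = 100.0 * (ndvi - env_min) / span
    out = np.where(span > 0, np.clip(raw, 0.0, 100.0), np.nan)
    return float(out) if out.ndim == 0 else out


def tci(lst, env_min, env_max):
    """Temperature Condition Index in [0, 100]; cool years score high."""
    lst = np.asarray(lst, dtype=float)
    env_min = np.asarray(env_min, dtype=float)
    env_max = np.asarray(env_max, dtype=float)
    span = env_max - env_min
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = 100.0 * (env_max - lst) / span
    out = np.where(span > 0, np.clip(raw, 0.0, 100.0), np.nan)
    return float(out) if out.ndim == 0 else out
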