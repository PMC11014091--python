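"""Synthetic study generator: geometry, weather, vegetation, labels, yields.

Everything the forecasting pipeline consumes can be generated here from a
known generative model, so every downstream stage is testable without any
satellite archive:

* a rectangular administrative tiling with jittered (non-integer) boundaries
  over a pixel grid, plus an arable-fraction raster;
* daily per-unit weather from a sinusoidal annual cycle with unit offsets,
  year effects and AR(1) day-to-day noise;
* daily NDVI/LST observations whose phenology is a double logistic in
  cumulative GDD (so thermal-time resampling has real signal), with
  independent cloud gaps;
* a two-orbit crop-classification fixture covering every branch of the
  overlap-resolution rule, with configured unsown segments;
* yields from a known linear model on scaled predictors plus Gaussian noise,
  so the forecasting loop's skill and selected features can be checked
  against ground truth.

All randomness flows from a single seed; per-unit sub-streams keep unit
series reproducible when ``n_units`` changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping

from .crop_mask_fusion import CROP_LEGEND, NO_CROP
from .thermal_time import CROP_BASE_TEMPERATURE, GddParams, accumulate_gdd

# ---------------------------------------------------------------------------
# configuration

#: generative yield model: dt/ha of yield per unit of scaled predictor.
#: Mid-season thermal stress condition and early-season deep soil moisture
#: are classic drought-limited-yield drivers.
DEFAULT_YIELD_COEFFICIENTS = {"TCI_gdd600": 0.8, "sm_7_28_gdd300": 0.5}

#: double-logistic phenology in thermal time, per crop:
#: (green-up midpoint, green-up rate, senescence midpoint, senescence rate)
#: in degC day, plus winter/bare background NDVI and mean peak NDVI.
CROP_PHENOLOGY = {
    "winter wheat": dict(onset=250.0, rate_on=80.0, offset=1000.0, rate_off=120.0),
    "winter rapeseed": dict(onset=220.0, rate_on=80.0, offset=950.0, rate_off=120.0),
    "maize": dict(onset=150.0, rate_on=70.0, offset=1100.0, rate_off=140.0),
}
NDVI_BACKGROUND = 0.15
NDVI_PEAK_MEAN = 0.78
NDVI_PEAK_SD = 0.05
NDVI_NOISE_SD = 0.05
LST_OFFSET_C = 8.0  # bare-soil LST excess over air temperature
LST_NDVI_SLOPE = 10.0  # degC of evaporative cooling per unit NDVI
LST_NOISE_SD = 1.5

BASELINE_YIELD_RANGE = (30.0, 90.0)  # dt/ha


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic run."""

    n_units: int = 30
    years: tuple[int, ...] = (2018, 2019, 2020, 2021, 2022)
    grid_shape: tuple[int, int] = (24, 24)
    cloud_prob: float = 0.3
    crop: str = "winter wheat"
    yield_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_YIELD_COEFFICIENTS)
    )
    yield_noise_sd: float = 0.1  # dt/ha; ~signal sd / 3 under the defaults
    n_segments: int = 40
    n_unsown_segments: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        years = tuple(int(y) for y in self.years)
        if list(years) != sorted(years) or len(years) < 3:
            raise ValueError("years must be sorted ascending with length >= 3")
        self.years = years
        if not 0.0 <= self.cloud_prob <= 1.0:
            raise ValueError("cloud_prob must be in [0, 1]")
        if self.yield_noise_sd < 0:
            raise ValueError("yield_noise_sd must be >= 0")
        if self.crop not in CROP_BASE_TEMPERATURE:
            raise ValueError(f"unknown crop {self.crop!r}")

    def gdd_params(self) -> GddParams:
        return GddParams(base_temperature=CROP_BASE_TEMPERATURE[self.crop])


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline should recover."""

    true_coefficients: dict[str, float]
    baseline_yields: pd.Series  # dt/ha per unit
    unsown_segment_ids: frozenset[str] = frozenset()


def _rng(config: SyntheticConfig, stream: int, member: int = 0) -> np.random.Generator:
    """Deterministic sub-stream: one root seed, keyed by purpose and unit."""
    return np.random.default_rng([config.seed, stream, member])


def unit_ids(config: SyntheticConfig) -> list[str]:
    return [f"unit{i:03d}" for i in range(config.n_units)]


# ---------------------------------------------------------------------------
# geometry


@dataclass
class AdminGrid:
    """Unit polygons over the pixel grid plus the arable-fraction raster."""

    units: dict[str, Polygon]
    arable: np.ndarray
    coverage: dict[str, np.ndarray]  # per-unit pixel coverage fractions
    grid_shape: tuple[int, int]


def _tile_counts(n_units: int) -> tuple[int, int]:
    """Near-square factorisation n_units = nr * nc with nr <= nc."""
    nr = int(np.floor(np.sqrt(n_units)))
    while n_units % nr:
        nr -= 1
    return nr, n_units // nr


def generate_admin_grid(config: SyntheticConfig) -> AdminGrid:
    """Rectangular unit tiling with jittered boundaries + arable raster.

    Interior tile boundaries fall at non-integer pixel coordinates, so
    boundary pixels have fractional unit coverage; the unit polygons
    partition the grid exactly.  Arable fractions are uniform in [0, 1]
    (they span both sides of the 30 % screening threshold).
    """
    nrows, ncols = config.grid_shape
    nr, nc = _tile_counts(config.n_units)
    if nrows < 2 * nr or ncols < 2 * nc:
        raise ValueError(
            f"grid {config.grid_shape} too small for {config.n_units} units "
            f"({nr}x{nc} tiling needs >= {2 * nr}x{2 * nc} pixels)"
        )
    rng = _rng(config, stream=1)
    # jittered cut positions, clear of the outer edge by >= 1 pixel
    ys = np.concatenate(
        [[0.0], np.linspace(0, nrows, nr + 1)[1:-1] + rng.uniform(-0.4, 0.4, nr - 1), [float(nrows)]]
    )
    xs = np.concatenate(
        [[0.0], np.linspace(0, ncols, nc + 1)[1:-1] + rng.uniform(-0.4, 0.4, nc - 1), [float(ncols)]]
    )
    units: dict[str, Polygon] = {}
    ids = unit_ids(config)
    k = 0
    for i in range(nr):
        for j in range(nc):
            units[ids[k]] = Polygon(
                [
                    (xs[j], ys[i]),
                    (xs[j + 1], ys[i]),
                    (xs[j + 1], ys[i + 1]),
                    (xs[j], ys[i + 1]),
                ]
            )
            k += 1
    arable = rng.uniform(0.0, 1.0, size=(nrows, ncols))
    from .spatial_aggregation import pixel_coverage_fractions

    coverage = {
        uid: pixel_coverage_fractions(poly, (nrows, ncols))
        for uid, poly in units.items()
    }
    return AdminGrid(
        units=units, arable=arable, coverage=coverage, grid_shape=(nrows, ncols)
    )


# ---------------------------------------------------------------------------
# weather

_T_MEAN_ANNUAL = 9.0  # degC, continental east-European plain
_T_AMPLITUDE = 12.0
_T_PHASE_DOY = 110.0  # warmest day ~ doy 201
_UNIT_OFFSET_SD = 3.0  # country-scale north-south climate spread
_YEAR_OFFSET_SD = 0.8
_AR1_RHO = 0.6
_AR1_SD = 2.0


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    eps = rng.normal(0.0, sd * np.sqrt(1 - rho**2), size=n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        out[t] = rho * out[t - 1] + eps[t]
    return out


def generate_weather(config: SyntheticConfig) -> pd.DataFrame:
    """Daily weather per unit: temperatures, precipitation, radiation, soil moisture.

    Columns: unit_id, date, tmax, tmin, tmean, precip, radiation, sm_0_7,
    sm_7_28.  Tmean follows a sinusoidal annual cycle plus a fixed unit
    offset, a yearly anomaly and AR(1) noise; Tx/Tn straddle it by a random
    positive half-range, so Tx >= Tn by construction.
    """
    frames = []
    for ui, uid in enumerate(unit_ids(config)):
        rng = _rng(config, stream=2, member=ui)
        unit_offset = rng.normal(0.0, _UNIT_OFFSET_SD)
        for year in config.years:
            dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
            n = len(dates)
            doy = dates.dayofyear.to_numpy(dtype=float)
            season = np.sin(2 * np.pi * (doy - _T_PHASE_DOY) / 365.25)
            tmean = (
                _T_MEAN_ANNUAL
                + _T_AMPLITUDE * season
                + unit_offset
                + rng.normal(0.0, _YEAR_OFFSET_SD)
                + _ar1(rng, n, _AR1_RHO, _AR1_SD)
            )
            half_range = 4.0 + np.abs(rng.normal(0.0, 1.0, size=n))
            wet = rng.random(n) < 0.35
            precip = np.where(wet, rng.gamma(1.2, 4.0, size=n), 0.0)
            radiation = np.maximum(
                0.0, 12.0 + 10.0 * season + rng.normal(0.0, 2.0, size=n)
            )
            sm_0_7 = np.clip(0.30 + _ar1(rng, n, 0.85, 0.04), 0.0, 1.0)
            sm_7_28 = np.clip(0.32 + _ar1(rng, n, 0.80, 0.05), 0.0, 1.0)
            frames.append(
                pd.DataFrame(
                    {
                        "unit_id": uid,
                        "date": dates,
                        "tmax": tmean + half_range,
                        "tmin": tmean - half_range,
                        "tmean": tmean,
                        "precip": precip,
                        "radiation": radiation,
                        "sm_0_7": sm_0_7,
                        "sm_7_28": sm_7_28,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# vegetation


def double_logistic(gdd, onset, rate_on, offset, rate_off):
    """Canonical two-sigmoid greenness curve in thermal time, in [0, 1]."""
    g = np.asarray(gdd, dtype=float)
    up = 1.0 / (1.0 + np.exp(-(g - onset) / rate_on))
    down = 1.0 / (1.0 + np.exp((g - offset) / rate_off))
    return up * down


def generate_vegetation(
    weather: pd.DataFrame, config: SyntheticConfig
) -> pd.DataFrame:
    """Daily NDVI/LST observations per unit, with independent cloud gaps.

    NDVI follows the crop's double-logistic curve of cumulative GDD with a
    year-specific peak amplitude plus observation noise; LST is air
    temperature plus a bare-soil offset minus evaporative cooling
    proportional to NDVI.  Each unit-day is cloud-masked (both NDVI and LST
    missing) independently with probability ``cloud_prob``.

    Columns: unit_id, date, ndvi, lst.
    """
    phen = CROP_PHENOLOGY[config.crop]
    params = config.gdd_params()
    frames = []
    for ui, uid in enumerate(unit_ids(config)):
        rng = _rng(config, stream=3, member=ui)
        wu = weather[weather["unit_id"] == uid]
        for year in config.years:
            wy = wu[pd.DatetimeIndex(wu["date"]).year == year]
            tt = accumulate_gdd(wy, params, unit_id=uid, crop=config.crop)
            gdd = tt.gdd.to_numpy()
            n = len(gdd)
            peak = np.clip(rng.normal(NDVI_PEAK_MEAN, NDVI_PEAK_SD), 0.6, 0.95)
            curve = double_logistic(gdd, **phen)
            ndvi_true = NDVI_BACKGROUND + (peak - NDVI_BACKGROUND) * curve
            ndvi = np.clip(ndvi_true + rng.normal(0.0, NDVI_NOISE_SD, n), 0.0, 1.0)
            lst = (
                wy["tmean"].to_numpy()
                + LST_OFFSET_C
                - LST_NDVI_SLOPE * ndvi_true
                + rng.normal(0.0, LST_NOISE_SD, n)
            )
            cloudy = rng.random(n) < config.cloud_prob
            ndvi[cloudy] = np.nan
            lst[cloudy] = np.nan
            frames.append(
                pd.DataFrame(
                    {"unit_id": uid, "date": tt.gdd.index, "ndvi": ndvi, "lst": lst}
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# yields


def make_ground_truth(config: SyntheticConfig) -> GroundTruth:
    """Draw per-unit baseline yields and fix the true coefficient vector."""
    rng = _rng(config, stream=4)
    lo, hi = BASELINE_YIELD_RANGE
    baselines = pd.Series(
        rng.uniform(lo, hi, size=config.n_units), index=unit_ids(config), name="baseline"
    )
    return GroundTruth(
        true_coefficients=dict(config.yield_coefficients),
        baseline_yields=baselines,
    )


def generate_yields(
    predictors: pd.DataFrame, truth: GroundTruth, config: SyntheticConfig
) -> pd.DataFrame:
    """Yields from the known linear model on globally min-max-scaled predictors.

    ``predictors`` is indexed by (unit_id, year).  The generative scaling
    uses the global column min/max (the generator may see everything; only
    the *forecaster* is leakage-constrained).  Output columns: unit_id,
    year, yield_dt_ha, floored at zero.
    """
    missing = [c for c in truth.true_coefficients if c not in predictors.columns]
    if missing:
        raise ValueError(f"coefficient names absent from predictor matrix: {missing}")
    rng = _rng(config, stream=5)
    signal = np.zeros(len(predictors))
    for name, coef in truth.true_coefficients.items():
        col = predictors[name].to_numpy(dtype=float)
        span = np.nanmax(col) - np.nanmin(col)
        scaled = (col - np.nanmin(col)) / span if span > 0 else np.zeros_like(col)
        signal = signal + coef * np.nan_to_num(scaled, nan=0.5)
    noise = rng.normal(0.0, config.yield_noise_sd, size=len(predictors))
    units = predictors.index.get_level_values(0)
    y = truth.baseline_yields.loc[units].to_numpy() + signal + noise
    out = predictors.index.to_frame(index=False)
    out.columns = ["unit_id", "year"]
    out["yield_dt_ha"] = np.maximum(0.0, y)
    return out


def generative_signal_sd(predictors: pd.DataFrame, truth: GroundTruth) -> float:
    """Std dev of the deterministic yield signal; noise sd = this / SNR."""
    signal = np.zeros(len(predictors))
    for name, coef in truth.true_coefficients.items():
        col = predictors[name].to_numpy(dtype=float)
        span = np.nanmax(col) - np.nanmin(col)
        scaled = (col - np.nanmin(col)) / span if span > 0 else np.zeros_like(col)
        signal = signal + coef * np.nan_to_num(scaled, nan=0.5)
    return float(np.std(signal))


# ---------------------------------------------------------------------------
# classification fixture


@dataclass
class ClassificationFixture:
    """Two-orbit segment labels + priors + NDVI series + expected outcome."""

    segments: pd.DataFrame  # segment_id, orbit, label, p
    presence: pd.DataFrame  # crop, q
    ndvi: pd.DataFrame  # segment_id, date, ndvi
    expected_labels: pd.Series  # segment_id -> final label incl. "no crops"
    unsown_segment_ids: frozenset[str]


def _segment_ndvi(
    rng: np.random.Generator, config: SyntheticConfig, sown: bool
) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Season of daily NDVI for one segment: crop curve or bare-field floor."""
    year = config.years[-1]
    dates = pd.date_range(f"{year}-04-01", f"{year}-09-30", freq="D")
    if sown:
        # nominal thermal time: enough GDD by mid-May for a green canopy
        gdd = np.cumsum(np.full(len(dates), 9.0))
        curve = double_logistic(gdd, **CROP_PHENOLOGY[config.crop])
        base = NDVI_BACKGROUND + (NDVI_PEAK_MEAN - NDVI_BACKGROUND) * curve
    else:
        base = np.full(len(dates), NDVI_BACKGROUND + 0.03)
    ndvi = np.clip(base + rng.normal(0.0, NDVI_NOISE_SD, len(dates)), 0.0, 1.0)
    ndvi[rng.random(len(dates)) < config.cloud_prob] = np.nan
    return dates, ndvi


def generate_classification_fixture(config: SyntheticConfig) -> ClassificationFixture:
    """Segments engineered to exercise every overlap-resolution branch.

    The first segments realise, in order: both orbits agreeing; criterion
    (1) (higher p and higher q); criterion (2) keeping the higher-p crop;
    criterion (2) switching to the higher-q crop; the exact dp == dq tie;
    equal p broken by q; a full tie kept on the first orbit; and a
    single-orbit segment.  The remainder are random two-orbit cases.  The
    expected final label of every segment is known by construction, with
    configured unsown segments expected as "no crops".
    """
    rng = _rng(config, stream=6)
    crops = [c for c in CROP_LEGEND if c != NO_CROP]
    # distinct presence priors so any crop pair has a strict q ordering
    qs = np.round(np.linspace(0.15, 0.85, len(crops)), 3)
    presence = pd.DataFrame({"crop": crops, "q": qs})
    q = dict(zip(crops, qs))

    def pair(hi_q: bool):
        a, b = [crops[i] for i in rng.choice(len(crops), size=2, replace=False)]
        if (q[a] > q[b]) != hi_q:
            a, b = b, a
        return a, b  # q[a] > q[b] iff hi_q

    rows, expected = [], {}

    def add(seg, obs, want):
        for orbit, (label, p) in enumerate(obs, start=1):
            rows.append((seg, orbit, label, round(float(p), 4)))
        expected[seg] = want

    # branch-coverage segments
    a, _ = pair(True)
    add("seg000", [(a, 0.8), (a, 0.6)], a)  # orbits agree
    a, b = pair(True)
    add("seg001", [(a, 0.8), (b, 0.5)], a)  # criterion (1)
    a, b = pair(False)  # q[a] < q[b]
    dq = q[b] - q[a]
    add("seg002", [(a, 0.9), (b, 0.9 - (dq + 0.05))], a)  # (2): dp > dq, keep A
    add("seg003", [(a, 0.45 + dq * 0.5), (b, 0.45)], b)  # (2): dp < dq, switch
    # p values equal to the q values make dp == dq bit-exact -> strict rule gives B
    add("seg004", [(a, q[b]), (b, q[a])], b)
    add("seg005", [(a, 0.6), (b, 0.6)], b)  # equal p -> higher q
    add("seg006", [(a, 0.6), (a, 0.6)], a)  # full tie -> first orbit
    a, _ = pair(True)
    add("seg007", [(a, 0.7)], a)  # single orbit

    n_fixed = len(expected)
    for i in range(n_fixed, config.n_segments):
        a, b = pair(bool(rng.integers(2)))
        p_a, p_b = np.round(rng.uniform(0.35, 0.95, size=2), 3)
        if p_a == p_b:
            want = a if q[a] >= q[b] else b
        else:
            hi, lo = (a, b) if p_a > p_b else (b, a)
            dp = abs(p_a - p_b)
            if q[hi] >= q[lo]:
                want = hi
            else:
                want = hi if dp > q[lo] - q[hi] else lo
        add(f"seg{i:03d}", [(a, p_a), (b, p_b)], want)

    seg_ids = sorted(expected)
    # unsown fields drawn from the random segments so the engineered
    # branch-coverage cases keep their overlap-resolution outcome
    pool = seg_ids[n_fixed:] if len(seg_ids) > n_fixed else seg_ids
    unsown = frozenset(
        pool[i]
        for i in rng.choice(
            len(pool), size=min(config.n_unsown_segments, len(pool)), replace=False
        )
    )
    ndvi_rows = []
    for i, seg in enumerate(seg_ids):
        srng = _rng(config, stream=7, member=i)
        dates, vals = _segment_ndvi(srng, config, sown=seg not in unsown)
        ndvi_rows.append(pd.DataFrame({"segment_id": seg, "date": dates, "ndvi": vals}))
        if seg in unsown:
            expected[seg] = NO_CROP

    segments = pd.DataFrame(rows, columns=["segment_id", "orbit", "label", "p"])
    return ClassificationFixture(
        segments=segments,
        presence=presence,
        ndvi=pd.concat(ndvi_rows, ignore_index=True),
        expected_labels=pd.Series(expected, name="label"),
        unsown_segment_ids=unsown,
    )


# ---------------------------------------------------------------------------
# text-format writers


def write_geojson(units: dict[str, Polygon], path) -> None:
    """Unit polygons as a GeoJSON FeatureCollection (grid coordinates)."""
    import json

    features = [
        {
            "type": "Feature",
            "properties": {"unit_id": uid},
            "geometry": mapping(poly),
        }
        for uid, poly in units.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_ascii_grid(arr: np.ndarray, path, nodata: float = -9999.0) -> None:
    """Raster as an ESRI ASCII grid (plain text, unit-spaced pixels)."""
    nrows, ncols = arr.shape
    header = (
        f"ncols {ncols}\nnrows {nrows}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize 1.0\nNODATA_value {nodata}\n"
    )
    body = np.where(np.isnan(arr), nodata, arr)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.6g")
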