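"""Predictor matrix construction and the leakage-safe boosted-tree yield loop.

The forecasting design matrix has one row per (unit, year) and 105 named
columns: thirteen variables -- air temperature min/max/mean, solar radiation
and its accumulation since 1 April, soil moisture at 0-7 and 7-28 cm, daily
and accumulated-since-1-April precipitation, NDVI, VCI, LST and TCI -- read
off at the eight GDD milestone levels, plus the seasonal maximum NDVI.

Yields are modelled as anomalies: the target is the residual of a unit's
yield from its own training-years mean, predicted by an eXtreme Gradient
Boosting ensemble after three training-only preprocessing steps (min-max
scaling to [0, 1], removal of predictor pairs with |Pearson r| > 0.75, and
iterative importance-based feature elimination).  Skill is estimated by
leave-one-year-out cross-validation in which *every* step -- scaling bounds,
correlation pruning, feature selection, the unit baselines and the fit --
is recomputed without the held-out year, so no fold sees its own answer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from xgboost import XGBRegressor

from .condition_indices import build_envelope, tci, vci
from .thermal_time import (
    GddParams,
    MilestoneGrid,
    accumulate_gdd,
    milestone_dates,
    resample_to_thermal_time,
)

CORRELATION_THRESHOLD = 0.75
SEASON_MAX_NDVI = "max_NDVI_season"

#: the thirteen per-level variables, in reporting order
LEVEL_VARIABLES = (
    "tmin",
    "tmax",
    "tmean",
    "radiation",
    "radiation_accum_apr1",
    "sm_0_7",
    "sm_7_28",
    "precip",
    "precip_accum_apr1",
    "NDVI",
    "VCI",
    "LST",
    "TCI",
)

_ACCUM_SOURCE = {"radiation_accum_apr1": "radiation", "precip_accum_apr1": "precip"}
_INSTANT_SOURCE = {
    "tmin": "tmin",
    "tmax": "tmax",
    "tmean": "tmean",
    "radiation": "radiation",
    "sm_0_7": "sm_0_7",
    "sm_7_28": "sm_7_28",
    "precip": "precip",
}


def predictor_names(grid: MilestoneGrid) -> list[str]:
    """The full predictor vocabulary for a milestone grid."""
    names = [f"{v}_gdd{int(lv)}" for v in LEVEL_VARIABLES for lv in grid]
    return names + [SEASON_MAX_NDVI]


@dataclass
class BoostParams:
    """Fixed gradient-boosting hyperparameters (shallow, heavily shrunk)."""

    n_estimators: int = 100
    max_depth: int = 3
    learning_rate: float = 0.1

    def regressor(self, seed: int) -> XGBRegressor:
        return XGBRegressor(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            objective="reg:squarederror",
            importance_type="total_gain",
            tree_method="hist",
            max_bin=64,  # ample for r <= a few hundred rows, halves fit cost
            n_jobs=1,
            random_state=seed,
            verbosity=0,
        )


# ---------------------------------------------------------------------------
# matrix construction


def build_predictor_matrix(
    weather: pd.DataFrame,
    vegetation: pd.DataFrame,
    params: GddParams,
    grid: MilestoneGrid | None = None,
    *,
    reference_years: list[int] | None = None,
) -> pd.DataFrame:
    """Assemble the (unit, year) x predictors matrix from daily inputs.

    Weather variables are read on the first day each GDD level is attained;
    the two accumulation columns sum daily values from 1 April up to and
    including that day.  NDVI and LST are resampled to thermal time (linear
    in GDD across cloud gaps); VCI/TCI scale them against the per-unit
    envelope built over ``reference_years`` (default: all years present).
    Unattained levels yield NaN.  Rows with no attained milestone at all are
    dropped with a warning.
    """
    grid = grid or MilestoneGrid()
    weather = weather.copy()
    weather["year"] = pd.DatetimeIndex(weather["date"]).year
    vegetation = vegetation.copy()
    vegetation["year"] = pd.DatetimeIndex(vegetation["date"]).year
    years = sorted(weather["year"].unique())
    reference_years = list(reference_years) if reference_years else years

    rows: dict[tuple[str, int], dict[str, float]] = {}
    resampled: dict[str, dict[int, dict[str, dict[float, float]]]] = {}
    for uid, wu in weather.groupby("unit_id", sort=True):
        vu = vegetation[vegetation["unit_id"] == uid]
        resampled[uid] = {}
        for year in years:
            wy = wu[wu["year"] == year].sort_values("date")
            vy = vu[vu["year"] == year].sort_values("date")
            if len(wy) == 0:
                continue
            tt = accumulate_gdd(wy, params, unit_id=uid)
            mdates = milestone_dates(tt, grid)
            wy_idx = wy.set_index(pd.DatetimeIndex(wy["date"]))
            apr1 = pd.Timestamp(year, 4, 1)
            row: dict[str, float] = {}
            for var in LEVEL_VARIABLES:
                for lv in grid:
                    name = f"{var}_gdd{int(lv)}"
                    d = mdates[lv]
                    if var in _INSTANT_SOURCE:
                        row[name] = (
                            float(wy_idx.loc[d, _INSTANT_SOURCE[var]])
                            if d is not None
                            else np.nan
                        )
                    elif var in _ACCUM_SOURCE:
                        if d is None:
                            row[name] = np.nan
                        else:
                            sel = wy_idx.loc[
                                (wy_idx.index >= apr1) & (wy_idx.index <= d),
                                _ACCUM_SOURCE[var],
                            ]
                            row[name] = float(sel.sum())
            sat: dict[str, dict[float, float]] = {}
            if len(vy) and vy["ndvi"].notna().any():
                ndvi_obs = pd.Series(
                    vy["ndvi"].to_numpy(), index=pd.DatetimeIndex(vy["date"])
                )
                lst_obs = pd.Series(
                    vy["lst"].to_numpy(), index=pd.DatetimeIndex(vy["date"])
                )
                sat["NDVI"] = resample_to_thermal_time(ndvi_obs, tt, grid)
                sat["LST"] = resample_to_thermal_time(lst_obs, tt, grid)
                row[SEASON_MAX_NDVI] = float(ndvi_obs.max())
            else:
                sat["NDVI"] = {lv: np.nan for lv in grid}
                sat["LST"] = {lv: np.nan for lv in grid}
                row[SEASON_MAX_NDVI] = np.nan
            for lv in grid:
                row[f"NDVI_gdd{int(lv)}"] = sat["NDVI"][lv]
                row[f"LST_gdd{int(lv)}"] = sat["LST"][lv]
            resampled[uid][year] = sat
            rows[(uid, year)] = row

    # condition indices against the reference-period envelope
    for uid, by_year in resampled.items():
        ref = [y for y in reference_years if y in by_year]
        if not ref:
            continue
        ndvi_by_year = pd.DataFrame(
            {lv: [by_year[y]["NDVI"][lv] for y in ref] for lv in grid}, index=ref
        )
        lst_by_year = pd.DataFrame(
            {lv: [by_year[y]["LST"][lv] for y in ref] for lv in grid}, index=ref
        )
        env = build_envelope(ndvi_by_year, lst_by_year, unit_id=uid)
        for year, sat in by_year.items():
            for lv in grid:
                rows[(uid, year)][f"VCI_gdd{int(lv)}"] = vci(
                    sat["NDVI"][lv], env.ndvi.loc[lv, "min"], env.ndvi.loc[lv, "max"]
                )
                rows[(uid, year)][f"TCI_gdd{int(lv)}"] = tci(
                    sat["LST"][lv], env.lst.loc[lv, "min"], env.lst.loc[lv, "max"]
                )

    X = pd.DataFrame.from_dict(rows, orient="index")
    X.index = pd.MultiIndex.from_tuples(X.index, names=["unit_id", "year"])
    X = X.reindex(columns=predictor_names(grid)).sort_index()
    empty = X.isna().all(axis=1)
    if empty.any():
        warnings.warn(
            f"dropping {int(empty.sum())} unit-year rows with no attained milestone"
        )
        X = X[~empty]
    return X


# ---------------------------------------------------------------------------
# training-only preprocessing


def scale_predictors(
    X: pd.DataFrame, train_index: pd.Index
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Min-max scale every column to [0, 1] using training rows only.

    Held-out values are clipped into [0, 1].  Columns constant (or entirely
    missing) on the training rows carry no trainable information and are
    dropped with a warning.  Returns the scaled matrix and the bounds table
    (columns ``min``/``max``).
    """
    train = X.loc[train_index]
    lo, hi = train.min(axis=0), train.max(axis=0)
    span = hi - lo
    constant = span.isna() | (span <= 0)
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant/empty predictor columns"
        )
    keep = X.columns[~constant.to_numpy()]
    scaled = (X[keep] - lo[keep]) / span[keep]
    scaled = scaled.clip(lower=0.0, upper=1.0)
    bounds = pd.DataFrame({"min": lo[keep], "max": hi[keep]})
    return scaled, bounds


def impute_missing(X: pd.DataFrame, train_index: pd.Index) -> pd.DataFrame:
    """Fill missing cells with the training-rows column median.

    Cold years leave high milestones unattained; dropping whole rows would
    discard most of an already tiny sample, so cells are imputed instead.
    """
    med = X.loc[train_index].median(axis=0)
    return X.fillna(med)


def drop_correlated(
    X: pd.DataFrame, threshold: float = CORRELATION_THRESHOLD
) -> pd.DataFrame:
    """Greedily remove columns until no pair has |Pearson r| > threshold.

    Strictly above: a pair at exactly the threshold survives.  At each step
    the most-correlated offending pair is located and its member with the
    higher mean absolute correlation to the remaining columns is removed
    (the findCorrelation scheme); ties drop the later column, a stable
    preference for earlier columns.
    """
    if len(X) < 3:
        raise ValueError("need >= 3 rows to estimate correlations")
    corr = X.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)
    alive = np.ones(len(X.columns), dtype=bool)
    while True:
        sub = corr[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() <= threshold:
            break
        idx_alive = np.flatnonzero(alive)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)  # earliest max pair
        means = sub.mean(axis=1)
        if means[i] > means[j]:
            drop = i
        elif means[j] > means[i]:
            drop = j
        else:
            drop = max(i, j)  # tie -> later column loses
        alive[idx_alive[drop]] = False
    return X.loc[:, X.columns[alive]]


def select_features(
    X: pd.DataFrame,
    y: pd.Series,
    k: int,
    *,
    seed: int = 0,
    boost: BoostParams | None = None,
) -> list[str]:
    """Recursive importance-based elimination down to ``k`` features.

    Repeatedly fits the boosted ensemble and removes the lowest-importance
    features (total gain) until ``k`` remain.  Features the ensemble never
    splits on (zero gain) are removed together, since unused columns do not
    influence the deterministic fit; among used features the bottom 10 % of
    the remaining set (at least one) go per iteration -- the usual recursive
    feature elimination step schedule.  ``k >=`` column count returns all
    columns.
    """
    boost = boost or BoostParams()
    cols = list(X.columns)
    if k >= len(cols):
        return cols
    if k < 1:
        raise ValueError("k must be >= 1")
    while len(cols) > k:
        model = boost.regressor(seed)
        model.fit(X[cols].to_numpy(), y.to_numpy())
        imp = np.asarray(model.feature_importances_, dtype=float)
        zero = np.flatnonzero(imp == 0)
        if len(zero) and len(cols) - len(zero) >= k:
            cols = [c for i, c in enumerate(cols) if i not in set(zero)]
            continue
        n_drop = min(max(1, int(0.1 * len(cols))), len(cols) - k)
        drop = set(np.argsort(imp, kind="stable")[:n_drop])
        cols = [c for i, c in enumerate(cols) if i not in drop]
    return cols


def compute_residuals(
    y_train: pd.Series,
) -> tuple[pd.Series, pd.Series]:
    """Per-unit mean-anomaly targets from training years only.

    ``y_train`` is indexed by (unit_id, year).  Returns (residuals,
    baselines); units with fewer than two training years are skipped with a
    warning (no meaningful within-unit anomaly).
    """
    counts = y_train.groupby(level="unit_id").size()
    ok_units = counts[counts >= 2].index
    skipped = counts.index.difference(ok_units)
    if len(skipped):
        warnings.warn(f"skipping units with < 2 training years: {list(skipped)}")
    y_ok = y_train[y_train.index.get_level_values("unit_id").isin(ok_units)]
    baselines = y_ok.groupby(level="unit_id").mean()
    residuals = y_ok - baselines.reindex(
        y_ok.index.get_level_values("unit_id")
    ).to_numpy()
    return residuals, baselines


# ---------------------------------------------------------------------------
# evaluation


def metrics(pred, obs) -> dict[str, float]:
    """R2 (squared Pearson correlation), MAE, RMSE and MAPE (%).

    R2 follows the squared-correlation definition; the 1 - SSE/SST variant
    is also returned (``r2_sse``) since the two differ for biased
    predictions.  Observation-zero pairs are excluded from MAPE with a
    warning.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) < 2:
        raise ValueError("need >= 2 prediction/observation pairs")
    err = pred - obs
    out = {
        "mae": float(np.mean(np.abs(err))),
        "rmse": float(np.sqrt(np.mean(err**2))),
    }
    if np.ptp(obs) > 0 and np.ptp(pred) > 0:
        r, _ = stats.pearsonr(pred, obs)
        out["r2"] = float(r**2)
    else:
        out["r2"] = float("nan")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    out["r2_sse"] = float(1.0 - np.sum(err**2) / sst) if sst > 0 else float("nan")
    nz = obs != 0
    if not nz.all():
        warnings.warn(f"excluding {int((~nz).sum())} zero observations from MAPE")
    out["mape"] = (
        float(np.mean(np.abs(err[nz] / obs[nz])) * 100.0) if nz.any() else float("nan")
    )
    return out


@dataclass
class LoocvResult:
    """Held-out predictions, pooled metrics and per-fold selected features."""

    predictions: pd.DataFrame  # unit_id, year, observed, predicted, baseline
    metrics: dict[str, float]
    selected: dict[tuple[str, int], list[str]] = field(default_factory=dict)
    failed_folds: list[int] = field(default_factory=list)


def loocv(
    X: pd.DataFrame,
    y: pd.Series,
    *,
    k: int | None = None,
    seed: int = 0,
    corr_threshold: float = CORRELATION_THRESHOLD,
    boost: BoostParams | None = None,
) -> LoocvResult:
    """Leave-one-year-out cross-validation of the full forecasting chain.

    ``X`` and ``y`` are indexed by (unit_id, year); folds hold out one year
    at a time (with a single unit this is the classic per-region small-n
    design).  Inside each fold the scaling bounds, median imputation,
    correlation pruning, feature selection, per-unit baselines and the model
    fit are all recomputed from the training years alone.  ``k`` defaults to
    ``min(5, n_years - 1)``.  Predictions are floored at zero (a yield).
    """
    X, y = X.align(y, join="inner", axis=0)
    years = sorted(set(X.index.get_level_values("year")))
    if len(years) < 3:
        raise ValueError("need >= 3 years for leave-one-year-out CV")
    if k is None:
        k = min(5, len(years) - 1)
    boost = boost or BoostParams()

    pred_rows = []
    selected: dict[tuple[str, int], list[str]] = {}
    failed: list[int] = []
    for year in years:
        test_mask = X.index.get_level_values("year") == year
        train_idx, test_idx = X.index[~test_mask], X.index[test_mask]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scaled, _ = scale_predictors(X, train_idx)
                scaled = impute_missing(scaled, train_idx)
                pruned = drop_correlated(scaled.loc[train_idx], corr_threshold)
                resid, baselines = compute_residuals(y.loc[train_idx])
            feat = select_features(
                pruned.loc[resid.index], resid, k, seed=seed, boost=boost
            )
            model = boost.regressor(seed)
            model.fit(pruned.loc[resid.index, feat].to_numpy(), resid.to_numpy())
            test_units = test_idx.get_level_values("unit_id")
            known = test_units.isin(baselines.index)
            test_idx = test_idx[known]
            if len(test_idx) == 0:
                raise ValueError("no held-out unit has a training baseline")
            yhat = model.predict(scaled.loc[test_idx, feat].to_numpy())
            base = baselines.reindex(test_idx.get_level_values("unit_id")).to_numpy()
        except Exception as exc:  # noqa: BLE001 - fold isolation is the contract
            warnings.warn(f"fold {year} failed and is excluded: {exc}")
            failed.append(year)
            continue
        for (uid, yr), p, b in zip(test_idx, np.maximum(0.0, yhat + base), base):
            pred_rows.append(
                {
                    "unit_id": uid,
                    "year": yr,
                    "observed": float(y.loc[(uid, yr)]),
                    "predicted": float(p),
                    "baseline": float(b),
                }
            )
            selected[(uid, yr)] = list(feat)
    predictions = pd.DataFrame(pred_rows)
    if len(predictions) < 2:
        raise ValueError("too few successful folds to compute metrics")
    return LoocvResult(
        predictions=predictions,
        metrics=metrics(predictions["predicted"], predictions["observed"]),
        selected=selected,
        failed_folds=failed,
    )
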