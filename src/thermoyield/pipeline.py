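"""End-to-end synthetic study: generate, build predictors, cross-validate.

Thin glue over the stage modules, used by the CLI, the acceptance script and
the recovery tests.  The ground-truth yield model is known, so the run
reports not only CV skill but also how often the true driver predictors were
selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import synthetic_data as synth
from .thermal_time import MilestoneGrid
from .yield_model import LoocvResult, build_predictor_matrix, loocv


@dataclass
class StudyResult:
    """Everything one synthetic forecasting experiment produces."""

    config: synth.SyntheticConfig
    truth: synth.GroundTruth
    predictors: pd.DataFrame
    yields: pd.DataFrame
    cv: LoocvResult

    @property
    def true_feature_selection_rate(self) -> float:
        """Fraction of folds whose selected set contains *all* true drivers."""
        wanted = set(self.truth.true_coefficients)
        hits = [wanted <= set(feat) for feat in self.cv.selected.values()]
        return sum(hits) / len(hits) if hits else float("nan")


def run_synthetic_study(
    config: synth.SyntheticConfig,
    *,
    k: int | None = None,
    snr: float | None = None,
    permute_yields_seed: int | None = None,
) -> StudyResult:
    """Generate a synthetic study and evaluate the forecasting loop on it.

    ``snr``, when given, overrides ``config.yield_noise_sd`` so the noise sd
    equals the generative signal sd divided by ``snr``.  With
    ``permute_yields_seed`` the yield column is randomly permuted across all
    unit-years before modelling -- the null experiment in which any apparent
    skill can only come from leakage.
    """
    weather = synth.generate_weather(config)
    vegetation = synth.generate_vegetation(weather, config)
    X = build_predictor_matrix(
        weather,
        vegetation,
        config.gdd_params(),
        MilestoneGrid(),
        reference_years=list(config.years),
    )
    truth = synth.make_ground_truth(config)
    if snr is not None:
        config.yield_noise_sd = synth.generative_signal_sd(X, truth) / snr
    yields = synth.generate_yields(X, truth, config)
    y = yields.set_index(["unit_id", "year"])["yield_dt_ha"]
    if permute_yields_seed is not None:
        import numpy as np

        rng = np.random.default_rng(permute_yields_seed)
        y = pd.Series(rng.permutation(y.to_numpy()), index=y.index, name=y.name)
        yields = y.rename("yield_dt_ha").reset_index()
    cv = loocv(X, y, k=k, seed=config.seed)
    return StudyResult(
        config=config, truth=truth, predictors=X, yields=yields, cv=cv
    )
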