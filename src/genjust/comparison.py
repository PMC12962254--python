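"""Model-fit comparison against rating data.

Each model's scale-normalized predictions are paired with observed ratings —
by default at the trial level (every participant-trial paired with its
condition's prediction), optionally at the cell level (18 condition means) —
and scored with three fit statistics:

- R^2: the squared Pearson correlation between predictions and observations
  (not 1 - SSE/SST, so badly mis-ordered models get small positive values
  rather than negative ones);
- RMSE: root mean squared residual, in rating-scale units;
- MAE: mean absolute residual.

Cell means for plotting carry 95% confidence intervals corrected with the
Cousineau-Morey method: each participant's grand mean is removed (and the
global grand mean restored) before per-cell variances are computed, and the
variances are inflated by C/(C-1) for C cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inference import STUDY_WITHIN, cell_matrix
from .models import DEFAULT_VALUE_F, MODELS, prediction_table


@dataclass(frozen=True)
class FitStats:
    model: str
    r_squared: float  # NaN when predictions are constant over the pairs
    rmse: float
    mae: float
    n_pairs: int


def cm_ci(matrix: np.ndarray, confidence: float = 0.95) -> np.ndarray:
    """Cousineau-Morey within-subject CI half-widths per cell.

    ``matrix`` is participants x cells.  Participant offsets are removed
    before computing per-cell variances, which are then rescaled by the Morey
    factor C/(C-1); half-widths are t-based with n-1 df.
    """
    Y = np.asarray(matrix, float)
    if Y.ndim != 2 or Y.shape[0] < 2 or Y.shape[1] < 2:
        raise ValueError("need at least 2 participants and 2 cells")
    n, C = Y.shape
    normed = Y - Y.mean(axis=1, keepdims=True) + Y.mean()
    var = normed.var(axis=0, ddof=1) * C / (C - 1)
    tcrit = stats.t.ppf(0.5 + confidence / 2, n - 1)
    return tcrit * np.sqrt(var / n)


def cell_means(trials: pd.DataFrame, confidence: float = 0.95,
               within: tuple[str, ...] = STUDY_WITHIN) -> pd.DataFrame:
    """Per-condition mean rating with Cousineau-Morey CIs (one row per cell)."""
    Y, cells, _ = cell_matrix(trials, "rating", within)
    means = Y.mean(axis=0)
    hw = cm_ci(Y, confidence)
    out = pd.DataFrame(cells, columns=list(within))
    out["mean"] = means
    out["ci_low"] = means - hw
    out["ci_high"] = means + hw
    return out


def _pair(predictions: pd.DataFrame, trials: pd.DataFrame,
          granularity: str) -> tuple[np.ndarray, np.ndarray]:
    key = ["abs_level", "rel_level", "dangerous"]
    pred = predictions.set_index(key)["normalized"]
    if granularity == "trial":
        obs = trials["rating"].to_numpy(float)
        idx = pd.MultiIndex.from_frame(trials[key])
    elif granularity == "cell":
        cm = trials.groupby(key, observed=True)["rating"].mean()
        obs = cm.to_numpy(float)
        idx = cm.index
    else:
        raise ValueError("granularity must be 'trial' or 'cell'")
    try:
        p = pred.loc[idx].to_numpy(float)
    except KeyError as e:
        raise ValueError(f"no prediction for observed condition: {e}") from e
    return p, obs


def fit_stats(predictions: pd.DataFrame, trials: pd.DataFrame,
              granularity: str = "trial") -> FitStats:
    """Score one model's predictions against the data.

    When the paired predictions are constant, the correlation (hence R^2) is
    undefined and reported as NaN; RMSE and MAE are still returned.
    """
    p, obs = _pair(predictions, trials, granularity)
    resid = obs - p
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mae = float(np.mean(np.abs(resid)))
    if np.ptp(p) == 0 or np.ptp(obs) == 0:
        r2 = float("nan")
    else:
        r = float(np.corrcoef(p, obs)[0, 1])
        r2 = r * r
    return FitStats(model=predictions.attrs.get("model", "?"),
                    r_squared=r2, rmse=rmse, mae=mae, n_pairs=len(obs))


def fit_all_models(trials: pd.DataFrame, value_f: float = DEFAULT_VALUE_F,
                   granularity: str = "trial",
                   models: tuple[str, ...] = MODELS) -> list[FitStats]:
    return [fit_stats(prediction_table(m, value_f=value_f), trials, granularity)
            for m in models]


@dataclass
class ModelRanking:
    by_r_squared: list[str]   # best first; NaN R^2 ranks last
    by_rmse: list[str]        # best (smallest) first
    by_mae: list[str]
    best: str | None          # None when the criteria disagree or tie


def rank_models(fits: list[FitStats]) -> ModelRanking:
    """Rank models per criterion; a single best requires dominance on all three."""
    if len(fits) < 2:
        raise ValueError("need at least 2 models to rank")
    by_r2 = sorted(fits, key=lambda f: (-f.r_squared if not math.isnan(f.r_squared)
                                        else math.inf))
    by_rmse = sorted(fits, key=lambda f: f.rmse)
    by_mae = sorted(fits, key=lambda f: f.mae)

    def strictly_first(ranked, attr, reverse):
        a, b = getattr(ranked[0], attr), getattr(ranked[1], attr)
        if math.isnan(a) or math.isnan(b):
            return not math.isnan(a)
        return a > b if reverse else a < b

    best = None
    if (by_r2[0].model == by_rmse[0].model == by_mae[0].model
            and strictly_first(by_r2, "r_squared", reverse=True)
            and strictly_first(by_rmse, "rmse", reverse=False)
            and strictly_first(by_mae, "mae", reverse=False)):
        best = by_r2[0].model
    return ModelRanking(
        by_r_squared=[f.model for f in by_r2],
        by_rmse=[f.model for f in by_rmse],
        by_mae=[f.model for f in by_mae],
        best=best,
    )
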