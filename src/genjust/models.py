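"""The five competing justifiability scoring models.

Each model maps the prevalence pair (P(f|G), P(f|G')) of a feature f in a
target group G and a referent group G' to a raw justifiability score:

- ``absolute``:          P(f|G)                      (absolute reading)
- ``subtraction``:       P(f|G) - P(f|G')            (difference reading)
- ``general_fraction``:  P(f|G) / P(f)               (target vs. pooled prevalence)
- ``specific_fraction``: P(f|G) / P(f|G')            (target vs. referent prevalence)
- ``vrs_hybrid``:        Value(f) * deltaP*          (associative-learning hybrid)

where deltaP* = [P(f|G) - P(f|G')] / [1 - P(f|G')] is the relative-difference
(cue-validity) statistic and Value(f) is an emotional-impact multiplier equal
to 1 for non-dangerous features and > 1 for dangerous ones.  Raw scores are
mapped onto the response scale (-3..+3) by an order-preserving min-max affine
map so that model predictions and ratings are directly comparable.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .design import (
    DANGER_LEVELS,
    RELATIVE_LEVELS,
    ABSOLUTE_LEVELS,
    Condition,
    full_design,
    nominal_prevalences,
)

MODELS = ("absolute", "subtraction", "general_fraction", "specific_fraction",
          "vrs_hybrid")
STATISTICAL_MODELS = MODELS[:4]
DEFAULT_VALUE_F = 1.5
RATING_LO, RATING_HI = -3.0, 3.0


def pooled_prevalence(p_target: float, p_referent: float,
                      weight_target: float = 0.5) -> float:
    """P(f) over both groups combined; equal weights since both samples have n=180."""
    if not 0 < weight_target < 1:
        raise ValueError("weight_target must lie in (0, 1)")
    return weight_target * p_target + (1 - weight_target) * p_referent


def delta_p_star(p_target: float, p_referent: float) -> float:
    """The relative-difference statistic [P(f|G) - P(f|G')] / [1 - P(f|G')]."""
    if p_referent >= 1:
        raise ZeroDivisionError(
            "delta P* undefined: 1 - p_referent is 0 (p_referent = 1)")
    return (p_target - p_referent) / (1 - p_referent)


def predict(model: str, p_target: float, p_referent: float,
            value_f: float | None = None) -> float:
    """Raw justifiability score of one model for one prevalence pair."""
    if not (0 <= p_target <= 1 and 0 <= p_referent <= 1):
        raise ValueError("prevalences must lie in [0, 1]")
    if model == "absolute":
        return p_target
    if model == "subtraction":
        return p_target - p_referent
    if model == "general_fraction":
        pf = pooled_prevalence(p_target, p_referent)
        if pf <= 0:
            raise ZeroDivisionError("general_fraction undefined: pooled P(f) is 0")
        return p_target / pf
    if model == "specific_fraction":
        if p_referent <= 0:
            raise ZeroDivisionError("specific_fraction undefined: p_referent is 0")
        return p_target / p_referent
    if model == "vrs_hybrid":
        if value_f is None:
            raise ValueError("vrs_hybrid requires value_f")
        if value_f < 1:
            raise ValueError("value_f must be >= 1")
        return value_f * delta_p_star(p_target, p_referent)
    raise ValueError(f"unknown model: {model!r}")


def normalize_to_scale(raw: Mapping | pd.Series | np.ndarray | Iterable[float],
                       lo: float = RATING_LO, hi: float = RATING_HI):
    """Min-max affine map sending min(raw) -> lo and max(raw) -> hi.

    Order- and tie-preserving; idempotent on already-normalized input.
    Raises on a degenerate (constant) score set, for which no order-preserving
    map onto the scale exists.
    """
    if isinstance(raw, Mapping):
        keys = list(raw.keys())
        values = np.asarray([raw[k] for k in keys], dtype=float)
        out = normalize_to_scale(values, lo, hi)
        return dict(zip(keys, out))
    values = np.asarray(list(raw) if not isinstance(raw, np.ndarray) else raw,
                        dtype=float)
    mn, mx = values.min(), values.max()
    if mx == mn:
        raise ValueError("cannot normalize a constant score set")
    out = lo + (values - mn) * (hi - lo) / (mx - mn)
    if isinstance(raw, pd.Series):
        return pd.Series(out, index=raw.index)
    return out


def prediction_table(model: str, design: list[Condition] | None = None,
                     value_f: float = DEFAULT_VALUE_F) -> pd.DataFrame:
    """Raw and scale-normalized predictions of one model over the design.

    The four statistical models ignore dangerousness, so their scores are
    normalized over the 9 distinct (absolute, relative) cells and replicated
    across the dangerousness factor.  The hybrid model multiplies dangerous
    cells by Value(f) first and is normalized over all 18 cells.

    Returns a DataFrame with columns abs_level, rel_level, dangerous, raw,
    normalized; ``.attrs["model"]`` records the model name.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model: {model!r}")
    design = full_design() if design is None else design
    rows = []
    for cond in design:
        pt, pr = nominal_prevalences(cond)
        vf = value_f if (model == "vrs_hybrid" and cond.dangerous) else 1.0
        raw = predict(model, pt, pr, value_f=vf if model == "vrs_hybrid" else None)
        rows.append({
            "abs_level": cond.absolute,
            "rel_level": cond.relative,
            "dangerous": int(cond.dangerous),
            "raw": raw,
        })
    df = pd.DataFrame(rows)
    if model in STATISTICAL_MODELS:
        # one normalization over the distinct (abs, rel) scores
        cells = df.drop_duplicates(["abs_level", "rel_level"]).set_index(
            ["abs_level", "rel_level"])["raw"]
        norm = normalize_to_scale(cells)
        df["normalized"] = [
            norm[(a, r)] for a, r in zip(df["abs_level"], df["rel_level"])]
    else:
        df["normalized"] = normalize_to_scale(df["raw"].to_numpy())
    df.attrs["model"] = model
    df.attrs["value_f"] = value_f
    return df
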