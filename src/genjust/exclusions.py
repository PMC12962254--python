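"""Pre-registered outcome-neutral data-quality tests and exclusion logic.

Four tests, each independent of the hypotheses:

1. practice trial rated below the scale midpoint;
2. floor/ceiling: at least 12 of 18 trial ratings in [-3, -2] (floor) or in
   [2, 3] (ceiling);
3. mean response time more than 3 SD from the grand mean of participant mean
   response times (strict inequality; a participant exactly at 3 SD passes);
4. answering "Not at all seriously" to the seriousness question.

A participant failing any test is excluded, unless 40% or more of the cohort
fails at least one test, in which case the quality gate trips: nobody is
excluded and a ``data_quality`` grouping column is carried instead.
Suspicion-based exclusion is a sensitivity re-run, not a primary exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import SERIOUSNESS_LEVELS

QUALITY_GATE = 0.40
FLOOR_CEILING_MIN_TRIALS = 12
RT_SD_LIMIT = 3.0


@dataclass
class ExclusionReport:
    n_total: int
    n_excluded: int
    counts: dict[str, int]                 # per-test failure counts
    quality_gate_tripped: bool
    flags: pd.DataFrame = field(repr=False)  # per-participant boolean flags

    @property
    def exclusion_proportion(self) -> float:
        return self.n_excluded / self.n_total


def test_practice(participants: pd.DataFrame) -> pd.Series:
    """Flag = practice rating strictly below the scale midpoint (0)."""
    return (participants.set_index("participant_id")["practice_rating"] < 0)


def test_floor_ceiling(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant floor and ceiling flags from the 18 trial ratings."""
    def per_participant(r: pd.Series) -> pd.Series:
        return pd.Series({
            "floor": int(((r >= -3) & (r <= -2)).sum()) >= FLOOR_CEILING_MIN_TRIALS,
            "ceiling": int(((r >= 2) & (r <= 3)).sum()) >= FLOOR_CEILING_MIN_TRIALS,
        })
    return trials.groupby("participant_id")["rating"].apply(per_participant).unstack()


def test_rt(trials: pd.DataFrame) -> pd.Series:
    """Flag participants whose mean RT lies outside grand mean +/- 3 SD.

    Computed on participant mean response times over the rating trials; the
    dispersion is the SD (ddof=1) of those participant means.  Strict
    inequality: a mean exactly at the 3-SD bound is not flagged.
    """
    means = trials.groupby("participant_id")["rt"].mean()
    if len(means) < 3:
        raise ValueError("response-time screening needs at least 3 participants")
    sd = means.std(ddof=1)
    if sd == 0:
        raise ValueError("response-time screening undefined: all participant "
                         "mean RTs identical (SD = 0)")
    grand = means.mean()
    return (means - grand).abs() > RT_SD_LIMIT * sd


def test_seriousness(participants: pd.DataFrame) -> pd.Series:
    """Flag only the lowest seriousness category."""
    s = participants.set_index("participant_id")["seriousness"]
    return s == SERIOUSNESS_LEVELS[0]


def suspicion_flags(participants: pd.DataFrame) -> pd.Series:
    cols = ["suspicious_absolute", "suspicious_relative", "suspicious_dangerousness"]
    p = participants.set_index("participant_id")
    return p[cols].astype(bool).any(axis=1)


def apply_exclusions(
    trials: pd.DataFrame,
    participants: pd.DataFrame,
    exclude_suspicious: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionReport]:
    """Run all four tests and apply the 40% quality gate.

    Returns (kept_trials, kept_participants, report).  RT flags are computed
    once on the full cohort, so the operation is idempotent on its own output
    apart from that cohort-relative statistic.  With ``exclude_suspicious``
    the pre-registered sensitivity re-run additionally drops participants who
    guessed a manipulation.
    """
    if participants.empty:
        raise ValueError("empty cohort")
    idx = participants["participant_id"]
    flags = pd.DataFrame(index=pd.Index(idx, name="participant_id"))
    flags["practice_fail"] = test_practice(participants)
    fc = test_floor_ceiling(trials)
    flags["floor"] = fc["floor"].reindex(flags.index).fillna(False).astype(bool)
    flags["ceiling"] = fc["ceiling"].reindex(flags.index).fillna(False).astype(bool)
    flags["rt_outlier"] = (test_rt(trials).reindex(flags.index)
                           .fillna(False).astype(bool))
    flags["not_serious"] = test_seriousness(participants)
    excluded = flags.any(axis=1)

    counts = {c: int(flags[c].sum()) for c in flags.columns}
    gate = (excluded.sum() / len(flags)) >= QUALITY_GATE
    flags["excluded"] = excluded & ~gate

    report = ExclusionReport(
        n_total=len(flags),
        n_excluded=int(excluded.sum()),
        counts=counts,
        quality_gate_tripped=bool(gate),
        flags=flags,
    )
    if gate:
        kept_p = participants.copy()
        kept_p["data_quality"] = excluded.reindex(idx).to_numpy().astype(int)
        kept_t = trials.merge(kept_p[["participant_id", "data_quality"]],
                              on="participant_id")
        return kept_t, kept_p, report

    drop = set(flags.index[flags["excluded"]])
    if exclude_suspicious:
        drop |= set(suspicion_flags(participants).pipe(lambda s: s.index[s]))
    kept_p = participants[~participants["participant_id"].isin(drop)].copy()
    kept_t = trials[~trials["participant_id"].isin(drop)].copy()
    return kept_t, kept_p, report


def kappa(coder_a, coder_b) -> float:
    """Cohen's kappa for two boolean/categorical coding vectors.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    marginal products.  Raises when p_e = 1 (both coders constant and equal
    margins), where kappa is undefined.
    """
    a = np.asarray(coder_a)
    b = np.asarray(coder_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("coders must be equal-length 1-d vectors")
    if len(a) < 2:
        raise ValueError("kappa needs at least 2 items")
    cats = np.unique(np.concatenate([a, b]))
    p_o = float(np.mean(a == b))
    p_e = float(sum(np.mean(a == c) * np.mean(b == c) for c in cats))
    if p_e == 1.0:
        raise ZeroDivisionError("kappa undefined: chance agreement p_e = 1")
    return (p_o - p_e) / (1 - p_e)
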