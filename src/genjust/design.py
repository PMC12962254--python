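"""Experimental design and stimulus construction.

The experiment is a fully within-participants 3 x 3 x 2 factorial: absolute
prevalence of a feature in a target group (low / intermediate / high, nominally
25% / 50% / 75%), relative prevalence of the feature in the target group
compared to a referent group (negative / equal / positive, a 20-percentage-point
offset), and dangerousness of the feature (dangerous / non-dangerous).  Every
participant sees each of the 18 cells exactly once, in fully randomized order,
as a 2 x 2 contingency table over two fictitious alien groups of 180 observed
members each.  The realized counts carry a small amount of jitter so that the
underlying percentage levels are not trivially recognizable.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

ABSOLUTE_LEVELS = ("low", "intermediate", "high")
RELATIVE_LEVELS = ("negative", "equal", "positive")
DANGER_LEVELS = ("non_dangerous", "dangerous")

#: Nominal P(feature | target group) per absolute-prevalence level.
ABSOLUTE_PREVALENCE = {"low": 0.25, "intermediate": 0.50, "high": 0.75}

#: Offset added to the target prevalence to obtain the referent prevalence.
#: "positive relative prevalence" means the target group has the feature MORE
#: often, i.e. the referent sits 20 percentage points BELOW the target.
RELATIVE_OFFSET = {"negative": +0.20, "equal": 0.0, "positive": -0.20}

N_PER_GROUP = 180
DEFAULT_JITTER_PP = 0.03


@dataclass(frozen=True)
class Condition:
    """One cell of the 3(absolute) x 3(relative) x 2(dangerousness) design."""

    absolute: str
    relative: str
    dangerousness: str

    def __post_init__(self) -> None:
        if self.absolute not in ABSOLUTE_LEVELS:
            raise ValueError(f"unknown absolute level: {self.absolute!r}")
        if self.relative not in RELATIVE_LEVELS:
            raise ValueError(f"unknown relative level: {self.relative!r}")
        if self.dangerousness not in DANGER_LEVELS:
            raise ValueError(f"unknown dangerousness level: {self.dangerousness!r}")

    @property
    def dangerous(self) -> bool:
        return self.dangerousness == "dangerous"


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of feature presence/absence in the target and referent samples."""

    n_target_with: int
    n_target_without: int
    n_referent_with: int
    n_referent_without: int

    def __post_init__(self) -> None:
        for v in (self.n_target_with, self.n_target_without,
                  self.n_referent_with, self.n_referent_without):
            if v < 0:
                raise ValueError("contingency counts must be non-negative")

    @property
    def n_target(self) -> int:
        return self.n_target_with + self.n_target_without

    @property
    def n_referent(self) -> int:
        return self.n_referent_with + self.n_referent_without

    @property
    def p_target(self) -> float:
        return self.n_target_with / self.n_target

    @property
    def p_referent(self) -> float:
        return self.n_referent_with / self.n_referent


@dataclass(frozen=True)
class TrialSpec:
    """Everything shown on one trial: names, feature, condition and counts."""

    planet_name: str
    target_name: str
    referent_name: str
    feature: str
    feature_dangerous: bool
    condition: Condition
    table: ContingencyTable
    presentation_index: int  # 1..18


def full_design() -> list[Condition]:
    """The 18 distinct conditions, in canonical (absolute, relative, danger) order."""
    return [Condition(a, r, d)
            for a, r, d in product(ABSOLUTE_LEVELS, RELATIVE_LEVELS, DANGER_LEVELS)]


def nominal_prevalences(condition: Condition) -> tuple[float, float]:
    """Nominal (p_target, p_referent) for a condition.

    The target prevalence is set by the absolute level; the referent prevalence
    is offset by +/- 20 percentage points according to the relative level.
    All nine combinations stay inside [0.05, 0.95].
    """
    p_target = ABSOLUTE_PREVALENCE[condition.absolute]
    p_referent = p_target + RELATIVE_OFFSET[condition.relative]
    return p_target, round(p_referent, 10)


def sample_contingency_table(
    condition: Condition,
    n_per_group: int = N_PER_GROUP,
    jitter_pp: float = DEFAULT_JITTER_PP,
    rng: np.random.Generator | None = None,
) -> ContingencyTable:
    """Draw the realized 2 x 2 table for a condition.

    The with-feature count of each group is drawn uniformly from the integer
    band ``nominal_count +/- round(jitter_pp * n_per_group)``, independently
    per group, so each realized proportion stays within ``jitter_pp`` of its
    nominal value.
    """
    if not 0 <= jitter_pp <= 0.05:
        raise ValueError("jitter_pp must lie in [0, 0.05]")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng() if rng is None else rng

    p_target, p_referent = nominal_prevalences(condition)
    band = int(round(jitter_pp * n_per_group))
    counts = []
    for p in (p_target, p_referent):
        nominal = int(round(p * n_per_group))
        lo, hi = nominal - band, nominal + band
        if lo < 0 or hi > n_per_group:
            raise ValueError(
                f"jitter band [{lo}, {hi}] leaves [0, {n_per_group}] "
                f"for nominal prevalence {p}"
            )
        counts.append(int(rng.integers(lo, hi + 1)))
    return ContingencyTable(
        n_target_with=counts[0],
        n_target_without=n_per_group - counts[0],
        n_referent_with=counts[1],
        n_referent_without=n_per_group - counts[1],
    )


def planet_name(rng: np.random.Generator) -> str:
    """A fictitious planet name: letter, double-digit number, letter (e.g. A-01-C)."""
    letters = string.ascii_uppercase
    a = letters[rng.integers(26)]
    b = letters[rng.integers(26)]
    num = int(rng.integers(100))
    return f"{a}-{num:02d}-{b}"


# Synthetic default pools.  Any 36 name tokens and 9 + 9 feature tokens work;
# real stimulus lists can be injected through generate_session.
DEFAULT_NAME_POOL = (
    "Toabos", "Ackeps", "Blerons", "Criddles", "Drulks", "Eprims",
    "Flurbs", "Grynds", "Hollips", "Ixads", "Jorbins", "Klemps",
    "Lurdocs", "Morlers", "Nexards", "Olfins", "Pradduks", "Quorels",
    "Rensips", "Skarbles", "Trivods", "Ulberds", "Vrossels", "Wimlets",
    "Xarpons", "Yedrils", "Zorbits", "Amtrids", "Beldors", "Cynmals",
    "Dorpexes", "Elquins", "Fandrels", "Gomtrips", "Hyrvads", "Intrels",
)
DEFAULT_DANGEROUS_FEATURES = (
    "spit acid", "carry a deadly virus", "attack intruders",
    "have venomous spines", "hunt in packs at night", "emit toxic fumes",
    "set fires", "lay explosive eggs", "bite unprovoked",
)
DEFAULT_NON_DANGEROUS_FEATURES = (
    "sleep under trees", "hum while walking", "collect round stones",
    "eat blue moss", "braid their fur", "sunbathe at noon",
    "whistle at sunrise", "stack leaves", "paint their shells",
)


def generate_session(
    rng: np.random.Generator,
    name_pool: Sequence[str] = DEFAULT_NAME_POOL,
    dangerous_features: Sequence[str] = DEFAULT_DANGEROUS_FEATURES,
    non_dangerous_features: Sequence[str] = DEFAULT_NON_DANGEROUS_FEATURES,
    n_per_group: int = N_PER_GROUP,
    jitter_pp: float = DEFAULT_JITTER_PP,
) -> list[TrialSpec]:
    """Build one participant session: 18 trials in uniformly random order.

    Each of the 36 group names and each of the 18 features is consumed exactly
    once; planet names are drawn on the fly, re-drawing collisions.
    """
    if len(name_pool) != 36:
        raise ValueError(f"name_pool must have 36 tokens, got {len(name_pool)}")
    if len(dangerous_features) != 9 or len(non_dangerous_features) != 9:
        raise ValueError("feature pools must have 9 dangerous and 9 non-dangerous tokens")

    conditions = full_design()
    order = rng.permutation(len(conditions))
    names = list(rng.permutation(np.asarray(name_pool, dtype=object)))
    feats = {
        "dangerous": list(rng.permutation(np.asarray(dangerous_features, dtype=object))),
        "non_dangerous": list(rng.permutation(np.asarray(non_dangerous_features, dtype=object))),
    }
    planets: set[str] = set()
    trials = []
    for idx, cond_i in enumerate(order, start=1):
        cond = conditions[cond_i]
        planet = planet_name(rng)
        while planet in planets:
            planet = planet_name(rng)
        planets.add(planet)
        trials.append(TrialSpec(
            planet_name=planet,
            target_name=str(names.pop()),
            referent_name=str(names.pop()),
            feature=str(feats[cond.dangerousness].pop()),
            feature_dangerous=cond.dangerous,
            condition=cond,
            table=sample_contingency_table(cond, n_per_group, jitter_pp, rng),
            presentation_index=idx,
        ))
    return trials


def select_stimuli(
    feature_ratings: pd.DataFrame,
    name_associations: pd.DataFrame,
    n_features_per_class: int = 9,
) -> tuple[list[str], list[str], list[str]]:
    """Apply the pilot stimulus-selection filters.

    Parameters
    ----------
    feature_ratings : DataFrame with columns ``feature`` and
        ``mean_dangerousness`` (one row per candidate feature).
    name_associations : DataFrame with columns ``name``, ``exposures`` (how
        many raters saw the name), ``top_kind_associations`` (how many
        associated it with its single most frequent kind) and
        ``total_associations`` (all associations given for the name).

    Returns
    -------
    (dangerous, non_dangerous, names): the ``n_features_per_class`` highest-
    and lowest-rated features and the names surviving both association
    filters.  A name is removed if more than 10% of its viewers associated it
    with one kind, or if more than 50% of all its associations pointed to one
    kind.
    """
    if len(feature_ratings) < 2 * n_features_per_class:
        raise ValueError("need at least "
                         f"{2 * n_features_per_class} candidate features")
    ranked = feature_ratings.sort_values(
        "mean_dangerousness", ascending=False, kind="mergesort")
    dangerous = ranked["feature"].head(n_features_per_class).tolist()
    non_dangerous = ranked["feature"].tail(n_features_per_class).tolist()

    na = name_associations
    abs_prop = na["top_kind_associations"] / na["exposures"]
    rel_prop = na["top_kind_associations"] / na["total_associations"].replace(0, np.nan)
    keep = ~((abs_prop > 0.10) | (rel_prop.fillna(0.0) > 0.50))
    names = na.loc[keep, "name"].tolist()
    if len(names) < 36:
        raise ValueError(
            f"only {len(names)} names survive the association filters; 36 required")
    return dangerous, non_dangerous, names


def session_to_frame(participant_id: str, trials: Sequence[TrialSpec]) -> pd.DataFrame:
    """Serialize one session's stimuli to the tidy CSV schema."""
    rows = []
    for t in trials:
        rows.append({
            "participant_id": participant_id,
            "trial_index": t.presentation_index,
            "planet": t.planet_name,
            "target_name": t.target_name,
            "referent_name": t.referent_name,
            "feature": t.feature,
            "dangerous": int(t.feature_dangerous),
            "abs_level": t.condition.absolute,
            "rel_level": t.condition.relative,
            "n_target_with": t.table.n_target_with,
            "n_target_without": t.table.n_target_without,
            "n_referent_with": t.table.n_referent_with,
            "n_referent_without": t.table.n_referent_without,
        })
    return pd.DataFrame(rows)
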