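"""Synthetic participant cohorts.

Ratings are generated exactly the way the illustrative simulated datasets in
the study protocol were: take a generating model's scale-normalized
prediction for the trial's condition and add Gaussian noise, censoring at the
scale ends (-3, +3).  The response scale has no midpoint, so an exact 0 is
remapped to the nearest representable nonzero value on the side the noise
perturbed towards.

Everything else in a participant record (practice trial, response times,
manipulation checks, dangerousness ratings of the features, humanness
covariate, seriousness answer, suspicion flags) exists so that the
pre-registered exclusion and manipulation-check stages have realistic input.
Designated "bad" participants violate exactly one targeted quality test;
their fractions default to the per-test failure counts observed in the study
(64/244 practice, 6/244 response time, 5/244 seriousness, 28/244 suspicious).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import design as dsg
from .design import Condition, ContingencyTable, TrialSpec, full_design, generate_session
from .models import DEFAULT_VALUE_F, RATING_HI, RATING_LO, prediction_table

#: Rating noise SD on the -3..+3 scale, calibrated by quadrature so that an
#: absolute-model cohort yields a trial-level R^2 of about .66 for the
#: generating model, the magnitude of the study's headline fit.
DEFAULT_NOISE_SD = 1.85

SERIOUSNESS_LEVELS = (
    "Not at all seriously", "Not seriously", "Not particularly seriously",
    "Somewhat seriously", "Seriously", "Very seriously",
)

BAD_KINDS = ("practice_fail", "floor", "ceiling", "rt_outlier", "not_serious",
             "suspicious")

#: Per-test injected failure fractions mirroring the study's achieved sample.
STUDY_BAD_FRACTIONS = {
    "practice_fail": 64 / 244,
    "rt_outlier": 6 / 244,
    "not_serious": 5 / 244,
    "suspicious": 28 / 244,
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort (the study conditions)."""

    n_participants: int = 244
    generating_model: str = "absolute"
    value_f: float = DEFAULT_VALUE_F
    noise_sd: float = DEFAULT_NOISE_SD
    rt_median: float = 6.0       # seconds; log-normal location
    rt_log_sd: float = 0.4
    bad_fractions: dict[str, float] = field(
        default_factory=lambda: dict(STUDY_BAD_FRACTIONS))
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.bad_fractions) - set(BAD_KINDS)
        if unknown:
            raise ValueError(f"unknown bad_fractions keys: {sorted(unknown)}")
        fracs = [self.bad_fractions.get(k, 0.0) for k in BAD_KINDS]
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("bad_fractions must lie in [0,1] and jointly sum to <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class TrialResponse:
    spec: TrialSpec
    rating: float
    rt: float


@dataclass
class ParticipantRecord:
    participant_id: str
    age: int
    gender: str
    practice_rating: float
    trials: list[TrialResponse]
    manip_abs_assignment: str
    manip_rel_assignment: str
    manip_abs_response: float
    manip_rel_response: int
    dangerousness_ratings: dict[str, float]
    humanness: float
    seriousness: str
    suspicion_flags: dict[str, bool]


def _avoid_midpoint(x: float, direction: float) -> float:
    if x == 0.0:
        return float(np.nextafter(0.0, direction if direction != 0 else 1.0))
    return x


def simulate_rating(condition: Condition, model: str,
                    value_f: float = DEFAULT_VALUE_F,
                    noise_sd: float = DEFAULT_NOISE_SD,
                    rng: np.random.Generator | None = None,
                    predictions: pd.DataFrame | None = None) -> float:
    """One noisy rating: normalized model prediction + N(0, noise_sd), censored at +/-3."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    if predictions is None:
        predictions = prediction_table(model, value_f=value_f)
    row = predictions[(predictions["abs_level"] == condition.absolute)
                      & (predictions["rel_level"] == condition.relative)
                      & (predictions["dangerous"] == int(condition.dangerous))]
    mu = float(row["normalized"].iloc[0])
    eps = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
    rating = float(np.clip(mu + eps, RATING_LO, RATING_HI))
    return _avoid_midpoint(rating, np.sign(eps))


def normalized_prediction_vector(model: str, value_f: float = DEFAULT_VALUE_F) -> np.ndarray:
    """Normalized predictions in canonical full_design() cell order (length 18)."""
    pred = prediction_table(model, value_f=value_f)
    order = {(c.absolute, c.relative, int(c.dangerous)): i
             for i, c in enumerate(full_design())}
    out = np.empty(18)
    for _, row in pred.iterrows():
        out[order[(row["abs_level"], row["rel_level"], int(row["dangerous"]))]] = \
            row["normalized"]
    return out


def simulate_rating_matrix(model: str, n_participants: int,
                           noise_sd: float = DEFAULT_NOISE_SD,
                           value_f: float = DEFAULT_VALUE_F,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Vectorized ratings, shape (n_participants, 18) in canonical cell order.

    The fast path behind large simulation studies (model recovery, type-I
    calibration); identical noise model to :func:`simulate_rating`.
    """
    rng = np.random.default_rng() if rng is None else rng
    mu = normalized_prediction_vector(model, value_f)
    eps = rng.normal(0.0, noise_sd, size=(n_participants, 18)) if noise_sd > 0 \
        else np.zeros((n_participants, 18))
    ratings = np.clip(mu[None, :] + eps, RATING_LO, RATING_HI)
    zero = ratings == 0.0
    if zero.any():
        side = np.where(eps[zero] >= 0, 1.0, -1.0)
        ratings[zero] = np.nextafter(0.0, 1.0) * side
    return ratings


def matrix_to_trials_frame(ratings: np.ndarray,
                           participant_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Minimal long trial frame (no stimulus tokens) from a rating matrix."""
    n = ratings.shape[0]
    ids = [f"p{i:04d}" for i in range(n)] if participant_ids is None else list(participant_ids)
    cells = full_design()
    return pd.DataFrame({
        "participant_id": np.repeat(ids, 18),
        "abs_level": np.tile([c.absolute for c in cells], n),
        "rel_level": np.tile([c.relative for c in cells], n),
        "dangerous": np.tile([int(c.dangerous) for c in cells], n),
        "rating": ratings.ravel(),
    })


def _assign_bad(config: CohortConfig) -> list[str | None]:
    """Disjoint bad-participant assignment: first round(frac*n) get each kind."""
    labels: list[str | None] = [None] * config.n_participants
    i = 0
    for kind in BAD_KINDS:
        k = int(round(config.bad_fractions.get(kind, 0.0) * config.n_participants))
        for _ in range(k):
            labels[i] = kind
            i += 1
    return labels


def simulate_cohort(config: CohortConfig) -> list[ParticipantRecord]:
    """Generate a full synthetic cohort, deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    preds = prediction_table(config.generating_model, value_f=config.value_f)
    mu = {(r["abs_level"], r["rel_level"], int(r["dangerous"])): r["normalized"]
          for _, r in preds.iterrows()}
    bad = _assign_bad(config)
    abs_map = {"low": -1.0, "intermediate": 0.0, "high": 1.0}
    rel_map = {"negative": -1, "equal": 0, "positive": 1}
    records = []
    for i in range(config.n_participants):
        kind = bad[i]
        session = generate_session(rng)
        trials = []
        for t in session:
            key = (t.condition.absolute, t.condition.relative, int(t.feature_dangerous))
            if kind == "floor":
                rating = float(rng.uniform(-3.0, -2.0))
            elif kind == "ceiling":
                rating = float(rng.uniform(2.0, 3.0))
            else:
                eps = float(rng.normal(0.0, config.noise_sd))
                rating = float(np.clip(mu[key] + eps, RATING_LO, RATING_HI))
                rating = _avoid_midpoint(rating, np.sign(eps))
            rt = float(rng.lognormal(np.log(config.rt_median), config.rt_log_sd))
            if kind == "rt_outlier":
                rt *= 10.0
            trials.append(TrialResponse(spec=t, rating=rating, rt=rt))

        practice = float(rng.uniform(-3.0, -0.1)) if kind == "practice_fail" \
            else float(rng.uniform(0.5, 3.0))
        abs_assign = dsg.ABSOLUTE_LEVELS[rng.integers(3)]
        rel_assign = dsg.RELATIVE_LEVELS[rng.integers(3)]
        abs_resp = float(np.clip(abs_map[abs_assign] + rng.normal(0.0, 0.8), -3, 3))
        if rng.random() < 0.7:
            rel_resp = rel_map[rel_assign]
        else:
            rel_resp = int(rng.integers(-1, 2))
        feat_ratings = {}
        for t in session:
            base = 3.41 if t.feature_dangerous else 0.67
            feat_ratings[t.feature] = float(np.clip(rng.normal(base, 1.0), 0.0, 4.0))
        humanness = _avoid_midpoint(
            float(np.clip(rng.normal(-0.38, 1.38), -3, 3)), 1.0)
        seriousness = SERIOUSNESS_LEVELS[0] if kind == "not_serious" \
            else SERIOUSNESS_LEVELS[int(rng.integers(3, 6))]
        flags = {"absolute": False, "relative": False, "dangerousness": False}
        if kind == "suspicious":
            flags[("absolute", "relative", "dangerousness")[rng.integers(3)]] = True
        records.append(ParticipantRecord(
            participant_id=f"p{i:04d}",
            age=int(np.clip(round(rng.normal(18.5, 1.1)), 17, 40)),
            gender=("woman", "man", "unspecified")[
                int(rng.choice(3, p=[0.848, 0.148, 0.004]))],
            practice_rating=practice,
            trials=trials,
            manip_abs_assignment=abs_assign,
            manip_rel_assignment=rel_assign,
            manip_abs_response=abs_resp,
            manip_rel_response=rel_resp,
            dangerousness_ratings=feat_ratings,
            humanness=humanness,
            seriousness=seriousness,
            suspicion_flags=flags,
        ))
    return records


# ---------------------------------------------------------------------------
# tidy-frame conversion and CSV round-trip

def trials_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        for tr in r.trials:
            t = tr.spec
            rows.append({
                "participant_id": r.participant_id,
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
                "rating": tr.rating,
                "rt": tr.rt,
            })
    return pd.DataFrame(rows)


def participants_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "participant_id": r.participant_id,
            "age": r.age,
            "gender": r.gender,
            "practice_rating": r.practice_rating,
            "manip_abs_assignment": r.manip_abs_assignment,
            "manip_rel_assignment": r.manip_rel_assignment,
            "manip_abs_response": r.manip_abs_response,
            "manip_rel_response": r.manip_rel_response,
            "humanness": r.humanness,
            "seriousness": r.seriousness,
            "suspicious_absolute": int(r.suspicion_flags["absolute"]),
            "suspicious_relative": int(r.suspicion_flags["relative"]),
            "suspicious_dangerousness": int(r.suspicion_flags["dangerousness"]),
        })
    return pd.DataFrame(rows)


def feature_ratings_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        danger_feats = {t.spec.feature: t.spec.feature_dangerous for t in r.trials}
        for feat, rating in r.dangerousness_ratings.items():
            rows.append({
                "participant_id": r.participant_id,
                "feature": feat,
                "dangerous": int(danger_feats[feat]),
                "rating": rating,
            })
    return pd.DataFrame(rows)


def write_cohort(records: Sequence[ParticipantRecord], outdir: str | Path) -> dict[str, Path]:
    """Write trials / participants / feature-ratings CSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (("trials", trials_frame(records)),
                        ("participants", participants_frame(records)),
                        ("feature_ratings", feature_ratings_frame(records))):
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p
    return paths


def read_cohort(outdir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    outdir = Path(outdir)
    # round_trip parsing so a written cohort is recovered bit-for-bit
    trials = pd.read_csv(outdir / "trials.csv", float_precision="round_trip")
    _validate_midpoint_free(trials["rating"])
    participants = pd.read_csv(outdir / "participants.csv",
                               float_precision="round_trip")
    feats = pd.read_csv(outdir / "feature_ratings.csv",
                        float_precision="round_trip")
    return trials, participants, feats


def _validate_midpoint_free(ratings: pd.Series) -> None:
    if (ratings == 0.0).any():
        raise ValueError(
            "justifiability ratings contain an exact scale midpoint (0), "
            "which the response scale excludes")


def records_from_frames(trials: pd.DataFrame, participants: pd.DataFrame,
                        feature_ratings: pd.DataFrame) -> list[ParticipantRecord]:
    """Rebuild full participant records from the tidy frames (CSV round-trip)."""
    _validate_midpoint_free(trials["rating"])
    records = []
    feats_by_p = dict(tuple(feature_ratings.groupby("participant_id", sort=False)))
    trials_by_p = dict(tuple(trials.groupby("participant_id", sort=False)))
    for _, p in participants.iterrows():
        pid = p["participant_id"]
        tdf = trials_by_p[pid].sort_values("trial_index")
        tr = []
        for _, t in tdf.iterrows():
            cond = Condition(
                t["abs_level"], t["rel_level"],
                "dangerous" if t["dangerous"] else "non_dangerous")
            spec = TrialSpec(
                planet_name=t["planet"], target_name=t["target_name"],
                referent_name=t["referent_name"], feature=t["feature"],
                feature_dangerous=bool(t["dangerous"]), condition=cond,
                table=ContingencyTable(
                    int(t["n_target_with"]), int(t["n_target_without"]),
                    int(t["n_referent_with"]), int(t["n_referent_without"])),
                presentation_index=int(t["trial_index"]))
            tr.append(TrialResponse(spec=spec, rating=float(t["rating"]),
                                    rt=float(t["rt"])))
        fr = feats_by_p[pid]
        records.append(ParticipantRecord(
            participant_id=pid,
            age=int(p["age"]),
            gender=p["gender"],
            practice_rating=float(p["practice_rating"]),
            trials=tr,
            manip_abs_assignment=p["manip_abs_assignment"],
            manip_rel_assignment=p["manip_rel_assignment"],
            manip_abs_response=float(p["manip_abs_response"]),
            manip_rel_response=int(p["manip_rel_response"]),
            dangerousness_ratings=dict(zip(fr["feature"], fr["rating"].astype(float))),
            humanness=float(p["humanness"]),
            seriousness=p["seriousness"],
            suspicion_flags={
                "absolute": bool(p["suspicious_absolute"]),
                "relative": bool(p["suspicious_relative"]),
                "dangerousness": bool(p["suspicious_dangerousness"]),
            }))
    return records
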