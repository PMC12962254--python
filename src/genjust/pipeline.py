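"""End-to-end pipeline: simulate -> exclude -> analyze -> compare -> power.

A :class:`PipelineConfig` (YAML-serializable) plus a seed reproduces a run
byte-for-byte.  Stages execute in the pre-registered order; a run directory
collects the cohort CSVs, the exclusion report, ANOVA/ANCOVA JSON, fit
statistics, figures and a plain-text log.  A run can also start from an
external trial-level dataset, in which case the simulation stage is skipped
and the empirical analysis path is exercised instead.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (CohortConfig, feature_ratings_frame, participants_frame,
                     read_cohort, simulate_cohort, trials_frame)
from .comparison import cell_means, fit_all_models, rank_models
from .exclusions import apply_exclusions
from .inference import paired_t_bonferroni, rm_ancova, rm_anova
from .models import prediction_table
from .plots import cell_means_histogram, prediction_scatter
from .power import achieved_power


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    covariate: bool = True
    suspicion_sensitivity: bool = True
    granularity: str = "trial"
    value_f: float = 1.5
    input_dir: str | None = None   # run from existing cohort CSVs instead

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cohort = CohortConfig(**raw.pop("cohort", {}))
        return cls(cohort=cohort, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _anova_json(res: pd.DataFrame) -> dict:
    return {eff: {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                  for k, v in row.items()}
            for eff, row in res.round(6).to_dict("index").items()}


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute all stages; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"genjust {__version__}", f"seed {config.seed}",
                      f"config {dataclasses.asdict(config)}"]

    # -- stage 1: obtain data -------------------------------------------------
    if config.input_dir is not None:
        trials, participants, feats = read_cohort(config.input_dir)
        log.append(f"loaded external cohort from {config.input_dir} "
                   f"({participants.shape[0]} participants); simulation skipped")
    else:
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        records = simulate_cohort(cohort_cfg)
        trials = trials_frame(records)
        participants = participants_frame(records)
        feats = feature_ratings_frame(records)
        log.append(f"simulated cohort: {len(records)} participants, "
                   f"generating model {cohort_cfg.generating_model}, "
                   f"noise sd {cohort_cfg.noise_sd}")
    trials.to_csv(outdir / "trials.csv", index=False)
    participants.to_csv(outdir / "participants.csv", index=False)
    feats.to_csv(outdir / "feature_ratings.csv", index=False)

    # -- stage 2: outcome-neutral exclusions ----------------------------------
    kept_t, kept_p, report = apply_exclusions(trials, participants)
    for pid, row in report.flags[report.flags.drop(columns="excluded").any(axis=1)].iterrows():
        failed = [c for c in report.counts if row.get(c, False)]
        log.append(f"participant {pid} failed: {', '.join(failed)}")
    log.append(f"exclusions: {report.counts}; excluded {report.n_excluded} of "
               f"{report.n_total}; quality gate tripped: {report.quality_gate_tripped}")
    with open(outdir / "exclusions.json", "w") as fh:
        json.dump({"n_total": report.n_total, "n_excluded": report.n_excluded,
                   "counts": report.counts,
                   "quality_gate_tripped": report.quality_gate_tripped,
                   "final_sample": int(kept_p.shape[0])}, fh, indent=2)
    kept_t.to_csv(outdir / "kept_trials.csv", index=False)

    # -- stage 3: inference ---------------------------------------------------
    analyses = {"full": (kept_t, kept_p)}
    if config.suspicion_sensitivity:
        sus_t, sus_p, _ = apply_exclusions(trials, participants,
                                           exclude_suspicious=True)
        analyses["suspicion_excluded"] = (sus_t, sus_p)
    for name, (t_df, p_df) in analyses.items():
        res = rm_anova(t_df)
        with open(outdir / f"anova_{name}.json", "w") as fh:
            json.dump(_anova_json(res), fh, indent=2)
        log.append(f"ANOVA ({name}): n={res.attrs['n_subjects']}")
        if config.covariate:
            cov = p_df.set_index("participant_id")["humanness"]
            resc = rm_ancova(t_df, cov)
            with open(outdir / f"ancova_{name}.json", "w") as fh:
                json.dump(_anova_json(resc), fh, indent=2)

    # paired t-tests per factor on the full kept sample
    ttests = {}
    for factor in ("abs_level", "rel_level"):
        wide = kept_t.pivot_table(index="participant_id", columns=factor,
                                  values="rating", aggfunc="mean", observed=True)
        ttests[factor] = [dataclasses.asdict(r) for r in paired_t_bonferroni(wide)]
    # dangerousness manipulation check: per-participant mean rated dangerousness
    fr = feats[feats["participant_id"].isin(kept_p["participant_id"])]
    wide_danger = fr.pivot_table(index="participant_id", columns="dangerous",
                                 values="rating", aggfunc="mean", observed=True)
    wide_danger.columns = ["non_dangerous", "dangerous"]
    ttests["dangerousness_check"] = [dataclasses.asdict(r) for r in
                                     paired_t_bonferroni(
                                         wide_danger,
                                         comparisons=[("non_dangerous", "dangerous")])]
    with open(outdir / "ttests.json", "w") as fh:
        json.dump(ttests, fh, indent=2)

    # -- stage 4: model comparison -------------------------------------------
    fits = fit_all_models(kept_t, value_f=config.value_f,
                          granularity=config.granularity)
    pd.DataFrame([dataclasses.asdict(f) for f in fits]).to_csv(
        outdir / "fits.csv", index=False)
    ranking = rank_models(fits)
    log.append(f"model ranking (R^2): {ranking.by_r_squared}; best: {ranking.best}")
    cm = cell_means(kept_t)
    cm.to_csv(outdir / "cell_means.csv", index=False)
    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    cell_means_histogram(cm, title="empirical cell means",
                         path=figdir / "cell_means.png")
    for f in fits:
        preds = prediction_table(f.model, value_f=config.value_f)
        prediction_scatter(preds, kept_t, granularity="cell",
                           path=figdir / f"scatter_{f.model}.png")

    # -- stage 5: sensitivity power ------------------------------------------
    n = int(kept_p["participant_id"].nunique())
    anova_full = rm_anova(kept_t)
    power_out = {}
    for eff, m in (("abs_level", 3), ("rel_level", 3), ("dangerous", 2)):
        eta = float(anova_full.loc[eff, "partial_eta_sq"])
        pr = achieved_power(eta, n=n, m=m)
        power_out[eff] = {"eta_p2": eta, "n": n, "m": m,
                          "power": round(pr.power, 4), "lambda": pr.lam}
    with open(outdir / "power.json", "w") as fh:
        json.dump(power_out, fh, indent=2)
    log.append(f"achieved power: { {k: v['power'] for k, v in power_out.items()} }")

    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return outdir
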