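"""Simulate a synthetic participant cohort and write it to tidy CSVs.

Each participant gets a full randomized session (18 trials, one per design
cell, each with a jittered 2 x 2 contingency table over fictitious alien
groups), ratings generated from a model's normalized predictions plus
Gaussian noise censored at the scale ends, response times, manipulation
checks, a humanness covariate and data-quality fields.
"""

from genjust import CohortConfig, simulate_cohort, write_cohort
from genjust.cohort import trials_frame

config = CohortConfig(n_participants=20, generating_model="absolute",
                      noise_sd=1.85, bad_fractions={}, seed=1)
records = simulate_cohort(config)
paths = write_cohort(records, "scratch/example_cohort")

trials = trials_frame(records)
print(f"{len(records)} participants, {len(trials)} trials")
print("files:", *paths.values())
print("\nfirst participant's first three trials:")
cols = ["trial_index", "planet", "target_name", "feature", "abs_level",
        "rel_level", "dangerous", "n_target_with", "n_referent_with", "rating"]
print(trials.loc[:2, cols].to_string(index=False))
print("\ncell means (should track the absolute model's -3/0/+3 plateaus):")
print(trials.groupby("abs_level")["rating"].mean().round(2).to_string())
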