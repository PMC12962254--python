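"""Apply the four pre-registered outcome-neutral data-quality tests.

The cohort below injects known failure fractions; the report recovers them
per test.  Fewer than 40% of participants fail, so the quality gate stays
open and the flagged participants are excluded.  Cohen's kappa quantifies
agreement between two (here simulated) coders of suspicion responses.
"""

import numpy as np

from genjust import CohortConfig, apply_exclusions, kappa, simulate_cohort
from genjust.cohort import participants_frame, trials_frame

config = CohortConfig(n_participants=100, seed=3,
                      bad_fractions={"practice_fail": 0.20,
                                     "rt_outlier": 0.05, "not_serious": 0.03})
records = simulate_cohort(config)
kept_trials, kept, report = apply_exclusions(trials_frame(records),
                                             participants_frame(records))
print("per-test failure counts:", report.counts)
print(f"excluded {report.n_excluded} of {report.n_total} "
      f"({report.exclusion_proportion:.0%}); "
      f"quality gate tripped: {report.quality_gate_tripped}")
print(f"final sample: {len(kept)} participants")

rng = np.random.default_rng(0)
coder_a = rng.random(100) < 0.2
coder_b = np.where(rng.random(100) < 0.8, coder_a, rng.random(100) < 0.2)
print(f"\nsuspicion coding agreement, Cohen's kappa = {kappa(coder_a, coder_b):.2f}")
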