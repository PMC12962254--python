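# Methods

## The experimental model

The package simulates and analyzes a fully within-participants 3 × 3 × 2
factorial rating study.  On each trial a participant sees a 2 × 2
contingency table giving the number of members of a fictitious target group
and referent group (180 observed members each) that do or do not show a
feature, then rates how justifiable a generic sentence attributing the
feature to the target group is, on a continuous −3…+3 scale with no
midpoint.  The factors are absolute prevalence of the feature in the target
group (nominally 25 / 50 / 75%), relative prevalence (referent group offset
by +20 / 0 / −20 percentage points; "positive" means the target group has
the feature *more* often), and dangerousness of the feature.  Every
participant contributes exactly one trial per cell, in uniformly random
order, with every group name and feature used exactly once per session.

"About 20% more often" is implemented as 20 *percentage points*, not a
ratio: a multiplicative reading would make the low-prevalence/positive cell
(25% vs 5%) incoherent with the rest of the grid, and the additive reading
keeps all nine prevalence pairs inside [0.05, 0.95].

Realized table counts are jittered so the underlying percentage levels are
not trivially recognizable: each group's with-feature count is drawn
uniformly from the integer band nominal ± round(jitter·180), default jitter
0.03 (≤ 0.05 by construction).  The uniform band is a modeling choice — only
the existence and small size of the jitter is fixed by the design — and the
band keeps every realized proportion within the stated tolerance while
leaving the mean unbiased.

## The five rating models

With p = P(f|G), q = P(f|G′): absolute reading p; subtraction p − q; general
fraction p / P(f) with P(f) = (p + q)/2 (equal pooling weights because both
observed samples have n = 180); specific fraction p / q; and the hybrid
Value(f) · ΔP\*, ΔP\* = (p − q)/(1 − q), with Value(f) = 1 for neutral and
1.5 by default for dangerous features (any value > 1 is theoretically
admissible; fits can profile over a grid).

Predictions are mapped onto the response scale by a per-model min–max affine
map.  The four statistical models ignore dangerousness, so they are
normalized over their 9 distinct (absolute, relative) scores and replicated
across the dangerousness factor; the hybrid multiplies dangerous cells by
Value(f) *before* a single normalization over all 18 cells.  Ratios enter
the normalization untransformed (no log), which is what produces the
characteristic single extreme cell of the fraction models (e.g.
specific fraction = 5.0 at 25% vs 5%) and of the hybrid (ΔP\* = −4 at 75%
vs 95%).  Min–max onto the rating scale is one of several defensible affine
rules; it is isolated behind `normalize_to_scale` so an alternative rule is
a one-line change.

## Synthetic cohorts

A simulated rating is the generating model's normalized prediction plus
Gaussian noise, censored at ±3; an exact 0 (the excluded scale midpoint) is
remapped to the nearest representable nonzero value on the side the noise
pushed towards.  The noise SD defaults to **1.85**, calibrated by quadrature
(exact censored-Gaussian moments, no simulation) so that a cohort generated
from the absolute-prevalence model yields a trial-level R² of ≈ .66 for its
generating model — the magnitude of the empirical headline fit this class of
study reports.  Under the same quadrature, σ = 1.0 would give R² = .89 and
σ = 2.25 would give R² = .56.

The rest of a participant record exists to exercise the exclusion and
manipulation-check stages with realistic input, and makes no behavioral
claims: response times are log-normal (median 6 s, log-SD 0.4); the
absolute-prevalence manipulation check maps the assigned level to −1/0/+1 on
its estimate scale plus N(0, 0.8) noise; the relative check is answered
correctly with probability 0.7, otherwise uniformly; dangerousness ratings
of the 9 dangerous vs 9 neutral features are drawn around 3.41 vs 0.67 on
the 0–4 scale; the humanness covariate is N(−0.38, 1.38) censored to the
scale; demographics echo a first-year psychology sample.

Designated "bad" participants violate exactly one targeted quality test
(practice rating below 0; all trials in the floor or ceiling band; mean RT
inflated ×10; lowest seriousness answer; or a suspicion flag).  Their
default fractions mirror the achieved sample of the study the pipeline
models: 244 participants with 64 practice, 6 response-time, 5 seriousness
failures and 28 suspicion-flagged.  Injection is disjoint, so per-test
counts are exact by construction; the union of failures can exceed an
empirical union in which tests overlapped.  One caveat: the ±3 SD
response-time rule is cohort-relative, so a clean participant can still be
flagged by chance under log-normal RTs — per-test counts are guaranteed only
for the quantities the generator injects.

What passing tests on these cohorts shows is that the *pipeline* is correct
and well calibrated, not that real raters behave like prediction-plus-noise:
real data compress the scale ends (empirical cell means near ±1.4 rather
than ±3), which is why a generator matched to the empirical R² regime does
not simultaneously match empirical RMSE.

## Exclusions

The four outcome-neutral tests: practice rating strictly below the midpoint;
at least 12 of 18 ratings in [−3, −2] (floor) or [2, 3] (ceiling), intervals
closed at the labeled anchors; participant mean RT outside grand mean ± 3 SD
of the participant means (the dispersion base is the SD of participant
*means*, and the inequality is strict, so a participant exactly at the bound
survives); and answering the lowest seriousness category.  A participant
failing any test is excluded unless ≥ 40% fail at least one, in which case
nobody is excluded and a `data_quality` grouping column is carried instead.
RT flags are computed once on the full cohort, making the operation
idempotent on its own output.  Suspicion-based exclusion is a sensitivity
re-run (the pipeline writes both result sets), not a primary exclusion.

## Inference

The repeated-measures ANOVA is computed through orthonormal contrast scores:
for each effect, the Kronecker product of orthonormal Helmert contrasts (for
involved factors) and normalized averaging vectors (for uninvolved factors)
projects each participant's cell-mean vector onto the effect's subspace.
Because these contrasts plus the grand-mean direction form an orthonormal
basis of the cell space, all effect, error and between-subject sums of
squares add up exactly to the total — a conservation law the tests assert.
F values agree with statsmodels' AnovaRM to 8 significant digits; per-effect
Greenhouse–Geisser ε (trace formula on the contrast-score covariance) agrees
with pingouin's to machine precision.  GG (not Huynh–Feldt) is used
throughout, consistent with the corrected dfs this class of study reports;
effect size is partial η² = SS_effect / (SS_effect + SS_error).

The ANCOVA mean-centres the continuous covariate and partials it (its
interaction with each within-subject contrast) out of each effect's error
term, losing one error df per contrast; with a centred covariate the effect
sums of squares are unchanged, so an uninformative covariate reproduces the
ANOVA.  A `covariate` row reports the between-subjects regression on
participant means.  Within-effects are orthogonal to participant means only
in expectation, so the ANOVA and ANCOVA within-effect F values agree
approximately, not identically, in finite samples.

Bonferroni families are the 3 pairwise tests within a 3-level factor and the
3 simple-effect tests of the dangerousness × absolute-prevalence
interaction; paired-test effect size is d = t/√n (which reproduces the
printed consistency t(174) = −70.95 ↔ d = −5.36).  Welch tests use
Satterthwaite dfs with pooled-SD d.

## Model comparison

Each observation is paired with its condition's normalized prediction —
trial-level by default (each participant-trial), cell-level optionally.  R²
is the squared Pearson correlation, *not* 1 − SSE/SST: badly mis-ordered
models should score small positive values rather than negative ones, and a
constant prediction vector yields an undefined (NaN) R² while RMSE/MAE are
still reported.  A model is declared best only if it leads on all three
statistics; otherwise the per-criterion rankings are returned without a
winner.  Cousineau–Morey intervals remove each participant's mean (restoring
the grand mean), inflate the per-cell variances by C/(C − 1) for C cells,
and use t-based 95% intervals.

## Power

G*Power's one-group repeated-measures within-factors convention:
λ = f²·N·m·ε/(1 − ρ), df₁ = (m − 1)ε, df₂ = (N − 1)(m − 1)ε, with
f² = η²ₚ/(1 − η²ₚ).  This parameterization reproduces the three published
anchor values exactly (required N = 147 at η²ₚ = .035 and 90% power;
achieved power .71 at η²ₚ = .018, N = 175 and .88 at η²ₚ = .021, N = 233,
both at m = 2, ρ = 0, ε = 1).  `required_n` brackets by doubling and
bisection, exploiting strict monotonicity of power in N.  Power values are
compared at two printed decimals.

## Calibration studies and problem sizes

The validation suite runs two simulation studies, sized to finish in
minutes on one core:

- **null type-I calibration**: 2000 replicate pure-noise cohorts of n = 30;
  each of the 7 ANOVA effects must reject at α = .05 in 5% ± 1.5% of
  replicates, asserted on the GG-corrected p the pipeline reports.  GG is
  mildly conservative under exact sphericity (observed rates ≈ .039–.053,
  lowest for the df = 4 three-way interaction), which the band accommodates;
- **generating-model recovery**: 100 replicate cohorts of n = 175 per
  generating model at the default noise SD; the comparison stage must rank
  the generator best in ≥ 80% of replicates (observed: 100% for all five),
  and absolute-model cohorts must land in the empirical trial-level R²
  regime [0.5, 0.8] (observed ≈ .65–.69).

Both run on a vectorized rating-matrix path that shares the noise model and
the ANOVA/fit code paths with the record-level simulator.

## Known limitations

- The additive prediction-plus-noise generator cannot reproduce empirical
  scale compression (it matches R², not RMSE, of real data).
- The exact jitter distribution, rating-scale normalization rule and
  R²-pairing granularity of any particular empirical deposit are design
  choices here; all three are isolated behind single functions or flags so
  they can be aligned with an external dataset when one is loaded through
  the pipeline's external-input path.
- Power analysis is analytic only and covers the one-group within-factors
  design; between-group or mixed designs are out of scope.
- Only coded boolean suspicion flags are modeled; free-text suspicion
  responses and their human judging are not.
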