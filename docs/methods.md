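# Methods

This note documents the models and procedures implemented in `periglyc`, the
provenance and units of every tunable parameter, what the synthetic cohort
generator does and does not emulate, and the numerical and design choices
made where the design was genuinely open.

## 1. Window segmentation

Each participant's study span is partitioned into half-open, minute-resolution
intervals of five classes anchored on logged exercise sessions:

| class | definition |
|---|---|
| `DURING` | `[start, start + duration)` of a session |
| `EARLY`  | the 3 h after a session end (early recovery) |
| `PRE`    | the 2 h before a session start |
| `LATE`   | from the end of early recovery to the first 08:00 local time strictly after it, or to the next session's `PRE` start if sooner (late recovery) |
| `NONEX`  | all remaining time |

When windows of different sessions overlap, the priority order is
`DURING > EARLY > PRE > LATE > NONEX`. Only late recovery is explicitly
subordinated to a following pre-exercise window; early recovery is a fixed
3-hour period, so it outranks a following session's `PRE`. Ties within one
class resolve to the nearest qualifying session (most recent for
`DURING`/`EARLY`/`LATE`, next upcoming for `PRE`). A timestamp exactly on a
boundary belongs to the later window. If a session's early recovery ends at
or after 08:00, the late-recovery cutoff is the *next* day's 08:00; the
cutoff clock time is configurable. The final session's late recovery is
clipped to the span end.

Timestamps are timezone-naive local clock time; daylight-saving transitions
are out of scope (the synthetic data never cross one).

The partition is built by interval arithmetic over the set of candidate
boundaries and is verified in the test suite against an independent
brute-force oracle that paints labels onto a minute grid in reverse priority
order; equality is asserted on 100+ randomized instances plus hand-built
edge cases, and total duration is conserved exactly on every cohort.

## 2. CGM band metrics

Bands follow the international consensus thresholds on integer mg/dL
readings: `<54`, `54–69`, `70–180`, `181–250`, `>250`. TBR (time below
range) is the share of readings <70 (level 2: <54), TIR is 70–180 inclusive,
TAR is >180 (level 2: >250). The boundary conventions (54 and 250 attached
to the inner bands) follow the consensus decomposition in which overall TBR
splits into a `<54` and a `54–69` component.

Time share is approximated by reading share on the nominal 5-minute grid; no
interpolation across CGM gaps. The default pooling is reading-weighted
across all time of a class (matching "percentage of time spent below
range"); an unweighted per-participant mean is exposed as an option because
published reports do not always state which was used. Window classes with
zero readings are reported with `n_readings = 0` and NaN percentages, never
zero-filled. Published per-window TBR figures are treated as *total* TBR
(<70), consistent with the non-exercise decomposition (2% + 1% summing to an
overall 3%).

## 3. Episode classification

Episodes are logbook-reported, not CGM-derived (automated episode detection
is deliberately out of scope). Level is assigned from the lowest observed
glucose: <54 mg/dL → level 2, otherwise level 1. An episode reported with
symptoms but no glucose value is levelled 1 *by convention* and carries an
explicit `level_imputed` flag, because published reports do not state how
such episodes were handled. A session is hypoglycemic if it carries ≥1
episode (phases before/during/after pooled — per-session prevalences are
defined that way); it is a level-2 session if any episode is level 2.
Stratified rates (activity type; modified-Borg intensity categories
nothing/low/moderate/high) use sessions with a non-missing stratum variable
as denominator, and the stratum counts are audited against the total in the
tests.

## 4. Adjustment classification and deviation flags

Three guidance rules generate per-session deviation flags:

* `late_or_no_temp_target` — temporary target not activated ≥60 min before
  start. Activation at exactly −60 min counts as early ("at least 1 h"
  wording wins over "over 1 h" where sources conflict). Activation after the
  session end is invalid input.
* `snack_within_1h_before` — any carbohydrate intake strictly within 60 min
  before start. The pre-exercise carbohydrate window is (0, 120] min before
  start. Whether an intake was announced to the AID system is not recorded;
  the flag tests timing only.
* `single_intake_gt20g_during` — any single during-exercise intake strictly
  exceeding 20 g (exactly 20 g is compliant).

Temporary-target percentages use the complete-case denominator (sessions
whose adjustment logbook block is present); carbohydrate summaries use all
sessions. Medians and IQRs (25th/75th percentiles, linear interpolation) are
computed over per-session summed grams among sessions with any intake.

## 5. Mixed-effects logistic model

Per-session reported hypoglycemia is modelled as
`logit P(y_ij | b_i) = x_ij'β + b_i`, `b_i ~ N(0, σ²)` over participants.
The marginal likelihood is maximized by *adaptive* Gauss–Hermite quadrature:
for every likelihood evaluation the posterior mode and curvature of each
`b_i` are found by (globally convergent, clipped) Newton steps and the
quadrature nodes are re-centred there, so 20 nodes give estimates stable to
<1e-3 against 40 nodes (asserted in the tests). σ is optimized on `[0, 8]`
with L-BFGS-B; at the boundary the model degenerates cleanly to ordinary
logistic regression. Standard errors come from the numerically
differentiated observed information; Wald CIs and p-values use α = 0.05,
two-sided, with no multiple-testing correction (recorded in the output
metadata). Flags are fitted jointly (one model, three fixed effects) and
singly (three models), and both are reported. Sessions missing the
adjustment block are excluded (complete case) from all association models,
since the temporary-target flag is undefined for them. Non-convergence and
separation are reported via `converged = false`, never silently; a
single-participant fit and a constant outcome raise immediately. The fitter
is validated against `lme4::glmer` (nAGQ = 20) to ~1e-4 agreement on
coefficients, σ, and standard errors, and against the closed-form sample
odds ratio on zero-variance data. The models are unadjusted (no activity
type/intensity covariates), matching the reported analysis; stratum fixed
effects can be added through the design-matrix interface.

`calibration_study` is the simulation harness: it regenerates cohorts on an
effect grid and reports per-flag rejection fractions, giving type-I error at
effect 0 and power elsewhere.

## 6. Synthetic cohort generator

The generator targets the *statistical structure* of a one-month free-living
AID exercise cohort; it contains no insulin–glucose physiology and no pump
algorithm logic (explicit non-goals).

**Scheduling.** 86 participants, 30 days. Each participant draws a weekly
session rate uniform on [2.0, 3.2] (inclusion criterion ≥2/week; the mean of
2.6/week reproduces the published total of ~954 sessions), giving
`round(rate × 30/7)` sessions on distinct days, one per day, with start
times uniform on 07:00–21:00 and durations truncated-normal (mean 1.5 h, SD
1.1 h, clipped to [0.25, 6] h) — one-session-per-day plus the 6 h cap
guarantees non-overlap. Activity type (aerobic/anaerobic/mixed) and Borg
category follow the published mix (73/9/15 and 2/27/61/9, renormalized over
non-missing), with small logbook missingness rates (3.5% type, 1% Borg).

**Logbook marginals.** Temporary-target categories 27/46/27 (≥1 h before /
<1 h or during / none); the adjustment block is missing for 13.6% of
sessions (824/954 complete). Pre-exercise intake in 36% of sessions, grams
lognormal with median 20 g and σ_log = 0.514 (matching the 15–30 IQR
ratio), offset uniform in the 2 h before start. During-exercise intake in
27% of sessions with total grams lognormal (median 25.5 g, σ_log = 0.679).
The published 10% rate of single >20 g intakes is inconsistent with
single-bolus consumption (27% × P(total > 20) ≈ 17%), so totals over 20 g
are taken as one bolus with probability 0.59 (solved in
`scripts/calibrate_defaults.py`) and otherwise split into ≤20 g portions —
encoding both the median and the 10% rate.

**Hypoglycemia.** Session episodes follow
`logit P = α(type) + b_i + Σ_f δ_f·flag_f` with participant intercepts
`b_i ~ N(0, 0.5²)` and all deviation effects δ zero by default (the
published analysis found no significant association). The base log-odds
α(type) are *solved* (Gauss–Hermite inversion) so that the marginal
per-type rates equal the published 20/12/21% regardless of σ. Given an
episode, its level is 2 with participant-specific probability
`q_i ~ Beta(a, 2a)` (population mean 1/3 — two-thirds of hypo sessions are
level 1). The dispersion `a = 0.276` is calibrated so that 38% of
participants experience ≥1 level-2 episode over the month: with independent
level assignment that fraction would be ~53%, so the published participant-
level figure forces hypoglycemia *depth* to cluster within participants.
This is a modelling choice — the true joint distribution is unreported — and
it implies strong between-participant heterogeneity in level-2 propensity.
Episode descriptors (phase 10/60/30 before/during/after, symptom classes
10/13/42/35, interruption 69/19/12) are drawn independently; asymptomatic
episodes are detected by CGM (80%) or capillary readings. Symptomatic
level-1 episodes lack a glucose value in 5% of cases, exercising the
imputation path.

**CGM process.** Readings sit on a 5-minute grid over the study month
(~743k readings). Within each window the band sequence is a Markov chain
that stays in the current band with probability `cgm_persistence` and
otherwise redraws from the window class's stationary occupancy; the chain is
re-initialized from the stationary distribution at every window boundary, so
*every* reading's marginal band distribution equals the configured occupancy
of its class exactly, for any persistence. The default persistence is 0:
the pipeline's metrics depend only on marginal band membership, and
independent readings make the generator's calibration-recovery guarantees
hold at binomial precision (a stay-probability ρ inflates the SD of a pooled
occupancy by ≈ √((1+ρ)/(1−ρ))). Users wanting CGM-like autocorrelation for
run-length-sensitive analyses can raise `cgm_persistence`; per-class
marginals are preserved by construction and tested at ρ = 0.9. Within-band
values are uniform integers (metrics depend only on band membership), the
sensor range is [40, 400] mg/dL. For 25% of sessions the peri-exercise
readings (start − 2 h to end + 3 h) are deleted, emulating the published
714-of-954 CGM availability; missingness is at session level because the
study counted whole sessions with usable CGM.

**Window-conditional occupancies (defaults).** Only per-window TBR (and
TIR/TAR totals) are published; the level splits within TAR are chosen
plausibly (5% above 250 mg/dL everywhere):

| class | <54 | 54–69 | 70–180 | 181–250 | >250 |
|---|---|---|---|---|---|
| PRE | 0.3 | 0.7 | 73 | 21 | 5 |
| DURING | 2 | 4 | 69 | 20 | 5 |
| EARLY | 1.7 | 3.3 | 69 | 21 | 5 |
| LATE | 1.3 | 2.7 | 74 | 17 | 5 |
| NONEX | 1 | 2 | 73 | 19 | 5 |

(percent; each row sums to 100.)

**Reproducibility.** One master seed; participant `i` uses substreams
`SeedSequence([seed, i, 0])` (logbook) and `([seed, i, 1])` (CGM), so
growing the cohort never reshuffles earlier participants. Identical config
and seed yield byte-identical output files (tested).

**What the generator does not emulate.** Real CGM traces have smooth
within-band trajectories, trend arrows, sensor noise and compression
artefacts; real session schedules cluster on weekends; hypoglycemia depends
on insulin on board, meal timing and glucose trend, none of which exist
here. Passing calibration-recovery tests therefore demonstrates that the
*segmentation, counting and classification code* is correct and that the
generator hits its configured marginals — not that the pipeline's behaviour
on real data has been validated against a ground truth. Known deliberate
deviations from the published cohort: the weighted by-type hypoglycemia
marginal is 19.4% rather than 20.0% (the published by-type rates and type
mix are mutually inconsistent at full precision; the difference is well
inside Monte-Carlo error at n ≈ 954), and the share of participants with ≥1
episode of any level comes out ≈86% vs a published 78% — a consequence of
calibrating the participant-level *level-2* figure instead; no acceptance
quantity depends on it.

## 7. Numerical choices and degenerate inputs

* Percentile computations use linear interpolation (numpy default).
* Probability vectors must sum to 1 within 1e-9; band occupancies likewise.
* Empty cohorts produce headers-only CSVs; empty summaries are NaN, not 0.
* Readings outside the labeled span are excluded with a logged count, never
  silently dropped.
* Mixed-model mode search clips Newton steps to ±4 log-odds; fixed effects
  are bounded at ±25; |β| > 15 after fitting is flagged as separation.
* The quadrature-stability and glmer cross-checks pin the numerics; the
  closed-form 2.25 odds-ratio check pins the zero-variance limit.

## 8. Simulation study sizes

The packaged acceptance/calibration studies use: the full default cohort
(86 × 30 days, ~700k readings) for marginal recovery; 600 replicates of a
reduced 30-participant × 10-session cohort for type-I error (the per-flag
rejection band 0.05 ± 0.02 is asserted with a 2-MC-SE allowance for the
simulation estimate itself); 100 replicates of a 120-participant
single-activity-type cohort (β = 0.8, σ = 1.0) for parameter recovery; and
25 full-cohort replicates per effect size for the power curve. These sizes
keep each study's Monte-Carlo error well below the tolerance it checks.

## 9. Known limitations

* The calibration is circular by design: the generator encodes the published
  marginals the pipeline is then required to recover. This is an end-to-end
  correctness test of the analysis code, not an independent replication.
* The Wald test for the rare >20 g flag is mildly conservative at the
  reduced cohort size (~3.1% empirical rejection at nominal 5% over 3000
  replicates); with ~6 expected events among flagged sessions this is
  expected small-sample behaviour.
* Device-stratified analyses, CGM-derived episode detection, random slopes,
  and AGP-style summary statistics (GMI, CV, MAGE) are out of scope.
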