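# Methods

This note documents the models and procedures implemented in `elderwatch`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic testbed can and cannot show.

## Study design

The package studies a rule-mining question: given usage logs of an elderly
tele-care platform in which distress alerts are defined by five known
behavioural rules, can a cost-sensitive decision-tree learner rediscover
those rules, and how well does a compact pair of extracted alert rules
classify the full dataset? Because no real usage data is available, the
cohort is synthetic and the ground truth is generated by construction; every
downstream claim is therefore about the *method*, not about real seniors.

Units of analysis are tumbling (non-overlapping) 3-day windows aligned to
the observation start. The default observation period is 363 days, chosen
as the largest multiple of 3 within a year so that each user contributes
exactly 121 complete windows and a 50-user cohort yields 6 050 records; a
sliding window would multiply record counts and correlate adjacent rows.

## Synthetic cohort and usage simulator

* **Demographics.** Age ~ Normal(75, 10²) years, rounded to integers and
  truncated at 18; marital status multinomial with fractions
  married .30 / widowed .50 / single .10 / divorced .08 / cohabitation .02;
  a uniformly drawn residence district (dropped during preparation, kept
  for schema completeness).
* **Usage profiles.** Three latent profiles — low / average / high — are
  allocated by exact largest-remainder quota (20/50/30 %, i.e. 10/25/15
  users at n = 50) and shuffled over users so profile is independent of
  demographics. Quota rather than multinomial allocation keeps the
  per-profile record counts of the default run fixed.
* **Sessions.** Per user per day, session counts are Poisson with a
  profile rate (0.35 / 1.2 / 3.0 sessions·day⁻¹). Durations are log-normal
  (medians 55 / 40 / 30 min, log-sd 0.55) with a "marathon" mixture
  component (probabilities 0.10 / 0.07 / 0.05, duration uniform on
  130–420 min) — the heavy tail the 3-hour alert rules key on. Start hours
  come from a daytime weight vector (07–22 h, mild morning and evening
  bumps) with a night component (23:00–07:00; probabilities
  0.08 / 0.06 / 0.04), needed so night-marathon alerts can occur at all.
  Overlapping draws are resolved by pushing a session one minute past the
  previous session's end, so one user's sessions never overlap. The rate
  and mixture defaults were calibrated once so that the overall alert
  prevalence of a default run lands near 15 % of windows, the operating
  regime the evaluation design assumes; they are configuration, not fitted
  quantities.
* **Weather.** A single regional series: daily maximum temperature is a
  sinusoid (annual mean 20 °C, half-range 8 °C, peak in mid-July,
  day-to-day sd 3 °C); the daily minimum subtracts a uniform 5–12 °C
  diurnal range. Humidity bounds are uniform with the natural maximum kept
  strictly below 100 % so the injected sentinel (below) stays unambiguous.
  The sky-condition label (Rain, Light Rain Showers, Partly Cloudy,
  Scattered Clouds, Clear, Other) is simulated directly as a categorical
  rather than derived from humidity — the downstream score only consumes
  the label.
* **Calendar.** Weekends by weekday arithmetic; holidays are an injectable
  date list (a Portuguese-style 2014 fixture by default).
* **Error injection.** Each temperature/humidity field of each windowed
  record is independently replaced, with rate 0.02, by the sentinel
  outliers −9999 (temperature) or 100 (humidity), emulating corrupted feed
  values. Counts are logged in a provenance record. Labels are computed on
  clean data *before* injection: errors are a data-quality nuisance for
  the learner, not part of the ground truth.

All stages draw from generators derived from one master seed via named
seed-sequences, so any stage is independently reproducible and inserting a
stage does not reshuffle the others.

## Alert rules and labelling

The five ground-truth rules, with the boundary readings used:

| rule | condition | boundaries |
|------|-----------|------------|
| R1 | no access during a 3-day window of plain weekdays, user profile high/average | the inactivity gap is identified with the tumbling window itself |
| R2 | age 70–80, divorced/widowed/single, session starts 23:00–07:00, duration > 180 min | age band closed; start-hour band decides (a session *starting* in the band counts); duration strict |
| R3 | married, age > 70, duration > 180 min | age strict, duration strict |
| R4 | day's max temperature in [15, 30] °C, condition ∈ {Clear, Partly Cloudy, Scattered Clouds}, duration > 180 min | temperature band closed; missing weather makes the rule abstain |
| R5 | ≥ 3 consecutive accessed weekends then a missed one | weekend access = any session starting Saturday or Sunday; the alert is dated to the missed weekend's Saturday |

A window is an alert iff at least one rule event falls in it; the fired
rule codes are recorded. Session-level events are attributed to the window
containing the session start. These labels are verified in the tests by an
independent brute-force re-evaluation written directly from the rule
statements.

## Feature preparation

The windowed table carries, per user-window: age, district, marital
status, access counts (total, weekend/holiday, morning 07:00–12:00),
session-duration extrema (min), offline-gap extrema (min, within-window:
gaps between window edges and session intervals; an empty window is fully
offline, 4 320 min), weather extrema over the 3 days, the sky condition of
the warmest day, and the alert flag. Preparation then:

* blanks the sentinels (no imputation — averaging corrupted fields would
  bias the sample);
* derives **ac = rt + rh**, with rt = 0 (< 15 °C) / 1 ([15, 30] °C, band
  closed to match the R4 reading; the raw mapping leaves the endpoints
  open) / 2 (> 30 °C) from the window's cleaned maximum temperature, and
  rh = 0 (rainy) / 2 (clear-ish) / 1 (other) from the stored condition;
  missing temperature propagates to missing ac;
* clusters users into low/average/high usage by seeded k-means (k = 3,
  10 restarts) on per-user mean offline time, labelling clusters by centre
  order (lowest offline = high usage). k-means replaces the proprietary
  two-step clustering that inspired this profiling step; fitting on sorted
  values makes assignments invariant to record order. Fewer than three
  distinct per-user means raises a degenerate-clustering error;
* discretises: session times into half-open 30-minute bands, offline times
  into half-open 12-hour bands, age into (−∞,65], (65,80], (80,90],
  (90,∞) (open-left/closed-right, as this banding is conventionally
  printed). Raw `age` and `time_session_max` are kept alongside their
  bands because the final alert rules threshold at 70 years and
  120/180 minutes, which the bands cannot express exactly;
* drops identifier-like columns (surrogate key, user id, window start,
  district, alert date) and encodes the alert flag as 0/1 and profile as
  low = 0 / average = 1 / high = 2.

## Decision-tree learner

A C4.5-family binary classifier, written for this package:

* **Splits.** Numeric attributes: binary threshold splits evaluated at
  every boundary between distinct observed values; the node stores the
  smallest right-side observed value T with semantics (x < T | x ≥ T), so
  extracted rules read `attr >= 180` and planted thresholds present in the
  data are recovered literally. Categorical attributes: one multiway split
  over the categories present at the node. Selection maximises gain ratio
  among splits with positive gain; gain is scaled by the known-value
  fraction at the node. Ties (within 10⁻¹⁰) break by attribute name, then
  by smaller threshold, making training invariant to record order.
* **Growth.** To purity or until no split has positive gain — no depth,
  purity or leaf-size limits, mirroring an intentionally unconstrained
  induction setup.
* **Missing values** (and categories unseen at a node) follow the majority
  branch, during training and prediction alike — a simpler policy than
  fractional instances, chosen for testability.
* **Pruning.** Subtree replacement using the Clopper–Pearson upper
  confidence limit of the leaf error at CF = 0.25 (the classical
  pessimistic estimate); a subtree collapses when the node-as-leaf
  estimate is no worse than the sum over its leaves. Subtree raising is
  not implemented.
* **Cost-sensitive labelling.** After pruning, each leaf with counts
  (n₀ no-alert, n₁ alert) predicts alert iff n₁·C(FN) > n₀·C(FP); unit
  costs reduce to majority labelling with ties to no-alert. Because the
  criterion is monotone in C(FN), raising the false-negative cost can only
  enlarge the predicted-alert set — asserted as a property test. The
  default experiment cost matrix is C(FN) = 5, C(FP) = 1: a missed
  distress event is treated as far costlier than a false alarm. The costs
  affect leaf labelling only, not split selection or pruning.
* **Scores.** A leaf's score is its alert fraction n₁/(n₀+n₁), used for
  ROC analysis.
* **Rule extraction.** One conjunctive rule per leaf: the path conditions
  with redundant numeric bounds merged (tightest ≥ and < per attribute).
  The majority branch of a categorical split is exported with `!=`
  conditions so the rule set is total over complete, in-vocabulary
  records and reproduces the tree's predictions on them exactly
  (property-tested); records with missing values match no rule and
  default to no-alert, which is the one place rules and tree can differ.

This learner stands in for the commercial C5.0 system: gain ratio and
pessimistic pruning are shared with that family; boosting, winnowing,
fractional missing-value handling and cost-sensitive split selection are
deliberately out of scope.

## Evaluation harness

* **Cross-validation.** Seeded shuffled 10-fold partition (fold sizes
  differ by ≤ 1). All models over the same record subset share the same
  partition, so with/without-cost variants are compared fold for fold.
  Hit rates (per-class recall), accuracy and AUC are arithmetic means over
  folds (a pooled mode is available behind a flag); correct/incorrect
  counts are pooled over folds so they sum to the subset size. After CV
  the model is refitted on the full subset and its rules extracted.
* **Experiment grid.** Eight models: {all records, low, average, high
  profile} × {unit costs, FN-averse costs}.
* **AUC** is computed from the leaf scores (trapezoidal ROC area, equal to
  the pairwise concordance probability with ties counting ½); folds whose
  test split contains one class contribute no AUC term and are logged.
* **Model selection** drops models with AUC ≤ 0.6 or alert hit rate
  ≤ 0.6 (both configurable); on the embedded reference metrics this
  reproduces the published keep/drop pattern (M3, M4, M7, M8 kept).
* **Final-rule testing** applies the two selected alert rules in a single
  pass to *all* windowed records — the full initial dataset, augmented
  with the ac score derived after cleaning (the raw windowed table does
  not carry ac). Reported precision mirrors the reference tables: hit
  rates to 3 decimals, accuracy/error to 2.

## Problem sizes

Default analyses run at the study conditions themselves: 50 users ×
121 windows (6 050 records) for labelling, preparation and the experiment
grid; 10 000 users for demographic-fidelity checks; 2 500 records for
planted-rule recovery; ≤ 12-record tables for exhaustive split-selection
oracles. These sizes are the package's chosen defaults for its test suite
and scripts.

## What the generator does not emulate

The simulator produces independent users with stationary behaviour; it has
no trends, illness episodes, seasonality in usage (only in weather), no
correlation between weather and session behaviour, no multi-region
weather, and no biosensor channels. Ground-truth alerts are *defined* by
the five rules, so label soundness checks verify internal consistency, not
clinical validity. Consequently, passing tests show that the pipeline
implements its stated procedures faithfully and that the learner can
rediscover rule structure from windowed features under realistic noise —
they say nothing about detection performance on real usage data.

## Known limitations

* The learned per-model CV metrics depend on the synthetic process and
  will not numerically match analyses built on other data sources; only
  the metric *arithmetic* (embedded reference tables) and the qualitative
  selection pattern are exact reproduction targets.
* Humidity 100 % is physically valid but reserved as a sentinel, following
  the cleaning convention this pipeline mirrors; natural humidity is
  therefore capped below 100 in the generator.
* Whether offline time should carry across window boundaries is an open
  design point; the implementation computes it within-window.
* The tree learner's majority-branch missing-value policy can make rule
  and tree predictions differ on incomplete records (rules abstain to
  no-alert).
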