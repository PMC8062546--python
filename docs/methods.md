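# Methods

This note documents the models and conventions behind `shiftsense`: what
the pipeline computes, what the synthetic cohort emulates, the parameters
that matter, and the design choices made where more than one reasonable
convention exists.

## Analysis day and workday inference

Nursing shifts straddle midnight, so all day-level aggregation uses a
**23:00-anchored analysis day**: the day for date *d* runs from 23:00 on
*d−1* to 23:00 on *d*. This makes the 23:00–03:00 diurnal bin contiguous
within a single day and gives every timestamp exactly one day. A sleep
session belongs to the analysis day containing its **onset**, so a night
nurse's post-shift morning sleep (onset ≈ 09:50) counts toward the workday
it follows.

Work status per participant-day is inferred from three evidence sources
with fixed precedence: a daily at-work survey answer beats the
garment-sensor presence flag, which beats badge-proximity hits in the unit
(threshold ≥ 1 hit, configurable). The precedence ordering is a package
convention — the relative reliability of the three sources is a judgement
call (self-report is direct; the garment is worn only at work but can be
forgotten; proximity can register pass-throughs). Days with no evidence are
labelled `unknown` and are excluded from, never imputed into,
status-conditional aggregates. Labelling is deterministic and monotone:
adding work-indicating evidence at the decisive precedence level can never
turn a workday into an off-day.

## Activity features

Minute heart rate relative to HRmax = 220 − age (valid ages 18–100) is
classified with half-open intervals: rest < 0.50, moderate [0.50, 0.70),
vigorous [0.70, 0.85), excluded ≥ 0.85. The half-open convention makes the
zones exhaustive with no gap between integer-percent descriptions
(“50–69%”, “70–84%”). Zone ratios are taken over valid (non-excluded)
heart-rate minutes; vigorous activity is also reported in minutes/day. The
walk ratio divides minutes with steps > 0 by minutes with *any* step
observation — missing minutes are not treated as non-walking — and is
invariant to step magnitude.

Days with fewer than `min_valid_minutes = 480` (8 h) valid heart-rate
minutes are dropped; the threshold is a coverage floor chosen so that a
day's ratios reflect at least a third of the day, and it is configurable
and logged. Participants need ≥ 5 labelled days per status to enter that
status's aggregate; the same ≥ 5 rule applies to sleep sessions, and EMA
mixed models require ≥ 10 responses per participant.

The moderate ratio is checked for redundancy against the rest ratio
(Spearman ρ per status, flagged below −0.7) and is excluded from
between-group models when flagged — in both the simulated and the
motivating real setting the moderate zone is essentially the complement of
rest once vigorous time is negligible.

## Sleep features

Mid-sleep = onset + (offset − onset)/2, reduced to clock minutes. MSW and
MSF are **circular medians**: each mid-sleep is re-expressed in the 24 h
window centred on the group's circular mean, then the ordinary median is
taken. The median (not the mean) is used because night-shift free-day
timing is heavy-tailed, and all distances are minimal circular distances —
ΔMS = min(|MSW − MSF|, 1440 − |MSW − MSF|) ∈ [0, 720] — since a naive
linear difference would report 22 h for a 2 h wrap. Timing regularity is
summarised by the circular median and the circular range (shortest arc
containing all observations). Sessions of any length are kept by default
(no nap filter); `min_session_min` can impose one. Plain MSF is used (no
sleep-debt correction of the free-day midpoint).

## Statistical battery

* **t-tests**: pooled variance, df = n₁+n₂−2.
* **Fisher's exact test**: sample (cross-product) odds ratio ad/bc with the
  exact two-sided p (sum of hypergeometric probabilities ≤ observed); a
  zero off-diagonal cell yields an infinite OR with a flag.
* **Three-way ANOVA**: main effects shift + age group (<40 / ≥40) + gender,
  Type II sums of squares — appropriate for an unbalanced main-effects-only
  design. Estimated marginal means average model predictions equally over
  the 2×2×2 factor grid, with model-based SEs and 95% t-intervals. A
  constant outcome raises rather than reporting an undefined F.
* **2×6 repeated-measures ANOVA** (pingouin): between factor shift, within
  factor diurnal bin, listwise deletion of incomplete subjects. Mauchly's
  test gates the Greenhouse–Geisser correction (applied when p < 0.05;
  corrected dfs are ε-scaled and never larger than uncorrected). Per-bin
  contrasts are uncorrected two-sample t-tests (Fisher's LSD convention).
* **Linear mixed models** (statsmodels MixedLM, REML): fixed effects shift,
  work status, and their interaction (treatment coding, reference night
  shift / off-day); random intercept per participant. Reported t
  statistics use the residual-df convention (N observations − 4 fixed
  effects); a boundary (zero-variance) fit is flagged, with estimates still
  returned — on balanced designs they coincide with OLS.
* **Standardized-β regressions**: outcome and the continuous feature are
  z-scored; binary covariates stay as 0/1 dummies (reference night shift,
  male, age ≥ 40), so each dummy's β reads as the standardized shift of the
  outcome for the non-reference level. Z-scoring dummies instead would
  change their βs by a factor of the dummy SD; the 0/1 convention is
  documented rather than hidden.

## Synthetic cohort

The generator emulates a 10-week, 113-nurse study (69 day / 44 night; one
root seed with per-participant spawned substreams, so adding a participant
never perturbs the others; identical config + seed ⇒ byte-identical
output). Defaults are the study conditions, not tuning knobs:

* **Schedules**: 3 twelve-hour shifts/week (typical full-time nursing),
  days drawn uniformly within each week; rotations are not simulated. For
  night nurses a shift starting on *d* makes both *d* and *d+1* ground-truth
  workdays, because both analysis-day windows contain worked hours.
* **Roster**: group marginal counts for gender (51/69, 31/44 female),
  degree (10/69, 11/44 graduate), and native language (39/69, 25/44) are
  assigned exactly, so the roster reproduces the target contingency tables;
  ages are Gaussian (day 39.4 ± 8.9, night 35.2 ± 7.5, clipped 23–65).
* **Activity**: per shift × status cell occupancy targets (rest 73.0/82.4%
  workday, 76.5/83.5% off-day; vigorous 4.1/3.2 and 7.5/5.3 min; walk
  31.3/27.6 and 25.3/21.3%). Between-participant spread: rest-propensity SD
  0.12, walk SD 0.07, vigorous multiplier ~ Gamma(2, ½) — spreads chosen as
  physiologically plausible between-person variation consistent with the
  target group-level SEs. Diurnal structure comes from per-bin walk-offset
  profiles (mean-zero across bins): day nurses walk mostly 07–19 h,
  night nurses mostly 19–07 h on workdays, and night nurses keep a flatter,
  later off-day profile. Rest offsets mirror walk offsets at −0.6×. Rest
  minutes follow a 24 h sinusoidal baseline (mesor 0.40·HRmax, amplitude
  0.04·HRmax, acrophase 15:00 day / 03:00 night); higher zones draw
  uniformly within their band.
* **Sleep**: workday cells anchor onset at 23:50 (day) and 09:52 (night);
  each off-day cell is **positioned so the implied mid-sleep gap equals the
  configured social jet lag** (52.5 min day, 425 min night — day nurses
  drift later on days off, night nurses swing back toward a diurnal
  schedule). Day-to-day onset SDs (45/60 day, 40/110 night) make night
  off-day timing the most irregular. A participant chronotype offset
  (SD 25 min) shifts both statuses equally and therefore cancels in ΔMS;
  a per-participant jet-lag deviation (SD 25 min) does not. Efficiency is
  Gaussian per cell; offset = onset + duration/(efficiency/100), so
  duration ≤ interval always.
* **EMAs**: one survey/day at a shift-appropriate slot (day 06/12/18 h,
  night 18/00/06 h), linear model with participant random intercepts;
  defaults plant a work-status effect on stress (+0.35) and anxiety
  (+0.25), a night × workday interaction on negative affect (+0.33), and a
  negative work-status effect on positive affect, then round and clip to
  scale. Clipping mildly attenuates planted effects (~10–15%), which is why
  estimator-calibration checks simulate the linear model directly.
* **Baselines**: Gaussian per group at the target means/SDs; life
  satisfaction is additionally coupled to the participant's latent walking
  propensity with a negative day-shift interaction (std-β +0.26 / −0.62),
  so the feature-to-survey regressions have a recoverable signal.
* **Missingness**: whole-day wear dropout 0.30 (≈ 49 of 70 days recorded),
  i.i.d. minute dropout 0.05, sleep recorded on 65% of days (≈ 45
  sessions/participant), EMA response rate 0.80 (≈ 56 responses), and 8% of
  days with no work evidence. Dropout is time-homogeneous; a compliance
  decline over weeks is not modelled.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: PPG artefacts and device-specific sleep
staging, rotating or irregular schedules, autocorrelated activity bouts,
weekday/weekend structure, informative (compliance-related) missingness,
and any causal coupling between activity and sleep. The generator is
judged only on reproducing the cited group-level summaries and on
parameter-recovery behaviour.

## Numerical conventions and degenerate inputs

Clock arithmetic is exact in minutes; circular medians resolve ties by the
ordinary median in the re-centred window. Zone boundaries are half-open as
above, so boundary heart rates classify deterministically. Zero-length
schedules, empty streams, and all-missing configurations return empty
frames rather than erroring; non-invertible designs (constant outcomes,
perfect collinearity, empty factor levels, both-groups-constant t-tests)
raise informative errors. Report tables round to display precision
(ratios/minutes 1 dp, ORs/βs 2 dp); `stats.json` keeps full precision, and
every table value equals the JSON value after the declared rounding.

## Problem sizes used in checks

The test suite exercises the full pipeline at the default cohort size
(113 participants, 10 weeks) for jet-lag recovery (5 seeds) and directional
reproduction (20 seeds), and uses reduced sizes elsewhere — e.g. 500
simulations at n = 60 for ANOVA type-I calibration and 200 replicates of a
30-participant design for mixed-model CI coverage — sizes chosen to make
Monte-Carlo bands tight enough to be informative while keeping the default
run quick on a laptop.

## Known limitations

Evidence-based labelling misclassifies ~2–3% of workdays (survey missing
and garment forgotten), which slightly attenuates status contrasts; medians
make the sleep-timing features robust to this. The ±1 h analysis-day
anchor means a small share of late-evening sleep onsets fall into the
neighbouring day's window. Estimated marginal means assume the
main-effects model; with strong interactions they would mislead. The
mixed-model residual-df convention is anti-conservative relative to
Satterthwaite for small clusters.
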