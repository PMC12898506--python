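# Methods

`akiews` implements a dynamic early-warning pipeline for incident acute
kidney injury (AKI) in adult ICU patients: every 6 hours during a stay it
summarizes the preceding trajectory, predicts the probability of a first
KDIGO-stage AKI beginning in the next 24 hours, and evaluates both the
window-level classifier and the resulting bedside alert stream.  Because
the real multi-center EHR extracts the design targets are credentialed
resources, the package ships a synthetic ICU cohort generator with known
ground truth; every downstream stage is exercised and validated on it.

## Rolling-window cohort

Each eligible stay is expanded into overlapping prediction windows with a
12 h feature window, a 2 h gap and a 24 h outcome horizon, refreshed on a
6 h stride.  The time axis is continuous hours from ICU admission and every
interval in the package is half-open `[start, end)`.  The first cutoff sits
at t = 12 h (one full feature window after admission).  A window's label is
1 iff the stay's first AKI onset falls in `[cutoff+2, cutoff+26)`.  Stays
are censored at the first onset: cutoffs stop once `cutoff + gap` would
pass it, which also drops the ambiguous windows whose gap would straddle
the onset.  Windows whose horizon extends past discharge are kept and
labeled from observed data; dropping them would bias the cohort against
short stays.  Exclusions (age outside 18–88 or privacy-masked, RRT at ICU
entry, AKI before the first eligible cutoff, missing ESKD/baseline status,
stays shorter than feature window + gap) are logged with the first
triggered reason.  Cross-validation folds partition patients, never
windows, so all windows of a patient share a fold.

## KDIGO labeling

AKI staging is computed time-respectingly from raw streams:

- **Creatinine**, at each laboratory timestamp `t`: baselines are the
  minimum SCr over `[t−48 h, t)` (absolute-rise criterion, ≥ 0.3 mg/dL) and
  over `[t−168 h, t)` (relative-rise criteria).  Ratio bands are half-open:
  1.5–2.0× → stage 1, 2.0–3.0× → stage 2, ≥ 3.0× → stage 3.  Both baselines
  missing → the criterion is not computable.  The absolute stage-3 rule for
  SCr ≥ 4.0 mg/dL is deliberately not implemented: staging here is limited
  to rise/ratio/RRT criteria.
- **Urine output**: charted volumes are summed over the trailing 6/12/24 h
  and normalized by the most recent weight at or before `t`
  (mL/kg/h).  Rates are missing while the lookback window extends before
  admission (`t < W`) — without this rule the near-empty early windows
  would stage virtually every stay as oliguric in its first hours — and
  whenever no weight record exists.  Thresholds are strict: rate6 < 0.5 →
  stage 1, rate12 < 0.5 → stage 2, rate24 < 0.3 or rate12 = 0 → stage 3.
- **RRT**: stage 3 from the start of any renal-replacement episode.

The overall stage at `t` is the maximum over computable components; AKI
onset is the earliest assessment time (creatinine timestamps ∪ hourly grid
∪ RRT starts) at which any criterion first fires.  The vectorized labeler
is checked against an independent per-timestamp brute-force evaluation, and
a causality test verifies that perturbing data after `t` never changes the
assessment at `t` (the measurement exactly at `t` is part of that
assessment, as staging happens at laboratory timestamps).

## Features

Streams are summarized over lookbacks ending at the cutoff: last / mean /
SD / min / max / OLS slope over the 12 h feature window for vitals; 48–72 h
slopes, within-stay deltas (trailing 12 h mean minus the earlier lookback
mean) and piecewise slope changes (PSC) for the trajectories that carry AKI
precursor signal; last observed value over 48 h for labs; urine-output
volume and weight-normalized rates; vasopressor exposure; and statics
(age, admission weight, sex, unit type, comorbidity flags).  PSC fits a
continuous two-segment line with the breakpoint chosen by exhaustive least
squares over interior observed timestamps (series are short, so exhaustive
search is exact and cheap) and reports the slope difference.  Trend
lookbacks read history beyond the 12 h window but never at or past the
cutoff.  Nothing is imputed: missingness is preserved as NaN and handled
natively by the trees, because the ordering pattern of measurements is
itself informative.  Screening — computed on training rows only and applied
unchanged to validation rows — drops columns above 50% missingness and
near-zero-variance columns (most frequent non-missing value covering >99%
of rows, a chosen operationalization) and reports, without dropping,
feature pairs with |Pearson| or |Spearman| above 0.95.  Categoricals are
one-hot encoded with training-learned vocabularies; unseen levels map to
all-zero indicators.

## Model

Gradient-boosted trees (XGBoost, `binary:logistic`, histogram method) with
monotone constraints on clinically directional predictors: creatinine and
BUN summaries and vasopressor exposure must not lower predicted risk, and
urine-output summaries must not raise it.  Hyperparameters come from a
small grid (depth, learning rate, subsampling, minimum child weight,
boosting rounds; the shipped default has two points) searched with
patient-grouped k-fold CV, selecting the point with the best mean per-fold
out-of-fold AUC; the final booster is refit on all development rows.  SHAP
values are computed with the booster's built-in TreeSHAP
(`pred_contribs=True`) on out-of-fold rows, pooled across folds by simple
average of mean |SHAP|; the top-k features (61 by default) are kept, in the
original column order so that k = p reproduces the model exactly, and the
model is refit.  Out-of-fold risks are recalibrated by Platt scaling fit on
the logit of the predicted probability — this choice makes a second fit on
recalibrated output a near-identity.  The operating threshold maximizes the
F2 score over the sorted unique out-of-fold risks, breaking ties toward the
smaller threshold (higher sensitivity); the deployment default is 0.125.

## Evaluation

Discrimination (tie-corrected Mann–Whitney AUC, step-interpolated AUPRC)
and threshold metrics (recall, specificity, precision, F1/F2, balanced
accuracy, MCC, Brier) carry 95% percentile confidence intervals from a
bootstrap that resamples whole patients (2000 resamples by default;
replicates with undefined statistics are excluded and counted).
Calibration is summarized by the logistic slope/intercept on logit(risk),
calibration-in-the-large (offset model with slope fixed at 1), expected
calibration error over 10 equal-width bins, Brier score, and a reliability
curve.  Decision-curve analysis uses the standard net-benefit calculus:
`NB = TP/N − (FP/N)·pt/(1−pt)`; treat-all gives `π − (1−π)·pt/(1−pt)` and
treat-none 0, and avoided unnecessary interventions per 100 windows are
`100·(NB_model − NB_all)/w`.  Subgroup AUCs are compared with unpaired
DeLong tests (placement-value variance) under Bonferroni correction, and
cohort balance with absolute standardized mean differences.

Alert analytics operate at the event level: an alert is a window whose
recalibrated risk reaches the threshold; a true positive has the onset
inside its label interval.  Lead time is measured from the prediction
cutoff — the moment the prediction is issued — to onset, with strict
`>6/12/18/24 h` detection bins over each event's first true-positive alert.
False positives in AKI stays are binned by time to the eventual onset; the
lower edge of the first bin is the 26 h label-interval boundary (an onset
within 26 h makes the alert a true positive).  Burden metrics count alerts
per patient-day and per 12 h shift, the union of per-alert coverage
intervals `[cutoff, cutoff+26)` raw and capped at discharge, repeat alerts
(issued while a previous alert's coverage is active), and the fraction of
stays with ≥1 / ≥2 alerts.

## Synthetic cohort generator

The generator emulates the structure of ICU EHR extracts: one stay per
patient with demographics, ten comorbidity flags, a nullable ESKD/baseline
status, log-normal length of stay (median 3.6 days), irregular vitals
(~0.9 charts/h), sparse labs (~1 draw/9 h), hourly near-complete urine
output charting, an admission weight with an optional mid-stay
remeasurement, vasopressor/contrast exposures, and rare chronic entry-RRT
stays that exercise the exclusion rules.

Each stay draws a latent renal *insult* time from a constant hazard whose
log is a baseline (default 0.0045/h) plus effect sizes times risk drivers:
two trajectory-pattern drivers (hemodynamic downtrend, oliguric tendency)
and three static drivers (sepsis, CKD, standardized age).  Insults are
generated as per-stay unit exponentials divided by the hazard, so realized
event rates are exactly monotone in the baseline — `calibrate_prevalence`
exploits this to bisect the baseline until the window-level label
prevalence matches a target (the study regime is 12–17%) within ±2
percentage points.

After an insult, creatinine rises piecewise-linearly to a plateau whose
multiplier is drawn from the stage-1/2/3 bands (1.5–1.9×, 2.0–2.9×,
≥3.0×; configurable mix), crossing the 0.3 mg/dL and 1.5× thresholds
within hours, so a creatinine criterion is always satisfiable before
discharge unless it intervenes; stays with the oliguria driver also drop
below 0.5 mL/kg/h for over 6 h.  Systemic responses (heart rate, breathing,
oxygenation, bicarbonate/anion gap, BUN) shift gradually from the insult
onward, and lab sampling intensifies by a severity multiplier (default 2×)
after the insult — the informative, missing-not-at-random ordering pattern
that motivates leaving missingness unimputed.

Driver *patterns* are expressed whenever a stay carries the driver flag; a
pattern anchors to the insult as its prodrome (mean-arterial-pressure
decline and a mild sub-threshold urine-output dip beginning
`prodrome_lead` hours before it) only when that driver's effect size is
non-zero.  With all effects zero the drivers are biologically inert:
patterns occur at random times and insults arrive independently of every
observable covariate.  The only residual label–feature dependence in that
null configuration is the hours-scale pre-onset tail of the renal
trajectory itself, which is intrinsic to any outcome defined from the data
stream; the fast threshold crossing keeps it small, and the null
configuration empirically yields out-of-fold AUCs near 0.53.

What the generator does **not** emulate: multi-stay patients,
waveform-resolution physiology, medication dose titration, competing risks
(death within the horizon is an ordinary negative), center effects, or
COVID-era case-mix shifts.  Passing tests therefore demonstrate the
correctness and leakage-safety of the pipeline machinery and the
recoverability of planted signal — not clinical-grade discrimination on
real ICU data.

## Problem sizes and numerical choices

Tests run the full pipeline at up to 2000 stays (≈20k windows) with
5-fold grouped CV for the planted-signal recovery checks and 800 stays for
the null control, three seeds each; the bootstrap-coverage study uses 500
repetitions of a 500-cluster design at 400 resamples.  These sizes were
chosen so the planted/null contrast is statistically unambiguous while the
whole suite stays desk-scale.  Degenerate inputs are handled explicitly:
slopes need ≥2 distinct time points, SDs ≥2 points, PSC ≥4 points with ≥2
strictly on each side of a candidate breakpoint; probabilities are clipped
to [1e−6, 1−1e−6] before logits with a warning; a separable Platt fit
falls back to a ridge-penalized fit with a warning; single-class threshold
metrics are reported as NaN and flagged, never silently zeroed.
Determinism: one master seed drives counter-based per-stay generator
substreams (stable under cohort-size changes), fold assignment, booster
seeds, and every bootstrap.
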