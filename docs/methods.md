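# Methods

This note documents the models, numerical choices and defaults behind
`redtia`, and what the synthetic data does and does not emulate.

## Time-activity model and ground truth

Structure activity is modelled as `C e^(−λt)` (mono) or
`C (e^(−λ₁t) − e^(−λ₂t))` with `λ₂ > λ₁ > 0` (bi).  All rates are *effective*
decay constants combining physical decay and biological clearance; no
separate physical-decay term is carried.  Amplitudes are in MBq, times in
hours, TIA in MBq·h via the closed forms `C/λ` and `C(1/λ₁ − 1/λ₂)`.  Mono
and bi share one type with a kind tag so that fit-type bootstrapping and
model selection operate on a single family.  `λ₂ = λ₁` is rejected at
construction (the curve collapses to zero everywhere).  Exponential sums with
four or more parameters are out of scope: with four-point reference data they
are underconstrained.

The ground truth for every error metric is the analytic TIA of the reference
model — the 4-point AIC-selected fit for measured cohorts, the generating
model for simulated curves.

## Fitting

* **2 points**: exact inversion, `λ = ln(A₁/A₂)/(t₂−t₁)`, `C = A₁ e^{λt₁}`.
* **≥3 points, mono**: unweighted least squares in activity space,
  initialized from the ordinary-least-squares line fit of `ln A` vs `t`
  (positive activities only).  The sign of λ is left free; fits with `λ ≤ 0`
  (flat or rising data, which do occur on noisy late-time pairs) are returned
  *flagged invalid* rather than raising — the inclusion policy belongs to the
  error analysis.
* **4 points, bi**: least squares with `C > 0`, `λ₂ = λ₁ + δ`, `δ > 0`,
  multi-started from a fixed, seed-free grid (slow half-life 200/100/50 h ×
  rate ratio 3/10); the lowest-RSS converged start wins.
* **Model selection**: plain `AIC = n ln(RSS/n) + 2k` with k = 2 (mono) or 3
  (bi).  AICc is unusable here: its correction denominator `n − k − 1` is
  zero at n = 4, k = 3.  An RSS floor of 1e−12 MBq² guards `ln 0`; ties and
  both-at-floor resolve to mono (parsimony).

Fitting is unweighted and in activity space (not log space).  This treats
all time points symmetrically and matches the additive Gaussian noise used in
simulation; the log-space line fit is used only for initialization.

For the Monte-Carlo sweep (~3.3 million three-point fits per full run) a
vectorized variable-projection fitter solves the same problem: for fixed λ
the optimal amplitude is `C(λ) = ΣAe/Σe²`, leaving a 1-D profile objective
minimized by safeguarded Newton iterations from the row-wise log-linear
start.  It is cross-checked against the per-fit `scipy.optimize.least_squares`
route in the test suite; the two agree to ~1e−5 in RSS on noisy triples.

## Single-time-point estimators

Hänscheid: `TIA = A(t)·2t/ln2`.  On mono truth its relative error is
`2x·2^(−x) − 1` with `x = t/T_eff`: zero at x = 1 and x = 2, maximal
`2/(e·ln2) − 1 ≈ +6.15 %` at `x = 1/ln2`.  Madsen:
`TIA = A(t)·e^(λ_pop t)/λ_pop`, exact when the patient's λ equals λ_pop and
otherwise off by the factor `(λ/λ_pop)·e^{(λ_pop−λ)t}`.  Both properties are
verified against numeric integration in the tests.

Population half-lives are runtime configuration per structure.  The shipped
defaults (kidney 50 h, healthy liver 65 h, spleen 70 h, tumor 90 h) are
editable placeholders that simply echo the synthetic generator's medians;
every report records the values used.  Results that depend on a clinic's
actual population kinetics cannot be reproduced without configuring them.

## Sampling schedules

* STP grid: hourly, 1–240 h (240 times).
* 2TP grid: 4-hourly, 4–240 h (60 times, 1770 unordered pairs) — the unique
  uniform 4-hour grid after injection yielding exactly 1770 pairs.
* 3TP: with injection at the start of day 0, scans are restricted to the
  beginning/middle/end of each day (24k, 24k+4, 24k+8 h; day 0 offers only
  4 h and 8 h, day 10 only 240 h — 30 times), and no two scans may be within
  12 h (equivalently, on the same day).  This is the unique reading
  consistent with 3294 admissible triples, confirmed independently by the
  elementary-symmetric-polynomial count over per-day slot multiplicities
  (2, 3×9, 1).
* Clinical 4-scan cohorts: all 6 two-scan and 4 three-scan subsets, with
  scans mapped to the nominal windows 3–5, 21–52, 71–126, 144–194 h.
  Out-of-window scan times are assigned to the nearest window boundary with
  a warning rather than dropped, since real scheduling is imperfect.

## Measurement noise

Repeat quantification (4 repeats) of phantom objects at several scan lengths
yields per-group relative standard deviations; the "effective activity"
`A_eff = A·L/25 min` maps shorter scans onto the lower count rates of later
imaging days.  `RSD(A_eff) = a·A_eff^b` is fit by ordinary least squares on
the log-log group data; groups with zero mean or zero spread are excluded
with a warning (their log is undefined).

Noise injection draws `Normal(A_true, RSD(A_true)·A_true)` about each sampled
point, evaluated at the *noise-free* activity.  Negative draws are clamped to
an activity floor of zero — keeping the draw count deterministic per point —
and two-point fits involving a floored zero are flagged invalid.  The
clamping fraction stays below 1 % wherever RSD < 0.3.

Default power law: `b = −0.5` from counting statistics (RSD ∝ 1/√counts) with
`a = 0.10`, i.e. ≈ 1 % repeatability at 100 MBq effective activity, rising to
≈ 10 % at 1 MBq — consistent with repeatability reported for modern
quantitative SPECT and with the error magnitudes such studies observe at
optimal schedules.  The default phantom table uses 7 objects (8.5–310 MBq)
at 10 scan lengths spanning a 16-fold count reduction.  The intercept `a` is
an extrapolation to 1 MBq and is recovered from a 4-repeat table only to
~15–30 %; the exponent `b` to ~10 %.

## Cohort simulation

Per structure, the reference fits of a (real or synthetic) cohort define the
generating distribution: fit-type labels (bootstrap source, uniform draw with
replacement per curve) and, per parameter, a lognormal with `s` = SD of the
natural log of the cohort values (sample SD, ddof = 1) and `μ` = exp of the
mean log, truncated to the cohort min/max.  For the slow decay constant the
truncation may be widened to a literature effective-half-life range when one
is supplied.  Truncated sampling is by rejection (exact, with a 10⁵-attempt
cap guarding misconfiguration); biexponential `(λ₁, λ₂)` are jointly
resampled until `λ₂ > λ₁` so neither marginal is distorted by swapping.  Fit
types with fewer than two reference fits are dropped from the bootstrap
source with a warning.

The study runs 250 curves per structure (kidneys pooled) by default.  One
noise realization per curve and hourly grid point is shared by all schedules
touching that point, and the random stream is hierarchical
(seed → structure → curve), so adding schedule families never perturbs curve
generation and runs are bitwise reproducible from one seed.  A full
250-curve × all-families sweep over four structures takes about a minute on
one CPU.

## Error metrics and reporting

Percent error is `100(est − true)/true`; per schedule the cohort is
summarized by MPE (mean), SD (sample SD, ddof = 1), MAPE and RMSE on the
absolute MBq·h scale — RMSE is therefore scale-weighted toward high-uptake
structures, matching the conventional unit choice for such tables.  The 95 %
CI of the MPE uses the normal approximation (1.96·SD/√n) by default, with a
t-interval switch.  Invalid fits are excluded from the means but counted in
`n_total`; an optional "penalized" policy substitutes a configurable percent
cap so failure-prone schedules surface in RMSE rankings.  The optimal
schedule is the RMSE argmin, exact ties breaking to the lexicographically
earliest time tuple.  Whether cohort SD columns are sample or population SD
is a convention; sample SD is used throughout.

## Synthetic data: what it emulates, and what it does not

The generator emulates a 28-patient cohort (healthy liver, left/right
kidney, spleen, 1–5 tumors each) imaged once inside each nominal window,
with the default kinetics above, lognormal spreads `s_λ = 0.3`, `s_C = 0.5`,
a 30 % biexponential fraction and an uptake half-life of ~2 h (fast uptake:
monoexponential refits that miss the uptake phase then overestimate TIA only
slightly, the small positive bias expected clinically).  Amplitudes follow
liver 250 > spleen 120 > kidneys ~90 > tumor 60 MBq.

It does **not** emulate: image formation, segmentation or registration
errors; partial-volume effects; correlations between patient covariates and
kinetics; multi-phase clearance beyond the biexponential; or bone-marrow
kinetics.  Passing tests therefore demonstrate correctness of the estimators
and of the simulation machinery under the stated generative model — not
clinical accuracy for any particular patient population, which requires
deriving the distributions and noise model from real data via the provided
pipeline.

## Known limitations

* The biexponential fit explores a fixed 6-start grid; pathological data
  could in principle hold a better local minimum outside it.
* The batch 3-point fitter bounds λ to [−0.29, 5] /h to keep exponentials
  finite over 240 h; fits at the boundary are invalid or extreme anyway.
* The clinical-style analysis requires exactly four scans per curve; curves
  with other counts are skipped with a warning.
* The lognormal form of the parameter distributions is an assumption; no
  goodness-of-fit testing is performed.
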