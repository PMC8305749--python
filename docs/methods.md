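# Methods

This note documents the models and procedures implemented in `driverisk`,
the choices made where the design was genuinely open, and what the synthetic
generators do and do not establish about real traffic data.

## 1. Collision-risk labeling

For a follower at speed `v_f` behind a leader at speed `v_l` with gap `d`,
the braking-distance margin is

    DSS(t) = (v_l² − v_f²) / (2 μ g) + d(t) − τ v_f(t)

with friction rate μ = 0.7, gravity g = 9.8 m/s², and reaction time
τ = 1.5 s while the follower is accelerating and 0.7 s while decelerating or
idling. The collision risk is the extra reaction time implied by a negative
margin, CR(t) = |DSS|/v_f when DSS < 0 and 0 otherwise, and the per-driver
Average Collision Risk is the time average of leader-side and follower-side
risk, ACR = (1/T) Σ [CR_L + CR_F] Δt at Δt = 0.04 s, T = (n−1)Δt.

Scope rules: the leader pair counts only when the gap is ≤ 50 m (measured on
the gap column, i.e. bumper-to-bumper, since the convention for the 50 m
range is not otherwise determined); the follower pair counts only during a
lane change, which starts when the vehicle centre crosses a lane line and
ends at the first frame more than 0.5 m past it. Drivers observed for 10 s
or less are flagged ineligible rather than dropped.

Degenerate and numerical choices:

- **CR at v_f = 0 with DSS < 0 is defined as 0.** The defining ratio is
  singular there and a stopped follower cannot close the gap.
- **Accelerating vs decelerating** is decided from the acceleration sign
  with a ±0.05 m/s² dead-band to avoid chattering between the two reaction
  times around a ≈ 0.
- **Whether the ACR sum runs over all frames or only paired frames is
  immaterial**: unpaired frames contribute CR = 0 either way.

The risky/normal threshold is the IQR outlier rule on the **non-zero** ACR
distribution, Threshold = Q3 + 1.5 (Q3 − Q1), with linear-interpolation
quartiles (the common default; the convention is recorded in the
`ThresholdReport` so results are reproducible under other conventions). A
driver is risky iff ACR > Threshold. At least 4 non-zero ACR values are
required.

## 2. Spectral features

Each driver contributes three signals: longitudinal speed, lateral speed,
and the gap to the preceding vehicle (capped at 50 m, with no-leader frames
imputed at the cap so the spectral input is bounded without sentinel
spikes). Each signal is mean-removed, transformed by the DFT
(`DFT_k = Σ x_n exp(−2πi kn/N)`), normalised by N, and the amplitudes are
linearly interpolated from the natural bin frequencies k/(NΔt) onto the
fixed grid 0.04, 0.08, …, 0.80 Hz. The fixed grid — rather than the first
20 raw bins, whose frequencies depend on N — is what makes drivers with
different observation lengths comparable; mean removal keeps the DC term
from swamping the spectrum (the mean is separately a feature). The mean,
sample (n−1) standard deviation, and coefficient of variation (guarded to 0
when |mean| ≤ 1e-12) complete each signal's block.

The default is 20 amplitudes per signal, i.e. 3 × (20 + 3) = 69 features.
`n_dft=21` yields 72 for anyone needing that count.

Recursive feature elimination is provided but off by default: features are
ranked by booster gain importance, the least important is dropped, and the
stratified-CV AUPRC is tracked; elimination stops when the score has not
improved for 3 consecutive steps (ties prefer fewer features).

## 3. Resampling

Thirteen options behind one interface, parameterised — where a target
balance is meaningful — by the **sampling fraction**: the minority/majority
count ratio after resampling, in (f0, 1] with f0 the original fraction.
Fraction 1 is exact balance; fraction f0 leaves the data untouched. This
fraction convention (rather than its majority/minority inverse) matches the
de-facto convention of resampling software and keeps reported optima
interpretable. The cleaners (Tomek links, ENN, RENN, AllKNN) have fixed
removal rules and take no fraction.

Implementation notes:

- SMOTE-family neighbours default to k = 5, ENN-family to k = 3 (commonly
  published defaults; both exposed in `SamplerSpec`).
- ENN removes a **majority** sample unless all k of its nearest neighbours
  share its class (the 'all' selection rule); RENN iterates ENN to a
  fixpoint; AllKNN sweeps k = 1…3. Cleaners only ever delete majority rows,
  so minority rows are never lost — also inside the hybrids.
- Tomek-link cleaning iterates until no opposite-class mutual-nearest pair
  remains (a single pass can expose new links).
- Borderline-SMOTE seeds from minority points whose 10-neighbourhood is at
  least half majority; SVM-SMOTE seeds from minority support vectors of an
  RBF SVC that are not entirely surrounded by majority points; ADASYN
  allocates synthetic counts in proportion to each minority point's majority
  neighbour share. All synthetic points are convex combinations of a
  minority point and one of its minority neighbours. When a boundary-seeding
  rule finds no usable seeds the method degrades to plain SMOTE rather than
  failing, so searches can traverse the whole space.
- SMOTEENN / SMOTETomek oversample to the requested fraction first, then
  clean.

## 4. Cost-sensitive boosting objectives

Weighted binary cross-entropy and weighted binary focal loss (minority
weight w ≥ 1, focusing parameter γ ∈ [0, 4]; γ = 0 recovers the weighted
cross-entropy exactly). Both are wired into XGBoost as custom objectives
with analytic first and second derivatives in the raw margin z (probability
p = σ(z)); the focal derivatives are stated in `losses.py` and are
unit-locked against a central finite-difference oracle (relative error
< 1e-5 over randomized (z, y, w, γ) grids) — this is the module's central
regression anchor, since the formulas are easy to get silently wrong.

The focal loss is non-convex in z and its curvature is genuinely negative
at extreme margins. Training therefore clamps the curvature at a
configurable floor (default 1e-12) for stable leaf weights; the
finite-difference comparisons are made on the unfloored values, which are
the quantity the differences estimate. Probabilities are clipped to
[1e-15, 1−1e-15]; the weight is applied inside the objective (for the
cross-entropy this is mathematically identical to per-sample weights, and it
handles the focal case uniformly). Training is single-threaded with a fixed
seed; margins start at 0 (base score 0.5).

## 5. Calibration and metrics

Platt scaling fits an unpenalised logistic regression on the log-odds of
the raw probabilities (log-odds for conditioning); isotonic regression fits
the monotone step function by pooled adjacent violators, clipped to [0, 1]
and to the fitted range outside it. Calibrators are always fitted on a
dedicated calibration fold, never on training or test rows.

Metrics: precision, recall, F1 at the 0.5 threshold (threshold-moving is
downstream policy, not part of evaluation); AUPRC by the average-precision
(rectangular) rule, avoiding the optimism of trapezoidal interpolation; and
ECE over M = 10 equal-width bins (M configurable and recorded; equal-width
chosen over equal-frequency as the more common reading, and empty bins
contribute zero). AUROC is deliberately not a selection criterion: with a
rare positive class it is deceptively optimistic. Selection is by AUPRC,
with ECE as the calibration criterion.

## 6. The joint search

A pipeline configuration is (sampling method, sampling fraction, loss kind,
minority weight w ∈ [1, 22.3], focal γ when applicable, calibration method,
booster hyperparameters). Booster ranges: n_estimators 10–350 (integer),
max_depth 3–10 (integer), learning_rate 0.1–1, subsample 0.5–1,
colsample_bytree 0.5–1.

Evaluation is stratified 5-fold CV with three roles: rotation i trains on
three folds (after resampling **only those rows**), calibrates on fold
(i+1) mod 5, and tests on fold i — one concrete realisation of the rotation,
fixed and recorded. The objective is the mean test-fold AUPRC. Failures are
soft: a degenerate configuration (e.g. a cleaner emptying a class) scores
−∞ and the search continues.

The optimizer is a factorized Tree-structured Parzen Estimator
(`tpe.py`): past trials are split at the γ = 0.25 quantile into good/bad
sets, each parameter gets truncated-Gaussian-mixture (numeric) or smoothed
count (categorical) density estimates l and g, 24 candidates are drawn from
l, and the candidate maximising l/g is suggested; the first 20 trials are
drawn from the prior. Conditional parameters (fraction only for
fraction-capable samplers, γ only under the focal loss) are sampled
hierarchically and their densities are built only from trials where they
were active.

The winner by CV1 objective is re-evaluated on CV2 — the same stratified
5-fold construction under an independent shuffle seed — so the CV1−CV2 gap
exposes search overfitting. `run_rounds` repeats the whole procedure with
distinct seeds and reports every round's winner plus mean CV2 metrics; the
winning configurations often differ between rounds while the objectives
agree closely, which is why both are reported. No early stopping is
applied; the trial log supports plotting the running best by iteration.

The manual baseline (`manual_grid`) enumerates the full factorial
{13 samplers} × {2 losses} × {3 calibrations} = 78 combinations with the
booster fixed at the range midpoints and the minority weight tuned per
combination by a short inner TPE (10 iterations by default; 0 keeps a fixed
weight) — the per-combination hyperparameter policy is otherwise
undetermined, and a short inner tune is the closest practical reading of
"trained independently". `threshold_sensitivity` re-labels drivers at a
list of ACR thresholds and reruns a fixed-budget search per threshold,
marking thresholds with fewer than k risky drivers infeasible.

## 7. Synthetic generators

**Traffic simulator.** Per-lane platoons (12 vehicles) behind a head
vehicle whose target speed carries a ±3 m/s sinusoidal perturbation
(period 25 s, random phase); followers use a time-gap-seeking proportional
controller (speed gain 0.9 s⁻¹, gap gain 0.35 s⁻²·m·s — chosen so
transients occur but ordinary drivers stay safe) with class-specific
acceleration bounds and an emergency guard that prevents overlap. Desired
time gaps: normal N(1.5, 0.3) s floored at 0.85 s; aggressive N(0.55, 0.08)
floored at 0.35 s — at 25 m/s an aggressive gap sits below the 0.7 s
reaction-time margin, so negative-DSS episodes occur for aggressive drivers
by construction while normal drivers produce only small transient risk.
Defaults: 500 vehicles, 3 lanes, 0.04 s sampling, 60 s duration, 5%
aggressive fraction (near the 4.29% risky share of the motivating
population). A 10% subset performs one lane change (4 s lateral ramp),
exercising the crossing detector and the follower-side risk term. The rule
is deliberately a simple proportional controller, not a named car-following
model: the artifact needs plantable risk and schema fidelity, not
traffic-flow realism — so passing tests show the pipeline recovers planted
risk, not that it reproduces empirical headway distributions.

**Classification generator.** Two spherical Gaussians at a controlled
Mahalanobis separation (default 3) with exact minority counts (default
fraction 1/23.3, i.e. majority/minority 22.3) and 69 features, drop-in for
the feature pipeline. It returns the analytic Bayes posterior p_true
(prior odds included) and a power-law-miscalibrated score
p_raw = p_true^(1/β) (so p_true = p_raw^β): β = 1 is calibrated by
construction; β ≠ 1 is a monotone distortion that isotonic calibration must
correct on held-out data. What it does not emulate: feature correlation
structure, non-Gaussian tails, or label noise unless requested — so
search-behaviour results on it are qualitative, not quantitative forecasts
for trajectory data.

## 8. Problem sizes and determinism

Tests and the reproduction script run at desk scale: classification
problems of 200–10,000 rows, traffic simulations of up to 500 vehicles ×
60 s, TPE budgets of 200 iterations against exhaustive grids of ~21
combinations. Every stochastic component takes an explicit seed (data
generation, resampling, booster, fold shuffles, TPE), and identical seeds
reproduce identical trials bit-for-bit under single-threaded training.

## 9. Known limitations

- The grading of "accelerating" from finite-difference acceleration is
  sensitive to the dead-band at extremely smooth trajectories.
- SVM-SMOTE here interpolates only (no extrapolative variant), which keeps
  the convex-combination invariant uniform across the SMOTE family.
- The factorized TPE ignores parameter interactions (as does the standard
  implementation it follows); on strongly coupled spaces it can be slower
  to converge than a joint model.
- The manual grid's inner weight tuning uses a small budget; its per-combination
  objectives are noisier than the headline search's.
- Isotonic regression on small calibration folds (< a few hundred rows) is
  noisy; Platt scaling is preferable there, and the search is free to pick it.
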