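# Methods

## Quasi-stiffness extraction

A trial is a stance-phase series of sagittal knee angle (degrees, flexion
positive) and internal knee moment (N·m, extension positive). Boundary
detection works on sample indices, so time-based and percent-of-stance grids
are treated identically: *b* is the global moment maximum, *a* the moment
minimum on [start, b], *c* the moment minimum on [b, end], ties broken to
the earliest sample (reading the stance left to right). Trials whose maximum
sits on a series boundary or whose stages have fewer than 3 samples fail
segmentation and are excluded from modeling, with the reason logged.

Stage stiffnesses are OLS slopes of moment on angle (angle converted to
radians, so K is in N·m/rad) over the inclusive index ranges [a, b] and
[b, c]. Moment is the regressand because quasi-stiffness is dM/dθ.
The weight-acceptance stiffness is defined as the arithmetic mean of the two
stage slopes rather than a single fit over [a, c]: the extension stage is
longer, and a single fit would be dominated by it. Excursions are reported
as magnitudes in degrees; the weight-acceptance excursion is the mean of the
stage excursions. Both averaging identities hold bit-exactly by
construction.

No smoothing is applied by default. An optional centered moving average
(`smooth_window`) can be applied to the moment trace *before boundary
detection only* — fits always use raw samples — for noisy measured data.
Fits are performed on the raw samples between the detected points, so the
slope estimate depends on the sampling density of the series.

## Predictor basis

The pseudo-static moment model M_b ∝ W·H·poly(V) together with near-linear
stage behaviour K ≈ M_b/Δθ motivates the default seven-term basis
{WH/Δθ, WHV/Δθ, WHV²/Δθ, WH, WHV, WHV², Δθ} plus intercept. The basis is
data, not code: any list of (WH, V, Δθ) power products can be supplied via
`BasisSpec` (YAML-loadable), with the Δθ exponent restricted to {−1, 0, 1}.
Δθ enters in radians for dimensional consistency. Each response uses its own
stage excursion (Δθ_flex for K_flex, Δθ_ext for K_ext, Δθ_wa for K_wa).

Froude quantities: Fr = V²/(g·l) with leg length l = 0.53·H (standard
anthropometric ratio) and g = 9.81 m/s². The preferred-speed Froude number
defaults to 0.25, the dynamic-similarity value for self-selected walking;
it is a parameter, not a constant, because empirically the flexion and
extension stiffnesses cross at a somewhat lower Froude number (≈ 0.21 in
the reference cohort).

## Model fitting and validation

OLS is fit on raw predictor scales (statsmodels), so coefficients drop
directly into design formulas; classical SEs and two-sided t p-values are
reported. Backward elimination removes the single largest-p non-intercept
term with p > α (default 0.05) per refit until all retained terms are
significant; the intercept is never removed but its p-value is reported. A
rank-deficient design raises an error naming the collinear terms; if every
term is eliminated an intercept-only model is returned with a warning.

Cross-validation is stratified by subject — all trials of one subject held
out together, preventing leakage across a subject's repeated speeds. For
each fold and component count k, a PLS1 model (scikit-learn NIPALS,
predictors and response z-scored within the training fold) is fit and the
held-out trials predicted; PRESS(k) sums squared held-out residuals over
folds, the optimal k minimizes PRESS (ties to fewer components), predicted
R² = 1 − PRESS/SS_tot. Folds with a constant training response are skipped
with a warning. Both the mean training R² at the optimal k and the predicted
R² are reported, since the two can differ substantially.

Prediction error is the mean over trials of |predicted − observed|/observed
× 100, excluding (with a warning) trials with zero observed stiffness.
Outliers are flagged as |externally studentized residual| > 3 and never
auto-removed; fits whose residual mean square is at rounding level relative
to the response scale flag nothing, since studentization there divides
noise by noise.

## Stature reduction

Each retained term c·(WH)^e·V^p·Δθ^d maps under V → √(Fr_opt·g·0.53·H),
Δθ → mean Δθ to c·(Fr_opt·g·0.53)^{p/2}·(meanΔθ)^d·(WH)^e·H^{p/2}; the
intercept passes through. The reduction is exact: the stature model at
(W, H) equals the parent model at (W, H, V_opt(H), mean Δθ) to rounding.
The default mean excursion is the cohort value 16.5°; per-stage means are
configurable and the pipeline uses the dataset's own stage means. The
average-value baseline predicts every trial by the dataset-mean stiffness.
Model families are compared on the single trial per subject whose speed is
closest (in absolute m/s; ties to the slower trial) to the preferred speed.

## Synthetic cohort

The generator reproduces the study design the models are meant for: 14
subjects (9 treadmill × 4 speeds evenly spaced on 0.75–2.00 m/s; 5
overground × 20 speeds evenly spaced on a per-subject range drawn within
1.01–2.63 m/s), W ~ N(72.5, 11.5²) kg truncated to [50, 100], H ~ N(1.70,
0.13²) m truncated to [1.40, 1.90] (the 0.13 SD is the value consistent
with the reference cohort's individual heights), weight-acceptance
excursion ~ N(16.5°, 4.4°²) truncated positive, drawn per trial.

True stage stiffnesses follow a global linear model in three basis terms,

    K_stage = a_stage·WH/Δθ + b_stage·WH·V/Δθ + c·WH,

with b_flex = 0.12 > 0 (flexion stiffness rises with speed) and
b_ext = −0.04 (mild decrease), a shared WH coefficient c = 1.30, and
a_flex = 0.10; a_ext is derived so that the two stages cross at the
preferred speed for Froude 0.22 at the reference height 1.70 m. Sharing the
WH term makes the crossing speed common to all subjects, which keeps the
generating coefficients global (recoverable by a single pooled regression)
while the per-subject crossing Froude numbers spread over ≈ 0.20–0.26 with
1/H, matching the spread observed across real subjects. A strictly constant
per-subject crossing Froude number would instead require subject-specific
coefficients and no global truth. The default coefficients place the cohort
stiffness distribution inside the reference envelope (81–745 N·m/rad; ≥99 %
of trials at the default noise level) with means near the reference cohort's
(≈ 300 N·m/rad).

Each loop is sampled on 101 stance points. Boundary indices are drawn at
5–11 % (a), 30–40 % (b) and 55–65 % (c) of stance; the moment rises
linearly in angle from (θ_a, 0.05·M_b) to (θ_b, M_b) and returns linearly
to (θ_c, M_c), with a falling lead-in and rising lead-out so a, b, c are
interior extrema; flexion and extension excursions are equal within a
trial. Gaussian noise with SD 3 % of the trial's peak moment is added to
the moment only — the angle is treated as the precise measurement, matching
the moment-on-angle fit direction. An optional curvature parameter (default
0) bends the stages to stress-test R² reporting. Everything is reproducible
from a single integer seed.

What the generator does *not* emulate: within-stage physiological
nonlinearity and hysteresis, angle measurement noise, soft-tissue and
marker artifacts, inter-lab processing differences, and any dependence of
excursion on speed. Passing recovery tests therefore demonstrates that the
pipeline estimates what it claims under the model's own assumptions, not
that real knees are piecewise-linear springs.

## Validation experiments and problem sizes

All Monte-Carlo utilities take an explicit seed (default 20130322) and
derive replicate seeds from it. The standard experiment sizes are: 136-trial
cohorts; 200 replicates for stepwise recovery and planted-noise type-I
checks (100 in the acceptance script); 20 seeds for crossing-Froude
recovery; 50 seeds for the model-family comparison.

Known behaviour worth stating plainly: under the default 3 % moment noise,
backward stepwise selection retains at least one inactive basis term in a
substantial fraction of replicates. Three effects compound: (i) with four
inactive terms at α = 0.05, selection arithmetic alone retains a false term
in ≳ 19 % of replicates even under ideal conditions; (ii) the stiffness
noise is multiplicative (noise scales with the peak moment), so classical
homoscedastic p-values are anti-conservative; (iii) noise shifts the
detected extrema by about a sample, producing excursion errors correlated
with the stiffness errors (errors-in-variables) that bias coefficients by
several of their very small SEs. A two-predictor experiment with clean
design shows the nominal ≈ 5 % type-I rate, and the noiseless pipeline
recovers generating coefficients to ~1e−15, isolating the causes to the
study conditions rather than the fitting machinery. Users doing inference
on real data should treat stepwise p-values as descriptive.

## Limitations

Level walking only; weight-acceptance phase only (no stance-termination or
swing modeling, no mechanical work/hysteresis computation); pooled OLS with
no per-subject random effects; published coefficient values are not
reproduced because the original trials are unavailable — the pipeline is
validated by parameter recovery instead.
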