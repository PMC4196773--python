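# Methods

## The second-order autoregulation model

The Aaslid–Tiecks model treats the normalised pressure deviation
`dP = (ABP − ABP_base)/(ABP_base − CrCP)` as the input to a discrete
second-order system with time constant `T` (s), damping `D` and gain `K`
(see the recursion in the README). `K` scales the only corrective term, so
`K = 0` is a purely passive response (flow follows perfusion pressure) and
`K → 1` full restoration; for a sustained unit pressure drop the fixed point
of the recursion is `CBFV_base·(1 + (1−K)·dP)`, i.e. the output settles at
`K` in drop-normalised units. Ten canonical `(T, D, K)` combinations grade
ARI 0–9; grades 5–9 are underdamped (`D < 1`) and overshoot the baseline.

The canonical table is bundled as constants (it predates this package and
is reproduced from the original model description). The state recursion is
forward-Euler at the working rate; at 5 Hz and `T = 0.65` s (`f·T = 3.25`)
the discretisation is coarse and the ARI-9 overshoot is larger than the
continuous-time solution's. We deliberately generate the standardisation
templates with the *same* 5 Hz recursion that the classic estimators use on
real 5 Hz data, so templates and measurements share one discretisation.

`T`, `D` and `K` are interpolated to the 0.1-ARI grid with a not-a-knot
cubic spline through the ten nodes (natural splines available via
`bc_type`); node values are reproduced exactly and the interpolated `K` is
clipped to [0, 1].

## Measuring the model-free parameters

All measurements run on drop-normalised signals: baseline = mean over the
4 s before release, zero = the post-release minimum, located within 6 s
(CBFV) or 2 s (ABP) of release. The minimum search *includes* the release
sample: for an ideal step stimulus the true minimum is the release instant
itself, and excluding it renormalises every template. Ties go to the
earliest sample.

The two-line characterisation scans every breakpoint `τ` on the sample grid
in `[t_min + 0.4 s, t_min + 10 s]`:

* transient line: unconstrained least squares over `[t_min, τ]`, endpoints
  included;
* steady line: the constant `CBFV(τ)` over `(τ, τ + Δt_S]`;
* score: pooled MSE (total squared error of both segments over the total
  sample count).

Exact score ties are resolved toward the **largest** `τ`: a perfectly flat
response (no recovery at all, ARI 0) ties at every breakpoint, and the
longest admissible transient is the physically meaningful description of a
response that never reaches a steady state. This convention also makes the
template `Δτ` range come out as [1.20 s, 10.00 s] — the fastest grade sets
the minimum, the flat grade sits at the search cap — matching the published
parameter bounds.

`φ` is the difference of arctangent angles (degrees, slopes in normalised
units per second) between the CBFV transient line and the least-squares ABP
recovery line over `[t_min_ABP, t_min_ABP + Δt_ABP]`; each angle is clamped
to [0°, 90°] before subtraction, so a falling CBFV transient contributes 0°.

### Calibrated window lengths

Two window lengths are not derivable from first principles and were
calibrated once against the published descriptive statistics of the 91
template parameters:

* `Δt_S` (steady window) = **7 s**. A grid scan over 2–12 s showed 7 s
  reproduces the template statistics essentially exactly (mean `k_S` 0.689,
  max 1.068; mean `Δτ` 6.189 s, min 1.20 s, max 10.00 s; R² 0.998); shorter
  windows bias `Δτ` low.
* `Δt_ABP` (ABP recovery segment) = **2 s**, the same span as the ABP
  minimum search; it has no effect on step-stimulus templates and only a
  mild smoothing effect on real recovery slopes.

Both are `Config` fields and can be changed; the standardisation model
records the configuration it was fitted under, and bounds always come from
the same template set as the coefficients.

## Standardisation

Ordinary least squares of the generating ARI on `(k_S, Δτ, φ)` over the 91
templates (statsmodels OLS; coefficients, R², per-coefficient t statistics
recorded). Before evaluation each parameter is clamped to its
template-derived (min, max); the result is clipped to [0, 9]. The package
also ships the published coefficient vector `(1.631, 3.751, −0.137, 0.099)`
with its published bounds (`published_model()`), so users can score data on
the established scale without refitting.

**Identifiability caveat.** The three parameters are nearly collinear over
the templates (each is a smooth monotone-ish function of ARI), so the
*individual* OLS coefficients are poorly identified even though the fitted
index is very stable: perturbing the measured parameter curves by ~0.035 in
`k_S`, ~0.12 s in `Δτ` (below one 5 Hz sample) and ~0.8° in `φ` is enough
to move the optimum from this package's refitted vector
`(−0.082, 4.420, 0.024, 0.115)` to the published one at R² 0.997. The two
vectors produce index values that agree to ≈0.25 RMS over the full
template range. Quantities that survive this ill-conditioning — R², the
parameter descriptive statistics, the fitted index itself (template
self-consistency RMSE 0.12, max error 0.31) — are the meaningful
reproduction targets; individual coefficients are not. Refit-based results
in this package therefore use the refitted vector, and comparisons on the
published scale use `published_model()`.

## Classic estimators and RoR

The least-squares classic ARI drives the model with the observed ABP
(baseline from the 4 s pre-release window, CrCP 12 mmHg), scales templates
by the observed CBFV baseline, and picks the grade minimising MSE over
`[t0, t0 + 16 s]`; the candidate set is the ten canonical grades by default
(the 0.1 grid optionally). The correlation variant works on drop-normalised
signals (no CrCP needed), maximises Pearson correlation over the ten
grades, and refines interior maxima with a parabola through the three
neighbouring correlations; the vertex of an interior maximum always lies
within half a grade, so rounding recovers the integer grade exactly on
noiseless data. Boundary maxima are returned unrefined.

RoR follows the original definition: per-channel baseline normalisation,
`CVR = ABPn/CBFVn`, OLS slope over the 14 samples in `[t0+1, t0+3.6]` s,
divided by the ABP drop. The phrase "the magnitude of the ABP drop,
calculated as the normalised mean ABP during the same interval" admits two
readings; the headline value uses `drop = 1 − mean(ABPn)` (the original
definition) and the literal alternative `drop = mean(ABPn)` is always
reported alongside (`ror_literal`). With CVR defined pressure-over-flow the
slope is *negative* for an intact response, zero for a passive one; the
magnitude grows with the autoregulation grade up to ARI ≈ 7 under an ideal
step, then saturates — the fast response is largely finished before the
1–3.6 s window opens, and the ARI-9 overshoot can even flip the sign. This
saturation is a property of the measure, not of the implementation.

## Reliability statistics

Unbiased CoV per subject: `(1 + 1/(4n))·sd/mean·100`. SEM is
`sqrt(SS_within/df)` from the one-way repeated-measures decomposition, with
missing cells handled by pooling squared deviations from each subject's own
mean over available cells and `df = N_obs − n_subjects`; for balanced
complete tables this is exactly the classical within-subject mean square.
Subjects with fewer than two recorded repetitions are dropped. Bland–Altman
reports the mean difference and `bias ± 1.96·sd` limits. Group hypothesis
tests (t-tests, ANOVA omnibus, post-hoc) are standard statsmodels/scipy
calls and deliberately out of scope.

## The synthetic generator

`SimSpec` encodes one manoeuvre: 30 s at 5 Hz, release at 5 s, 90 mmHg ABP
baseline with a 25 % drop (≈22 mmHg, a typical thigh-cuff response),
55 cm/s CBFV baseline, CrCP 12 mmHg. The stimulus is an ideal sustained
step by default — the condition the standardisation templates assume — with
optional exponential recovery toward baseline (`abp_recovery_rate`). CBFV
is the model response at the spline-interpolated parameters for a
*continuous* true ARI. Noise is additive white on the 5 Hz beat-mean
series, scaled to each channel's drop amplitude; a raw-recording variant
adds a per-beat raised half-sine pulse (zero at the diastolic onset) purely
to exercise beat detection. Cohorts draw subject-level ARI
`N(5, between_sd)` and per-repetition jitter `N(0, within_sd)`, both
clipped inside the scale; the returned table holds the per-repetition true
values so SEM recovery can be checked against `within_sd` directly, and the
labelled manoeuvres can be re-scored by any index.

What the simulator does *not* emulate: reflected pressure waves,
respiratory and CO₂ modulation, Doppler spectral noise, probe artefacts,
heart-rate variability, or any mismatch between the true physiology and
the second-order model (the simulated CBFV *is* a model response).
Passing tests therefore show correctness of the algorithms and their
statistical behaviour under the stated noise model — not clinical validity
on real recordings. In particular the classic estimators are unrealistically
stable here (the data come from their own template family), which makes the
simulated reliability advantage of the model-free index a conservative,
directional check only.

## Numerical conventions and degenerate inputs

Time is in seconds from the start of the series; `t0` is always explicit.
Filtering is forward-backward (zero phase), so beat timing is unshifted and
the effective magnitude response is the squared Butterworth response. Beat
detection uses local minima under a rolling-median threshold with a 0.3 s
refractory period; inter-beat intervals outside 0.3–2.0 s raise a warning.
Per-beat means are placed at cycle onset times (this preserves the time of
the post-release minimum to within one output sample through the full
chain) and splined to the 5 Hz grid without extrapolation. A drop amplitude
at or below tolerance raises a no-drop error; flat signals make the
correlation variant raise a degenerate-input error rather than guess; model
state divergence (T too small for the rate) raises a numeric-instability
error. The standardisation model serialises to JSON bit-exactly.

## Problem sizes

Default analyses are small: 91 templates × ≈50 breakpoint candidates for a
standardisation fit (≈1 s), and the simulated-cohort checks use 16×6 to
50×6 designs with 200-replicate noise studies — sizes chosen to mirror the
study design while keeping the full suite interactive.
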