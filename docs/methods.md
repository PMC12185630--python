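# Methods

## Shrinkage model

For k participants with scalar MLEs y_i and per-participant error variances
σ_i², the James–Stein estimate is z_i = ȳ + c (y_i − ȳ) with

    c = 1 − SE̅² (k − 3) / Σ (y_i − ȳ)²,    SE̅² = mean(σ_i²).

Unequal variances are always averaged into SE̅² (a deliberate simple
heuristic; no precision-weighted variant is offered). Two algebraic
identities follow directly and are enforced as tests: the shrunk estimates
keep the grand mean exactly, and their sample variance is c² times the MLE
sample variance. c ≤ 1 always; the positive-part variant clips c < 0 to 0
and is the default, with a flag exposing the raw estimator (used by the
dominance property test, since the positive part dominates the raw JSE).
Cohorts with k < 4 are rejected outright rather than silently returning the
MLEs: the factor needs k − 3 > 0, and shrinkage guarantees degrade badly for
tiny cohorts anyway. Zero spread between estimates (division by zero in c)
is an error, not a fallback.

Risk is compared as summed squared error from truth across the cohort; the
percent reduction is defined as 0 in the degenerate case SSE_MLE = 0. The
reported p-value is a two-sided paired t test on the k pairs of
per-participant *squared* errors; squared (not absolute) errors were chosen
because SSE is the quantity being compared.

## Per-participant estimators

**Foot-placement gain.** Per step: midstance pelvis state
P = (X_pelvis, Ẋ_pelvis, Ẏ_pelvis) and next stance-foot position
S = (X_foot, Y_foot). The model ΔS = J ΔP is fitted by OLS in deviation
form: both sides are centered on their means over the *truncated* window
(the MLE must use only the short-duration data) and regressed without an
intercept. Residual degrees of freedom are n − 4 (three slopes plus the
implicit mean); coefficient variances use the homoskedastic OLS formula.
Row/column convention: rows (X_foot, Y_foot), columns (X_pelvis, Ẋ_pelvis,
Ẏ_pelvis), so the shrunk scalar — the sideways-foot response to sideways
pelvis velocity — is J[0, 1]. At least 7 steps are required; rank-deficient
designs are an error.

**Walking metabolic rate.** Breath-wise power from the Brockway conversion
Ė = 16.58 V̇O₂ + 4.51 V̇CO₂ (W/kg with fluxes in mL s⁻¹ kg⁻¹). The steady
state is the asymptote a₀ of Ė = a₀ + a₁ e^(−t/τ), fitted by bounded
nonlinear least squares (scipy trust-region reflective) on the first n
breaths, n ≥ 5. Initialization: a₀ = mean of the last third of the window,
a₁ = first sample − a₀, τ = span/3, with τ bounded in (0, 10·span] and up to
5 jittered-τ restarts on failure; a fit that still fails is returned with
converged = False and the participant is excluded from a sweep (k held
constant across the grid). Breaths are weighted equally regardless of
breath duration, and truncation is by breath count, not elapsed time.

The SE of a₀ is a case-resampling bootstrap (resample breath indices with
replacement, refit; 1000 reps by default, seeded substreams per
participant). The spread across replicates is summarized by the
normal-consistent median absolute deviation rather than the plain standard
deviation: a small fraction of resampled sets lose the early transient,
drive τ to its bound, and extrapolate an absurd asymptote, and those few
refits otherwise dominate the SE (measured ~3× inflation of the plain SD at
n = 54 with default noise, versus a 1.07 ratio to the fresh-noise
Monte-Carlo sd for the MAD). MAD was preferred to the IQR for its higher
breakdown point; both calibrate equivalently.

**Resting metabolic rate.** The per-participant estimate is the mean Ė over
the first n breaths. A single SE is shared by the whole cohort: center each
participant's truncated series, pool the deviations across participants,
and bootstrap the SE of a mean of n draws from the pool. Constant series
give SE = 0 exactly.

## Truncation sweep

Truth is the estimate at the full-trial length (100 steps, or 54/40
breaths); MLEs are recomputed from the first n samples for each grid value,
shrunk across participants, and scored against truth. On synthetic cohorts
the generator's true parameters are also known, so both comparisons are
emitted (`pct_reduction` vs proxy truth, `pct_reduction_true` vs generator
truth). Near the full trial length the proxy-truth comparison can go
negative: with nested first-window truncation the full-trial estimate is the
efficient combination of the short window and the remainder, so the actual
error of the MLE relative to proxy truth is much smaller than its
infinite-data error variance, and shrinkage calibrated to the latter
overshrinks. This is a property of finite proxy truth, not of the
estimator; the generator-truth columns show the genuine (small, positive in
expectation) improvement in that regime.

Truncation is always the first window — no sliding or averaged windows — and
participants excluded at any length are excluded from the whole sweep so
that k is common to every grid value. The SSE decay summary fits
SSE_JSE = a₁ e^(−b₁ n) by OLS on log(SSE) (only defined when all SSEs are
positive). The shrinkage-factor trend is reported as the Spearman
concordance of c with n, with adjacent decreases flagged; a constant c has
no defined rank trend and is reported as "no trend". The whole sweep is
bit-reproducible given (seed, config): bootstrap randomness comes from
per-(length, participant) substreams spawned from the config seed.

## Synthetic cohorts

Each generator draws a per-participant true parameter from
Normal(between_mean, between_sd²) and emulates the within-participant
sampling process:

* **Stepping** (defaults: k = 8, gain 0.25 ± 0.08 between participants,
  100 steps): pelvis-state deviations ΔP ~ Normal(0, diag(0.01², 0.05²,
  0.05²)) (m, m/s — typical midstance pelvis variability on a treadmill),
  ΔS = J ΔP plus residual noise of sd 0.01 m, absolute coordinates rebuilt
  around a 1.3 m/s forward velocity and 0.72 m step offset. These defaults
  give regression R² ≈ 0.6 and a 25-step shrinkage factor around 0.8,
  resembling a healthy-adult cohort.
* **Walking metabolics** (defaults: k = 11, a₀ = 4.5 ± 0.4 W/kg,
  a₁ = −2.0 ± 0.3 W/kg, τ = 30 ± 5 s redrawn until positive, 6.5 min):
  breath times from a gamma renewal process (mean interval 2.2 s, CV 0.2 —
  any positive-interval process would do; this one reproduces the imperfect
  proportionality between breath count and elapsed time), additive noise
  sd 0.3 W/kg, power clipped at zero, then split into V̇O₂/V̇CO₂ with a
  constant respiratory exchange ratio 0.85 by inverting the Brockway
  equation so the conversion round-trips exactly.
* **Resting** (defaults: k = 27, 1.2 ± 0.15 W/kg, noise sd 0.25 W/kg):
  constant power plus noise at the same breath process.

Within-participant noise magnitudes are plausibility defaults validated by
self-consistency (coverage and calibration tests), not measured values; all
scales are config-overridable. What the generators deliberately omit:
step-to-step autocorrelation and drift in gait, slow metabolic drift and
non-exponential kinetics components, RER variation within a trial, and any
marker-level measurement process. Passing tests therefore demonstrate the
statistical machinery — shrinkage identities, risk dominance, bootstrap
calibration, sweep trends — under the assumed hierarchical Gaussian
structure, not robustness to real-data pathologies such as population
heterogeneity (for which clustering before shrinkage is the usual advice).

## Problem sizes and numerical choices

Monte-Carlo checks use 2000 replicates for the Gaussian dominance study,
200 seeded cohorts for the sweep-shape study, 500 fresh-noise refits against
a 1000-rep bootstrap (averaged over 10 realizations) for SE calibration, and
100 replicate cohorts in the acceptance report; these sizes put Monte-Carlo
error well below the effects being checked while keeping a laptop run in
minutes. Floating-point identity checks use 1e-12 relative tolerance
(scaled by data magnitude); noiseless-recovery checks 1e-10 (linear
algebra) and 1e-6 relative (nonlinear fit). Degenerate inputs are decided,
not left to chance: identical estimates and k < 4 are errors, a constant
metabolic series fits a₀ = mean with a₁ ≈ 0, and an all-duplicate bootstrap
draw (no time span) is discarded.

## Known limitations

Only one scalar is shrunk per problem; the full 2×3 Jacobian is never
shrunk jointly (no multivariate JSE). Empirical-Bayes, isotonic, and
pretest alternatives are out of scope. The CLI reads only the package's own
CSV dialects; raw motion-capture or calorimetry exports must be converted
upstream. Real recorded cohorts can be analyzed by writing trials in the
documented CSV dialects and running `estimate`/`shrink`/`sweep` on them.
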