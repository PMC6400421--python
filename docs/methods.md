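# Methods

`serialbias` models serial dependence in perceptual reports: the systematic
attraction of a current judgment toward (or repulsion away from) recently
seen stimuli and recently made decisions. The package has two halves that
feed each other: mechanistic population-coding simulators that *generate*
biased behavior, and a statistical pipeline that *measures* bias in
trial-level behavioral tables — synthetic or real.

## 1. The DoG model of serial dependence

Trial errors `y_ij` (subject *i*, trial *j*) are modeled as a first
derivative of a Gaussian of the wrapped previous-minus-present difference
`x_ij` (previous stimulus, ΔS, or previous response, ΔR; degrees in
(−90, +90]):

    y_ij = x_ij · α_i · w · c · exp(−(w·x_ij)²) + e_ij
    α_i  = α₀ + u_i,   u_i ~ N(0, σ_u²),   e_ij ~ N(0, σ_e²)

`α_i` is the curve's peak height in degrees (attractive bias > 0), `w` the
inverse width in 1/degrees (peak at ±1/(w√2)), and `c = √2·e^0.5` the
constant that makes α equal the peak height exactly. Only the amplitude is
random over subjects; the width is a shared fixed effect (random widths
contribute next to nothing and the reduced model is preferred by model
selection in this literature).

**Estimation.** At fixed `w` the model is linear in the amplitude, so the
package maximizes an exact profile likelihood: for each `(w, λ)` with
`λ = σ_u²/σ_e²`, the amplitude and σ_e² have closed GLS forms through a
rank-1 Woodbury identity per subject; a 2-parameter Nelder–Mead search (4
starts, `w` started at 0.05) does the rest. This replaces a generic
first-order NLME approximation with an exact computation for this model
class; a test verifies agreement with `statsmodels` MixedLM on the
linearized model at the optimal width.

**Width bounds.** `w` is searched in [0.008, 0.15] by default, i.e. the
curve's peak constrained to lie between ≈4.7° and ≈88°. Outside that range
the amplitude — the height of a peak where no data exist — becomes an
unbounded extrapolation: on a 10°-spaced predictor grid, a fit with
`w = 0.27` can report α ≈ −200° while the fitted curve never exceeds 0.4°.
Empirical widths for this task family cluster around 0.02–0.06, well
inside the bounds.

**Inference.** The group amplitude is tested with `z = α₀/SE`, but the
p-value is referenced against a t distribution with `n_subjects − 1`
degrees of freedom, and the SE comes from the joint observed information
over (α₀, w, log λ). Two deliberate deviations from the common
normal-reference/conditional-SE recipe, both forced by calibration: under
the null the width carries no information (the profile scans a family of
basis shapes — a Davies-type problem), and the nominal z-test rejects a
true null ~12% of the time at the 5% level. With the joint information and
the subject-level t reference, the empirical type-I error is ≈0.04–0.05
and 95% CIs cover generating amplitudes in >90% of replications (both are
asserted in the test suite at 1,000 and 50 replications respectively).

**Conditional variant.** For designs with two trial classes (e.g. whether
the previous trial required a report), the model carries independent
amplitudes α (class 0) and k (class 1) with independent subject random
effects, and their difference is tested with
`z = (α−k)/√(SE_α²+SE_k²)` against the standard normal. The width is
shared across classes by default: a class with no real effect cannot pin
its own width, and its amplitude would be unidentified (an optional
`width_offset` adds a bounded per-class width perturbation, |z_w| ≤ 0.1).

## 2. Population-coding simulators

Both data-generating models share a three-stage architecture:

1. **Encoding** — 180 orientation channels, preferred orientations 0–179°,
   tuning `r(θ) = A·exp(β(cos(Δ)−1))` with β = 4.68 and unit base
   amplitude.
2. **Decision** — a readout unit computing the weighted circular mean of
   preferred orientations, weights = channel response × readout weight
   vector `W` (initially uniform, 1/180 ≈ 0.0056). Decoding is invariant
   to rescaling of `W`.
3. **Response** — the decoded orientation plus Gaussian report noise
   (σ_ω = 10° by default, giving a mean absolute error ≈ 8°).

**Gain model (attractive).** After each stimulus the encoding amplitudes
become `G = 1 + α_g·exp(β(cos(Δ to previous stimulus)−1))`: channels tuned
near the previous orientation become more responsive, pulling the next
decode toward it. Readout weights stay uniform.

**Two-process model (repulsive + attractive).** Encoding amplitudes become
`A = 1 − α_g·exp(...)` (classical adaptation; repulsive), while after every
*report* the decision unit re-centers a readout template
`w_j ∝ c + α_w·exp(β_w(cos(X − R_j)−1))` (normalized to sum 1, offset
c = 0.1) on the reported orientation and folds it into the running weights
`W ← W·W_decay + w_j`. No report (catch trial), no update. The persistence
of decisional templates is what produces attractive serial dependence in
this model, and it follows decisions rather than stimuli.

**Angle conventions.** Orientation has period 180°, so the tuning,
gain/adaptation and decoding cosines operate on doubled angles (0° and
179° are near neighbors; the decoder doubles, averages, halves back). The
decisional template instead uses the identity cosine on degrees: its
quoted concentration β_w = 24.5 corresponds to a circular SD of ≈11.6° on
that convention (doubling would halve it), and the doubled-template variant
produces far too little attraction at the calibrated operating point. Both
mappings are switchable per component (`angle_mapping`,
`template_angle_mapping`), and `beta_to_fwhm`/`fwhm_to_beta` convert
between concentration and width under either convention. No standard width
definition reproduces a quoted full width at half height of 28.2° for
β = 4.68 exactly (doubled-angle FWHM ≈ 31.6°, identity-convention circular
SD ≈ 28.3°); the helper is provided rather than forcing agreement.

**Template center.** The template is centered on the actual (noisy)
report, not the noise-free decode (`template_center="response"`,
switchable). This is the configuration in which the model reproduces the
signature result it exists to explain: in replicas of the adjustment
experiments, the ΔR model fits and predicts better than the ΔS model
(rmse(ΔS) − rmse(ΔR) > 0 in essentially every iteration, fitted
α_ΔR ≈ 1.7 vs α_ΔS ≈ 1.1). Centering on the pre-noise decode reverses
that asymmetry. The cost is visible at the published operating point: with
the forgetting factor engaged (W_decay = 0.19) the simulated ΔS amplitude
is ≈1.0–1.1°, below the 1.35° calibration target, which the model does
meet under the calibration conditions themselves (no forgetting,
≈1.45–1.5°). We prefer the configuration that preserves the model's
central qualitative property over one tuned to a single printed value.

**Memory depth.** Gain/adaptation profiles are recomputed each trial from
the immediately preceding stimulus only (one-back), as the update rules
reference only θ_{n−1}; an `accumulate` mode (profiles summed with an
exponential recovery factor) is available for exploring sequence designs.

## 3. Calibration (three steps) and replicas

- **Step 1 — gain sweep.** For a grid of α_g (default 50 points in
  0.05–0.95), simulate 10,000 standard-grid trials per point with the
  decision stage off and fit the DoG on ΔS. Gain yields positive,
  adaptation negative amplitudes, both monotone in α_g. At α_g = 0.33 the
  gain model produces ≈ +1.2°, adaptation ≈ −1.7°; at α_g = 0.14
  adaptation alone gives ≈ −0.8°.
- **Step 2 — template grid.** With adaptation fixed at α_g = 0.14 and no
  forgetting, grid-search (α_w ∈ [0,1], β_w ∈ [1,50] log-spaced; reduced
  25×25 grid) minimizing the squared distance between the per-ΔS-level
  mean simulated error and a target DoG(α = 1.35°, w = 0.05). Common
  random numbers are used across grid points. At 5,000 trials per point
  the argmin is stable at α_w ≈ 0.083, β_w at the wide end of a shallow
  valley (the objective is nearly flat in β_w beyond ≈25). At 2,000
  trials per point the argmin can flip to the adjacent grid point
  (0.0417); the acceptance run therefore uses 5,000.
- **Step 3 — forgetting factor.** Given a reference single-trial error
  sequence (synthetic by default), sweep W_decay over a grid and minimize
  the squared distance between reference and noise-free model errors on
  the same stimulus sequence. The decay signature is subtle relative to
  10° report noise, so the packaged recovery test uses a low-noise
  (σ = 2°) synthetic reference, which recovers a generating decay of 0.19
  to within ±0.05 at 5,000 trials.

**Replicas.** `replicate_exp12` simulates artificial subjects on
constrained-walk orientation sequences and compares ΔS vs ΔR fits per
iteration; the two-process model reproduces ΔR superiority, the gain model
does not (differences centered at 0). `replicate_exp5` simulates
six-stimulus sequences (five unreported items then a report) and fits the
conditional DoG on (a) the current sequence's last unreported stimulus and
(b) the previous trial's reported stimulus: two-process yields repulsion
from (a) and attraction toward (b); gain yields attraction to (a) and
nothing for (b).

## 4. Synthetic behavioral data

The generator reproduces the trial *structures* of the eight designs
(orientation grids with consecutive-difference constraints implemented as
a balanced shuffled-multiset random walk; 40% catch trials; six-item
sequences with 20% truncated attention checks; randomized contrasts; dot
ensembles and retro-cued dot arrays) and generates responses as
stimulus + DoG serial term + optional sum-of-three-sinusoids orientation
bias + Gaussian noise, wrapped to [0, 180). With `predictor="delta_R"`
generation is sequential so each response feeds the next trial's
predictor. RTs are log-normal (median 2.2 s, log-SD 0.5, matching the
reported 2.23 ± 1.26 s scale) with an optional contaminant fraction (fast
<200 ms and extreme slow values) for filter testing. Size tasks generate
errors as configurable linear combinations of ΔS/ΔR/ΔC plus a
miscalibration slope.

What the generator does *not* emulate: real oblique-effect bias shapes
(the injected sinusoid family is exactly the residualization family, so
removal can be exact — real biases are only approximately sinusoidal),
RT–accuracy coupling, lapses/guessing, learning or fatigue drifts, and any
spatial structure. Passing recovery tests therefore demonstrate estimator
correctness under the stated noise model, not robustness to every
idiosyncrasy of human data.

## 5. Preprocessing

Errors are wrapped to ±90°, trials with RT < 200 ms or |z(RT)| > 3.5
(per subject) are removed *along with the immediately following trial*
(iterated to a fixed point, which makes the filter idempotent), errors are
demeaned per subject, and an iterative two-sided Grubbs test (α = 0.05,
t-based critical value) prunes residual outliers per subject. Orientation
response bias is residualized per subject by a robust sum-of-three-
sinusoids fit on normalized orientation (FFT-seeded multistart; points
beyond ±3 SD down-weighted to 0.1; fourth-degree-polynomial fallback on
non-convergence), after which the response and ΔR columns are rebuilt from
the residual errors. Size bias is residualized by a per-subject linear
fit of error on size. A permutation test against shuffled stimulus–response
pairings screens for at-chance performance.

## 6. Model comparison

ΔS vs ΔR is decided by (i) a Monte Carlo permutation test on the
difference in fit rmse (predictors independently permuted within subject;
two-sided exceedance p with add-one correction), (ii) subject-stratified
70/30 cross-validation scored by test-set rmse using fitted subject
amplitudes, (iii) for orthogonal predictors, a resampled two-predictor
general-dominance analysis (75% subject-stratified subsamples restricted
to |Δ| ≤ 40°, random-intercept mixed models, marginal-R² contributions)
and (iv) AIC plus a Vuong-style standardized per-observation
log-likelihood comparison for equal-dimension non-nested linear models
(an ordinary χ² LRT degenerates there). The dominance inner loop uses a
fast closed-form profiled random-intercept solver (rank-1 Woodbury,
1-D variance-ratio search) that is cross-checked against statsmodels
MixedLM in the tests; user-facing linear mixed fits go through MixedLM.

## 7. Forced-choice analyses

Yes/No "vertical" responses are converted to hit/false-alarm rates per
Deviation × SNR × Congruency cell with the 1/(2N) extreme-rate correction,
d′ = z(hit) − z(FA) and criterion c = −(z(hit)+z(FA))/2. d′ feeds a
random-intercept linear model with Deviation (absolute, since d′ cells
collapse signed tilts), SNR and their interaction, fitted separately per
congruency condition. Baseline-corrected sensitivity compares congruent
per-SNR d′ (collapsed over Deviation) against the incongruent grand mean,
with a paired t-test between SNR extremes. Raw proportion differences
(incongruent − congruent) per signed tilt are fitted with the conditional
DoG across the two SNR conditions of interest.

## 8. Reproducibility and problem sizes

Every stochastic routine takes an explicit seed; simulations are
bit-reproducible given one. The pipeline writes a manifest with derived
seeds and SHA-256 hashes of all outputs. Default problem sizes used by
the packaged checks: 10,000-trial simulations for calibration points
(averaged over several independent runs where a single fitted amplitude
has Monte Carlo SD ≈ 0.15°), 25×25 × 5,000 trials for the step-2 grid,
50 replications × (10 subjects × 400 trials) for coverage, and 1,000
null simulations for test calibration.
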