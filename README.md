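# serialbias

Serial dependence in perception: every perceptual report is pulled by the
recent past — attracted toward previous decisions, repelled from previous
stimuli. `serialbias` is a Python toolkit for quantifying and modeling
these history biases in trial-level behavioral data (orientation
adjustment, forced-choice and size-estimation tasks), written for
psychophysicists and computational-neuroscience researchers.

It packages three things:

1. **A multilevel DoG model of serial dependence.** Trial errors are fitted
   as a derivative-of-Gaussian of the wrapped previous-minus-present
   difference,

   `y_ij = x_ij · α_i · w · c · exp(−(w x_ij)²) + e_ij`, with
   `α_i = α₀ + u_i`

   — amplitude α in degrees (attraction > 0), inverse width w, subject-level
   random amplitudes — estimated by exact profile likelihood
   (`DoGModel(...).fit()` → results object with estimates, standard errors,
   tests and `summary()`), plus a two-condition variant, shuffle-null and
   future-trial controls for spurious dependence, residualization of
   orientation/size response biases, RT/Grubbs outlier filters, and
   ΔS-vs-ΔR model comparison by permutation test, stratified
   cross-validation, dominance analysis and AIC.

2. **Two population-coding simulators** of the mechanisms behind these
   biases: a *Gain* model (sensitivity boost around the previous stimulus →
   attraction) and a *Two-process* model (sensory adaptation → repulsion,
   plus a decisional readout template that persists across trials with a
   forgetting factor → attraction toward previous reports). Both decode 180
   orientation-tuned channels through a weighted circular mean, and a
   three-step calibration maps gain factors to bias amplitudes, fits the
   decisional template against a target bias profile, and selects the
   forgetting factor.

3. **A synthetic-data generator** reproducing the trial structures of eight
   experiment designs (constrained orientation walks, catch trials,
   stimulus sequences, contrast manipulations, dot ensembles) with known
   ground-truth biases, so the whole pipeline is testable end to end
   without human data. An optional loader accepts real trial tables in the
   same CSV schema.

## Worked example

```python
import serialbias as sb

# 10 subjects x 400 trials with a known attractive bias
# (alpha = 2 deg, w = 0.05) and 10-deg report noise
_, table = sb.generate_design("exp1", n_subjects=10, n_trials=400, seed=7)
gt = sb.GroundTruth(alpha_true_per_subject=2.0, w_true=0.05, sigma_noise=10.0)
behavior = sb.generate_behavior(table, gt, seed=8)

res = sb.DoGModel.from_dataframe(sb.add_derived_columns(behavior)).fit()
print(res.summary())
```

```
Multilevel DoG fit (amplitude random over subjects)
=======================================================
n trials: 3990    n subjects: 10
alpha0   1.7403 deg   SE 0.2863   z  6.079   p 0.0001838
w        0.0436 1/deg  (peak at +-16.2 deg)
sigma_u  0.0000   sigma_e  9.8627
loglik  -14793.72   AIC 29595.44   rmse 9.8627
```

The fitted group amplitude (1.74°, CI covering the generating 2°) is the
peak height of the bias curve: reports are pulled up to ~1.7° toward the
previous stimulus, maximally when consecutive orientations differ by ~16°.
The same fit applied to a simulation of the adaptation mechanism recovers
repulsion instead:

```python
cfg = sb.SimulationConfig(model="two_process", gain_factor=0.33,
                          template_amplitude=0.0, w_decay=0.0, seed=9)
sim = sb.run_simulation(table, cfg)
fit = sb.DoGModel.from_dataframe(sb.add_derived_columns(sim)).fit()
# -> adaptation-only simulation: alpha0 = -1.92 deg (p = 5.52e-05)
```

A `serialbias` command-line interface wraps the same functionality
(`serialbias synth|simulate|fit|compare|optimize|run`), and `run_pipeline`
executes synth → preprocess → fit → compare with a reproducibility
manifest.

See `docs/methods.md` for the model definitions, estimation details,
calibration procedure and known limitations.

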