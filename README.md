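# whiskerglm

Encoding models of primary whisker neuron (PWN) spiking, driven by whisker
mechanics.

PWNs — trigeminal-ganglion afferents innervating a single whisker follicle —
form the interface between the world and the somatosensory pathway. During
natural pole exploration, is their spiking predicted by whisker *kinematics*
(the angle θ of the whisker) or by the *rotational forces* acting at the
follicle — the bending moment, proportional to curvature change Δκ during
touch, and the inertial moment, proportional to angular acceleration during
free whisking? This package provides the full analysis toolchain to answer
that question: biomechanical feature extraction from tracked whisker
curves, point-process GLM encoding models, stringent single-trial
prediction scoring with chance controls, free-whisking tuning analyses,
and the two methodological simulations that make the comparison
interpretable — all driven by a synthetic-session generator with known
ground truth, so every stage is testable without recordings.

## The model

Spiking is modelled as a Bernoulli point process at 1 ms resolution. The
probability of a spike in bin *t* is

```
y_t = f( k · x_t + h · n_t + b ),    f(z) = 1 / (1 + e^-z)
```

where **k** is a stimulus filter on the recent history of a sensory
variable (x_{t-Lk+1}, …, x_t; L_k = 5 by default), **h** is a spike-history
filter on the L_h = 2 bins strictly before *t* (capturing refractoriness),
and *b* is a bias setting the spontaneous rate — 8 fitted parameters in
the standard configuration. Fitting minimises the Bernoulli negative
log-likelihood plus a ridge penalty α‖k‖² (α = 0.01) on the stimulus
filter; the problem is convex and solved with exact gradients.

Prediction accuracy is the **PCC**: the Pearson correlation between the
recorded spike train and a sampled model prediction on held-out trials,
both smoothed with a 100 ms boxcar — a single-trial metric with no
trial-averaging. Each unit's PCC is the median over 10 random train/test
splits and is compared against chance PCCs from circularly time-shifted
(3000–8000 ms) spike trains via a signed-rank test (p = 0.0025,
Bonferroni-corrected).

Free-whisking analyses decompose the angle into whisking amplitude and
phase (6–30 Hz band-pass + Hilbert transform) and test amplitude, phase
and angular-acceleration tuning with equi-populated-bin tuning curves,
shuffle nulls, and a rectified two-sided regression
r_i = μ₀ + μ₁|a_i| + μ₂Δ_i|a_i| that classifies direction selectivity.

## Worked example

`examples/02_fit_and_evaluate_glm.py` simulates an active pole-exploration
session, drives a curvature-tuned model neuron, and asks both candidate
variables to predict its spikes:

```
simulated unit: 426 spikes (11.8 spikes/s)

curvature_change: median PCC  0.953  chance  0.014  significant=True
           angle: median PCC  0.051  chance -0.006  significant=False
```

The curvature GLM predicts the unit's single-trial spike train almost
perfectly and far above chance; the angle GLM fails — during active touch,
angle and curvature are decoupled (correlation ≈ 0.2), so a moment-tuned
unit is not mistakable for an angle-tuned one. The other scripts in
`examples/` each demonstrate one capability: session simulation, the
whisking battery, the passive-coupling confound, the single-trial
prediction ceiling, and contact-force computation. A thin CLI
(`whiskerglm simulate|fit-glm|evaluate|whisking|confound|variability|run`)
wraps the same entry points.

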