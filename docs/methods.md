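# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limits of what the test suite demonstrates.

## The encoding model

Spike counts n_t ∈ {0, 1} in 1 ms bins are Bernoulli with probability
y_t = f(k·x_t + h·n_t + b), f the logistic function. Conventions:

* The stimulus history window **includes** the current bin
  (x_{t−Lk+1} … x_t); the spike history window is **strictly causal**
  (n_{t−Lh} … n_{t−1}). Defaults L_k = 5, L_h = 2, so a single-stimulus
  model has 8 fitted parameters; the "instantaneous" variant (L_k = 1)
  has 4.
* Multi-stimulus models concatenate one filter block per input. The
  quadratic variant appends the squared z-scored stimulus history,
  capturing U-shaped tuning (needed for angular acceleration, where units
  may respond to either sign); the z-scoring constants are stored in the
  model and re-applied at prediction.
* Histories never cross trial boundaries. The first max(L_k, L_h) bins of
  each trial are masked from the likelihood; during generation and
  sampled prediction the missing history at a trial start is zero-padded
  (stimulus at rest, no prior spikes).

**Fitting.** The cost is the Bernoulli negative log-likelihood plus a
ridge penalty α‖k‖² on the stimulus filter(s) only — not on h or b —
with α = 0.01. The penalty is *added* (a true ridge): prediction is
robust over orders of magnitude of α, which is only coherent for a
penalty, not a reward. The objective is convex; L-BFGS with the exact
analytic gradient (gtol 1e-8) from a zero initialisation finds the global
optimum (verified by random restarts). The NLL is computed stably via the
softplus identity (log(1+e^z)), which needs no probability clipping; the
link itself clips |z| at 30 when emitting probability series. For
optimiser conditioning, stimulus columns are z-scored internally; linear
models are returned with filters mapped back to raw stimulus units (the
mapping is exact), so fitted gains are directly comparable to generating
gains.

**Prediction.** "Sampled" mode generates a predicted spike train
recursively, feeding the *sampled* spikes back through the history filter
— the stochastic object the single-trial metric requires. "Expected" mode
(history off) provides a deterministic probability series for
diagnostics. One sampled train is drawn per train/test repeat; averaging
several is possible but not the default.

## Single-trial evaluation

Trials are split 50/50 at random; the model is fitted on the training
half and sampled on the testing half; both trains are smoothed with a
100 ms boxcar (within trials only; overlap-normalised at edges so the
mean is preserved); the PCC is computed over the *concatenated* test set
(one long pseudo-trial), excluding the masked head of each trial. The
median over 10 repeats is the unit's score; smoothing widths 1–100 ms are
supported.

Chance level: the spike train is circularly shifted by a uniform draw in
3000–8000 ms (rate exactly preserved) and the entire fit/evaluate repeat
re-run, 10 times with fresh splits. The actual and chance PCC sets are
compared with a two-sided exact signed-rank test at p = 0.0025
(0.05 Bonferroni-corrected across 20 units); n = 10 pairs is the smallest
set for which that threshold is attainable (minimum two-sided p =
2/1024). A master seed expands into logged per-repeat sub-seeds, so every
stochastic result replays exactly.

## Whisker mechanics

* Curvature at the base of the quadratic Bezier curve uses the exact
  derivative formula κ = (x′y″ − x″y′)/(x′²+y′²)^{3/2} at s = 0.
  Curvature change subtracts the per-trial intrinsic curvature, estimated
  as the mean of κ over the first 100 ms of the trial (pre-contact).
* The bending-moment proxy is M = EI·Δκ with configurable stiffness EI
  (default 1): all forces are in stiffness-normalised units, since
  absolute calibration requires whisker-specific inertia data.
* Contact: the point on the curve minimising distance to the pole centre
  (exact cubic stationarity roots, not iterative); F = M/(r sin φ),
  F_ax = F sin(θ_base − θ_contact), F_lat = F cos(θ_base − θ_contact).
  Only sin φ enters the magnitude, so the sign choice of the contact
  normal is immaterial. A minimiser at the distal endpoint (tip
  slip-off) is flagged with a warning rather than silently trusted.
* Angular acceleration: Savitzky–Golay smoothing (order 5, 31 ms window)
  followed by central second differences; a strategy switch selects the
  filter's own second-derivative coefficients instead. Both reproduce
  polynomials up to the filter order exactly; values within half a window
  of an edge are edge-affected and excluded from analyses.
* Angles are degrees at interfaces, radians internally; protraction is
  increasing angle.

## Whisking analyses

Amplitude and phase come from a zero-phase (forward–backward) Butterworth
band-pass at 6–30 Hz followed by the analytic signal, applied per trial.
Phase 0 sits at maximum protraction of the band-passed angle. Tuning
curves use equi-populated (rank-split) bins — occupancies differ by at
most one sample — 30 bins for amplitude/acceleration, 8 for phase, with
bins below a 2° amplitude threshold excluded from phase analyses. Tuning
regressions are weighted by per-bin counts.

The phase shuffle test compares the observed tuning-curve maximum with
the 95th percentile of maxima from 500 circularly shifted spike trains
(3000–8000 ms). The percentile is the order-statistic ("higher")
empirical quantile, which is exactly valid for a discrete permutation
null; linear interpolation between atoms over-rejects slightly.

The acceleration regression is fitted as r_i = μ₀ + μ₁·g(a_i) +
μ₂·Δ_i·g(a_i) with Δ_i = 1 for a_i < 0 and g(a) = |a| by default. With
the rectified regressor the three canonical selectivity classes map
cleanly onto coefficient signs: μ₂ significantly > 0 → preference for
negative acceleration; μ₂ < 0 → positive; μ₁ > 0 with μ₂ ≈ 0 → no
preferred direction; neither → not sensitive. The signed form g(a) = a is
retained as an option, but it assigns μ₂ < 0 to both pure-positive and
pure-negative rectifier tunings and therefore cannot express the
classification rules self-consistently; the rectified default resolves
that. Units of a are deg/s² as produced by the acceleration operator.

## Synthetic study conditions

The generator defines the conditions under which everything is tested.

**Active pole exploration.** Trials of 3 s; a pole at one of 11 positions
spanning ±6 mm (shuffled blocks, so 11 trials cover all 11 positions);
whisking = slow sinusoidal setpoint (10 ± 5°) + amplitude-modulated
carrier (15 ± 5°) + white noise. The carrier frequency is not metronomic:
it wanders around 8 Hz as an Ornstein–Uhlenbeck process (SD 1 Hz, τ =
500 ms, clipped to 6–30 Hz). This matters: with a strictly periodic
carrier, circular shifts differing by one whisking period reproduce the
same phase alignment, which collapses shuffle nulls onto a handful of
effective draws and mis-calibrates the phase test. Touch begins when the
protracting angle crosses a pole-position-dependent threshold
(18° + 1.2°/mm) after the pole rises at 500 ms, and ends at retraction
below it. During touch the pole arrests most of the rotation: only a
compliance fraction (0.1) of the free rotation still appears in the base
angle, and the blocked remainder is absorbed as bending, Δκ =
gain × blocked rotation, with gain growing rostrally
(0.004 mm⁻¹/° × (1 + 0.5·pole/6 mm)) and *flipping sign* for the most
caudal positions (< −3 mm), where pushing straightens the intrinsically
curved shaft — both curvature-increasing and curvature-decreasing touches
occur in real exploration. Outside touch a small exponentially smoothed
ripple (SD 0.001 mm⁻¹, τ = 20 ms) stands in for torsional effects. These
choices give touch fractions of ~0.2–0.3, Δκ spanning the ~0.05 mm⁻¹
video scale, per-episode Δκ peaks separable from the non-touch ripple,
and a session-level angle–Δκ correlation of ~0.2 — the loose coupling
diagnostic of active touch.

**Passive deflection.** Trials of 3 s with a 100 ms actuator-off lead
(used for the intrinsic-curvature estimate). White-noise mode: Gaussian
noise convolved with a decaying exponential (τ = 10 ms), rescaled to SD
2.1°. Trapezoid mode: 10 Hz, amplitude 8°. Curvature change is
constructed as Δκ = σ_Δκ (ρ·u + √(1−ρ²)·v), where u is the standardised
angle, v independent **frame-wise white** noise, ρ the correlation target
(default 0.96) and σ_Δκ = 0.0084 mm⁻¹ (±3 SD spans the video scale).
This closed-form mixture hits the target exactly in expectation for any
ρ ∈ [0, 1]. The whiteness of v is a deliberate choice: per-frame
curvature estimates carry frame-wise tracking noise, whereas the
actuator-driven signal is smooth; making the decoupling noise as smooth
as the signal would let no smoothing width average it out and would
overstate the angle model's deficit in the confound study.

**Spike generation.** Recursive Bernoulli sampling from a known GLM, with
the sampled spikes feeding the history term; deterministic given a seed.

## The two simulation studies

**Confound study.** A constrained 4-parameter model neuron — k = [γ]
(instantaneous curvature) or k = γ[−1, 1] (curvature derivative), h =
(−2, −2), bias b — is driven by the curvature-change trace of a 60 s
emulated white-noise session. b is tuned to a 50 spikes/s target by
bisection against the *sampled* rate with common random numbers (a
mean-field fixed point underestimates refractory suppression by ~20% at
this rate). The source conditions pin the rate but not the modulation
depth γ; the default (14 logit units per SD of the input) puts the unit
in the strongly driven, near-deterministic regime of a well-entrained
mechanoreceptive afferent, where sampled trains are tightly
stimulus-locked. Two independent trains are sampled (train/test); 5-tap
GLMs are fitted on the training train from either angle or curvature
and scored by the PCC between their sampled prediction and the test
train after 5 ms boxcar smoothing. At these conditions the study yields
curvature PCC ≈ 0.94 and angle PCC ≈ 0.86 (mean over 10 replicates):
the angle model, fed a variable it was never driven by, performs within
~0.08 of the true-variable model purely through the 0.96 coupling. The
residual angle-side gap is dominated by the fast component of the
coupling noise driving threshold crossings the angle trace cannot see;
its exact size depends on the (unreported) spectrum of the real
angle–curvature residuals, so the angle PCC is the softer of the two
numbers.

**Trial-variability study.** A known stochastic unit (moderate gain, 2
logit/SD, 20 spikes/s by default) generates 100 trials of spikes to a
frozen 60 s curvature input. A minimal 4-parameter GLM is refitted on
trial 1 and scored two ways: single-trial (sampled prediction vs
held-out single trials, 100 ms smoothing, median over 5) and
repeated-trial (PCC between the 100-trial PSTHs of the refitted model
and of the generating unit, 5 ms PSTH bins). The repeated-trial score
exceeds the single-trial score for any genuinely stochastic unit and
both approach 1 for a near-deterministic one (gain 30 logit/SD) — the
single-trial metric's downward bias is response variability, not model
error.

## What the synthetic conditions do and do not show

The generator reproduces the *statistical structure* the analyses rely
on: sampling rates, trial structure, the active vs passive
angle–curvature coupling contrast, position-dependent touch coupling,
touch/non-touch separability, realistic rates and refractoriness, and
whisking rhythmicity with frequency wander. It does not model 3-D whisker
shape, torsion (beyond a ripple), head or snout motion, tracking
failures, or the diversity of real PWN biophysics; passing tests
demonstrate that the *pipeline* is correct and calibrated under known
ground truth, not that any particular biological claim holds for new
recordings. Population-level percentages over recorded units are out of
scope for the same reason.

## Numerical and size choices

* Default session lengths for tests and studies are 24–300 s (8–100
  trials of 3 s) — long enough that fitted 4-parameter models recover
  generating parameters (bias within ±0.05, gain correlation > 0.98 at
  3×10⁵ bins) at a cost of seconds per fit.
* Null-calibration checks use 200 simulated null units; at nominal 5%
  the acceptance bound is ≤ 8%, and the measured rates are ~5%.
* Degenerate inputs raise explicit errors rather than returning numbers:
  all-spike/all-silent responses, zero-variance PCC inputs, sin φ = 0
  forces, trials shorter than the intrinsic window, quantile bins
  degenerate under massive ties, touch episodes with no pre-onset
  reference frame.
* Serialization is plain delimited text (one row per 1 ms bin) plus a
  JSON metadata sidecar — diffable at these sizes and lossless to float
  formatting precision.
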