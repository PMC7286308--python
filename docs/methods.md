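# Methods

## Model

### Latent dynamics

The latent space of the autoencoder is the state of a brain network model
on a structural connectome with weights `w_ij ≥ 0` (projection from region
j into region i), zero diagonal, symmetrized as `(W + Wᵀ)/2` and divided by
its largest-magnitude eigenvalue so the spectral radius is exactly one.

**Firing rate.** One latent per region, linear consensus dynamics

    ẋ = A x,   A = k·SN − I,   0 < k < 1.

For the normalized symmetric SN every eigenvalue of A lies in
`[−(1+k), k−1]`, so free propagation decays; `k = 0.9` everywhere (nearby
values behave equivalently because the encoder absorbs the rescaling).

**Wilson–Cowan.** Two latents per region, excitatory and inhibitory
currents, each relaxing toward a sigmoidal drive

    Ė_i = −E_i + α·S(c_ee E_i − c_ei I_i + k_e + Σ_j w_ij (E_j + I_j))
    İ_i = −I_i + α·S(c_ie E_i − c_ii I_i + k_i + Σ_j w_ij (E_j + I_j))

with `S(x) = 1/(1+e^(−x))`. The network input mixes E and I through the
same weights, as written above; the emitted signal is the excitatory
current. The local constants are not determined by the resting-state
fitting problem itself, so the simulator defaults to the classic planar
values `c_ee=16, c_ei=12, c_ie=15, c_ii=3, α=1`, all configurable, with
`k_e = k_i = 0.9`.

### Encoder

A stack of LSTM layers (desk-scale default: 2 layers × 96 units; the
full-scale configuration of 7 layers on 50-frame segments is a parameter
choice away) reads the measured frames and emits, per frame and region, a
Gaussian latent: mean and standard deviation (softplus, floored at 1e−4).
A reparameterized sample is advanced one Euler step by the noise-free
latent model; the result is the predicted next frame. Sampling the latent
makes the trained system stochastic and acts as a regularizer; an optional
Gaussian-prior (KL) penalty exists behind `kl_weight` but is off by
default since prediction error alone defines the objective.

The output heads additionally carry a linear skip path from the two most
recent input frames. Two details matter at desk scale:

* **Warm start.** At the prescribed learning rate (1e−4) and iteration
  budget (≤2,000), Adam moves each weight by at most `lr × iters = 0.2`,
  which cannot traverse the O(1) distances a cold-started coordinate map
  needs. The skip weights are therefore initialized from a ridge lag-2
  linear predictor of the training data mapped through a damped inverse of
  the one-step propagator; the recurrent stack then learns the
  history-dependent correction. Disable with `warm_start_skip=False`.
* **Integrator timescale.** The Euler step `dt` is expressed in frames.
  `dt = 1` makes the firing-rate propagator `k·SN`, which for a
  spectrally normalized connectome is nearly singular (bulk eigenvalues
  near zero): the latent inverse problem becomes ill-posed and latents
  lose interpretability. The default `dt = 0.25` — a neural relaxation
  time of ~3 s at TR 0.72 s, physiologically more plausible than 0.72 s —
  keeps the propagator `I + dt·A` well conditioned (eigenvalues ≈
  0.52–0.98) and close to the identity. The prediction target is still
  the next measured frame.

### Training

Each example is a pair of consecutive 50-frame segments of one scan: the
first supplies the recurrent state (burn-in), the loss is the mean squared
next-frame error over every frame of the second. The first segment of a
scan is never a loss target (its hidden state is unknown). Minibatches of
20 pairs, Adam at 1e−4, global gradient-norm clipping at 1.0, at most
2,000 iterations. All gradients are derived by hand (LSTM BPTT, heads,
reparameterized sample, one BNM step) and are checked against central
finite differences in the test suite to ~1e−6 relative error.

Forecasting is recursive: the latent at the current frame is sampled,
stepped, and the predicted frame becomes the next encoder input; long
generative runs (1,000 frames) use the same loop.

## Synthetic data

The generator produces what the estimator expects to see: ROI matrices at
TR 0.72 s from a modular, bi-hemispheric connectome (dense within-module,
sparser between, inter-hemispheric edges thinned — the signature of
tractography counts), driven by the firing-rate or Wilson–Cowan model,
bandpassed to 0.008–0.125 Hz and two-axis z-normalized exactly like
empirical data. Using the firing-rate model itself as the ground-truth
generator makes latent-recovery experiments well-posed: the encoder is
asked to learn a latent space that really generated the data.

**Noise color.** The state noise defaults to an Ornstein–Uhlenbeck drive
with an 8-frame (~5.8 s) correlation time rather than a white per-frame
drive. White state noise at the frame rate yields data markedly rougher
than measured BOLD (persistence one-step R² ≈ 0.90 versus ≈ 0.97 reported
for real resting-state scans) and, once band-limited, concentrates the
predictable variance in the filtered noise rather than in the network
propagator — which makes one-step-optimal latents amplify weakly coupled
connectome directions and destroys latent interpretability. An OU
correlation time on the order of the hemodynamic response restores
realistic smoothness (persistence R² ≈ 0.96) and a well-posed latent
problem. The plain white drive remains the simulator default
(`noise_tau=0`) and is available in the generator.

Because every series is z-scored, the noise amplitude σ cancels from all
reported accuracy metrics; what matters is the noise color and the
connectome spectrum.

**Planted structures.** QPP events are pasted additively at
Poisson-thinned onsets (proposal rate inflated to cancel the dead time the
minimum gap imposes), with the paste scale pre-compensated so the nominal
amplitude is the event-to-background SD ratio *after* re-standardization;
re-standardization is per region only, because a frame-axis pass acts as
dynamic gain control and selectively squashes coherent event frames. The
test pattern is a Hann-tapered one-cycle transient with random per-region
phases: spectrally spread (distinguishable from narrowband background)
yet robust to the one-to-two-frame jitter of correlation peaks in noise.
Planted FC states are piecewise-stationary Gaussian regimes with rank-2
factor covariances and geometric dwell times.

**What the fixtures do not contain:** hemodynamic convolution (the model
output is treated directly as the fMRI-like signal), subject variability,
motion or physiological artifacts, subcortical structures, task input.
Passing the recovery suites therefore demonstrates correctness of the
algorithms under the stated generative assumptions, not performance on
real scanner data.

## Evaluation battery

* **R² per forecast step** — per region `1 − SSE/SST` over pooled
  evaluation frames, then unweighted mean across regions; the persistence
  forecaster (repeat the last frame) is the null. On z-scored AR(1) data
  persistence obeys `R² ≈ 2ρ − 1`, a useful sanity anchor.
* **FC similarity** — Pearson correlation of strict upper triangles of
  region-correlation matrices (the diagonal carries no information).
* **Spectral slope** — Welch periodograms (128-frame segments, 50%
  overlap) averaged across regions; `−d log10 P / d log10 f` fitted by
  least squares in 0.01–0.1 Hz; a band dominated by a single bin is
  rejected as non-broadband (NaN with a warning).
* **QPP detection** — iterative template matching: seed with a random
  ~20 s window, correlate with the signal at every lag (mean per-region
  correlation of standardized windows), average the windows at
  suprathreshold local maxima (entry threshold 0.1 on the first
  iteration, 0.2 after, peaks at least one window apart) into the next
  template, iterate to convergence; best of several random starts by
  summed peak correlation. Occurrence is counted against the 95th
  percentile of local-maximum correlations pooled over 100
  amplitude-preserving phase-randomized surrogates (common phase shifts
  across regions, preserving the cross-spectral structure). Note that a
  template *learned from the same scan* is selection-biased: its null
  rate runs above the nominal α level; calibration claims are tested
  with independent templates.
* **FC states** — sliding-window (36 s default; the 50 s variant is a
  parameter) Pearson FC, Fisher z with |r| clipped to 1−1e−6, k-medians
  on vectorized upper triangles (assignment by L1 distance, centers by
  element-wise median — the L1-optimal center — seeding k-means++-style
  with L1 distances, best of several restarts, ties to the earliest);
  dwell times are run lengths × window step, transitions count label
  changes with the diagonal zeroed and rows normalized.

## Numerical choices and degenerate inputs

* Butterworth order 4, forward-backward (`sosfiltfilt`): zero phase so
  template timing is not shifted. The conditioning band defaults to
  0.008–0.125 Hz; a lower edge of 0.0008 Hz is accepted via parameters
  but is indistinguishable from DC at 15-minute scan lengths.
* Two-axis z-normalization: time axis first, then frame axis. A single
  application is not idempotent (the frame pass perturbs column statistics
  by ~1/√M); iterating converges quickly to a genuine fixed point.
* Global signal regression leaves residuals exactly orthogonal to the
  global mean; the residual global mean is identically zero, so a second
  regression is degenerate and is rejected rather than silently dividing
  by noise. Constant columns/frames are detected with relative
  tolerances, not exact zeros.
* Forward-Euler truncation: the integrator is first order; halving `dt`
  halves the deviation from the matrix-exponential closed form. At
  `dt = 0.1` over 10 steps the deviation is a few percent of the initial
  amplitude (the fastest network modes have |eigenvalue| up to 1+k); at
  `dt = 0.05` it is within 2%.
* Training aborts with a diagnostic on non-finite loss; learning rate 0
  provably leaves parameters untouched (null Adam update).
* Random-number policy: a single integer seed drives connectome
  generation, simulation noise, parameter initialization, batch
  selection, latent sampling and surrogate generation; identical seeds
  give bit-identical outputs.

## Scale of the bundled studies

The bundled end-to-end study uses 20 regions, 40 scans of 1,200 frames
(~14.4 min equivalent each), a 2-layer × 96-unit encoder and ≤2,000
training iterations — sized so the full suite trains in a few minutes on
one CPU while leaving the training dynamics (warm start + recurrent
refinement) non-trivial. The atlas-scale configuration (66 regions, 7
layers, hundreds of scans) is reachable purely through parameters.

## Known limitations

* The encoder needs a full segment (50 frames) of history before its
  predictions are meaningful; the first segment of every scan is burn-in.
* The Wilson–Cowan variant trains (loss decreases, gradients verified)
  but is not tuned to the accuracy of the firing-rate variant here; its
  local constants are fixed rather than learned by default.
* Long generative runs reproduce FC structure only partially at this
  training scale, and their high-frequency power exceeds band-limited
  data — re-filter simulated output before dynamical analyses.
* Recursive forecast accuracy beyond ~3 steps is bounded by the
  innovation content of the data itself; reported multi-step numbers are
  specific to the generator's noise color.
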