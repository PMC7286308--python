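# bna — brain network autoencoders for resting-state fMRI

Whole-brain models of spontaneous activity (brain network models, BNMs)
couple one neural-mass unit per atlas region through the structural
connectome. Simulated freely from random initial conditions they reproduce
time-averaged properties of resting-state fMRI such as average functional
connectivity, but they are not synchronized to any measurement, so they say
little about the *next* thing a real brain will do.

This package implements the **brain network autoencoder (BNA)**: a stacked
recurrent (LSTM) encoder maps a window of measured ROI frames to a Gaussian
distribution over the *latent state of a BNM* — the per-region firing rate
x_i, or the Wilson–Cowan excitatory/inhibitory currents (E_i, I_i). A sample
from that distribution is advanced one Euler step by the network model on
the connectome,

    x(n+1) = BNM(F(x(n))),     firing rate:  x(n+1) = x̃ + dt·(A x̃),
                               A = k·SN − I  (consensus operator, k < 1),

and the result is the predicted next frame. Training minimizes the mean
squared next-frame error with Adam; multi-step forecasts feed predictions
back recursively. Because the connectome SN is symmetrized and spectrally
normalized, every eigenvalue of A is negative and free network propagation
decays — the encoder supplies the state, the physics supplies the step.

Alongside the autoencoder the package provides everything needed to
evaluate it the way whole-brain simulations are evaluated:

* `bna.connectome` — loading, validation, largest-eigenvalue normalization
  and synthesis of modular bi-hemispheric connectomes;
* `bna.bnm` — traditional firing-rate and Wilson–Cowan simulators
  (Euler–Maruyama, optional OU-colored drive);
* `bna.preprocess` — zero-phase bandpass (0.008–0.125 Hz), global signal
  regression, two-axis z-normalization, segmentation;
* `bna.autoencoder` — the BNA as a scikit-learn-style estimator
  (`fit` / `predict_next` / `forecast` / `encode`);
* `bna.metrics` — per-step R², per-ROI MSE, FC and FC similarity, 1/f
  spectral slope, persistence (last-frame) null forecaster;
* `bna.dynamics` — quasiperiodic-pattern (QPP) detection with
  surrogate-calibrated occurrence rates, sliding-window Fisher-z FC and
  L1 k-means (k-medians) state clustering with dwell/transition statistics;
* `bna.synthdata` — seeded generators of BNM-driven band-limited cohorts,
  planted QPP events and planted FC-state sequences with ground truth.

## Worked example

Train on a synthetic cohort — 40 scans × 1,200 frames of 20-ROI data
generated by the firing-rate BNM on a modular connectome, band-limited and
z-normalized like empirical ROI matrices — and evaluate on held-out scans:

```python
from bna.benchmark import prediction_study

study = prediction_study(seed=1)          # trains ~3 min on one CPU
print(study["one_step_r2"])               # 0.996
print(study["r2_per_step"])               # [0.996, 0.969, 0.900, 0.785, 0.636]
print(study["persistence_r2_per_step"])   # [0.959, 0.840, 0.658, 0.436, 0.202]
print(study["latent_corr"])               # 0.969
```

Reading these numbers: one-step-ahead predictions explain 99.6% of the
held-out variance; recursive forecasts stay above R² 0.9 through three
steps (≈2 s of data) and above 0.6 through five, while the persistence
null — "the next frame is the last frame" — ties only at step one and
collapses beyond it. The latent firing-rate traces correlate 0.97 with the
measured signal: the encoder's coordinate change is close to the identity,
so the latent state remains physically interpretable.

The same pipeline is available from the shell:

```bash
bna synth --rois 20 --duration-s 864 --seed 3 --out ts.tsv
bna preprocess --in ts.tsv --band 0.008 0.125 --out ts_pp.tsv
bna train --model fr --sc sc.tsv --data scans/ --iters 2000 --seed 0 --out model.npz
bna predict --model model.npz --in segment.tsv --horizon 12 --out pred.tsv
bna evaluate --model model.npz --data held_out/ --out eval.json
bna qpp --in ts_pp.tsv --window-s 20 --out qpp.json
bna states --in ts_pp.tsv --k 7 --out states.json
```

Every output gets a JSON manifest (version, configuration, seed, input
hashes) so artifacts are reproducible from their manifests alone.

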