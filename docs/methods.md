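# Methods

`pcleservo` implements closed-loop regression of the probe–tissue distance
for probe-based confocal laser endomicroscopy (pCLE) scanning: a
bidirectional diagonal state-space (S4D) sequence model predicts, for every
frame in an acquisition buffer, the signed offset of the probe from the
optimal (least-blur) scanning position, and a servo loop moves the probe by
the negative of the newest prediction until it stabilizes inside the
working band. Training needs no per-frame distance annotation beyond the
recording grid itself: an exponential trajectory planner manufactures
pseudo-labelled approach sequences from recorded sweeps.

All positions are signed distances in µm relative to the optimum, which the
simulator places at 0; the physical working band of the probe (±35 µm) is
the convergence target.

## Synthetic scanner

One "video" is a virtual probe sweep over a fixed tissue sample: one frame
at every 5 µm position in [−400, +400] µm (161 frames), matching the
acquisition geometry of stepper-driven miniprobe recordings.

Image formation per frame:

```
pixels = clip( blur(texture, σ(|d|)) · (1 + speckle) + tilt(d) + noise, 0, 1 )
σ(|d|)  = σ₀ + c·|d|^γ          σ₀ = 0.5 px, σ(400 µm) = 8 px, γ = 1.5
```

* **Texture** — a dense field of soft Gaussian blobs (default 150 per
  frame, radii log-uniform from 1 px to S/8) plus fine micro-granularity
  (white noise smoothed at 0.7 px), emulating the many small stained
  nuclei of cellular tissue. The granularity guarantees band-limited
  energy near Nyquist, so defocus measurably removes high-frequency
  content — the physical signal the whole method rests on.
* **Defocus** — applied in the frequency domain with the exact Gaussian
  transfer function (periodic boundary). A truncated spatial kernel leaves
  a sidelobe floor in the spectrum that, at heavy defocus, dominates the
  residual texture energy and breaks the monotone blur–frequency
  relationship; the exact transfer function makes the highest-band energy
  fraction strictly non-increasing in |d| over the entire grid (verified
  to 1e−10 in the tests).
* **γ > 1** — the blur *gradient* flattens toward the optimum: clarity
  improvements become less apparent close to the best position, which is
  what makes the near-field regression hard in the real task and is
  preserved here.
* **Noise** — multiplicative speckle (σ = 0.08) and additive Gaussian
  sensor noise (σ = 0.02 on a [0,1] intensity scale), both seeded per
  frame. These magnitudes make the white-noise floor comparable to the
  residual texture energy of heavily defocused frames, which is the noise
  regime the feature design has to survive.
* **Signed asymmetry cue** (`asymmetry_strength`, default 0.3) — an
  illumination tilt with amplitude proportional to the *signed* position:
  `tilt = 0.3 · (d/400) · (x − ½)`. Pure defocus is an even function of
  d, so a perfectly symmetric simulator would make the sign of the
  distance unidentifiable from images in principle — no regressor could
  beat chance on direction, and the closed loop could never approach from
  the negative side. On real tissue the two sides of the focal plane are
  visually distinct (the probe compresses tissue on one side), and
  single-frame direction accuracies around 95% are reported on real pCLE;
  the tilt is the simulator's minimal stand-in for that asymmetry.
  Setting `asymmetry_strength = 0` restores an exactly ±-symmetric
  scanner (used by the symmetry tests).

Desk-scale defaults: 64×64 px frames, 8 training / 2 test videos with
disjoint texture seeds.

## Features

Each frame is normalized (per-frame standardization, affine remap
0.5 + z/6 **without clipping** — a hard clip would inject spurious
high-frequency energy that grows with blur) and summarized by:

1. **Spatial branch** — a small strided conv encoder (1→8→16 channels,
   strides 4 and 2, ReLU) with global mean **and first-moment** pooling
   (per-channel x̄- and ȳ-weighted means) followed by a linear projection
   and LayerNorm. Plain average pooling is translation invariant and
   therefore blind to global intensity gradients; the moment channels
   expose the signed tilt directly.
2. **Frequency branch** — log energy fractions of 8 concentric radial
   bands of the power spectrum (radius normalized to the axis Nyquist,
   corners absorbed into the top band), **after noise-floor correction**:
   the median power of the outermost band is subtracted from every non-DC
   bin. Without the correction the white sensor-noise floor dominates the
   high bands of defocused frames and the band profile becomes non-monotone
   in |d|.
3. **Global statistics** — raw-frame mean, log-sd, and the two first
   intensity moments, on fixed ~unit scales.
4. **Window-relative differences** — every band energy and statistic is
   additionally expressed relative to the *sharpest frame in the current
   acquisition window* (the frame with maximum log-sd). Absolute spectra
   and moments are confounded by the individual tissue sample's texture;
   within-video differences cancel that confound exactly. This is the
   normalization a practical focus measure applies, and it is what lets a
   model trained on eight textures stay calibrated on a new one.

A single trainable affine map with GELU (the fusion encoder ε) fuses
spatial (32) + absolute bands (8) + relative differences (12) + absolute
moments (2) into the 32-dimensional per-frame vector the sequence model
consumes.

## Sequence model

The regressor is a stack of bidirectional diagonal state-space layers.
One S4D bank is H=32 independent SISO systems with diagonal complex state
(S4D-Lin initialization A = −½ + iπn, B = 1, N = 8 modes, timescales
log-uniform in [10⁻³, 10⁻¹]), discretized per step by zero-order hold and
applied as a causal convolution with the Vandermonde kernel
K_l = 2·Re(Σ C B̄ Ā^l). The equivalent stepwise recurrence is implemented
as an independent oracle and the two paths are cross-checked to 1e−6 in
the tests. Inside the trainable network the state dynamics (A, B, Δ) stay
frozen at initialization and the output maps C, skips D and all
projections train — the kernel is then linear in its trainable complex
parameters, which keeps the backward pass a single contraction.

A bidirectional layer runs one bank over the sequence and a second,
independently parameterized bank over the reversed sequence (output
reversed back), GELU on each branch, then channel concatenation and a
trained projection back to the model width ("concat-project"; a summation
mode is kept for ablation). Blocks are pre-LayerNorm residual; the full
model has 3 blocks, the fine-tuned variant 1. A per-frame affine head
scaled by 400 (so the network learns O(1) targets) emits signed distances
in µm.

A separate **single-frame head** serves the guided controller during the
first N_S = 3 scanning steps. It is a small MLP over the spectral band
energies and intensity moments only — deliberately excluding the conv
features, whose calibration cannot be prevented from attaching to the
appearance of the handful of training textures (see Domain randomization).

## Pseudo-labelled training

* **Planned approach trajectories** (the bulk of the data; one per grid
  start position per video by default, 161/video): from a start P0 the
  planner emits N = 10 positions decaying exponentially in magnitude to
  α = 0.1 µm with a constant per-step ratio, snapped to the grid by
  floor(p/5)·5. The frames recorded at those positions, labelled with the
  positions themselves, form one training sequence. The printed source
  form of this recurrence has the exponent's sign flipped — it would grow
  as P0²/α rather than converge — and is kept only behind a debug flag;
  the decaying form is the only reading consistent with the planner's
  stated purpose. Floor rounding sends positive tails exactly to 0 and
  negative tails to −5 (a "nearest" mode is available).
* **Stationary windows** (10/video): a grid position plus small
  grid-snapped jitter (σ = 30 µm), labelled with the true positions.
  Closed-loop inference can dwell on a nearly constant buffer — a state a
  planned decay never produces — and a model trained on decays alone
  learns that mutually similar late frames mean "at the optimum" and
  freezes the probe wherever it hovers.
* **Rollout windows** (10/video): scatter sequences produced by the
  update P ← P − (P + e), e ~ N(0, 70 µm), emulating the buffer shapes of
  the guided phase, labelled with true positions.
* **Crop augmentation**: each batch is randomly truncated to a prefix or
  suffix of its sequences, matching the growing-prefix / sliding-suffix
  windows inference produces and preventing the model from keying on a
  frame's index rather than its appearance.
* **Domain randomization**: per-window constant offsets are added to the
  absolute band/statistic channels, drawn with the across-video spread
  measured on the training videos themselves (per-|d|-bin video means,
  std across videos). Texture confounds are constant within a video and
  vary across videos; randomizing them in training forces the model onto
  the within-window structure that transfers. The offsets cancel inside
  the window-relative differences, exactly as real texture confounds do.
* **Single-frame supervision**: the guided-controller head trains on
  frames drawn uniformly from the recorded sweeps with their true
  positions (every recorded frame has one), under plain MAE — its job is
  coarse full-range accuracy, and the percentage-weighted sequence loss
  would starve it of large-distance supervision. This gradient also
  bootstraps the shared extractor out of the constant-prediction plateau
  that the percentage term otherwise creates on a cold start.

The sequence loss is L_MP = ½(MAE + MAPE) with MAPE in percent and
zero-label terms excluded from its mean (they are undefined; an
epsilon-denominator variant is available). MAE alone, MAPE alone, and a
heteroscedastic Gaussian NLL with a predicted per-frame log-variance are
selectable for ablations. Optimization is Adam, batch 8, triangular cyclic
learning rate between 1e−5 and 1e−4 with lr_min at epoch 0 and lr_max at
epoch 5 (period 10), 30 epochs. Everything is seeded; two identical runs
produce bit-identical parameters.

The fine-tuned variant (1 bidirectional layer initialized from the full
model's first layer, spatial encoder frozen, ε and heads training) runs 10
further epochs.

## Closed loop and evaluation

Each step acquires a frame at the current (grid-snapped, ±400-clamped)
position; the first N_S = 3 steps use the single-frame head, later steps
feed the last min(10, available) frames to the sequence model and take
the prediction aligned with the newest frame; the position update is
P ← P − d_pred. Per-frame conv features are cached so a K = 20-step run
costs one conv pass per acquired frame.

Convergence is retrospective: the first step index from which |position|
stays within the working band (±35 µm) to the end of the run. Metrics over
a run collection: MAE_1st (mean |first prediction − P0|), ACC_dir (sign
agreement of the first prediction, zero starts excluded), MAE^C (mean
|position| after convergence; mean ± sd across converged runs), W^B
(per-run max−min of post-convergence positions, averaged), BM (mean
post-convergence sharpness; variance of the Laplacian normalized by the
sweep maximum, so the sharpest frame of a video scores 1). Runs that never
converge contribute only to MAE_1st/ACC_dir; a model with zero converged
runs is assigned W^B = +∞ (stability-after-convergence never achieved),
which is how the fine-tuned-vs-untrained comparison is made meaningful.

The study protocol runs the K-step analysis from every test-grid start
with |P0| ≥ 100 µm (244 runs over the 2 test videos).

## What the simulator does and does not show

Passing tests demonstrate that the sequence model learns the blur-to-
distance mapping from pseudo-labels alone, that window-relative spectral
reasoning transfers across tissue textures, and that the closed loop
drives the probe into the working band from far starts with
post-convergence errors of order 10–20 µm. The simulator does not model
real confocal point-spread functions, staining variability, tissue
deformation under contact, motion blur, or the appearance statistics of
real acriflavine-stained tissue; absolute metric values on real recordings
will differ.

A structural limitation worth stating precisely: with eight training
textures, the *absolute* mid-range (|d| ≲ 150 µm) calibration of any
per-frame readout carries an irreducible per-video bias of several tens of
µm (the texture's own low-frequency moment and spectral level confound the
tilt and blur cues; the window-relative features remove the confound only
once the buffer contains a near-optimum reference frame). Closed-loop
convergence into the ±35 µm band therefore depends on the early steps
visiting the vicinity of the optimum at least once; runs on an unluckily
biased test texture can hover 40–120 µm from the optimum indefinitely. The
observed per-study convergence rates at the default conditions are roughly
50–70% of far starts depending on the texture draw, while converged runs
show MAE^C ≈ 10–20 µm and W^B ≈ 15–30 µm. For comparison, the reference
system on real data reports MAE^C_20 ≈ 25–29 µm with W^B_20 ≈ 50–70 µm —
i.e. post-convergence excursions that would themselves leave a strict
±35 µm band regularly; a hard stay-in-band criterion is stricter than what
either system's stability numbers imply.

## Numerical choices

* float64 throughout the autodiff engine; gradients of every op are
  verified against central differences.
* S4D stability is structural (Re(A) = −½ < 0, so |Ā| < 1); kernels are
  bounded by a geometric envelope and safe to length 10⁴.
* MAPE guard: zero-label terms dropped; all-zero labels give 0.
* Degenerate planner inputs: P0 = 0 gives the all-zero trajectory;
  0 < |P0| ≤ α holds position (the probe is already at the optimum's
  resolution limit).
* Frame lookup requires exact grid membership (tolerance 1e−6·5 µm); an
  off-grid lookup raises, signalling a discretization bug rather than
  silently interpolating.
* Run-direction tie-breaks: the window reference frame is the argmax of
  the log-sd channel; ties resolve to the earliest frame.
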