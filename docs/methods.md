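# Methods

This note documents the models and procedures implemented in `mfbnet`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Problem setting

Four-class motor-imagery (MI) decoding from multichannel EEG: a subject
imagines one of four movements (left hand, right hand, feet, tongue in the
standard benchmark protocols) while EEG is recorded from C electrodes at
250 Hz; each cue-aligned trial must be assigned its class. Motor imagery
modulates the sensorimotor mu (8–12 Hz) and beta (18–24 Hz) rhythms through
event-related desynchronization/synchronization, which leaves two
exploitable signatures: *where* oscillatory power concentrates spatially
(captured by common spatial patterns) and *how* oscillations in different
regions phase-lock to each other (captured by connectivity networks).
The pipeline computes both representations per trial and fuses them in a
convolutional classifier.

## Multifrequency brain networks

For a trial `X` (channels × samples) and a band `b`, each channel is
zero-phase bandpass filtered and extended to its analytic signal
`z(t) = x(t) + i H[x](t)`; the instantaneous phase is the four-quadrant
angle of `z` and the amplitude its modulus (an all-zero channel gets phase
0 by convention). The phase-locking value between channels x and y is

    PLV(x, y) = | ⟨ exp(i (φ_x(t) − φ_y(t))) ⟩_t |  ∈ [0, 1],

the modulus of the time-averaged unit phasor of the phase difference.  PLV
depends only on phases, so it is invariant to per-channel amplitude scaling.
Ten percent of samples at each end are trimmed before averaging because the
discrete Hilbert transform is unreliable at signal boundaries (fraction
configurable).

Each band yields a C × C PLV matrix; proportional thresholding keeps the
strongest 25% of the C(C−1)/2 upper-triangle links (58 of 231 at C = 22)
**with their weights** — weak-link discarding, not binarization — zeroes
the diagonal and re-symmetrises.  Ties are broken by (row, col)
lexicographic order so the operation is deterministic and idempotent.
Stacking the mu and beta layers gives the per-trial two-layer multifrequency
network fed to the network branches of the classifier.

Open choices made here: thresholding is applied per trial (the classifier
consumes per-trial networks) rather than to trial-averaged matrices, and
surviving links retain their PLV weights. Both are documented defaults,
not physiological claims.

## OVR filter-bank CSP and the feature image

A 43-band Chebyshev Type II filter bank covers 4–40 Hz.  The exact band
layout is a configurable scheme; the default stacks five width scales —
4 Hz bands stepped by 2 Hz (17 bands) and 8/12/16/20 Hz bands stepped by
4 Hz (8 + 7 + 6 + 5 bands) — ordered by (width, low edge).  Narrow bands
localise rhythm boundaries; wide bands retain broadband power structure.
Filters are order 4 (effective order 8 after forward–backward filtering)
with 30 dB stopband attenuation and a 2 Hz transition; the family is a
standard choice for FBCSP-style banks, and all design parameters are
exposed in configuration.

Within each band, one-versus-rest CSP solves, per class k, the generalized
eigenproblem

    P̄_k w = λ (Σ_j P̄_j) w,

where `P̄_k` is the class mean of trace-normalized trial covariances
`X Xᵀ / tr(X Xᵀ)`.  Trace normalization removes per-trial amplitude scale;
a relative ridge of 1e−8·tr/C on the pooled matrix guards conditioning.
Eigenvalues lie in [0, 1] and the eigenvector matrix whitens the pooled
covariance (`Wᵀ Σ W = I`), both asserted in tests.  Spatial filters are
fitted on the full MI segment (2.5–6 s) of training trials only and shared
across time windows (re-fitting per window is a possible variant; sharing
is the default because the windows all lie inside the fitted segment).

Features per (band, window, class): keep the first m and last m eigenvector
columns (most discriminative for class-vs-rest), project the windowed trial,
and take log10 of the resulting 2m variance shares — the log of a
probability vector, hence features always sum (in power) to 1.  With the 11
analysis windows (six 1 s windows sliding by 0.5 s, four 2 s windows, and
the full 2.5–6 s segment) and 4 classes this yields a 43 × 176 feature
image at m = 2 ("two pairs"); the reference architecture trace corresponds to
m = 3 (width 264), and m is a parameter since the two conventions coexist.
Columns are ordered window-major, then class, then the 2m features — a
fixed convention for reproducibility.

## Fusion classifier

Three convolutional branches feed one softmax head:

* **Network branches (mu, beta)** — input C × C adjacency matrix;
  conv 6×6@32 (same) → maxpool 2×2 → conv 4×4@64 (same) → conv 3×3@64
  (same) → maxpool 2×2 → conv 3×3@64 (same) → flatten (1600 at C = 22) →
  dense 64.  `same` padding keeps the node-by-node structure until pooling.
* **FBCSP branch** — input 43 × F feature image; conv 3×32@32 (valid) →
  maxpool 2×2 → conv 3×16@64 (valid) → conv 2×8@64 (valid) → flatten
  (102272 at F = 264; 54400 at F = 176) → dense 64.  The height-3 kernels
  fuse three adjacent filter-bank bands per step; `valid` padding is what
  reproduces the 43→41 height transition.

Branch outputs concatenate (192 features for the full model) into a dense
softmax layer.  All activations are exponential linear units whose
negative-branch scale λ is a learnable scalar per layer (initialized at 1,
updated by backpropagation; a fixed-λ mode exists).  Pooling uses floor
semantics (incomplete border windows dropped), which the reference shape
arithmetic (41→20, 233→116) requires.

Ablation variants are edits of the declarative architecture: A/B drop the
mu/beta network branch; C/D insert two extra convolutions (mirroring their
predecessors' kernels) after the 2nd and 3rd convolutions of the mu/beta
branch; E shrinks the FBCSP branch's first kernel to 2×32.  The two network
branches do not share weights ("same structure" is read as identical
topology, independent parameters).

The compute engine is a small float32 numpy implementation (im2col
convolutions, hand-derived backpropagation verified against finite
differences, Adam).  Training hyperparameters are conventional defaults,
all in configuration: Adam, learning rate 1e−3, batch 32, cross-entropy,
up to 300 epochs with patience 30, best-validation weights restored.  No
dropout or weight decay is applied by default.  Runs are bit-deterministic
given the seed.  Model inputs: network layers enter as raw weights in
[0, 1]; feature-image rows are standardized per band with training-set
statistics.

## Evaluation protocol

Per run: stratified 60/10/30 train/validation/test split, training with
early stopping on validation accuracy, test accuracy and Cohen's kappa

    κ = (p_o − p_e) / (1 − p_e),

with `p_e = 0.25` for the balanced 4-class design (the benchmark
accuracy/kappa pairs are consistent with this convention, e.g. 83.83% ↔
0.784, 91.26% ↔ 0.883); a marginal-based `p_e` from the confusion matrix is
also provided.  Results aggregate over independently seeded runs (ten by
default; run r uses seed base+r, logged in the report).  The ablation suite
reuses identical per-run splits across variants so comparisons are paired.

## Synthetic data: what it emulates, what it does not

The generator plants the two signatures the pipeline is designed to detect:

1. **Class-dependent phase coupling** — per class, a set of channel pairs
   shares a narrowband carrier (bandpass-filtered noise, not a sinusoid,
   so spatial covariance stays full-rank).  Coupled copies are the analytic
   carrier rotated by a fixed lag plus slow Gaussian phase jitter; with
   jitter sd σ the expected PLV is exp(−σ²/2) (circular-Gaussian
   resultant), giving a closed-form coupling dial.  The jitter process is
   lowpass (4 Hz) so rotation preserves analyticity to good approximation.
2. **Class-dependent spatial covariance** — a broadband component
   `L_k · white noise` with Cholesky factor of the class covariance,
   controlling CSP separability in every band.
3. **1/f background** — spectrally shaped white noise (power ∝ 1/f above
   1 Hz), the standard EEG noise floor, mixed at a configurable
   signal-to-noise power ratio.

The standard study condition (`default_config`) is 4 classes × 50 trials,
22 channels, 250 Hz, 6 s trials: each class owns a disjoint 5-channel
group, mu-coupled over 6 planted pairs (lag π/3, jitter 0.2 rad) with a 3×
variance boost and 0.3 within-group correlation, at snr 2.  These
conditions are deliberately strongly separable: they are structure-recovery
and plumbing tests, not difficulty benchmarks.

The ablation condition (`mu_only_config`) must confine class information to
the mu network layer, which takes two deliberate choices.  First, every
class shares the identity spatial covariance.  Second — and less obvious —
the planted pairs are disjoint and coupled in *quadrature* (lag π/2):
because the real and imaginary parts of an analytic signal are orthogonal
in time average, a quadrature-coupled pair has (near-)zero cross-covariance,
so the coupling is invisible to covariance-based CSP features in every
filter-bank band, while PLV, being lag-invariant, sees it at full strength.
With an in-phase lag the coupling leaks into band-limited covariance and
the FBCSP branch decodes the classes without the mu network layer, which
defeats the purpose of the ablation comparison.  On this condition the
mu-ablated variant sits at chance level while the full model, whose only
informative input is the mu layer, scores above it.

Real EEG differs in ways the generator does not model: non-stationarity
within and across trials, volume conduction (which inflates zero-lag
connectivity), artifacts (EOG/EMG), inter-subject variability, and much
lower separability.  Passing the synthetic benchmark therefore shows the
pipeline recovers planted structure and that every stage composes
correctly — not that the competition-benchmark accuracies would be
reproduced, which requires the external datasets.

A note on PLV nulls: for i.i.d. phases the null PLV is ~1/√N and 10⁴
samples keep it below 0.03.  For independent *narrowband* signals the
phase difference is a random walk that decorrelates at the band rate, so
the effective sample count is ~duration × bandwidth and the null sits
around 0.06–0.15 at 60 s of mu-band signal.  Tests assert the bound the
narrowband null actually satisfies, plus the rank property (planted pairs
always outrank background).

## Problem sizes and numerical choices

Default test/acceptance runs use the study conditions above with a reduced
training protocol (20 epochs, m = 2, 3 runs for the main protocol, 2 paired
runs for the ablation), chosen so the whole benchmark runs on a single CPU
in minutes while leaving a wide margin to its accuracy criterion.
Tolerances: PLV analytic-path vs direct phasor-average oracle agrees to
1e−10; CSP whitening to 1e−8 (the fitted ridge bounds this); the 2-channel
closed-form eigenvalues {0.8, 0.2} to ±0.02 at 20 trials × 5000 samples.
Signal-level "perfect" phase locking is asserted at 1e−4 rather than
exactly 1: a bandpass-filtered carrier has a small negative-frequency
residue, so the Hilbert-reconstructed phase of the rotated copy deviates
from the constructed phase at the 1e−6 level.

Degenerate inputs: zero signals are rejected where a quantity is undefined
(covariance trace, feature variances) or given a stated convention (phase
of an all-zero signal is 0); argmax ties in prediction resolve to the
lowest class index; thresholding ties are lexicographic.

## Known limitations

* No GDF/real-data reader is bundled; external benchmark data enter
  through the documented HDF5 container.
* The CNN engine is single-threaded CPU code; it is sized for the study
  conditions, not for large-scale hyperparameter search.
* The exact 43-band layout and the Chebyshev design parameters are
  documented defaults (the band count and 4–40 Hz range are fixed by the
  method; the layout inside that range is configurable).
* t-SNE feature visualization and statistical tests between ablation
  variants are out of scope.
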