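# Methods

## Signal model and preprocessing

A recording is a channels × samples matrix of continuous EEG
(microvolts) with stimulus events (onset sample, class, stimulus
frequency and phase). Preprocessing follows standard offline SSVEP
practice:

- **Band-pass filtering**: Butterworth of configurable order (default
  4) applied forward–backward (`sosfiltfilt`), i.e. zero-phase. The
  two passes square the magnitude response; zero phase is chosen
  deliberately because the frequency branch consumes the *complex*
  spectrum, whose phase content a causal filter would rotate
  channel-uniformly but window-dependently. Default band 7–64 Hz
  (6–80 Hz is conventional for the 12-class paradigm's time branch).
- **Resampling**: polyphase (`resample_poly`) with the rational ratio
  of target to source rate; event onsets are rescaled with the same
  factor. Only downsampling is supported — upsampling EEG creates no
  information and usually indicates a configuration error.
- **Epoching**: each trial starts `round(latency_s × fs)` samples
  after stimulus onset (the visual-evoked latency: 0.135 s for the
  12-class paradigm, 0.13 s for the 40-class ones) and spans
  `round(window_s × fs)` samples. Seconds-to-samples conversions use
  round-half-away-from-zero, fixed so that e.g. 0.135 s × 256 Hz =
  34.56 → 35 reproducibly. Trials whose window overruns the recording
  are dropped with a warning rather than padded — padding would
  corrupt the spectra. The 40-class adapters default to the 0.13 s
  latency; the Benchmark set documents no explicit value, and its
  acquisition matches the BETA protocol, so the BETA value is reused
  (configurable).

## Complex-spectrum features

The frequency branch consumes, per channel, the real and imaginary
DFT parts over the half-open band [7, 64) Hz at 0.2 Hz resolution:
285 + 285 = 570 values per channel. The half-open convention is what
makes (64 − 7)/0.2 an exact bin count. The fixed resolution is reached
by zero-padding each epoch to N = fs/0.2 samples (1280 at 256 Hz, 1250
at 250 Hz) before the FFT; this is what keeps the network input width
constant across window lengths of 0.4–1.2 s, so one architecture
serves all windows. No taper is applied (a taper would smear the
phase structure the complex representation exists to preserve) and the
DFT values are left unscaled — the first batch-normalisation stage of
the branch absorbs overall scale. Transforms run in float64 and are
stored as float32.

## Architecture

Input geometry: C channels, T samples, U classes. All convolutional
and fully connected weights are spectrally normalised (below).

- **TempNet** (time branch): two parallel paths — spatial `C×1`
  convolution (16 maps) then temporal `1×10` stride-2 convolution
  (32 maps), and the same pair in the opposite order — each
  convolution followed by BatchNorm and PReLU, each path ending in
  dropout; path outputs are summed. A bidirectional convolution
  applies a kernel-3, padding-1 convolution to the sequence and to its
  time-reversal (un-reversed afterwards), sums both, and mixes through
  a `1×1` convolution with BatchNorm/PReLU and dropout. Adaptive
  average pooling maps the width `(T−10)//2 + 1` (124 at T = 256, 121
  at T = 250, 47 at T = 102) to exactly 124. Pooling bin *i* averages
  input positions `[floor(i·L/124), ceil((i+1)·L/124))`; for L < 124
  bins repeat positions, which is what admits very short windows.
- **SpecNet** (frequency branch): two parallel paths over the C × 570
  spectrum ordering the spatial `C×1` and local spectral `1×10`
  stride-2 convolutions oppositely, each finishing with a `1×35`
  stride-2 context convolution: widths 570 → 281 → 124. The summed
  output passes channel attention: global average and global max
  descriptors share a two-layer bottleneck (32 → 8 → 32, ratio 4 — the
  smallest standard reduction at 32 maps, shared across both
  descriptors per the CBAM convention), outputs summed, sigmoid, and
  the resulting per-map scalar gates the map.
- **Fusion**: at each of the 32 × 124 positions the (time, frequency)
  value pair feeds a *shared* two-layer gate (2 → 16 → 2, PReLU
  between); softmax over the two logits gives convex weights for the
  weighted sum. Among the readings consistent with "position-wise
  weights from two fully connected layers plus softmax", the shared
  per-position gate is the parameter-efficient one; the alternative
  (a flat 3968 → 2×3968 gate) would dominate the parameter budget.
- **Classifier**: flatten (32·124 = 3968) → linear 198 → LayerNorm →
  PReLU → dropout 0.5 → linear U. No softmax in the forward pass; the
  loss applies it.

Single-branch ablation variants bypass fusion and feed the surviving
32 × 124 map directly to the classifier.

Weight initialisation is variance-scaled fan-in (gain for PReLU with
slope 0.25), drawn from a per-model seeded generator; PReLU uses one
learnable slope per feature map initialised at 0.25; BatchNorm uses
momentum 0.1 and eps 1e-5. Parameter count is independent of T
(adaptive pooling decouples window length from the classifier), which
the tests assert for T ∈ {102, 256, 307}.

## Spectral normalisation

Each weight matrix W (convolution kernels viewed as out-maps ×
everything else) is replaced in the forward pass by W/σ(W), σ(W) the
largest singular value. σ is estimated by power iteration with a
persistent left vector: one step per training forward pass, frozen at
evaluation — the standard algorithm. Gradients flow through the
normalisation with σ treated as u·(W v) for the current (detached)
singular-vector estimates. An all-zero weight is passed through with a
warning (its σ is 0). `converge_sigma` / `converge_spectral_norm`
refine the estimate for verification against an SVD oracle.

## Training and evaluation

Cross-entropy loss; Adam with learning rate 0.001; dropout 0.5; a
fixed epoch budget with no validation split or early stopping (none is
part of the protocol); batch size 32 with L2 coefficient 1e-4 for the
12-class paradigm, 128 and 1e-3 for the 40-class ones (the 40-class
sets are larger and noisier; the Benchmark set reuses the BETA values,
which are published only for the latter). L2 is implemented as weight
decay added to the Adam gradient.

LOSOCV trains one fresh model per held-out subject on all remaining
subjects. The fold seed is `base_seed + fold_index`, driving
initialisation, shuffling and dropout, so folds are independently
reproducible; re-running a fold is bit-deterministic. Evaluation-mode
batch normalisation uses running estimates.

Accuracy is the exact count ratio. ITR uses the Wolpaw formula with
0·log 0 = 0 at the P ∈ {0, 1} limits and is clamped to 0 for
P ≤ 1/G, where the formula goes negative — sub-chance folds otherwise
produce meaningless negative bit rates. T in the formula is the
stimulation window length only (no cue or gaze-shift time). Summaries
report mean ± sample SD (n−1) across subjects, and the mean ITR is the
mean of per-fold ITRs, not the ITR of the mean accuracy — the formula
is nonlinear in P. A single-fold summary reports SD 0 with a flag.

## Synthetic SSVEP generator

Per trial, channel c carries

    s_c(t) = gain_c · amp_subj · Σ_h a_h sin(2π h f (t − τ) + h φ),  t ≥ τ

with stimulus frequency f and phase φ from the paradigm grid
(12-class: 9.25–14.75 Hz step 0.5, phases advancing 0.5π, 8 occipital
channels at 256 Hz; 40-class: 8–15.8 Hz step 0.2, 9 parieto-occipital
channels at 250 Hz), harmonic amplitudes a = (1.0, 0.4, 0.2) by
default (a plausible decaying harmonic profile), and visual latency τ
(0.135 s / 0.13 s plus per-subject jitter, SD 10 ms). Subject
amplitude is lognormal with σ = 0.3; channel gains follow a fixed
occipital-weighted profile. Noise is a pink (power ∝ 1/f, 70%) plus
white (30%) mixture, scaled per trial so the channel-mean in-band
(7–64 Hz) signal-to-noise power ratio equals `snr_db` — the analysis
band is used so the knob is directly interpretable for the decoder.
Trials are separated by 0.5 s noise-only gaps; each block presents all
classes once in random order. All draws descend from a spawned
`SeedSequence` per subject, so datasets are reproducible and subjects
independent.

What the generator does **not** emulate: volume conduction, background
rhythms (alpha), eye blinks and movement artifacts, non-stationarity,
electrode impedance drift, or realistic inter-subject spectral
differences. Passing the end-to-end tests therefore demonstrates that
the pipeline recovers class structure under controlled conditions —
not that the published real-data accuracies are reproduced, which
requires the external datasets and their full protocol.

`estimate_snr` is the generator's QC: the ratio of periodogram power
within ±0.5 Hz (default) of the fundamental and configured harmonics
to the remaining in-band power. Noise-free trials (residual below
1e-9 of signal power) return a +300 dB sentinel.

## The standing desk-scale experiment

The acceptance suite runs the complete pipeline at a scale chosen for
a single CPU: 10 subjects, 12 classes, 2 blocks (48 trials/subject),
1.4 s stimulation, 5 dB in-band SNR, 1 s windows, LOSOCV at 30 epochs
for the fused model and both single-branch ablations (dataset seed
101, training base seed 7). At these conditions the fused model's mean
held-out accuracy is far above the 12-class chance level of 8.3%, and
it is at least as accurate as the weaker single branch, mirroring the
ablation ordering observed on real data. A separate test re-runs a
reduced fold twice and asserts bit-identical results.

## Numerical choices and limitations

- All network arithmetic is float32; DFT features are computed in
  float64 and cast. Batch statistics accumulate in float64 inside the
  JIT kernels.
- Argmax prediction breaks ties toward the lowest class index.
- Power iteration uses a 1e-12 norm floor; `spectral_normalize` (the
  standalone utility) starts from a deterministic uniform vector.
- The im2col/col2im and normalisation kernels have pure-NumPy
  fallbacks, tested equivalent to the JIT paths.
- Training the published protocol (150 epochs, 35–70 subjects, 64
  channels) on real datasets is computationally out of desk scope;
  the code supports it unchanged, but no real-data numbers are
  produced or asserted here.
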