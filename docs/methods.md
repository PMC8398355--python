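# Methods

## Signal model of the synthetic generator

Surface EMG during a sustained isometric-like contraction is commonly
modelled as band-limited Gaussian noise whose standard deviation follows
the contraction envelope. The generator implements exactly that:
each channel of a trial is white Gaussian noise band-passed (4th-order
Butterworth, zero-phase) into the channel's carrier band, normalized to
unit RMS, and multiplied by a ramp–plateau–ramp envelope with
raised-cosine edges (onset at 10% of the trial, offset at 90%, ramps of
10%). Class identity is encoded on two axes simultaneously:

- a binary **active-channel mask** cycling through the 15 non-empty
  masks of 4 channels, with active gains drawn once from U(0.8, 1.5);
- a class-specific **carrier-band centre** swept from 60 to 140 Hz
  (40 Hz wide bands, small per-channel offsets), inside the 50–150 Hz
  region where most sEMG spectral energy concentrates.

Either axis alone makes all 12 default class signatures pairwise
distinct; together they guarantee that a linear classifier on band-power
features separates the classes (verified by a cross-validated logistic
regression exceeding 90% at 10 trials/class), so end-to-end failures
indicate pipeline defects rather than an impossible task.

Nuisance components mirror what a recording rig adds: baseline white
noise (default RMS 0.05 signal units), 50 Hz powerline interference
(default amplitude 0.2, random phase per channel) and slow drift (two
random sinusoids in 0.2–3 Hz, total default amplitude 0.3). Subject
identity is a multiplicative log-normal gain per subject (σ = 0.15)
refined by a per-channel log-normal jitter (σ = 0.10) — enough to make
subject-wise splits meaningfully harder than trial-wise splits, while
leaving the task solvable.

What the generator does **not** emulate: motor-unit recruitment
dynamics, signal nonstationarity within the plateau, electrode lift-off
artifacts, crosstalk between muscles, and session-to-session electrode
placement shifts. Passing tests therefore demonstrate correct pipeline
mechanics and an upper-bound sanity check, not expected accuracy on
recorded data. The per-class trial count is configurable, with a
47-trials-per-class preset (distributed round-robin over subjects)
matching the protocol this pipeline targets.

## Preprocessing

A second-order IIR notch at 50 Hz with Q = 30 (≈1.7 Hz −3 dB width at
2048 Hz) removes powerline pickup while sparing the adjacent 45–55 Hz
sEMG content; a 4th-order Butterworth high-pass at 6 Hz removes drift.
Both are applied forward–backward (zero phase) by default so the
scalogram inherits no phase distortion; a causal mode exists for
streaming-like use. Because a narrow notch rings for roughly Q/f₀
seconds, `filtfilt` is given up to 2 s of reflective padding so the
transient decays outside the returned samples. No 500 Hz low-pass is
applied: the analysis grid itself caps at 500 Hz and Nyquist is 1024 Hz.
Filtering is per-trial, matching how trials are stored.

## Time–frequency representation

Each channel is transformed with a complex (analytic) Morlet CWT. The
frequency grid spans 6–500 Hz at 1 Hz spacing (495 rows) by default;
scales are `s_i = C·f_s/f_i` so each scale's pseudo-frequency equals its
grid frequency. The wavelet parameters — bandwidth B = 4.0, centre
frequency C = 1.5 cycles in pywt's `cmorB-C` convention — were chosen so
the representation honours its own contract on a 1 Hz grid: pure tones
from 20 to 400 Hz localize to the nearest grid row (observed error ≤ 2
rows) and ≥ 50% of a tone's scalogram energy stays within ±5 rows. A
shorter wavelet (e.g. B = 1.5, C = 1) exhibits a systematic ~2% downward
peak bias at high frequencies and fails both properties.

The four channel scalograms are stacked vertically (CH1 on top). The
fused scalar field is resized bilinearly to the target image size
*before* colorizing, so interpolation happens in magnitude space rather
than colour space, then min–max normalized (log-magnitude optional) and
mapped through a colormap ("jet" by default, configurable). Min–max
normalization makes the image invariant to overall amplitude scale — a
deliberate property (class identity lives in the spectral pattern, not
the gain), tested explicitly. Degenerate constant fields map to the
colormap's lowest colour (all-zero) or mid-scale (non-zero constant);
cone-of-influence columns are retained, keeping image width uniform.

## Feature extractor

The extractor follows the dense-connectivity design: stem 7×7 conv,
stride 2, 64 filters, BN–ReLU, 3×3/2 max pool; dense blocks of 6 and 12
composite layers (BN–ReLU–Conv 1×1 bottleneck of 4k channels–BN–ReLU–
Conv 3×3 of k channels, k = 32, pre-activation order); transition layers
(BN–ReLU–Conv 1×1–AvgPool 2×2) with compression θ = 0.5. Growth rate and
compression are derivable from the block arithmetic (64 + 6·32 = 256,
256·0.5 = 128, 128 + 12·32 = 512, 512·0.5 = 256) and exposed as config.
Features are read after the second transition: 14×14×256 → 50,176-vector
at 224×224×3 input. Convolutions carry no bias (BN follows); weights use
Kaiming fan-in initialization, BN starts at scale 1 / shift 0; 3×3
convolutions pad by 1 so concatenation is shape-consistent.

Because no GPU tensor framework is a dependency, the network runs on a
small numpy layer library written for this package (im2col convolution,
exact batch-norm backward, max/avg pooling, Adam). Backward passes
through the dense concatenation accumulate gradient slices per feature,
which is what makes the "every dense layer receives gradient" property
testable by direct inspection.

## Classifier

The DBN head is an RBM stack sized flatten → 1024 → 1500 with a 12-way
softmax output. Pretraining is greedy CD-1 (k configurable): the first
RBM has Gaussian visible units with unit variance — features are
standardized per dimension using training-set statistics only — and
deeper RBMs are Bernoulli–Bernoulli, trained on the previous layer's
hidden probabilities. RBM weights start at N(0, 0.01²), biases at zero;
defaults are 10 pretraining epochs at lr 10⁻³. Gibbs sampling inside a
CD update uses common random numbers across batch rows, making the
update an exact row-average (duplicating a row changes nothing) while
each row's sample remains marginally Bernoulli. Fine-tuning turns the
stack into a sigmoid MLP (weights and hidden biases carried over), adds
a Glorot-initialized softmax layer, and trains everything with Adam on
cross-entropy. The FC baseline is the identical architecture with random
initialization and no pretraining. The unusual widening 1024 → 1500
layer is kept exactly as specified.

Joint fine-tuning of the convolutional extractor is available
(`finetune(..., extractor=..., images=...)`, or
`ExperimentConfig(finetune_extractor=True)`), but the experiment default
keeps the extractor frozen: with a from-scratch extractor on small
synthetic corpora, frozen random convolutional features preserve the
class structure and the comparison of interest is between classification
heads, not feature-learning schedules.

## Evaluation protocol

Splits are subject-wise: all trials of the held-out subjects form the
test set. Standardization constants, pretraining and fine-tuning see
training subjects only. Accuracy is per-trial percent correct; the
confusion matrix accumulates over splits. Class feature profiles are the
per-class mean (over test trials) of the spatial channel-mean vector of
the extracted feature map; dispersion per class is summarized by
QD = Q3 − Q1, mean absolute deviation, and the sample standard deviation
(n − 1 denominator, as printed in the formula it implements). Quartiles
use linear interpolation between order statistics (type 7), recorded in
report metadata. Pearson correlations between class profiles populate a
12×12 matrix; each class's correlations to the others feed a Tukey
box-plot summary with 1.5×IQR fences.

## Desk-scale benchmark

`scaled_benchmark_config` defines the standing synthetic experiment:
6 subjects × 12 classes × 8 trials (full-length 5 s trials at 2048 Hz),
frequency grid coarsened to 8 Hz steps (62 rows per channel), 64×64
images, dense blocks (3, 6) with growth 12 (feature side 4, flatten
976), DBN head 976 → 128 → 96 → 12 (10 pretrain epochs, 60 fine-tune
epochs, batch 32), two held-out subject pairs ({1,2}, {3,4}), and five
training seeds for the DBN-versus-FC comparison. These sizes keep a full
run to a few minutes on one CPU while leaving every stage of the
pipeline exercised at realistic signal length.

## Numerical choices and edge cases

- All randomness flows through `numpy.random.default_rng` with seeds
  derived from a single experiment seed; reports are bit-reproducible.
- HDF5 datasets are written with `track_times=False` so equal seeds give
  byte-identical files.
- Double preprocessing warns and returns the trial unchanged (flag-based
  idempotence).
- A frequency grid whose top exceeds Nyquist, odd spatial dimensions at
  a transition layer, out-of-range labels, constant vectors in a
  correlation, and enumeration requests beyond 20 RBM units all raise
  explicit errors.
- Exact RBM log-likelihood uses the free-energy form with a log-sum-exp
  partition function; tests check it against an independently coded
  joint-state enumeration.

## Known limitations

- The numpy network trains at CPU speed; the package targets method
  validation and small studies, not large-scale training.
- The synthetic benchmark saturates (100% at default settings), so it
  bounds pipeline correctness, not comparative performance of the two
  heads; the head comparison is therefore directional (DBN ≥ FC).
- EDF export is not provided; CSV and HDF5 cover interchange.
- t-SNE visualization of learned features is intentionally delegated to
  external tooling rather than re-implemented.
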