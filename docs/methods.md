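# Methods

## Problem setting

Transmission imaging of semi-translucent tissue at several discrete
wavelengths produces very dim image stacks: absorption and scattering leave
few photons at the camera, and localized absorbing regions
("heterogeneities", tumor analogs) appear only as faint shadows.  Two
classical signal-recovery techniques raise the usable signal:

* **Frame accumulation (FA)** — averaging N consecutive frames divides the
  variance of uncorrelated noise by N.
* **Modulation–demodulation (M_D)** — the illumination intensity is made to
  oscillate sinusoidally at a carrier frequency f (3.5 or 4 Hz here); a
  lock-in demodulator then recovers the component of each pixel's time
  series at f, rejecting noise outside a narrow band around the carrier.

Their composition, **M_D-FA**, demodulates and then accumulates over each
carrier cycle.  The package implements the full chain — simulation,
preprocessing, quality metrics, pseudo-color fusion, dataset bookkeeping,
and the VGG16-family classifiers used to tell the heterogeneity classes
apart — on a synthetic phantom with known ground truth.

## Phantom simulator

The simulator is a Beer–Lambert stand-in for the real optics: each pixel's
transmittance is `exp(-OD)` with the optical density the sum of a
per-wavelength background term (the turbid medium) and the extra OD of
every inclusion covering the pixel (overlaps add).  This is deliberately
simpler than radiative transfer — no photon migration, no PSF, no
polarization — but it gives exact ground truth for transmittance, masks and
class labels.

The default phantom is a 96×96 px slab at four wavelengths (435, 546, 700,
860 nm) with six rectangular inclusions, two each of three materials,
centred around two-thirds of the slab width.  Material spectra follow the
qualitative contrasts of vegetable blocks used in transmission phantoms:
potato is the most translucent at every wavelength, carrot absorbs most
strongly in the red band, and pumpkin is the most translucent in the near
infrared.  The second block of each material is slightly larger and denser
(+0.06 OD), so the six blocks form six distinguishable classes, as in the
six-category classification task the pipeline targets.

Acquisition: the expected digital level is
`base_intensity * gain * transmittance * (1 + depth * sin(2π f t / fs))`,
to which Poisson shot noise (photon-equivalent counts, variance = gain ×
expected level) and Gaussian read noise are added before clipping and
quantizing to 8 or 16 bits.  A single camera seed fully determines the
noise stream.  The default study condition is deliberately dim: mean level
30 digital units on an 8-bit range, modulation depth 0.6, read noise 2 DU.

Sampling is `fs = f × frames_per_cycle` by default so that one carrier
cycle spans exactly 12 frames and accumulation windows are
cycle-synchronous.  (A 45 fps camera with a 3.5 or 4 Hz carrier cannot give
integer 12-frame cycles; the 12-frame cycle is taken as the defining
bookkeeping unit.)

What the simulator does **not** emulate: speckle, spatially correlated
noise, illumination nonuniformity, carrier frequency drift or jitter,
camera PSF and vignetting, and real fat-emulsion calibration.  Passing
tests therefore demonstrate the correctness and internal consistency of the
algorithms under controlled noise, not performance on real rig data.

## Preprocessing

* `frame_accumulate(seq, window)` averages non-overlapping blocks of
  `window` frames; trailing remainder frames are dropped (and counted in
  the metadata) so each output is the mean of exactly `window` inputs.  The
  output stays floating point — requantizing would forfeit part of the
  noise gain.
* `locate_carrier` takes the DFT of the spatial-mean time series (robust at
  low light), excludes DC, optionally restricts the search to
  `expected ± halfwidth`, and returns the magnitude-peak bin; ties break
  toward the lowest bin.  A peak below 3× the median off-peak magnitude
  raises a no-carrier error.
* `demodulate` is a per-pixel coherent lock-in: subtract the temporal mean
  (the carrier rides on a large DC transmittance term), mix with in-phase
  and quadrature references at the estimated carrier, low-pass both
  products with a centered moving average (reflected boundaries), and
  return the amplitude `2·sqrt(I² + Q²)` per frame.  Amplitude rather than
  phase is returned because the downstream use is intensity imaging, and
  the quadrature sum makes the estimate insensitive to the unknown carrier
  phase and to the sub-bin frequency error of the DFT estimate.  Frame
  count is preserved; frames within half a filter window of either end are
  boundary-affected and flagged.
* `md_fa` composes carrier location, demodulation and accumulation over one
  carrier cycle (window = `frames_per_cycle`).

**Lock-in integration time.**  The moving-average length is expressed in
carrier cycles (`lowpass_cycles`, default 10).  The default matters: a
moving average spanning a single cycle has an equivalent noise bandwidth
equal to the carrier frequency itself and rejects almost no broadband
noise, while the demodulated amplitude is smaller than the DC level by the
modulation depth m.  Under purely white noise the relative noise of M_D-FA
versus FA behaves like `(1/m)·sqrt(2/c)` with c the integration length in
cycles, so for m = 0.6 the lock-in chain only overtakes plain accumulation
for c ≳ 6.  Standard lock-in practice sets the time constant well above the
carrier period; ten cycles narrows the band to a tenth of the carrier while
remaining short against the 240–1,200-frame records used here.  With this
default the measured mean image SNR at the dim-light study condition orders
M_D-FA > FA > raw, which is the point of the combined technique.

## Image-quality metrics

`snr_db` is the single-image statistic
`10·log10(Σ f² / Σ (f − mean f)²)` — total signal power over
deviation-from-mean power, in dB.  It is scale-invariant and rewards noise
suppression relative to the retained level.  `mse`/`psnr_db` are the usual
reference-based measures; the PSNR peak defaults to `2^bit_depth − 1` of
the reference (a peak is undefined for float images, so it is an explicit
argument).  Degenerate cases (constant image, identical pair) are reported
as flagged infinities rather than exceptions so that batch sweeps over
wavelength/condition grids never abort; an all-zero image has no defined
signal and raises.  The logarithm is base 10 throughout (decibel
convention).

## Fusion and dataset bookkeeping

Pseudo-color images assign three of the four wavelengths to the R, G and B
channels; order matters, giving A(4,3) = n(n−1)(n−2) = 24 assignments,
enumerated lexicographically over the input wavelength order.  Channel
normalization is bit-depth scaling by default (keeps radiometry comparable
across combinations); per-channel min–max stretching is available for
display.  `crop_by_mask` cuts one patch per labeled heterogeneity (tight
bounding box plus padding, out-of-label pixels zeroed).

`dataset_counts` is pure arithmetic over an acquisition plan of
wavelengths × phantom configurations × illumination conditions.  With the
full campaign (4 × 5 × {unmodulated, 3.5 Hz, 4 Hz}, 1,200 frames per set,
12-frame windows) it yields 72,000 raw frames; 2,000 FA frames (unmodulated
sets), 48,000 demodulated frames (modulated sets, count-preserving), 4,000
M_D-FA frames; and 144,000 / 12,000 / 288,000 / 24,000 pseudo-color frames
for the original / FA / M_D / M_D-FA branches (per-wavelength time slots ×
24 assignments).  The original pseudo-color branch is built from the
unmodulated sets, matching the FA branch's bookkeeping.

`split_dataset` is a stratified 6:1:3 train/validation/test split with
largest-remainder apportionment per class — exact, deterministic and
summing to n (100 one-class items split 60/10/30).  Classes with fewer
than three members cannot be stratified and stay whole in the training
split, with a warning.

## Classifier variants

Four architectures share the 13-convolution, 5-stage VGG16 backbone
(widths 64, 128, 256, 512, 512; 3×3 kernels, stride 1, padding 1; 2×2/2
max pooling):

* **base** — backbone + three dense layers (4096, 4096, classes), dropout
  0.5 on the two hidden dense layers;
* **bn** — batch normalization after every convolution;
* **bn_se** — additionally squeeze-and-excitation attention with bottleneck
  ratio r = 16, placed after each convolution (default) or once per stage;
* **bn_se_gap** — the dense stack replaced by global average pooling plus a
  single linear map to the class count (a strictly parameter-free head
  cannot map 512 channels onto 6 classes, so one linear layer remains; this
  is an explicit interpretation).

The SE block computes a per-channel spatial mean z (squeeze), channel
weights `s = sigmoid(W2·relu(W1·z))` with bias-free projections W1 ∈
R^(C/r×C), W2 ∈ R^(C×C/r) (excite), and rescales channel c by s_c — so no
channel's activation can grow in magnitude.

Parameter accounting is closed-form (conv `Cin·Cout·9 + Cout`, dense
`in·out + out`, batch norm `2C`, SE `2C²/r`, pooling 0) and is verified
against a brute-force traversal of instantiated networks.  With the default
plan: a single SE block at C = 512, r = 16 holds 32,768 parameters;
per-stage SE totals 76,288 (≈0.06 % of the model); the GAP head removes
roughly 89 % of the 6-class dense-head model's parameters.  The exact
published totals for this family depend on unstated head/bias conventions,
so parameter claims are checked directionally (GAP variant < 15 % of base;
per-stage SE share < 0.1 %), not as exact reproductions.

The networks run on a compact numpy CNN engine (`mdfa.nn`) with explicit
forward/backward passes, verified layer-by-layer against central-difference
gradients.  Training uses Adam on softmax cross-entropy; the exposed
defaults mirror the study protocol (batch 32, learning rate 1e-4, weight
decay 5e-4, 30 epochs, dropout 0.5; the "momentum 0.9" of that protocol is
read as Adam's β₁).  Weight initialization is He-normal and fully
seed-determined; batch order and dropout masks derive from the training
seed, so runs are bit-reproducible single-threaded.

## Desk-scale evaluation harness

`run_experiment` binds the whole chain: simulate four-wavelength stacks of
the six-block phantom per preprocessing branch (raw / FA / M_D / M_D-FA at
matched noise), fuse pseudo-color images, crop per-block patches, split
6:1:3, train the requested variants and report one-vs-rest and macro
metrics from the test confusion matrix.  Macro (unweighted) averaging is
used for multi-class summaries; ratios with zero denominators are 0 with a
flag.

The default profile is sized for a single CPU: 32×32 patches placed on a
fixed canvas (preserving block size as a cue), stage widths divided by 4,
2 channel assignments, 48 output frames per branch (≈570 patches), 10
epochs at learning rate 1e-3.  The raised learning rate and reduced epochs
are a deliberate desk-scale trade: the small-width network on ~340 training
patches converges in a few hundred Adam steps, where the full-scale
protocol's 1e-4/30-epochs schedule is built for ImageNet-initialized
models on hundreds of thousands of patches.  Patches are standardized per
branch (global mean/SD) because the branches differ in absolute scale
(demodulated amplitudes carry the depth factor m).

Trend studies report the mean Eq-5-style image SNR per branch over 20
replicate stacks and the mean test accuracy per branch over 3 seeds.  They
assert orderings (M_D-FA > FA > raw for SNR; M_D-FA ≥ FA ≥ raw for
accuracy), not absolute published values: the original stacks are not
deposited and the published accuracies come from GPU-scale training, so
absolute reproduction is out of reach at desk scale by design.

## Numerical and degenerate-input choices

* Carrier ties break to the lowest DFT bin; DC is always excluded.
* FA remainder frames are dropped, never partially averaged.
* Overlapping inclusions sum ODs when rendering; the later label wins in
  the ground-truth mask (both documented, neither an error).
* Moving-average boundaries use reflection; affected frames are flagged,
  and interior-only comparisons are used in recovery tests.
* Saturating expected intensities set a metadata warning and clip.
* `input_size` must be a multiple of 32 (five 2×2 poolings).
* Infinite SNR/PSNR are values, not exceptions; all-zero images raise.

## Known limitations

* The optical model is attenuation-only; scattering blur and depth effects
  are absent, so real-data contrast between materials will be weaker and
  less cleanly separable than the synthetic classes.
* The lock-in assumes a stable carrier; drift/jitter correction and
  multi-carrier separation are out of scope.
* The CNN engine is single-threaded numpy: adequate for the desk-scale
  profile, not for full-resolution (224 px, width-512) training.
* Classification results on the synthetic task (near-perfect at the default
  noise) indicate pipeline correctness and preserve the preprocessing
  ordering, but do not predict absolute accuracy on real phantom imagery.
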