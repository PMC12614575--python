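# mdfa

Modulation–demodulation frame-accumulation (M_D-FA) preprocessing and
CNN classification for low-light **multispectral transmission imaging**
(MTI) of tissue phantoms.

Transmission imaging of semi-translucent tissue — the setting for optical
screening of breast heterogeneities — produces very dim stacks: absorption
and scattering leave few photons, and lesion analogs appear only as faint
shadows.  This package implements the two classical low-light recovery
techniques and their composition, the metrics that quantify the gain, the
pseudo-color wavelength-fusion/dataset machinery, and the VGG16 classifier
family used to identify the heterogeneities, together with a synthetic
phantom simulator that provides exact ground truth:

* **FA** (frame accumulation): mean over each window of N = 12 consecutive
  frames; uncorrelated noise variance drops by N.
* **M_D** (modulation–demodulation): the illumination oscillates at a
  carrier f (3.5 / 4 Hz, 12 frames per cycle); the carrier bin is located
  by FFT of the spatial-mean series and each pixel is demodulated by a
  coherent lock-in, returning the amplitude 2·√(I² + Q²) per frame.
* **M_D-FA**: demodulation followed by cycle-synchronous accumulation.
* **Quality metrics**: single-image SNR = 10·log₁₀(Σf² / Σ(f − f̄)²),
  MSE, and PSNR = 10·log₁₀(MAX²/MSE), all in dB.
* **Fusion**: A(4,3) = 24 ordered assignments of 3 of 4 wavelengths to RGB;
  mask-based per-heterogeneity cropping; campaign frame bookkeeping;
  stratified 6:1:3 splits.
* **Models**: VGG16, VGG16_BN, VGG16_BN_SE (squeeze-and-excitation channel
  attention, ratio r = 16) and VGG16_BN_SE_GAP (dense head replaced by
  global average pooling), with closed-form parameter accounting, on a
  compact numpy CNN engine with seed-exact training.

See `docs/methods.md` for the model assumptions, parameter defaults and
limitations.

## Worked example

```python
import numpy as np
from mdfa import (CameraSpec, ModulationSpec, default_phantom,
                  simulate_sequence, frame_accumulate, md_fa, snr_db)
phantom = default_phantom()                       # 96x96, six blocks, 4 bands
mod_off = ModulationSpec(3.5, 0.0, 12)            # unmodulated
mod_on  = ModulationSpec(3.5, 0.6, 12)            # 3.5 Hz carrier, depth 0.6
cam     = CameraSpec(base_intensity=30, read_noise_sd=2.0, seed=0)

raw  = simulate_sequence(phantom, 0, mod_off, cam, 240)   # dim 8-bit stack
fa   = frame_accumulate(raw, 12)                          # 240 -> 20 frames
mdfa = md_fa(simulate_sequence(phantom, 0, mod_on, cam, 240), mod_on)

for name, seq in [("raw", raw), ("FA", fa), ("M_D-FA", mdfa)]:
    print(name, round(float(np.mean([snr_db(f) for f in seq.frames[:20]])), 2), "dB")
```

prints (seed 0):

```
raw 11.61 dB
FA 17.14 dB
M_D-FA 17.51 dB
```

The raw dim-light frames sit near 11.6 dB; averaging each 12-frame cycle
buys ~5.5 dB, and demodulating at the carrier before accumulating buys a
further ~0.4 dB at these noise settings — the ordering
M_D-FA > FA > raw that motivates combining the techniques.

Campaign bookkeeping for the full acquisition plan (4 wavelengths ×
5 phantom configurations × 3 illumination conditions × 1,200 frames):

```bash
$ mdfa plan-counts
{
  "total_raw_frames": 72000,
  "fa_frames": 2000,
  "md_frames": 48000,
  "mdfa_frames": 4000,
  "pseudo_original": 144000,
  "pseudo_fa": 12000,
  "pseudo_md": 288000,
  "pseudo_mdfa": 24000,
  "channel_assignments": 24
}
```

## Command line

`mdfa` exposes the pipeline as composable stages sharing one YAML config:

```bash
mdfa simulate   --config run.yaml --out out/sim --seed 1
mdfa preprocess --in out/sim --mode mdfa --window 12 --out out/pre
mdfa quality    --in out/pre --reference out/sim --out out/report.csv
mdfa fuse       --in out/pre --combos 4 --out out/patches
mdfa model-report --variant bn_se_gap --se-placement per_stage
mdfa evaluate   --config sweep.yaml --out results/
mdfa pipeline   --config run.yaml --stages simulate,preprocess,quality,fuse --out out/
```

Every stage writes a manifest with SHA-256 checksums and the config hash;
deterministic stages reproduce identical checksums on rerun.

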