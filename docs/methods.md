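# Methods

## Problem and model

`pulsevit` estimates heart rate remotely from facial video
(remote photoplethysmography, rPPG). The cardiac cycle modulates blood
volume in skin capillaries, which modulates the light the skin reflects;
the green channel carries the strongest pulse signal-to-noise ratio. The
pipeline is:

1. **ROI masking.** Each frame comes with 68 facial landmarks
   (17 face outline, 10 eyebrow, 9 nose, 10 eyes, 22 mouth). Two forehead
   points are constructed by lifting the left-most and right-most eyebrow
   points upward by `k` times the height of the landmark bounding box
   (default `k = 0.25`, a configuration knob; this reaches mid-forehead on
   the synthetic face). The frame is masked to the convex hull of all 70
   points — pixels outside are zeroed, boundary pixels count as inside. The
   hull is used because "inside the landmarks" needs a concrete polygon and
   the hull covers forehead and cheeks without cutting eye/mouth holes.
2. **Crop / resize / normalize.** The nonzero region is cropped to its
   bounding box, zero-padded (centered) to square to avoid aspect
   distortion, bilinearly resized to the backbone's input size (224 for the
   full model, 64 for the CPU preset), scaled to [0, 1], and per-channel
   standardized with the ImageNet constants (configurable to identity).
3. **Windowing.** Non-overlapping windows of `W = 15` frames with stride 15
   (stride = W decorrelates training samples). Trailing partial windows are
   dropped rather than padded. Sources above the working rate are first
   down-sampled by nearest-index frame selection (e.g. 60 → 25 FPS). Each
   window is labeled with the (min, max, avg) of the heart-rate trace
   piecewise-linearly interpolated at its frame timestamps.
4. **Models.** Variant A: a frame-wise vision transformer (ViT-small
   geometry: 12 blocks, patch 16, width 384), whose per-frame class tokens
   feed a BiLSTM; a three-layer linear stack regresses one BPM value.
   Variant B: class tokens are tapped at five transformer depths
   (blocks 0, 3, 6, 9, 11 — roughly evenly spaced to avoid redundant
   features); each tap has its own decoder head (BiLSTM → batch norm →
   1D convolution along time → temporal mean-pool → linear) emitting an
   interval triple (min, max, avg) BPM. Training averages the five triples
   and minimizes the MAE of the three components against the window label.
   Inference fuses the averaged triple:

       HR = 0.25 * (min + max) / 2 + 0.75 * avg

   an affine combination with weights (0.125, 0.125, 0.75).
5. **Evaluation.** MAE and RMSE of the fused BPM against the window-average
   heart rate; RMSE ≥ MAE always (power-mean inequality).

A classical **green-channel spectral oracle** is included as a
learning-free baseline: spatial mean of green over the masked skin,
detrended by a 1 s moving average, Hann-windowed, zero-padded to ≥ 8192
samples, and the heart rate read off the spectral argmax in 0.7–3.0 Hz
(42–180 BPM, a standard physiological band). It doubles as an independent
check that synthetic videos encode their programmed rate.

## Synthetic data

Real rPPG corpora cannot ship with a test suite, so the generator emulates
their essential structure: an elliptical skin-colored region whose color is
modulated by a pseudo-PPG waveform, exact landmark tracks laid out by
formula on the ellipse, and an exact BPM trace.

- **Waveform**: phase-accumulator synthesis, sinusoid plus a second
  harmonic at 0.25 amplitude (a crude dicrotic notch). The fundamental
  dominates the spectrum, so spectral recovery of the programmed rate is
  unambiguous. PPG is sampled at 60 Hz, video rendered at 25 FPS, matching
  common recording setups.
- **Modulation routing**: green receives the full modulation depth,
  red/blue half of it, encoding the green channel's superior SNR so the
  green baseline is the right estimator.
- **Defaults**: 64×64 frames, 25 FPS, 30 s, modulation depth 0.05, no
  noise, no motion. Depth 0.05 keeps the skin-color swing (±7–8 digital
  levels out of 255) small relative to the mean, comfortably above the
  uint8 quantization floor at this frame size. Noise SD, illumination
  drift, and rigid jitter (integer-pixel, so landmark tracks stay exact)
  are free parameters; no published noise statistics exist for the target
  recordings, so they default to zero.
- **What it does not emulate**: photorealistic appearance, head pose beyond
  rigid jitter, skin-tone diversity, sensor rolling shutter, compression.
  Passing tests show the pipeline recovers a clean pulse signal end to end;
  they do not certify accuracy on real faces.

## Training

- **Engine**: the models run on a small reverse-mode autograd over numpy
  (`pulsevit.nn`), with gradients validated against central finite
  differences in the test suite. All arithmetic is float32; runs are
  deterministic given the seed (same-seed reruns reproduce the metric log
  bit-for-bit).
- **Optimizer**: Adam. The fixture recipe uses learning rate 3e-3 (inside
  the published tuning range [1e-6, 1e-1]) and batch size 32. Small batches
  (2–8) make the MAE gradient too noisy for the decoder to discover the
  temporal-frequency structure on the small fixture — it then collapses to
  predicting the training-mean rate — so the fixture batch is larger than
  the published search grid {2, 4, 8}, which targeted GPU-scale corpora.
  Learning rate 0 is accepted as a degenerate dry run in which nothing,
  including normalization statistics, may change.
- **Staged schedule (variant B)**: heart-rate information reaches the
  decoder as a low-amplitude oscillation of the per-frame embeddings, so
  the heads need many cheap, smooth gradient steps before the backbone is
  touched. Phase 1 caches the frozen backbone's class-token taps once and
  fits the five heads jointly on the head-averaged MAE loss (default 6000
  steps at batch 32 — cached-feature steps cost milliseconds); phase 2
  fine-tunes the whole model end to end at a tenth of the learning rate.
  Joint end-to-end training from step one needs several times more full
  backbone passes to leave the predict-the-mean plateau. ``head_steps=0``
  selects plain end-to-end training; variant A always trains end to end.
- **Splits** are by video (80/20, seeded), never by window, to prevent
  window-level leakage.
- **Budget**: the parameter-recovery fixture is 8 constant-rate videos
  (50–110 BPM, 30 s, 25 FPS, 64×64), about 400 windows; the recipe is 6000
  head steps plus 10 fine-tune epochs — a full run fits in under ten
  minutes on one CPU. The best-validation-MAE checkpoint is kept; no
  patience logic.
- **Head dimensions** (not published): BiLSTM hidden 128 per direction
  (tiny: 32), 1D conv kernel 3 with 64 channels (tiny: 16), linear to 3
  outputs; variant A linear stack 2·hidden → 256 → 64 → 1 (tiny:
  32 → 16 → 1). Head outputs are raw reals; an optional inference clamp to
  [30, 240] BPM is off by default.
- **Tiny preset**: depth 6, width 32, 2 heads, image 64, taps scaled as
  round(i·(depth−1)/11) → (0, 1, 3, 4, 5). Depth 6 is the smallest depth at
  which the scaled taps stay strictly increasing.
- **Hyper-parameter search**: a plain grid utility over the published
  ranges (learning rate [1e-6, 1e-1], batch {2, 4, 8}) replaces scheduler-
  based tuning; the scheduler choice is incidental to the method.

## Numerical choices

- Hull membership uses the hull's half-plane equations with a 1e-9 slack,
  so boundary pixels count as inside.
- Window labels clip the interpolated mean into [min, max]; float summation
  can otherwise put the mean of a constant trace an ulp outside the bounds.
- FPS down-sampling keeps indices `round(j·source/target)`, de-duplicated;
  no temporal blending.
- Batch norm normalizes the feature axis with statistics over batch and
  time (momentum 0.1); inference uses running statistics, which makes
  per-window outputs independent of batch composition.
- Degenerate inputs fail loudly: all-zero masked frames, collinear
  landmark hulls, empty HR traces, videos shorter than one window (the
  last returns an empty result rather than an error so callers can skip).

## Known limitations

- The full-size preset initializes randomly; no pretrained transformer
  weights are bundled, so published-scale accuracy on real corpora is out
  of reach here and is not claimed.
- The green oracle assumes a quasi-stationary rate over the analysis
  span; strongly time-varying rates smear the spectral peak.
- The synthetic fixture has no motion or illumination confounds by
  default, so the learned model's robustness claims are limited to clean
  signals.
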