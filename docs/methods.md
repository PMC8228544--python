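# Methods

## Sonification model

An image `I ∈ [0,1]^{H×W}` (row 0 at the top) is encoded into a mono
waveform of duration `D = D₀·(1 − r)`, where `D₀` is the base duration
(default 1 s, i.e. one image frame per second) and `r ∈ [0,1)` the
compression ratio.  `D` is divided into `W` equal column slices scanned
left to right; during slice `j` the signal is

    s(t) = Σ_i a_ij · sin(2π f_i t),     a_ij = I[i,j] / H,

with `f_i` on a log-linear scale from `f_min` to `f_max` (defaults 500
and 5000 Hz): `f(k) = f_min·(f_max/f_min)^{k/(H−1)}` for row `k` counted
from the bottom, so higher image rows map to higher pitch.  Design
choices the encoding leaves open and how they are fixed here:

* **Compression as faster scan.**  `r` shortens the column slices at
  unchanged row frequencies.  The alternative — resampling a rendered
  waveform — would shift every frequency and destroy the row→pitch code,
  so it is not offered.  A corollary worth testing (and tested): the set
  of active frequencies is invariant under `r`.
* **Amplitude law** is linear in brightness, scaled by `1/H` before a
  global peak normalization to `peak_level` (default 0.9); a silent image
  stays silent rather than being renormalized.
* **Phase** is continuous across slices (`φ_i = 0` at `t = 0`), which
  avoids clicks at slice boundaries.
* **Onset click**: an optional broadband burst (50 ms for behavioral
  stimuli, 0 in the model pipeline), prepended and excluded from the
  scan duration.
* Sampling rate defaults to 22 000 Hz; 22 050 is accepted via config.

The verification decoder projects each column slice onto complex
exponentials at the row frequencies and reports normalized magnitudes; it
is a diagnostic for the codec, not the model of perception.

## Log-mel frontend

Magnitude STFT (periodic Hann, `n_fft` 512 / hop 128 by default, no
centering) → triangular mel filterbank (HTK mel scale, 0 Hz to Nyquist,
64 bands) → `log(x + 10⁻⁶)` → the frame axis is brought to a fixed
`n_frames` (64) by linear resampling.  Resampling rather than
zero-padding keeps compressed soundscapes information-dense; pad-to-length
is available behind `pad_mode="pad"`.  The fixed output shape is what
lets one audio network serve every compression ratio.  All frontend
parameters are configuration, chosen so the default feature is a square
64×64 input that survives four 2×2 poolings.

The same computation is also expressed entirely through differentiable
primitives: sonification as a constant `(H·W) × T` sinusoid-basis matrix
product, framing as a gather, the DFT and mel projections as matrix
products, then log.  The two routes agree to ~10⁻⁹ relative (tested at
10⁻⁴) and the pixel gradients pass finite-difference checks; this graph
is what the GAN trains through.

## Networks and training

All networks run on a small reverse-mode autodiff engine written on
numpy (float64), shipped as `soundsight.nn`; every primitive is verified
against finite differences in the test suite.

* **Audio encoder**: 4 × (3×3 conv, ReLU, 2×2 max-pool) → 3 fully
  connected layers; the 128-wide penultimate ReLU activation is the audio
  embedding.  Adam, batch 64, learning rate 10⁻⁴, 10 epochs.  Channel
  widths (16/32/64/128) and the first FC width (512) are free choices.
  Features are standardized with training-set statistics.  A separate
  encoder is trained per compression ratio, isolating the ratio's effect.
* **Baseline image classifier**: 3 × (conv + pool) + 1 conv, a 128-wide
  dense embedding layer and a softmax output; the judge of generated
  images, and the feature extractor for the Fréchet distance.
* **Cross-modal AC-GAN**: generator = dense layer to a `(size/4)²` base
  map, two upsampling steps each quadrupling the feature-map area
  (side ×2), sigmoid output in [0,1]; discriminator = two conv/pool
  blocks on the log-mel feature with a sigmoid source head and a softmax
  class head.  Both paths into the discriminator pass through
  sonification + log-mel, so the discriminator never sees a raw image.
  Losses are the standard auxiliary-classifier pair; the class term's
  weight is configurable (0 = vanilla conditional GAN).  Output heads are
  initialized at small scale so an untrained discriminator is neutral;
  the discriminator can run at a lower learning rate than the generator
  (two-timescale updates), which stabilized training at small scale.
  Embeddings are precomputed from real soundscapes and the encoder stays
  frozen during GAN training.

## Sensitivity analysis

For each compression ratio: train the encoder, train `n_repeats` GANs
(all randomness derived from `(seed, ratio, repeat)`), generate samples
conditioned on held-out audio embeddings, and record (i) baseline-
classifier accuracy against the conditioning class, (ii) inception score
computed with the baseline classifier, (iii) Fréchet distance between
baseline-classifier embeddings of real and generated images.  The
*degradation knee* operationalizes "accuracy stops being stable" as the
smallest ratio whose accuracy standard deviation exceeds `sd_factor`
(default 3) times the median sd of all smaller ratios.  "Accuracy stops
being stable" is a qualitative notion; the sd-jump rule is this
package's formalization of it.

Two profiles are provided.  The **full profile** is the full-scale
experiment (10 digit classes at 28×28, 22 kHz / 1 s codec, 64×64
log-mel, GAN batch 100 for thousands of epochs, 5000 generated samples,
10 repeats); it is the configuration of record but needs hours of CPU.
The **toy profile** is the package's fast configuration and the one the
tests exercise: two well-separated glyph classes at 8×8, an 8 kHz /
0.4 s codec (frequencies 500–3500 Hz), 16×16 log-mel features, a
narrower encoder, and a GAN trained for 250 epochs with batch 20,
generator learning rate 2·10⁻³, discriminator 5·10⁻⁴ and class-loss
weight 3.  At this scale the pipeline reliably recovers the classes at
zero compression and degrades, with rising variance, by 90% compression
— the same direction as the full-scale analysis, at much coarser
resolution.

## Synthetic stimuli

* **Digit-like glyphs** replace a handwritten-digit corpus so tests are
  hermetic: ten stroke patterns (seven-segment style plus a diagonal)
  rendered with an anti-aliased distance field, then jittered by a
  seeded affine map (rotation ±10°, shift ±7%, scale 0.9–1.1).  They are
  cleanly separable — a classifier reaches >90% held-out accuracy — but
  lack the stroke-thickness and style variability of real handwriting,
  so passing tests show pipeline correctness, not performance on
  handwritten digits.  A loader for locally present IDX files exists;
  nothing is downloaded.
* **Shape set**: circle, square, triangle, cross, horizontal line, plus
  four affine variants each (scale, aspect, rotation+shift, shear) with
  small seeded parameter jitter — 25 images.  Which five basic shapes to
  use, and how to build the variants, are open choices; this set is an
  explicit stand-in with the standard cardinality and structure (5 basic
  + 20 variants).
* **Splits**: test = round(0.2·N) (half-up), validation = round(0.2·0.8·N)
  from the remainder, rest train; exhaustive and disjoint for any N ≥ 10.

## Behavioral protocol and simulated observer

Each session has a fixed structure: 15 training images
(5 basic + 10 seeded-random variants) × 10 repetitions = 150 training
trials in a pseudo-random order without immediate repetition; evaluation
= all 25 shapes × 5 = 125 four-alternative forced-choice trials with
three distractors drawn without replacement from the other 24 shapes and
the target slot uniform over the four positions (chance 0.25); five
repetitions per shape follow from 125 trials over 25 shapes.  Response
times are not modeled.

The simulated observer is a logistic psychometric link: recognition
probability `σ((d − d₅₀)/w)` in soundscape duration `d`, scaled by a
skill state that saturates exponentially with training exposure, floored
at chance and capped by a lapse rate.  `w = 0` gives a hard threshold
(used by the deterministic staircase tests); `w = ∞` gives
duration-independent behavior (the crossover null).  Staircase draws are
indexed by `(seed, item, level)` so a strictly more sensitive observer
can never receive a lower sensitivity score on the same seed and grid —
the monotonicity the procedure promises.  The observer is protocol
plumbing: it makes no claim about human listeners.

## Numerical choices and limitations

* float64 throughout; gradient tolerances 10⁻⁶ (primitives), 10⁻³
  (frontend pixel gradients), 10⁻² (full GAN path).
* Fréchet matrix square root via `scipy.linalg.sqrtm` with a real-part
  cast; rank-deficient covariances (fewer samples than embedding
  dimensions) are regularized with `10⁻⁶·I` under a warning, and tiny
  negative distances of numerical origin are clamped to zero.
* Inception score is computed on all samples at once by default; a
  `splits` option provides the conventional split-averaged variant.
* Peak normalization divides by `max(|x|) + 10⁻¹²` in the differentiable
  route (exact division in the reference route); the discrepancy is
  ~10⁻¹¹ relative.
* The GAN at toy scale occasionally produces a weak repeat; the sweep
  reports mean and sd over repeats rather than single runs for exactly
  this reason.
* No stereo panning, no real-time capture, no alternative encoders, no
  WGAN/hinge losses, no image-to-sound direction, and no statistical
  inference beyond means and standard errors in the protocol module.
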