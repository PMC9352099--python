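# Methods

This note records the models and procedures the package implements, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic-data harness does and does not establish.

## Synthetic dermoscopy generator

Each sample is a skin-toned background (default RGB (224, 172, 148)) with
i.i.d. Gaussian texture noise (sd 6 intensity units), a lesion drawn as a
filled ellipse whose boundary radius is modulated by three random Fourier
harmonics (amplitude = `border_jitter`, a fraction of the radius, < 0.5 so
the region stays star-shaped and 4-connected), dark quadratic-Bezier hair
strokes crossing the frame, and small bright discs emulating air bubbles.
The ground-truth mask is recorded **before** hairs and bubbles are painted,
so artifacts may cross the lesion without altering the truth — the
situation hair removal exists to handle.

Class styles: benign lesions draw colors from a light range
(RGB ≈ 150–180 / 105–135 / 85–110) with border jitter 0.03–0.10; malignant
from a dark range (≈ 60–110 / 35–70 / 25–55) with jitter 0.18–0.32. Axes
are sampled at 13–28 % of the frame side. These defaults give a mean
lesion-intensity gap of roughly 70 grey levels between classes — large
enough that a small network can learn the distinction from a few hundred
examples, which is the point of the harness.

Per-sample streams are spawned from `(dataset seed, sample index)` via
`numpy.random.SeedSequence`, so datasets are bit-reproducible and
order-independent. Coordinates are 0-based `(row, col)`.

What the generator does **not** emulate: diagnostic dermoscopic
microstructures (pigment networks, streaks, globules), specular gel
reflections, vignetting, camera noise models, or the inter-class ambiguity
of real lesions. Passing tests therefore demonstrate algorithmic
correctness and end-to-end plumbing, not clinical performance.

## Preprocessing

Closing uses a *flat* (grayscale max/min) structuring element, applied
independently per RGB channel, because the pipeline operates on color
photographs while the defining set formulas are binary; the flat max/min
form is the standard grayscale extension. Default kernel: cross 15×15 —
large enough to erase hairs a few pixels wide anywhere in the frame.
Borders are replicate-padded so image edges do not darken into artifacts
that would masquerade as lesion tissue downstream. Closing is idempotent
and extensive (close(x) ≥ x pointwise); both are asserted in the tests.

Gamma correction rescales to [0, 1], raises to γ (default 1.2, darkening),
rescales, and rounds half-away-from-zero. 0 and 255 are fixed points.

## Segmentation

* Grayscale conversion uses the standard luminance weights
  0.299/0.587/0.114 (the conversion itself is a convention; nothing
  downstream depends on the exact weights).
* The Otsu threshold is found by exhaustively scanning all 256 candidate
  levels and maximizing σ²(t) = w₀w₁(μ₀−μ₁)²; the scan *is* the
  implementation, and an independently coded brute-force scan plus
  scikit-image's `threshold_otsu` serve as oracles in the tests. A manual
  threshold of 120 exists as a documented fallback mode; the automatic
  threshold supersedes it by default.
* Mask polarity: lesions are darker than skin, so the raw "above
  threshold" mask marks skin white. When the white fraction exceeds one
  half the mask is inverted, making the lesion the foreground blob that
  the later stages select.
* Dilation kernel: 5×5 rectangle (only the size is prescribed; the
  rectangle is the simplest reading).
* The subtraction stage is defined only for mask-2 ⊇ mask-1; the
  impossible case (mask-2 black, mask-1 white) raises a warning and maps
  to black.
* Largest-blob ranking uses the pixel count of the *hole-filled*
  component, so a thin edge ring is ranked by the region it encloses
  rather than by its own thin area; ties break by scan order. Hole filling
  is the border-seeded complement (`scipy.ndimage.binary_fill_holes`),
  cross-checked against a hand-coded flood fill.
* One step of the published narrative applies an erosion to the
  subtraction output before blob selection; the mask chain implemented
  here goes directly from the edge ring to blob selection and filling,
  which matches the depicted mask sequence and the stated operation list.
* Degenerate inputs (constant image, empty foreground) return a result
  object with a `diagnostic` string instead of raising.

The final mask is slightly larger than the truth (it is the filled
*dilated* boundary), which costs a little Dice; over 50 synthetic lesions
the median Dice against ground truth is ≈ 0.94 (floor asserted: 0.90).

## Down-scaling and quality metrics

The bilateral filter is implemented directly as the normalized
double-Gaussian weighted mean over the d = 5 neighborhood, per channel,
replicate-padded. Defaults σ_color = σ_space = 75.

Box blur: the published radius-r description is internally inconsistent
(a "2r × 2r window" normalized as an average of four pixels); the
implementation uses the symmetric (2r+1)×(2r+1) uniform window that the
named radius-based filter actually computes, with the literal 2×2
four-pixel average available as `box_blur_four_pixel`. r = 0 is the
identity. Accumulation is float64, rounded half-away-from-zero.

PSNR is the standard 10·log₁₀(MAX²/MSE), MAX = 255. (A printed variant
20·log₁₀(MAX/MSE) is dimensionally inconsistent and does not reproduce the
reported 40–43 dB readings at MSE 3–5; the standard form does.) Identical
images report +∞. RGB pairs are converted to luminance before MSE, PSNR
and SSIM. SSIM uses the conventional 11×11 Gaussian window, σ = 1.5,
K₁ = 0.01, K₂ = 0.03 (scikit-image backend). DSC on photographs binarizes
both images at mid-intensity 128 first — a documented convention, since
Dice is defined on sets. Two empty masks give DSC 1.

Size accounting encodes both images with the same codec — lossless PNG by
default, so the ratio reflects information content; JPEG q85 is available
as a lossy alternative. The absolute KB figures depend entirely on the
codec, so the report records which one was used.

## Augmentation, split, folds, noise

The brightness and contrast operations are *factor* forms — brightness:
`clip(f · v)`; contrast: `clip(mean + f · (v − mean))` — with factors
1.3/0.7. (The published formulas present brightness as additive yet
describe both parameters as gains with those factor values; the factor
reading is the only one consistent with the quoted 1.3/0.7.) Photometric
augmentation emits the original plus four variants: an exact 5× count,
labels copied, dimensions unchanged.

Split rounding: per class, train = round-half-up(r_train·n),
test = round-down(r_test·n), validation = remainder. For the augmented
archive composition (9000 benign / 7485 malignant at 70:20:10) this yields
6300 + 5240 = 11 540 training images, matching the published training
total exactly. The published per-class validation/test counts for the
malignant class (1498/747) are *not* reproducible by any exact-arithmetic
rounding rule (0.2 × 7485 = 1497 exactly); the discrepancy is one sample
and most plausibly a floating-point artifact in the original tabulation,
so the rule above is used as stated.

k-fold partitioning is stratified (scikit-learn `StratifiedKFold`,
shuffled under the seed); per-class fold sizes differ by at most one and
every sample is validated exactly once.

Gaussian corruption interprets the noise "amount" (default 0.1) as the
**variance on unit-scaled intensities** — pixels are mapped to [0, 1],
i.i.d. N(0, amount) is added, then clipped and rescaled. Reading it as a
standard deviation or a salt-like proportion would be alternative
interpretations; the variance reading is the common convention of the
usual `random_noise`-style APIs.

## SCNN_12

Architecture constraints are forced by the published dimension chain:
valid (unpadded) stride-1 3×3 convolutions (224 → 222) and 2×2 stride-2
pooling with floor on odd sides (109 → 54). One sentence in the source
calls the convolutions 2×2, but every dimension and the repeated "3×3"
force 3×3. The stack: conv16 → pool → conv32 → pool → conv32 → pool →
conv64 → pool → flatten → dense-1024 (ReLU) → dropout 0.5 → dense-2 →
softmax. A sigmoid mode uses a single output unit with binary
cross-entropy.

The implementation is plain NumPy. Convolution forward/backward are
computed by summing kernel-offset shifts (nine tensordots for a 3×3
kernel); max-pool backward routes gradients through stored argmax indices;
dropout is inverted (scaled by 1/(1−p)) and active only in training.
Gradients are verified against central differences in the test suite.

Losses: binary and categorical cross-entropy, MSE, KL divergence, and
focal loss FL = −α(1−p)^γ y ln p − (1−α) p^γ (1−y) ln(1−p), with the
identity focal(γ=0, α=0.5) = ½ · BCE asserted. Probabilities are clamped
at 1e−7. The default training loss is categorical cross-entropy on the
2-unit softmax; binary cross-entropy is equivalent here and also
available.

Optimizers: Adam, Nadam, Adamax (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) with
classical L2 weight decay 1e−4 added to the gradient. The recorded
`momentum = 0.9` configuration value is honored as documentation only:
adaptive optimizers in this family carry momentum through β₁, not through
a classical momentum term.

Training is seeded and mini-batched (default batch 32); per-epoch train
and validation loss/accuracy are recorded and the weights of the
minimum-validation-loss epoch are restored at the end. A non-finite loss
aborts with a diagnostic. Two runs under the same seed are bit-identical.

A multi-network total-loss combination (weights A, B, C) that appears in
the source alongside the focal loss weights a *set* of networks the
single-model pipeline never trains; it is deliberately not implemented.

### Problem sizes used at desk scale

The reduced profile (64×64 input, filters 4/8/8/16, dense 256) is the
package's own choice of a configuration small enough to iterate on a
laptop CPU: 200 samples per class train in well under a minute, and on the
default synthetic classes 20 epochs of Adam 0.001 reach ≥ 90 % (typically
≈ 95 %) validation accuracy. The full 224×224 profile is retained and used
for everything that does not require training (shape traces, parameter
counts, building the model). Reproducing the published ≈ 98.7 % test
accuracy would require the real image archive and GPU-scale training and
is out of scope.

## Evaluation metrics

Malignant is the positive class (label 1). All rates are percentages in
full precision; tables round to 2 decimals at presentation. A rate with a
zero denominator is NaN. MAE is implemented as the *mean* absolute error
(the published formula omits the 1/n its own prose describes). The ROC is
a threshold sweep over the unique scores plus ±∞ endpoints, ties entering
together; trapezoidal AUC under this construction equals the all-pairs
concordance probability, which the tests assert exactly on vectors up to
length 200.

## Known limitations

* Segmentation assumes one dark lesion on lighter skin; multi-lesion
  frames and hypopigmented lesions defeat the polarity heuristic.
* The bilateral filter is O(d²) per pixel — fine at 224², not tuned for
  large frames.
* The synthetic classes are far more separable than real dermoscopy;
  accuracy numbers on them say nothing about clinical discrimination.
* The NumPy network is single-threaded BLAS-bound; it is a reference
  implementation, not a performance one.
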