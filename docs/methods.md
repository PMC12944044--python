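# Methods

## Model

The network is an encoder–decoder for 2-D multi-class segmentation
(background plus K foreground classes).  The encoder runs two branches in
lock-step at strides 4/8/16/32: a convolutional tower (strided entry
convolution, then two 3×3 conv–BatchNorm–ReLU blocks per stage) and a
pyramid-transformer tower (non-overlapping patch embeddings; blocks of
spatial-reduction self-attention plus an MLP, with layer normalization
over channels and residual connections).  Spatial-reduction attention
computes keys/values on a strided-convolution-downsampled copy of the
token grid (reduction ratios 8/4/2/1 per stage), keeping attention cost
linear in the token count.

### Feature coupling

At every stage boundary a Feature Coupling Unit aligns the branches.  The
previous CNN stage's map is projected into the next transformer stage's
embedding space (1×1 convolution → average pooling → layer norm → GELU),
concatenated channel-wise with the freshly patch-embedded tokens, and
mixed down with a learned 1×1 convolution before the attention blocks;
concatenation-then-mix was chosen over additive fusion so that the mixing
layer can learn the relative importance of the two feature families
instead of assuming their semantics align.  Symmetrically, each stage's
token grid is reconstructed into a CNN-shaped map (1×1 convolution →
BatchNorm → ReLU → bilinear resize) and fused with the CNN map to form
the per-stage skip feature e_i consumed by the decoder; the deep feature
f is the stage-4 fusion.  The wiring — projection of stage i feeding the
blocks of transformer stage i+1, the fused map also exported as e_i — is
one consistent reading of the block diagram and is fixed here as the
canonical interpretation.  With coupling ablated, the two branches run
independently and meet only in a single concatenation at the deepest
stage.

### Foreground/background disentanglement

The deep feature f enters K+1 weight-independent branches (two 3×3
conv–BN–ReLU units each) with 1×1 single-logit heads.  The K+1 logits
are normalized by a **joint** per-pixel softmax, which enforces the
complementarity constraint (mask values sum to one at each pixel) exactly,
in soft form; per-branch sigmoids could not guarantee this, which is why
joint normalization was adopted even though a per-branch reading of the
head is also defensible.

Each foreground mask is supervised by `L_k = CE(y_k, g_k) + Dice(y_k, g_k)`
against its one-hot ground truth; the background branch is supervised
against the complement of the foreground union.  The per-class weights

    β_k = 1 − σ(α (p_k − μ))

use the *predicted* pixel proportions p_k (mean mask value over batch and
pixels; a flag switches to ground-truth proportions), and are **detached**
from the computation graph: if gradients flowed through β, the optimizer
could shrink a predicted mask to inflate its own weight.  Proportions are
computed per batch rather than per image — with only a few foreground
classes, per-image means are noisy and per-batch pooling stabilizes μ.
Defaults α = 5 and λ (background weight) = 0.3.

### Category-aware aggregation

Decoder levels run deepest-first.  Each level refines its skip feature
with a 3×3 conv–BN–ReLU, concatenates the (2× bilinearly upsampled)
previous decoder output and mixes down to the level width; this fused
feature F is summarized per class as `C_ctx = F'ᵀ Y'` with Y' the prior
masks resized to the level's grid.  The raw product sums feature vectors
over pixels, so its magnitude grows linearly with the pixel count; the
context is therefore divided by H·W before the learned key/value maps —
without this the decoder's activation scale explodes level by level (the
oracle contract for the raw product is unchanged).  Pixel queries come
from a 1×1 convolution on the K *foreground* priors only (the background
enters through its context column); scores are divided by the embedding
width d (a `sqrt_scale` flag switches to the conventional √d), and the
softmax runs over the class axis, so each pixel distributes unit
attention over K+1 class tokens.  This per-class token attention is
O(N·K) rather than O(N²) and is the only dimensional reading under which
all the products involved are well-formed.  Priors are detached before
entering the aggregator by default: they are guidance supervised by their
own auxiliary loss, and letting the task loss deform them in the decoder
would destroy their calibration (a flag disables the detach).  The
aggregator runs at all four decoder levels with the priors resized per
level.  After the stride-4 level, a final 4× bilinear upsampling and a
1×1 head produce K+1 logits at input resolution; argmax ties break toward
the lower class index (background-favoring), fixed for reproducibility.

### Losses and training protocol

Total loss = `λ₁·CE + λ₂·Dice` on the final logits (multi-class CE as the
natural multi-class extension of the binary form; Dice averaged over the
K foreground classes) **plus** the auxiliary disentanglement loss with
inter-loss weight 1.0 (exposed as `dfm_weight`; no principled value is
available, and 1.0 keeps the two losses on comparable scales at
initialization).  Defaults (λ₁, λ₂) = (0.4, 0.6).  Optimization: AdamW
with β₁ = 0.9, β₂ = 0.999, ε = 1e−8, weight decay 1e−4, constant learning
rate 0.001 (no schedule is prescribed; a cosine hook exists in the
config), batch size 12.  Augmentation (each transform independently with
probability 0.5): horizontal/vertical flips, Gaussian blur with kernel
1–3, Gaussian noise with variance 10–50 interpreted on the 0–255
intensity scale, brightness ±0.2, contrast ±0.3, and a combined shift
(±0.2)/scale (±0.5)/rotation (±40°) warp, nearest-neighbour for labels.
Validation uses a deterministic 10% split taken by shuffling manifest
order under the run seed; the checkpoint with the best validation
*foreground-mean* Dice is kept (the foreground mean matches how
multi-organ benchmarks average over organs).

## Numerical choices

* Probabilities are clamped to [1e−7, 1−1e−7] before logs; soft Dice adds
  1e−5 to numerator and denominator (the bare formula is unstable for
  empty targets).
* Dice/IoU of two empty masks is defined as 1, empty vs non-empty as 0.
* HD95: boundary pixels are foreground pixels with at least one
  background 4-neighbour (the image border counts as background);
  directed distances are Euclidean nearest-boundary distances computed by
  a distance transform; percentiles use linear interpolation; the
  symmetric value is the max of the two directed 95th percentiles.  If
  either boundary is empty the image diagonal is returned as a sentinel
  and flagged out of the means.
* All arithmetic is float64.  Weight initialization is He-normal driven
  by an explicit generator, so models, runs and augmentation streams are
  bit-reproducible given one integer seed.

## Synthetic phantoms

The generator emulates the properties that make the target imaging
domains hard: several foreground structures of very unequal area
(default target fractions 0.15/0.06/0.02 at 64×64), overlapping intensity
distributions (per-class mean intensities 0.45/0.65/0.85 over a 0.2
background, with within-class std 0.08), boundaries blurred by a Gaussian
of σ = 1 px, and additive noise (σ = 0.03).  Shapes are rotated
super-ellipses painted from largest to smallest target area, so small
structures are never occluded; placement retries enforce near-disjoint
shapes and raise an explicit error when the requested fractions are
infeasible.  Target fractions are intents, not constraints — realized
fractions are recorded per sample and in the dataset manifest.

What the phantoms do *not* model: anatomy (no organ shapes or spatial
priors), acquisition physics (no CT/MRI noise spectra, bias fields or
partial-volume effects), 3-D context, and inter-patient variability
beyond random geometry.  Passing the synthetic experiments therefore
demonstrates that the architecture, losses and pipeline are correctly
implemented and that the dynamic weighting behaves as designed on
controlled imbalance — not that clinical-grade accuracy would transfer
to real modalities.

## Problem sizes

The `tiny` preset (stage widths 16/32/64/96, depth-1 transformer stages,
single-channel 64×64 inputs, ≈0.87 M parameters) is the default for all
tests and experiments; the `full` preset mirrors a PVT-b0-sized tower
(32/64/160/256, depth 2, mlp ratio 4, 3-channel 224×224 inputs) and is
retained for fidelity.  The standard experiments in the test suite and
acceptance script use 200 phantoms / 30 epochs for the convergence run,
96 phantoms / 30 epochs / 3 seeds for the ablation trend on an
imbalance-heavy set (smallest class ≤1% of pixels), and 200 optimizer
steps for the single-image overfit sanity check — sizes chosen so the
whole suite runs on one CPU in minutes while staying out of the noise
floor (at 10 epochs the smallest class is simply not learned yet and
every variant measures as zero).

## Known limitations

* The phantoms are separable almost purely by pixel intensity, so they
  exercise correctness and the small-target weighting but cannot reward
  global-context modelling: on these scenes the plain
  concatenate-and-decode baseline converges slightly faster than the full
  model at desk scale, and the architectural ordering observed on real
  anatomy should not be expected to reproduce here.

* The auxiliary priors are predicted at the deep-feature resolution
  (2×2 for 64×64 inputs, 7×7 at 224×224); they are coarse spatial
  guidance, not segmentation proposals.
* The transformer uses the tanh GELU approximation; BatchNorm statistics
  make training-mode outputs batch-dependent (evaluation uses running
  statistics and is deterministic).
* The numpy backend is single-device and gives no GPU path; the full
  preset is present but training it at 224×224 is outside desk scale.
* `augment` composes at most one affine warp per sample; compositions of
  repeated warps accumulate interpolation loss if chained externally.
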