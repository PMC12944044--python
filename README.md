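# dcanet

Dual CNN/transformer encoder–decoder for multi-class 2-D segmentation of
images with blurred boundaries and severely imbalanced structure sizes —
the regime of multi-organ CT/MRI slices and histology, where small,
low-contrast structures are routinely swallowed by large ones.

The network combines three ideas:

* **Feature Coupling Units (FCU)** — at every encoder stage, convolutional
  features (local detail) are projected (1×1 conv → average pool → layer
  norm → GELU), concatenated with the pyramid-transformer token grid
  (global context) and mixed down with a learned 1×1 convolution, so each
  semantic level carries both kinds of information.
* **Decoupled Feature Module (DFM)** — the deep feature `f` is split into
  K foreground branches and one background branch; a joint per-pixel
  softmax over the K+1 branch logits produces complementary soft masks
  `y_k` (they sum to one at every pixel).  Each branch is supervised with
  a CE+Dice loss `L_k`, weighted dynamically by

  ```
  β_k = 1 − σ(α (p_k − μ)),     p_k = mean_i y_{i,k},   μ = mean_k p_k
  ```

  so classes occupying fewer pixels than average get β > ½ and small
  targets are not drowned out.  Default α = 5; the background term enters
  with λ = 0.3:  `L_DFM = Σ_k β_k L_k + λ L_bg`.
* **Category-Aware Integration Aggregator (CAIA)** — at each decoder
  level, the fused feature `F` and the (resized) prior masks `Y` form a
  class-context matrix `C_ctx = Fᵀ Y` (one column of aggregated feature
  mass per class).  Pixel queries derived from the foreground priors
  attend over the K+1 class tokens, `A = softmax(Qᵀ K / d)`, and the
  attended feature is added back to the decoder feature through a 1×1
  convolution.

Training uses the hybrid main loss `L = λ₁ L_CE + λ₂ L_Dice` with
(λ₁, λ₂) = (0.4, 0.6) plus `L_DFM`, AdamW (β₁ = 0.9, β₂ = 0.999,
ε = 1e−8, weight decay 1e−4), initial learning rate 0.001 and batch
size 12.  Evaluation reports per-class Dice, IoU and the 95th-percentile
Hausdorff distance (HD95).

Everything — including the network layers and the reverse-mode autodiff
engine they run on — is implemented over numpy, so the package has no
deep-learning-framework dependency and trains desk-scale models on one
CPU.  A synthetic-phantom generator provides labelled multi-class scenes
with controllable class imbalance, intensity overlap, boundary blur and
noise, so the whole pipeline is trainable and testable offline.

## Worked example

```python
import numpy as np
from dcanet import PhantomSpec, tiny_config, TrainConfig, train
from dcanet.phantoms import generate_phantom, _child_seed

spec = PhantomSpec(seed=42)           # 64x64, K=3, fractions (0.15, 0.06, 0.02)
samples = [generate_phantom(spec.replace(seed=_child_seed(42, i)))
           for i in range(200)]
record = train(tiny_config(), TrainConfig(epochs=30, seed=1), None,
               samples=samples)
print(f"best held-out foreground Dice: {record.best_val_dice:.3f}")
print(f"epoch-1 loss {record.train_losses[0]:.3f} -> "
      f"epoch-30 loss {record.train_losses[-1]:.3f}")
```

prints (one CPU, a few minutes):

```
best held-out foreground Dice: 0.937
epoch-1 loss 3.086 -> epoch-30 loss 1.787
```

i.e. the tiny model (≈0.87 M parameters) segments the three foreground
classes of held-out phantoms with a mean Dice of about 0.94.  The total
loss retains an irreducible auxiliary-term floor (the deep prior masks
are 2×2 and cannot match 64×64 targets exactly); the segmentation part
of the loss drops far below half its starting value.  The same
pipeline is available from the shell:

```bash
dcanet generate --n 200 --out data/
dcanet train --data data/ --out runs/tiny -o train.epochs=30
dcanet eval --checkpoint runs/tiny/best_checkpoint.npz --data data/
dcanet ablate --data data/ --out ablation.csv \
    --grid '[{"alpha":0},{"alpha":5}]' -o train.epochs=10
```

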