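# egtransunet

Attention-enhanced U-shaped network for binary biomedical image
segmentation — polyps in endoscopy, nuclei in microscopy, skin lesions,
glands.  Lesions in such images vary widely in size and shape and often
have blurred boundaries on cluttered backgrounds; plain encoder–decoder
networks struggle both to extract discriminative lesion features during
encoding and to fuse spatial detail with semantic location across the
skip connections.  This package implements a U-Net-style architecture
that addresses both with three transformer-style modules:

* **PEM** (progressive enhancement module) — inside the third encoding
  stage: a 3×3 convolution branch and two *dilated self-attention
  convolution* (DSA) branches with dilation rates 2 and 3 are cascaded
  through gated convolutions
  `G = ReLU(W_f·F_low) ⊙ σ(W_g·F_high)`, letting larger receptive
  fields guide feature extraction at the original scale.
* **CSA** (channel–spatial attention) — at the bottleneck: multi-head
  self-attention over channel tokens, then over spatial tokens with a
  trainable absolute position bias `p_ij` added to the logits
  (`α_ij = softmax_j(e_ij + p_ij)`, `e_ij = (x_i W^q)(x_j W^k)^T/√d`).
* **SGA** (semantic guidance attention) — on the second decoding skip:
  decoder queries attend over the PEM-refined encoder keys/values after
  channel selection `A_w = σ(W·P)` (P = per-channel spatial means), and
  the attention context is concatenated with the decoder stream.

Training minimizes `L = α·L_BCE + β·L_Dice` (α = β = 0.5, ε = 1e-6) with
SGD (momentum 0.9, weight decay 1e-3, lr 5e-3 decayed ×0.1 every 40
epochs).  Evaluation reports Dice `2TP/(2TP+FP+FN)`, IoU
`TP/(TP+FP+FN)`, precision and recall, averaged per image.  Each module
has an ablation switch; with all three off the model is the plain
residual U-Net baseline.

Everything runs on a self-contained numpy reverse-mode autodiff core
(`egtransunet.nn`) — no GPU framework required — which keeps the package
fully testable on one CPU.  A seeded synthetic lesion generator
(`generate_synthetic`) emulates blurred-boundary blobs on cluttered
backgrounds so the whole pipeline works without downloading datasets.

## Worked example

```python
import numpy as np
from egtransunet import (ModelConfig, TrainConfig, SyntheticParams,
                         generate_synthetic, train, evaluate, complexity)

samples = generate_synthetic(12, SyntheticParams(seed=0))
train_set, val_set = samples[:8], samples[8:]
cfg = TrainConfig(lr0=0.02, decay_every=1000, epochs=40, batch_size=4, seed=0,
                  model=ModelConfig(input_size=(64, 64), base_width=8))
model, record = train(cfg, train_set, val_set)
print(f"epoch  0: loss {record.epochs[0]['train_loss']:.3f}  val mDice {record.epochs[0]['val_dice']:.3f}")
print(f"epoch 39: loss {record.epochs[-1]['train_loss']:.3f}  val mDice {record.epochs[-1]['val_dice']:.3f}")
df, means = evaluate(model, val_set)
print({k: round(v, 3) for k, v in means.items()})
rep = complexity(cfg.model)
print(f"parameters: {rep.parameter_count:,}   MACs at 64x64: {rep.mac_count/1e6:.1f} M")
```

prints (≈2 minutes on one CPU):

```
epoch  0: loss 0.732  val mDice 0.000
epoch 39: loss 0.142  val mDice 0.843
{'m_dice': 0.843, 'm_iou': 0.731, 'm_precision': 0.843, 'm_recall': 0.859}
parameters: 317,289   MACs at 64x64: 19.9 M
```

The training loss falls from 0.732 to 0.142 over 40 epochs (80 SGD
steps) and the model generalizes to four held-out synthetic images with
mean Dice 0.843 — an untrained model scores ≈0 because its near-uniform
probabilities threshold to all-background.  The complexity report counts
parameters exactly and multiply–accumulates by instrumenting a forward
pass.

The same workflow is available from the shell:

```sh
egtransunet synth --n 100 --out data/ --seed 0
egtransunet train --config cfg.yaml --data data/ --out run/ [--no-pem --no-csa --no-sga]
egtransunet evaluate --checkpoint run/best.npz --data data/ --out metrics.csv
egtransunet complexity --config cfg.yaml
```

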