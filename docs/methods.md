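# Methods

## The model

`egtransunet` implements an attention-enhanced U-shaped encoder–decoder
for binary biomedical image segmentation (polyps, nuclei, skin lesions,
glands).  An input image $X \in \mathbb{R}^{C\times H\times W}$ is mapped
to a per-pixel foreground probability map of the same spatial size.  The
backbone is a four-stage residual encoder (two residual blocks per stage,
the first with stride 2, channel plan $w\cdot(1,2,4,8)$ for base width
$w$) and a four-stage decoder (two convolutions and one bilinear 2×
upsampling per stage).  Three transformer-style modules augment it:

**Progressive enhancement module (PEM)**, applied to encoder stage 3.
Three parallel views of the stage-3 feature — a plain 3×3 convolution
$A$, and two *dilated self-attention convolutions* (DSA) with dilation
rates 2 and 3 — are cascaded through two gated convolutions:
$g_1 = \mathrm{ReLU}(W_f A)\odot\sigma(W_g\,\mathrm{DSA}_2(x))$, then
$g_2 = \mathrm{ReLU}(W_f' g_1)\odot\sigma(W_g'\,\mathrm{DSA}_3(x))$, and
the output is $\mathrm{ReLU}(\mathrm{BN}(A + g_2))$.  Inside DSA, the
query/key/value embeddings are 3×3 *dilated* convolutions (stride 1,
padding = dilation, no bias), so tokens carry local context while the
attention map $B\in\mathbb{R}^{n\times n}$ ($n = hw$) mixes globally:
$B = \mathrm{softmax}(M N^\top)$, output $= B\,T$ reshaped back to
$c\times h\times w$, followed by a 1×1 output projection.

**Channel–spatial attention (CSA)** at the bottleneck: multi-head
self-attention first over *channel* tokens (embedding = flattened
spatial map, no position bias), then over *position* tokens (embedding =
channel vector) with a trainable absolute position bias
$p_{ij} = (x_i W^v)\cdot a_{ij}^\top$ added to the scaled dot-product
logits $e_{ij}$ before the softmax.  Each stage has a residual
connection.

**Semantic guidance attention (SGA)** on the second decoding skip.  The
decoder feature (queries) attends over the PEM-refined encoder feature
(keys/values) after both streams pass *channel selection* —
$A_w = \sigma(W\,P)$ with $P$ the vector of per-channel spatial means —
and the attention context is concatenated with the decoder stream
($C_{low}+C_{high}$ channels).

## Training objective and metrics

$L = \alpha L_{BCE} + \beta L_{Dice}$ with $\alpha=\beta=0.5$ and Dice
smoothing $\varepsilon=10^{-6}$.  Defaults follow the published recipe
for this architecture family: SGD, momentum 0.9, weight decay $10^{-3}$
(on convolution/linear weights only), initial learning rate
$5\cdot10^{-3}$ decayed ×0.1 every 40 epochs, 300 epochs, batch size 4,
inputs resized to 320×320.  Evaluation uses confusion-count metrics
(Dice, Jaccard/IoU, precision, recall), averaged per image.

## Design choices at genuinely open points

* **DSA normalization axis.**  The defining softmax for $B$ can be read
  as normalizing over queries (each *column* of $B$ sums to 1) or over
  keys.  The key-axis reading — each output token's mixing weights sum
  to 1, consistent with standard attention and with the spatial-MHSA
  formula — is the default; `attention_axis="printed"` selects the
  query-axis variant.  DSA applies no $1/\sqrt{d}$ scale by default (the
  channel/spatial/SGA attentions do).
* **Position bias.**  Implemented as a full trainable table
  $a\in\mathbb{R}^{n\times n\times d_h}$ over ordered token pairs at the
  configured bottleneck grid, shared across heads, contracted with the
  value-projected query token.  Attention *values* are the
  value-projected tokens (the standard relative-position formulation);
  the table is sized at model build time, so the model is bound to its
  configured input resolution.
* **Token projections.**  Channel-MHSA projections are per-token linear
  maps in the channel-token view (an $hw\to hw$ linear shared by all
  channels).  This — not a cross-channel 1×1 convolution — preserves the
  symmetry property that identical channels receive uniform attention
  rows.  For spatial tokens the per-token linear is exactly a 1×1
  convolution.
* **PEM merge.**  "Combine" of the convolution branch with the cascade
  output is elementwise addition followed by BN+ReLU, keeping the
  channel count unchanged so PEM is a drop-in refiner.  Gate/embedding
  convolutions are 1×1.
* **SGA scope.**  Channel selection is applied to keys and queries, not
  values; the attention context *is* the refined low-level feature that
  enters the concatenation.  The projection of the concatenated
  $C_{low}+C_{high}$ feature back to the decoder's planned width is the
  first 3×3 convolution of the consuming decoder stage, identical in
  shape for the SGA and plain-concatenation paths, so ablations compare
  like with like.
* **Decoder wiring.**  Decoder stage 1 refines the CSA bottleneck
  without a skip; stages 2/3/4 fuse encoder stages 3/2/1.  "Second
  decoding" therefore pairs the two enhanced streams: SGA fuses the
  PEM-refined skip.  Upsampling is bilinear interpolation (not
  transposed convolution) to avoid checkerboard artifacts.
* **Printed-form discrepancies.**  The source formulas for this model
  family print an IoU of $2TP/(TP+FP+FN)$ (which exceeds 1) and a Dice
  loss without the factor 2 (0.5 at perfect prediction); the package
  implements the standard Jaccard index and the conventional Dice loss,
  with the factor-free Dice form selectable via `dice_form="printed"`.
  BCE is reduced as a per-pixel mean (a sum would scale with image area
  and swamp the Dice term at 320×320); `reduction="sum"` is available.
* **Empty-mask convention.**  If $TP=FP=FN=0$ all metrics are 1; if
  $TP=0$ with errors present, all are 0.  Probabilities are clipped to
  $[10^{-7}, 1-10^{-7}]$ before logarithms.

## Compute core

The package runs on its own reverse-mode autodiff core (`egtransunet.nn`)
over float64 numpy arrays: broadcasting arithmetic, matmul, dilated 2-D
convolution (kernel-tap accumulation), batch normalization, bilinear
upsampling, softmax, SGD with momentum.  Gradients are verified against
central finite differences in the test suite, and convolution against an
independent `scipy.signal` reference.  Multiply–accumulate counts are
measured by instrumenting a real forward pass, so complexity reports
reflect exactly what is computed; the parameter/MAC lattice is strictly
monotone in the ablation switches, and the full model costs about 2× the
baseline's MACs at 320×320 with the default width.

## Synthetic data

`generate_synthetic` emulates the target data regime: 1–3 bright blobs
per image (deformed ellipses, radius 6–12 px on a 64×64 canvas, radial
deformation capped at 25%, aspect 0.7–1.3), boundary blur σ=1.5 px,
contrast 0.45 over a smoothly cluttered background, multiplicative
texture (strength 0.15) and additive Gaussian noise (σ=0.05).  The mask
is the exact pre-blur blob support.  Mean foreground fraction is ≈
10–30%, in the range typical of curated lesion-segmentation datasets.
Everything derives from an explicit seed; equal seeds give bitwise-equal
datasets.

What this does *not* emulate: specular highlights, vignetting, instrument
borders, multi-scale clutter correlated with the lesion, inter-annotator
boundary ambiguity, or dataset shift between acquisition devices.
Passing the overfit and invariance tests therefore demonstrates that the
architecture, gradients, and training loop are correct and that the
modules do not impede optimization — not that the model reaches
published benchmark accuracy on real endoscopy or histology data, which
requires the original datasets and full-scale training.

## Problem sizes and numerics

Desk-scale runs use base width 8 at 64×64 (bottleneck 4×4, 16 spatial
tokens); the default configuration is base width 16 at 320×320
(bottleneck 20×20, 400 tokens; position table $400^2\times 8$).  The
overfit sanity runs memorize 8 synthetic images within 300 SGD steps
using a constant learning rate of 0.02 — a rate chosen for rapid
memorization of a tiny set; full-scale defaults keep the published
schedule.  Attention oracles are compared at 1e-5 absolute tolerance
(float64 throughout); attention-map normalization holds to 1e-6.
Degenerate inputs: single-token attention reduces to the value
projection; empty masks hit the $\varepsilon/\varepsilon$ Dice limit;
non-finite losses abort training with a diagnostic rather than
continuing silently.

## Known limitations

* The position-bias table and channel-token projections are resolution
  bound: a checkpoint evaluates only at its configured input size
  (datasets are resized, matching the intended pipeline).
* No pretrained backbone: the encoder is a seeded Kaiming-initialized
  residual network, narrower than a ResNet50; absolute FLOPs/parameter
  counts are not comparable to full-scale implementations, only the
  ablation *ordering* is meaningful.
* Single foreground class; no deep supervision; no test-time
  augmentation; CPU-oriented (float64 numpy), so full-scale 300-epoch
  training is out of scope.
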