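# Methods

## Problem and model

The task is binary classification of single-cell microscopy crops: *normal*
versus *contains at least one micronucleus*. The classifier is a hybrid
convolution/transformer network at the smallest MobileViT scale:

* stem: 3×3 stride-2 convolution to 16 channels (all convolutions are
  bias-free and followed by batch normalization and SiLU unless noted);
* an inverted-residual trunk at widths 16 → 24 → 24 → 24 with expansion
  factor 2: each MV2 block expands with a 1×1 conv, filters with a
  depthwise 3×3, projects back with a linear 1×1, and adds a shortcut when
  stride is 1 and channels are preserved;
* three transformer stages at widths 48/64/80 with embedding dims 64/80/96,
  encoder depths (2, 4, 3), 4 heads, MLP ratio 2, 2×2 patches. Each stage
  is a strided MV2 block followed by a MobileViT block: local 3×3 conv,
  1×1 projection to the embedding dim, patch unfold, pre-norm transformer
  encoder layers plus a closing LayerNorm, patch fold, 1×1 projection back,
  concatenation with the block input, and a 3×3 fusion conv;
* 1×1 expansion to 320 channels, global average pooling, linear head.

With a 1000-class head this baseline carries exactly 1,272,024 trainable
parameters, which pins down every width/depth/bias choice above; audits are
reported for both the 1000-class parity head and the 2-class task head.

### Convolution decomposition (Depth-Conv + PFCL)

The two 3×3 convolutions of each transformer stage — local C→C and fusion
2C→C — are optionally decomposed into a channel-wise depthwise 3×3 stage
followed by a pointwise 1×1 cross-channel fusion stage, both bias-free.
Normalization and SiLU attach only after the pointwise stage, so the
decomposition changes only the weight count:

* standard k×k: k²·C_in·C_out weights,
* decomposed: k²·C_in + C_in·C_out,

yielding savings of 8C² − 9C (local) and 16C² − 18C (fusion) at k = 3, and
302,016 in total over C ∈ {48, 64, 80} — exactly the measured difference
between the baseline (1,272,024) and decomposed (970,008) variants. The
receptive field is unchanged. A textual description of the decomposition
as "1×1 kernels" is inconsistent with this parameter arithmetic; the
depthwise-3×3 reading is the one the printed counts support, so it is the
one implemented.

### SE attention

Squeeze: global average pooling compresses each channel to a scalar,
Z_c = (1/HW) Σᵢ Σⱼ X(i, j). Excite: S = σ(W₂ δ(W₁ Z_c)) with δ = ReLU,
no biases, and a reduction ratio r = 4 (configurable; r is not derivable
from the published parameter totals, so those totals are matched only for
the attention-free variants). Inside an MV2 block, SE acts on the expanded
channels after the depthwise stage (the SEDD unit).

### NAM attention

The normalization-based operator is implemented literally as its three
stages: X̂ = BN(X); A = σ(f_att(X̂)); Y = X ⊙ A; Z = f_recon(Y), with
f_att and f_recon realized as bias-free 1×1 convolutions — the cheapest
operators consistent with "a convolution operation". A variant that
derives the weights from the normalization layer's own scale factors
(w ∝ |γ|, A = σ(w · X̂), no reconstruction conv), as in the original NAM
design, is available behind `use_bn_scale_weights`; the equation-literal
pathway is the default because the published description is the equations,
not the γ-weight recipe. In the MobileViT block, NAM (or SE) sits before
the local 3×3 by default (`attention_first`), with the opposite order
behind the same flag.

## Numerical substrate

Layers run on a compact reverse-mode autodiff core over float32 numpy
arrays: broadcasting arithmetic, batched matmul, dense convolution via
im2col, depthwise convolution via sliding-window einsum, reductions, shape
ops, sigmoid/SiLU/softmax and a log-sum-exp cross-entropy. Gradients of
every op are verified against central finite differences, and both
convolutions against scipy's direct correlation.

Numerical choices worth noting:

* The functional attention operators clip sigmoid outputs to
  [1e-12, 1 − 1e-12] so attention weights stay strictly inside (0, 1) even
  when the pre-activation saturates in floating point.
* unfold/fold reject feature maps the patch size does not divide — the
  pair is then an exact (bit-wise) inverse. Inside the MobileViT block a
  non-divisible map (e.g. the 7×7 map a 224 input produces at the last
  stage) is nearest-neighbor–resized to the next patch multiple before
  unfold and back after fold, mirroring standard MobileViT practice.
* Batch normalization uses batch statistics in training (momentum 0.1
  running averages) and running statistics in evaluation; evaluation after
  very few optimizer steps is therefore noisier than the training loss
  suggests.
* MAC audits count k²·(C_in/groups)·C_out·H_out·W_out per convolution,
  tokens·d_in·d_out per linear layer, and 2·B·heads·T²·d_head per
  self-attention layer; normalization and elementwise work is excluded.
  Parameter counts cover trainable arrays only (BN running stats excluded).

## Data protocol

* **Stratified 6:2:2 split** by largest-remainder rounding within each
  class: per-class counts match the ratios within one sample, and the
  assignment is a pure function of (manifest, seed).
* **Augmentation**: rotation up to ±30°, horizontal/vertical flips with
  probability 0.5, zoom in [0.8, 1.2] — reflection padding, bilinear
  interpolation, output size preserved. These values are conventional
  defaults; the protocol the classifier follows specifies the transform
  family but not its magnitudes.
* **Rebalancing** applies to the train split only: the majority class is
  randomly downsampled (optionally to a cap) and the minority class is
  expanded with augmented copies until the minority:majority ratio is
  within 2% of the 1:1 target. Augmented copies are materialized as new
  PNG files, so every manifest path names a distinct image, and the test
  split is asserted to contain no augmented row. An optional ×k expansion
  of the validation split is available (`expand_val`); it is off by
  default because published validation counts for this protocol are
  internally inconsistent and are not a target.
* **Loading**: images are resized bilinearly to the network input and
  standardized with fixed constants (mean 0.5, std 0.25 per channel).
* The training loop additionally applies random horizontal/vertical flips
  to each mini-batch on the fly (part of the same augmentation strategy;
  disable with `TrainConfig.augment_flips=False`).

## Training recipe

Adam (β = 0.9/0.999, ε = 1e-8) from an initial learning rate of 0.001
with cosine decay, batch size 64, 50 epochs, 224×224 inputs — the study
configuration, carried as `TrainConfig` defaults. Transfer learning copies
every checkpoint array whose name and shape match, reports skips, and can
hold the classification head at its fresh initialization; full fine-tuning
is the default, with a freeze-trunk option. Desk-scale runs in the tests
and examples shrink the problem to 64×64 inputs, batch 8 and 5 epochs on a
few hundred synthetic images, which one CPU handles in minutes; these
sizes are the package's own scaled-down study conditions.

## Synthetic data: what it emulates and what it does not

The generator renders single-cell crops: a background at intensity
0.10–0.25, one elliptical nucleus (semi-axes 0.22–0.38 of the image side
per axis, random orientation, intensity 0.65–0.85), and — for positives —
1–2 circular chromatin blobs with radius 0.10–0.33 of the nucleus minor
axis placed on a ring just outside the nucleus boundary, followed by
Gaussian blur (σ 0.7 px) and additive noise (σ 0.02). Grayscale morphology
is replicated to three RGB channels. The default pool imbalance is 6.5%
positive, the unaugmented test-set imbalance typical of the assay. An
*easy* variant (high contrast, no noise, 2–3 larger blobs) exists for
learnability checks — a plain threshold-and-count-blobs heuristic exceeds
90% balanced accuracy on it, so passing training-sanity tests means the
network found a real signal, not an artifact. A *shifted* variant (dimmer
stain, more noise) provides a second domain for transfer experiments.

What the generator does not emulate: staining chemistry and color
variation, point-spread functions, touching or binucleated cells, debris
and imaging artifacts. Tests passing on synthetic data therefore validate
the mechanics and the learning dynamics of the pipeline, not clinical
performance on real assay slides.

## Known limitations

* Published parameter totals are reproduced exactly only for the
  attention-free variants; the attention variants depend on unpublished
  choices (SE reduction ratio, NAM parameterization) and are reported as
  audited, not matched.
* Published MAC/FLOP figures follow an unidentifiable counting convention
  and are out of scope; the auditor documents its own convention.
* The numpy substrate is single-threaded BLAS-bound; full-scale (224×224,
  50-epoch) training is possible but slow, and the package is tuned for
  desk-scale experimentation and audits.
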