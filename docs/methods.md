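# Methods

## The attention operator

Given a convolutional feature map `T ∈ R^{m×n×k}` (height, width,
channels), the global attention block re-weights it along all three
axes. Directional pooling first compresses the map:

* height: `AvgPool_H(T), MaxPool_H(T) ∈ R^{1×n×k}`
* width: `AvgPool_W(T), MaxPool_W(T) ∈ R^{m×1×k}`
* channel: `GAP(T), GMP(T) ∈ R^{1×1×k}`

The two height-pooled maps are concatenated along the channel axis
(giving `1×n×2k`) and passed through a bottleneck `f(d(·))`, where `d`
is a 1×1 convolution `2k → ⌈k/r⌉` and `f` a 1×1 convolution `⌈k/r⌉ → k`,
each fused with batch normalisation and ReLU. The width branch mirrors
this. The channel branch applies a shared two-layer MLP (`W0`: dense
`k → ⌈k/r⌉` + ReLU; `W1`: dense `⌈k/r⌉ → k` + sigmoid) to the average-
and max-pooled descriptors and sums the two sigmoid outputs, so channel
weights lie in (0, 2). The output is the broadcast product

    O = T ⊙ H^{1×n×k} ⊙ W^{m×1×k} ⊙ C^{1×1×k}.

Design choices where the construction is genuinely open:

* **Outer directional pooling is the identity.** The branch definitions
  nominally end in another directional average pool, but the pooled
  axis already has extent 1 at that point; any pooling over a singleton
  axis is a no-op, and it is implemented as such.
* **Terminal sigmoid on the spatial branches, on by default.**
  Attention weights are conventionally bounded in (0, 1); a
  `terminal_sigmoid=False` mode gives the literal ReLU-terminated form.
* **`d`/`f` are shared between the height and width branches.** Both
  transforms are pointwise, hence shape-agnostic over the spatial axes,
  and the same symbols name them in both branches; sharing keeps the
  block lighter. `W0`/`W1` are likewise shared between the GAP and GMP
  paths of the channel branch.
* **Channel weights sum two sigmoids** (range (0, 2)); a
  `cbam_style_channel` flag applies a single sigmoid after summation
  (range (0, 1)) for the more common convention.
* **Reduction ratio `r = 8`** by default — a standard bottleneck choice
  balancing capacity against the lightweight claim; configurable.
* Hard-swish is available as the `d`/`f` activation but ReLU is the
  default; no governing formula uses h-swish.

The invariants that follow — output shape equals input shape, spatial
weights in (0, 1), channel weights in (0, 2), `|O| ≤ 2|T|` elementwise,
exact identity when all maps are 1 — are property-tested. The open
intervals are exact-arithmetic properties; in float32 a saturated
sigmoid rounds to 1.0, so bound tests run the engine in float64.

## The classifier

GABNet stacks depthwise-separable convolution (DSC) units — depthwise
3×3 → BN → ReLU → pointwise 1×1 → BN → ReLU — into two residual block
types: **Block A** (two DSC units, 2×2 max-pool, pointwise-projection
shortcut with max-pool; halves the spatial size) and **Block B**
(identity shortcut, shape-preserving). A stem DSC module at stride 2
precedes the stages; a global average pool and a single dense softmax
head finish the model. An attention block follows every residual block
(a per-stage-only mode exists).

Stage widths, depths and kernel sizes are not prescribed by the block
definitions; the defaults are a conventional lightweight ladder chosen
to land in the single-digit-million parameter regime:

| preset | input | stem | stage widths | blocks/stage | parameters |
|--------|-------|------|--------------|--------------|------------|
| `full` | 299×299×3 | 32 | 64, 128, 256, 512 | 2, 2, 3, 2 | ≈ 2.1 M |
| `tiny` | 128×128×1 | 8 | 16, 32, 64 | 1, 1, 1 | ≈ 17 k |

The `tiny` preset exists so the whole pipeline runs in CPU minutes;
all experiments in the test-suite and the acceptance script use it.
Initialisation is He-uniform for convolutions and Glorot-uniform for
dense layers, from a seeded generator, so identical configs produce
identical models.

## Numerical engine

No tensor/autodiff framework is assumed; `gabnet.nn` is a compact
reverse-mode autodiff core over numpy (NHWC layout) providing exactly
the primitives the model needs. Performance-relevant choices:

* default dtype float32 (float64 switchable; the finite-difference
  gradient checks in the test-suite use it);
* batch normalisation — and its usual trailing ReLU — is a single fused
  graph node with a hand-written backward pass, keeping the retained
  graph to one feature-map-sized intermediate per normalisation;
* depthwise 3×3 convolution is computed as nine shifted
  multiply-accumulates with TensorFlow-style "same" padding
  (output size ⌈input/stride⌉, extra padding bottom/right);
* 2×2 max-pooling uses ceil mode with −∞ padding; gradient ties route
  to the first argmax; the axis-reduction `max` splits ties evenly.

Every primitive's gradient is verified against central finite
differences in float64 (relative error < 1e-6; < 1e-3 through a whole
attention block).

## Preprocessing

Images are bilinearly resized to the network input size (half-pixel
centres, the align-corners-false convention; delegated to
scikit-image) and then min–max normalised per image with the global
minimum and maximum over all pixels and channels:
`X_norm = (X − X_min)/(X_max − X_min)`. A constant image is mapped to
all zeros — the formula is undefined there and zeros are inert. Resize
precedes normalisation. No augmentation is applied.

## Metrics

All metrics derive from the n×n confusion matrix (rows actual, columns
predicted): per class, `TP_i = X_ii`, `FP_i` = column sum − TP,
`FN_i` = row sum − TP, `TN_i` = rest. Accuracy is trace/total; recall,
precision and specificity are support-weighted averages of per-class
one-vs-rest rates; F1 is the harmonic mean of the weighted precision
and recall as a whole (a `from_per_class` flag gives the
support-weighted mean of per-class F1 instead, the scikit-learn
convention). A per-class 0/0 rate is defined as 0 with a warning. The
weighted recall is algebraically identical to accuracy
(`Σ TP_i / Σ support_i = trace/total`); the suite asserts this on random
matrices. AUC is the support-weighted mean of per-class one-vs-rest ROC
AUCs (ties count ½); classes absent from the truth vector are excluded
with re-weighting and a warning. Per-class AUC is computed with
scikit-learn; the test oracle is an independent Mann–Whitney
pair-counting implementation.

## Synthetic B-scans

The generator emulates the gross structure of retinal OCT B-scans: a
dark background with four bright retinal layer bands that follow a
shared smooth displacement curve (sinusoid + tilt), multiplicative
gamma speckle (unit mean, sd 0.18), and one class-specific lesion with
a ground-truth pixel mask:

* **CNV** — one bright irregular blob (3–5 overlapping ellipses)
  beneath/disrupting the band stack;
* **DME** — 2–4 dark elliptical cysts inside the band stack;
* **drusen** — 4–8 small bright bumps seated on the lowest band;
* **normal** — the unmodified background.

Geometry and contrast constants are fixture parameters of this package,
chosen once so that the four classes are *learnable but not trivial* at
desk scale: a pixel-level logistic baseline reaches roughly 0.8 test
accuracy (above the 0.7 floor the suite asserts, well below ceiling),
while the tiny convolutional classifier exceeds 0.9. Lesion mask areas
are kept within [0.05 %, 12 %] of the image by bounded resampling.
Class imbalance can mirror the public retinal-OCT corpus proportions
(37,206 / 11,349 / 8,617 / 51,140 for CNV/DME/drusen/normal) via the
`ucsd_proportions` preset with a scale factor.

What the generator does **not** emulate: real speckle correlation,
shadowing, vessel artefacts, device-dependent contrast, segmentation-
grade layer anatomy, or intra-class pathology diversity. Passing tests
therefore demonstrate that the pipeline is correct and that the
attention classifier can learn localized lesion signatures — not
clinical-grade performance on real OCT.

Determinism: each sample draws from `default_rng([global_seed, index])`,
so datasets regenerate byte-identically, including under partial
regeneration.

## Training recipe

Softmax cross-entropy, Adam at learning rate 1e-4, batch size 10, up to
300 epochs; the learning rate is multiplied by 0.1 when validation
accuracy has not strictly improved for 5 consecutive epochs, and
training stops early after 11 stagnant epochs. Both counters reset on
any improvement; the plateau counter also resets after a drop (so with
a constant validation sequence the drop fires at epoch 6 and the stop
at epoch 12 — asserted in the suite). The best-validation weights are
restored at the end. Ties count as no improvement.

The desk-scale experiment (`run_scaled_experiment`) keeps this schedule
but raises the learning rate to 2e-3 and the batch size to 16, capping
at 25 epochs: with 200 images per class (stratified 80/10/10 split) the
tiny preset then converges within CPU minutes; the full-scale defaults
are impractical at that problem size. These are the sizes used by the
test-suite and `scripts/acceptance.py`.

## Grad-CAM

For target class c and a chosen rank-3 activation A, channel weights
are the spatial means of ∂score_c/∂A; the map is `ReLU(Σ_k w_k A_k)`,
bilinearly upsampled to the input and normalised by its maximum
(all-zero maps stay zero). The default target layer is the last
attention-block output; the explained class defaults to the predicted
one. Correctness is checked against a closed-form single-layer model.

With synthetic masks available, localisation is scored as the fraction
of the top-10 % heatmap pixels falling inside the lesion mask; under a
random heatmap the expected score equals the mask's area fraction,
which provides the chance level for a one-sided paired test.

## Known limitations

* The numpy engine is single-threaded and eager; the `full` preset is
  buildable and trainable in principle but not at practical speed —
  desk-scale work uses `tiny`.
* Attention parameter counts assume bias-free pointwise convolutions
  (batch norm follows them); frameworks that add biases will report
  slightly higher totals.
* The synthetic benchmark is deliberately simplified (see above); no
  claim about real-data accuracy follows from it.
* Checkpoints are plain `.npz` archives of parameter arrays plus a JSON
  config; they are not portable to other frameworks.
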