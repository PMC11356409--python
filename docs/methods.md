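# Methods

## Problem setting

Segmentation models trained on public polyp collections degrade on images
from a new endoscopy rig: colour cast, illumination, texture statistics and
specular artefacts differ between datasets, and the new data is typically
unannotated, so the model cannot be fine-tuned directly.  This package
implements a self-adaptive teacher-student protocol for that setting: one
*teacher* segmenter is trained per annotated source domain, the teachers'
predictions on the unlabeled target domain are fused into soft
pseudo-labels, and a *student* segmenter of the same architecture is
trained on those pseudo-labels alone.  The fusion is the scientific core:
it weights each teacher by how close the target image is to that teacher's
training domain and by how confident the teacher is at each pixel.

## Pseudo-label fusion

For target image x and teachers i = 1..k with soft predictions
ŷ_i ∈ [0,1]^{H×W}:

* **Distribution weights.**  A small convolutional autoencoder φ_i is
  pre-trained per source domain on images only (MSE objective).  The
  reconstruction distance D_i = mean‖φ_i(x) − x‖² measures how far x lies
  from domain i; u = softmax(−D) is a per-image simplex, largest for the
  nearest domain.
* **Uncertainty weights.**  Each prediction carries a per-pixel entropy
  U_i = −ŷ_i log(ŷ_i + ε) with ε = 1e−8; v(p,q) = softmax over teachers of
  −U_i(p,q) is a per-pixel simplex, largest for the most confident
  teacher.  The single-term entropy is the implemented default (its
  maximum e⁻¹ sits at ŷ = e⁻¹); the full binary entropy
  −ŷ log ŷ − (1−ŷ) log(1−ŷ), which peaks at ŷ = 0.5, is available behind
  `binary_entropy=True` for users who want uncertainty centred on the
  decision boundary.
* **Fusion.**  Ŷ(p,q) = Σ_i ((u_i + v_i(p,q))/2) · ŷ_i(p,q).  The weights
  form a per-pixel simplex, so Ŷ is always inside the convex hull of the
  teacher predictions.  Ablation modes replace the weights with 1/k
  (`mean`), v alone (`uncertainty_only`) or u alone (`distance_only`); a
  `merge` pipeline baseline instead trains a single teacher on the pooled
  sources.

Distances are computed per target image (u is image-specific), not once
per dataset: the fusion is meant to adapt to each image's position between
the source distributions.

The student trains against the fused label binarized at 0.5 by default
(`student_binarize_threshold`).  The Tversky loss accepts soft targets
with the same soft-count formulas, and a purist may set the threshold to
`None` to train on Ŷ directly — but that path is improper whenever the
teachers disagree confidently.  If one teacher confidently predicts
foreground everywhere on the shifted target (a real failure mode of
domain transfer), its low entropy earns it a large uncertainty weight and
the fused label acquires a soft background floor around w ≈ 0.35.  Under
soft counts the all-foreground prediction then scores a *higher* Tversky
index than the exact fit P = Ŷ (with a 0.35 floor and typical foreground
mass: ≈0.56 vs ≈0.46), so student training collapses to all-foreground —
we observed exactly this, from the first epoch, at both α = 0.3 and
α = 0.5.  Binarizing keeps the fusion's decision (where the convex
combination crosses 0.5, which is where the distribution and uncertainty
weights act) while restoring a well-posed objective.

## Segmentation network

The segmenter is a coarse-to-fine attention network:

* **Encoder** — D residual blocks (conv-BN-ReLU-conv-BN with a projection
  skip), stride 2 each, channels doubling from `base_channels`; level d
  has spatial size input/2^(d+1).
* **Identify block** (deepest level) — channel self-attention followed by
  spatial self-attention, then a 1×1 conv + sigmoid producing the initial
  coarse mask P_ini.  Channel attention forms a c×c row-stochastic matrix
  softmax(QKᵀ/√c) over channels; spatial attention treats the w·h
  positions as tokens and forms a (wh)×(wh) matrix.  All projections are
  1×1 convolutions, single head, no positional encoding.
* **Refine blocks** (one per remaining level, walking up) — with the
  previous block's features O and mask P upsampled ×2 (bilinear; O also
  passed through a 1×1 channel-alignment conv), and z the encoder feature
  at this level:

      z ← Attn_all(z)
      z' = O − γ₁·Attn_fg(P ⊙ z) + γ₂·Attn_bg((1−P) ⊙ z)
      P' = σ(ω ⊗ z')

  The foreground stream isolates features the previous mask wrongly
  claimed (subtracted), the background stream recovers features the mask
  missed (added).  γ₁, γ₂ are learnable scalars initialised at 1; with
  both zero the block passes O through exactly, which the tests pin down.
  Gates use the soft mask (no binarisation) so gradients flow through the
  gating.

Every decoder level emits a sigmoid mask; the stack (finest first) is the
prediction pyramid, and the finest mask upsampled to input resolution is
the inference output.

## Loss

Per level, the Tversky loss 1 − (TP+s)/(TP + α·FP + β·FN + s) with soft
counts TP = ΣP·y, FP = ΣP·(1−y), FN = Σ(1−P)·y; α + β = 1 and
α = β = 0.5 recovers soft Dice exactly.  Defaults α = 0.3, β = 0.7
penalise false negatives harder — sensitivity to small lesions matters
more than over-segmentation in screening — and s = 1e−6 guards empty
masks.  The deep-supervision objective sums λ_d · Tversky(P_d, I(y, P_d))
over decoder levels, where I bilinearly downsamples the (possibly soft)
label to each level's size and λ_d = 2^d in decoder order (coarsest d = 0),
so the finest level dominates.  Schemes 1, d+1, 2^d, 3^d are selectable;
`linear` uses d+1 rather than d so the coarsest level keeps nonzero
supervision.

## Training protocol

Adam (lr 2e−4, β = 0.9/0.999), batch 4, 200 epochs at full scale; each
labeled domain is split 90/10 and the checkpoint with the best validation
Dice is kept (the selection criterion is our choice; only the split ratio
is prescribed).  Each stage re-seeds deterministically from the config
seed plus a stage offset, so the whole protocol is bit-reproducible on a
fixed seed.  The student never shares initialisation with a teacher, and
pseudo-labels are not refreshed during student training.

Autoencoders train for `max(40, epochs/2)` epochs (lr 1e−3, batch 8).
The floor matters: reconstruction distance only measures distribution
distance once every autoencoder has reached its own-domain reconstruction
floor — under-trained autoencoders differ more in convergence luck than in
domain fit, which corrupts the distribution weights.  At the full-scale
budget the half rule alone governs.

## Numerical core

No deep-learning framework is assumed: the package carries a compact
reverse-mode autodiff engine on NumPy (`sats.nn`) providing broadcasting
arithmetic, matmul, softmax, im2col convolution, batch norm and bilinear
resizing, each gradient verified against central finite differences in the
unit suite.  Everything is float32 and single-threaded-deterministic.
Bilinear resizing uses the half-pixel-centre convention as an explicit
pair of interpolation matrices, so 2× downsampling of block-aligned masks
is an exact block average (the loss tests rely on this).

## Synthetic benchmark

Real multi-centre polyp data cannot ship with the package, so the
generators emulate the situation at desk scale.  Each source domain has a
deterministic style: base hue on a 45° grid (seed-dependent global
rotation), illumination gain on a 0.25 grid — so two distinct domains
always differ by ≥10° hue or ≥0.2 gain — plus texture frequency, Gaussian
noise level, and Poisson-placed specular spots of a style colour.  An
image is a tinted mucosa background with an illumination gradient and
sinusoidal texture, one star-shaped polyp (deformed ellipse, hue-shifted
and brighter, own texture) whose area is kept in [2%, 40%] of the frame,
spots, then pixel noise.  The target style is a convex mixture of the
source styles with one dominant source at weight 0.8 plus small
perturbations; its spot colour mixes the source spot colours with a cold
(green/blue) tone and a raised spot rate, mimicking the bright artefacts a
private rig can add.  The dominant source is recorded in metadata, and the
construction keeps it the nearest style — an earlier draft that drew the
target spot colour independently could collide with a source's spot
colour and silently break that guarantee.

What the benchmark does *not* model: real anatomy (folds, vessels,
instruments, fluids), resolution above ~128², multiple polyps or negative
frames, and annotation noise.  Passing the synthetic suite therefore shows
the machinery is correct and the fusion recovers a planted domain
structure; it does not certify clinical performance.

## Desk-scale study sizes

The scaled study used by the tests and the acceptance script runs 3 source
domains × 60 images at 64×64, depth-3 network with base width 8 (~29k
parameters), 20 epochs — sizes chosen so the full protocol trains from
scratch in minutes on one CPU while leaving every qualitative property of
the full-scale recipe intact.  The default image size for demos is 128².

## Degenerate inputs and conventions

* Predictions are binarised at 0.5 for evaluation; HD is the full
  symmetric Hausdorff distance (HD95 behind a flag), boundaries are
  4-connected with the image border counting as background.
* Empty-vs-empty masks score 1 on the overlap metrics; an empty boundary
  makes HD/MSD fall back to the image diagonal, logged, never silent.
* Softmax weight computations shift by the minimum distance/entropy before
  exponentiating, so large distances cannot underflow to 0/0.
* Masks on disk are 0/255 PNG binarised at >127; soft pseudo-labels are
  16-bit PNG exact to 1/65535.

## Known limitations

* The attention cost is quadratic in w·h per level; 64–128² inputs are the
  practical envelope of the NumPy engine.
* γ₁/γ₂ learnable, unshared attention parameters across the all/fg/bg
  streams, and the number of refine blocks (D−1) are choices where the
  recipe is genuinely ambiguous; all are configurable.
* Distribution weights are nearly uniform when reconstruction distances
  are small relative to their spread (softmax on a ~1e−2 scale); the
  argmax is still informative, but downstream users should inspect the
  sidecar u vectors rather than assume sharp weights.
* Entropy-based uncertainty weights score confidence, not correctness: a
  teacher that fails on a shifted domain by confidently predicting
  foreground everywhere earns *low* entropy and therefore extra weight at
  exactly the pixels where better teachers hesitate.  When the
  distribution weights are near-uniform (previous point), this can make
  the full fusion marginally worse than plain averaging; the acceptance
  script reports both students' Dice so the comparison is visible rather
  than assumed.
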