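# Methods

## Model

The package implements masked-window self-supervised pretraining for small
tabular regression problems. A sample is a vector of L features in a fixed,
meaningful order (default L = 22: bands, vegetation indices, texture
statistics, topography). The pretext task corrupts a block of W consecutive
features and asks the network to reconstruct the whole vector from (a) the
uncorrupted remainder and (b) the corrupted block itself, so the encoder must
learn the joint structure of all feature groups rather than memorize
individual columns.

### Disturbance

* Window start P ~ Uniform{1, …, L−W−1}. Indexing is 0-based with half-open
  windows: the window covers features P … P+W−1, which makes the residual
  length exactly L−W (18 by default) and keeps the first and last feature
  always in the residual. The alternative inclusive reading (W+1 features)
  would contradict the residual width the flatten projection is specified
  against, so it is rejected.
* Auxiliary data x̃ = Ṅ + χ(window): a uniformly random permutation of the
  window entries (identity allowed) plus i.i.d. Gaussian noise. The noise is
  *added*, not substituted, and its standard deviation defaults to 1.0 —
  features are z-scored first, so σ = 1 means the mask is as strong as the
  signal. No noise parameters are inherited from prior work; σ is a free
  dial of the corruption strength.
* Fresh P, permutation and noise are drawn for every sample in every epoch;
  `views_per_sample` materializes extra views per epoch when wanted.

### Encoder

Each multi-view cascaded convolution module (MVCCM) runs three branches with
strides 1, 2, 3. A branch applies a small convolution (kernel 2), then a
medium convolution (kernel 3) on its output, concatenates the two maps along
the LENGTH axis, and applies a large convolution (kernel 4). Branch outputs
are concatenated along the length axis; the channel count K (16 in module 1,
32 in module 2) is constant inside a module. All convolutions are valid
(no padding) with ReLU; length-axis concatenation is the only convention
under which branches of different stride — hence different output length —
can be concatenated at all, which is why same-padding/channel-concatenation
variants were rejected. Two modules alternate with max pooling (window 2,
stride 2); the final map is flattened and linearly projected to L−W = 18.

For a length-18 residual the stage lengths are 36 → 18 → 36 → 18 and the
flatten width is 18 × 32 = 576. (The originally reported flatten width of 928
is not reproducible under any single padding/concatenation convention we
could construct; the package computes and logs its own width and treats the
projection *output* width, 18, as the binding quantity.)

### Decoder and stage-1 loss

The projected representation acts as a residual skeleton: its first P entries
stand for the features before the window, the rest for those after. It is
spliced with the auxiliary data at position P (an exact bijection, unit
tested), giving a length-L decoder input. The decoder is two valid conv+pool
blocks ((16, k3, s1), (32, k3, s1), pools 2/2: 22 → 20 → 10 → 8 → 4), a
flatten (128) and a linear layer back to L outputs. The output layer is
linear because targets are z-scored features of either sign. The loss is the
mean square over all L positions, not only the corrupted W; a
`masked_loss_only` flag enables the masked-positions-only variant for
experimentation (default off).

### Fine-tuning

Stage 2 consumes the full, undisturbed L-vector. Convolution kernels are
length-agnostic, so the pretrained blocks are reused as-is on length-L input
(stage lengths 46 → 23 → 49 → 24, flatten 768); only the flatten projection
is re-instantiated for the new width, and it is always trained in stage 2.
The biomass head is two fully connected layers (18 → 200, ReLU, 200 → 1
linear). By default the convolutional encoder is frozen during stage 2
(`freeze_encoder_in_stage2=False` enables joint updates). Biomass targets are
used on their native scale by default; `standardize_target=True` z-scores
them internally and inverts at prediction time.

## Numerical choices

* Layers are implemented directly on numpy with hand-derived backward passes
  (verified against central finite differences in the test suite); array
  layout is (batch, channels, length).
* Optimizer: Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) at learning rate 1e-4,
  batch size 20, for both stages. Fixed epoch counts, no early stopping, no
  gradient clipping; a non-finite loss aborts with the epoch index.
* Initialization: fan-in uniform (±1/√fan_in) from a seeded generator. The
  estimator's output bias is initialized to the mean of the training targets:
  targets live on a ~10–29 scale while the learning rate is 1e-4, and
  starting the scalar output at the target mean is the standard conditioning
  choice for unscaled regression targets.
* Standardization is fitted on training rows only and applied to test rows;
  constant columns standardize to exact zeros with std treated as 1.
* All randomness flows from one integer seed through spawned generator
  streams (initialization / disturbance / batching), so runs are
  bit-reproducible; fixed seeds give identical loss histories, predictions
  and ablation tables.
* Max pooling is the default (`pool_mode="avg"` is available); pooling and
  convolution shapes are validated at build time against the length formula
  ⌊(n−V)/S⌋+1, and an underflowing stage raises a configuration error naming
  the stage.

## Synthetic data

The real 58-plot dataset is confidential, so the generator emulates its
statistical structure: a latent canopy density c ~ U(0,1) drives seven
reflectance-like bands (red and short-wave decreasing in c, near-infrared
increasing) with relative Gaussian noise (`latent_noise`, default 0.3); the
six vegetation indices are computed from the synthetic bands with their
standard formulas; eight texture statistics are smooth nonlinear transforms
of c plus noise; the topographic factor is weakly correlated noise. A latent
diameter affine in c (1–10) feeds the allometric law y = 3.614·D^1.446; noise
(`biomass_noise`, default 0.5) is added and the result is affinely anchored
to the published 10–29 test-span so error magnitudes are on the published
scale.

What the generator does *not* emulate: spatial autocorrelation between
plots, sensor calibration artifacts, saturation of indices in dense canopy,
non-monotone biomass responses, or the real covariance of GLCM textures.
Tests passing on this generator therefore show that the mechanism works on
data with the assumed latent-monotone structure — not that the published
field-data error levels transfer.

## Evaluation harness

Holdout splits take ⌊0.7·n⌋ training rows after a seeded shuffle (58 → 40/18,
the study layout); fivefold cross-validation shuffles once and blocks
contiguously, giving test folds (12, 12, 12, 11, 11) for n = 58. The ablation
grid trains, on identical splits and seeds: T1 = pretraining + multi-view
encoder, T2 = pretraining + a plain single-branch encoder (two conv(k3,s1)
+pool blocks with matched kernel counts — the substitute architecture is not
specified anywhere, so a matched-budget plain CNN was chosen), T3 =
multi-view encoder with random initialization and no pretraining. MAE and
RMSE per (task, seed) are reported; the headline claim is directional and
statistical (median over seeds), not per-seed.

## Problem sizes

The default schedules in the test suite and `scripts/acceptance.py` use 200
epochs per stage, 58 synthetic samples, 3 seeds for the training-improves
check and 10 seeds for the ablation; these sizes keep a full reproduction at
a few minutes on one CPU while leaving the directional results unambiguous
(typical held-out MAE ≈ 1.1–1.6 for the full model vs ≈ 2.6–4.5 without
pretraining). The 1000-epoch schedule of the original experiments remains
the library default (`TrainConfig`).

## Known limitations

* The flatten width discrepancy above means parameter counts need not match
  the original implementation.
* Whether the original fine-tuning updates the encoder is ambiguous in the
  source description (the training procedure updates only the estimator; the
  stage is nevertheless called fine-tuning); both behaviors are exposed and
  freezing is the default.
* Biomass units are opaque (the source never states them); the package
  treats them as arbitrary positive units.
* The quoted "R² = 1.801" alongside the allometric law is impossible as a
  coefficient of determination and is presumed a typo; the power law is
  implemented as printed.
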