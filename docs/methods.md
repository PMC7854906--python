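# Methods

This note describes the models and procedures implemented in `eegadapt`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Problem setting

EEG is non-stationary: the signal distribution of the same subject drifts
between recording days, and differs strongly between subjects. A classifier
trained on labeled recordings from some *source* domains (earlier days, other
subjects) therefore degrades on a new *target* domain. The package implements
a transductive unsupervised domain adaptation pipeline: labeled source data
plus unlabeled target data are used jointly so that the learned representation
is both discriminative for emotion classes and invariant across domains.

## Feature pipeline

**Windowing.** Continuous multichannel EEG is cut into 2-s windows with 50%
overlap (both configurable), left-aligned at sample 0 with the trailing
remainder dropped; a 50-s record yields 49 windows at a 1-s hop. Window and
hop must be integer numbers of samples.

**Band decomposition.** Each window is decomposed into the five canonical
bands — delta 1–3, theta 4–7, alpha 8–13, beta 14–30, gamma 31–50 Hz — with a
zero-phase (forward–backward) Butterworth band-pass of order 4 applied per
window. Filtering per window keeps windows self-contained units; edge
transients at the 2-s scale are accepted. Note the canonical band edges leave
1-Hz gaps (3–4, 7–8, 13–14, 30–31 Hz): with order-4 roll-off the five band
variances recover the total 1–50 Hz power only up to this gap loss (about
10–14% depending on the sampling rate), which is why the tiling test bounds
the deficit at 15% rather than treating the bank as a perfect partition.

**Differential entropy.** Treating the band-limited samples in a window as
Gaussian, the feature is h = ½·ln(2πeσ²) in nats, with σ² the *population*
variance over the window (a descriptive statistic, not an inferential
estimate). Variances below a floor (default 1e-12) are clamped with a warning
so degenerate all-zero windows stay finite. No base-2 option is provided.

**Topographic images.** 3-D electrode positions (unit-sphere normalized) are
projected to the plane by the azimuthal equidistant projection about the
vertex: a point at polar angle θ maps to plane radius θ at its original
azimuth, preserving arc length along meridians and hence electrode adjacency.
Per-band DE values are interpolated with the Clough–Tocher scheme (C1
piecewise cubic on the Delaunay triangulation) onto a uniform square grid
spanning the electrode bounding square plus a 5% margin, symmetric about the
projection center — by default 32×32 per band, i.e. a 32×32×5 image per
window. Pixels outside the electrode convex hull take a fill value (default
0); there is no extrapolation or pseudo-electrode padding. Image row 0 is the
front of the head (nasion), column 0 the subject's left, fixed so images are
comparable across runs. Min–max standardization maps each scoped group
affinely to [0, 1]; the default scope is per image and band (each 32×32 slice
independently), with a per-band-global option, since either reading is
consistent with full-range per-slice contrast. A degenerate group (max = min)
maps to 0.

## Networks

The feature generator G_f is a CNN on the 5-band image stack; the classifier
G_c and domain discriminator G_d are softmax heads on its output feature.
Three presets are provided:

| preset | conv stack | dense widths | feature dim |
|---|---|---|---|
| `cross_day` | 5→6, pool, 6→64, pool | 512, 256 | 256 |
| `cross_subject` | 5→32→32, pool, 32→64→64→128→128, pool | 1024, 512, 256 | 256 |
| `compact` | 5→8, pool, 8→16, pool | 64, 32 | 32 |

Convolutions are 3×3, stride 1, *valid* (unpadded); pooling is 2×2, stride 2,
ceil-mode. This is the only standard convention under which the cross-day
flatten size works out to 7×7×64 for a 32×32 input (32→30→15→13→7). The
commonly quoted cross-subject flatten size (6×6×128) is not reproducible for a
32×32 input under any single standard convention we could identify; the layer
list is honored and the true flatten size (3×3×128) is always computed
dynamically from the actual spatial dimensions. `compact` is this package's
desk-scale preset for synthetic benchmarks; it shares the topology family and
exists so that multi-seed ablation grids run in minutes on one CPU.

Activations are ReLU (the architecture family's default; the original
description does not state one). Dense layers carry dropout at rate 0.5.
Classifier and discriminator are single dense layers by default (no hidden
sizes are part of the reference description); the discriminator depth is
configurable.

**Adaptive batch normalization.** An AdaBN layer follows every conv group and
dense layer. In training, each domain's sub-batch is standardized by its own
batch mean/variance and then transformed by *shared* learnable scale/shift;
running statistics are tracked per domain. Before evaluating a new domain, an
adapt pass recomputes that domain's statistics over the unlabeled pool in
fixed-size chunks (default 1024), merging chunk statistics exactly via the
pooled-moments formula. In eval mode each sample is normalized with its
domain's stored statistics; an unseen domain raises rather than silently
borrowing another domain's statistics. With adaptivity disabled the layer is
plain batch normalization (one shared statistics slot), which is the
source-only baseline's configuration.

**Implementation.** The layers are implemented directly on numpy arrays with
hand-derived analytic backward passes (im2col convolutions, ceil-mode pooling
with argmax routing, per-domain batch-norm backward, inverted dropout). The
gradient-penalty term additionally requires differentiating the
discriminator's *input-gradient norm* with respect to its parameters; for the
(ReLU-)MLP discriminator this double backprop is computed in closed form by
exploiting that ∇ₓs is multilinear in the weight matrices once the ReLU masks
are fixed (exact almost everywhere). Finite differences are never used
outside test oracles. Network internals default to single precision — ample
for stochastic-gradient training and about twice as fast on one CPU — while
all loss and oracle computations are double precision.

## The two-level objective

With H the discriminator's mean domain cross-entropy over the joint batch,
the sign convention used throughout is L_D = −H (the objective is often
written with L_D both maximized and negated inside a maximization; this
operational resolution matches the evident intent). The alternating steps per batch
are:

* **Discriminator step** (θ_d): minimize H + λ_L·GP, where
  GP = mean (‖∇ₓ s(x)‖₂ − 1)² is the Lipschitz gradient penalty. The
  penalized scalar s is the pre-softmax logit of the source domain — a
  softmax probability has bounded input-gradients, which would make the
  unit-norm target unreachable. Penalty evaluation points default to random
  convex combinations of paired source/target features (the WGAN-GP
  convention), with an option to penalize at the features themselves.
* **Generator/classifier step** (θ_f, θ_c): minimize
  L_G = L_C + λ_d·(−H) + λ_m·L_MMD + λ_z·‖W‖², i.e. source cross-entropy,
  domain confusion, feature-distribution alignment, and an L2 term over the
  dense weight matrices of G_f and G_c (biases and normalization parameters
  excluded; "the transformation matrix" is ambiguous as a parameter set, and weight
  decay conventionally targets weight matrices).

λ_L multiplies the penalty in the discriminator step only. Adversarial
optimization is realized by these explicit alternating steps (one
discriminator step per generator step by default) rather than a
gradient-reversal layer, so each objective corresponds to exactly one
update.

**MMD.** The first-level alignment is the biased multi-kernel squared MMD
between source and target feature sets, with RBF bank
κ(x,y) = Σₙ ηₙ·exp(−‖x−y‖²/(2σₙ)). The cross-term coefficient defaults to 2
(the standard biased estimator, guaranteed nonnegative); coefficient 1
reproduces the plain three-term form, at the cost of possible small
negative values, and is available as `cross_coefficient=1`. No bandwidths or
weights are prescribed for the kernel bank, so the default uses the median
heuristic: 5
kernels centered on the median pairwise squared distance of the pooled batch,
spaced by factors of 2, equally weighted, recomputed per batch (a fixed bank
can be supplied instead).

## Training protocol

Defaults follow the reference cross-day settings: λ_d = 0.1, λ_m = 0.1,
λ_z = 0.01, λ_L = 10; Adam with learning rate 5·10⁻⁴; batches of 160 split
half labeled source, half unlabeled target. (The reference cross-subject
settings — batch 224 split 112/112, λ_L = 0.1 — are reachable through the
same configuration.) Per epoch, source samples are covered exactly once in
seeded permuted batches; target samples are drawn without replacement from a
reshuffling cycle. Multi-source domains are merged into a single source label
for the discriminator (N = 2), matching the binary source/target batch split;
the per-domain-label mode can be obtained by relabeling upstream.

The stopping rule is this package's choice. It holds out 15% of each source
domain (stratified by class) as a validation set, early-stops on validation
classification loss with patience 20 within a 300-epoch cap, and restores the
best checkpoint. Training is transductive by default — the unlabeled target
pool participates in every batch — with a flag for inductive (source-only)
operation. All randomness (initialization, splits, batching, dropout,
penalty interpolation points) derives from one config seed through separate
spawned streams, so a fixed seed and config reproduce bit-identical metrics
on the same platform.

Leave-one-domain-out cross-validation makes each domain (day or subject) the
unlabeled target/test set once; target labels are used only for scoring after
training, and the training API has no slot for them. Evaluation runs an AdaBN
adapt pass over the full target pool first (whether per-batch or full-pool
adaptation was used originally is unstated; full-pool is the lower-variance
choice).

## Synthetic EEG generator

Real emotional EEG is not redistributable, so the generator emulates the
statistical structure the pipeline assumes. Each trial is a sum over bands of
band-limited Gaussian noise — synthesized with the *same* Butterworth bank
the feature extractor uses, so generator and extractor agree exactly on band
definitions — with per-channel standard deviation base_sd × class multiplier
(band, scalp region), plus a domain constant offset and domain-scaled
broadband noise, with a per-channel domain gain applied last. Classes thus
differ in where band power concentrates; domains differ by multiplicative
gain and noise level. Because gain multiplies all bands of a channel equally,
class-conditional band-power *ratios* are domain-invariant (the structure
adaptation should exploit) while absolute DE distributions shift (what the
adaptation must remove). Constant offsets leave per-window variances — and
hence DE — unchanged, and serve as an invariance check.

The packaged benchmark fixture has 2 classes × 3 domains, 61 channels, 12
trials of 50 s per domain (588 windows per domain at the standard windowing).
Classes concentrate alpha power frontally vs parietally (multiplier 2.2 in
the `easy` setting); domains apply opposing frontal/parietal gains and graded
broadband noise, calibrated during construction so that a source-only
classifier trained on two domains loses a large fraction of its accuracy on
the held-out third while the adaptive methods recover it. The `hard` setting
shrinks the class contrast and strengthens the shift for stress testing.

**What passing this benchmark shows — and does not.** It shows the whole
chain (features → images → adaptation → LOOCV) is wired correctly and that
the two-level objective actually removes the kind of domain shift it targets:
additive feature-space shifts with preserved class geometry. It does not
emulate artifacts (EOG/EMG), within-trial non-stationarity, volume-conduction
correlation structure, or realistic class overlap, so margins measured here
say nothing quantitative about real cross-day or cross-subject EEG.

## Numerical choices and degenerate inputs

* Variance floor 1e-12 before the DE logarithm; probability floor 1e-12
  before every cross-entropy logarithm.
* Batch-norm ε = 1e-5; running-statistics momentum 0.1; a training domain
  with fewer than two samples in a batch is an error, not a silent pass.
* Max-pool ties route the gradient to the first maximal element.
* Median-heuristic bank construction fails loudly if all pooled points are
  identical (zero median distance).
* MMD cross-coefficient 2 keeps the estimator ≥ 0 up to rounding (−1e-9
  tolerated in tests).
* Degenerate min–max groups map to 0; an empty interpolation mask is an
  error.
* The gradient penalty at a zero-gradient point has derivative contributions
  guarded against division by zero (the penalty value (0 − 1)² = 1 is still
  exact).

## Desk-scale problem sizes

The test suite and the acceptance script run the ablation benchmark with the
`compact` preset at image resolution 24, batches of 49 + 49, 8 epochs with
patience 4 — sizes chosen so a 4-method × 3-fold grid over several seeds
completes in minutes on one CPU while preserving the qualitative ordering
(two-level ≥ single-level ≫ source-only). The full-size presets and protocol
settings remain the defaults of `AdaptationConfig` and are exercised by the
architecture and unit tests.

## Known limitations

* The commonly quoted cross-subject flatten size cannot be reproduced for 32×32
  inputs (see above); the implementation follows the layer list.
* Exact double-backprop for the gradient penalty is implemented for the MLP
  discriminator family (any depth, ReLU hidden); a convolutional
  discriminator would need the corresponding derivation.
* AdaBN assumes the target pool used in the adapt pass is representative of
  the evaluation distribution; per-batch adaptation at test time is not
  implemented.
* Unsupervised alignment can in principle map classes onto the wrong side
  when the shift exceeds the class separation (label flipping); the
  classifier term discourages but cannot preclude it. This is inherent to
  the method, not an implementation artifact.
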