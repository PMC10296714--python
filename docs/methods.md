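# Methods

This note documents the models and procedures implemented in `endofeat`,
the parameter defaults and why they were chosen, the numerical conventions
that make results bit-reproducible, and what the synthetic data does and
does not establish.

## Enhancement chain

The chain assumes frames are RGB rasters scaled to [0, 1]; every stage maps
[0, 1] images to [0, 1] images and no stage changes the raster shape after
the initial resize to `working_size` (default 256×256; tests and the demo
use smaller sizes purely as a problem-size choice).

* **Rotation augmentation** uses exact array transposition for 90°/180°/270°
  right rotations — no interpolation, so the pixel multiset is preserved
  ("lossless").
* **Box filter**: per-channel convolution with an all-ones `size×size` mask
  (default 3×3) normalized by `size²` — without the normalization values
  would leave [0, 1]. The convolution is cropped to "same" size with zero
  padding so downstream shapes are stable.
* **Median filter**: per-channel `size×size` window median (default 3×3),
  zero-padded, for impulse-noise removal. Idempotent on constants.
* **RGB→HSI**: intensity I = (r+g+b)/3; hue is the angle
  θ = arccos(0.5[(r−g)+(r−b)] / √((r−g)² + (r−b)(g−b))) reflected to
  360° − θ when b > g; saturation S = 1 − 3·min(r,g,b)/(r+g+b).
  Degenerate pixels are defined, never exceptional: achromatic pixels
  (zero hue denominator, or r+g+b = 0) get H = 0 and S = 0, and the arccos
  argument is clamped to [−1, 1] against round-off.
* **CLAHE** is applied independently to the H (scaled to [0, 1]), S and I
  planes. Clip limit 0.01 of the dynamic range and an 8×8 tile grid are the
  common defaults for adaptive equalization; both are config fields. A
  constant plane is returned unchanged.
* **Chromatic weight map**: W(x) = exp(−(S(x) − μ)²/2σ²) with μ = 1,
  σ = 0.3. The Gaussian centered at full saturation up-weights
  chromatically vivid pixels (in endoscopy, the lesion-prone regions); the
  weighted plane is min–max rescaled to [0, 1] and becomes the LBP input
  (`S_CLAHEImproved`). The functional form is a design choice of this
  package; μ and σ are exposed for sensitivity analysis.
* **Ensemble + unsharp**: the three CLAHE planes are stacked into one
  3-plane image (hue divided by 360 so all channels share [0, 1]) and
  sharpened by `out = clip(img + amount·(img − G_σ(img)))` with σ = 1,
  amount = 1. That sharpened ensemble is the deep-feature input.

## Uniform LBP

Bit q = 0 sits at the east neighbor and bits proceed counter-clockwise over
the 8-connected ring at radius 1 (no interpolation); the threshold is
`E_q − E_c ≥ 0`, so ties set the bit (a constant patch yields code 255).
Any fixed ordering yields the same histogram up to a bin permutation; this
one is frozen so tests are bit-stable. A code is uniform when its circular
bit string has at most two 0↔1 transitions; exactly 58 of the 256 codes
qualify. The histogram has those 58 bins in ascending code order plus one
aggregate non-uniform bin (59 total), is L1-normalized so images of
different sizes are comparable, and excludes border pixels lacking a full
ring.

## Deep-feature contract and fusion

Deep features enter only through the `DeepExtractor` contract: a named,
fixed-dimension (default 512), deterministic map from image to vector. The
included stub mean-pools the image to 16×16×3 and applies a seed-fixed
random Gaussian projection — a deterministic stand-in that preserves
color/intensity class structure linearly but carries no learned semantics;
any trained CNN can be plugged in by wrapping its forward pass. Fusion is
column-wise concatenation in block order (deep_a, deep_b, lbp) with named
block spans retained, giving 512 + 512 + 59 = 1083 columns at the default
widths.

## Swarm wrapper selection

All three optimizers minimize

    fitness(mask) = w_err·(1 − acc) + w_frac·(|mask|/D),  w_err = 0.99, w_frac = 0.01,

where `acc` is the holdout accuracy of a k-NN classifier (k = 5) trained on
the masked columns over a single stratified 70:30 split fixed per run seed.
A single fixed split keeps every fitness evaluation cheap and deterministic
within a run; final quality reporting uses the cross-validation harness
instead. An all-zero candidate mask is repaired by force-setting one
random bit so fitness is defined everywhere. Population 20 and 50
iterations are the defaults; all settings live in `SelectorConfig`.

* **BDA** keeps strictly binary positions. Per agent the separation,
  alignment, cohesion, food-attraction and enemy-distraction vectors are
  computed over a global neighborhood (all other agents; food = best mask
  so far, enemy = current worst). The step is
  ΔX' = (s·S + a·A + c·C + f·L + e·E) + w·ΔX, and each bit flips with
  probability Tf(ΔX') = |ΔX'|/√(1+ΔX'²). The printed transfer form without
  the absolute value is negative for negative steps and cannot be a
  probability, so the v-shaped form of the original binary-dragonfly
  literature is used. Coefficients follow that literature's schedule:
  w anneals linearly 0.9→0.4; an exploration envelope
  `my_c = max(0.1 − 0.2k/T, 0)` scales s, a, c (each `2·rand·my_c`),
  f = 2·rand, e = my_c.
* **MFO** keeps continuous positions in [0, 1], clamped after each spiral
  move `|F−W|·e^{cr}·cos(2πr) + F` (c = 1, r uniform in [−1, 1] per
  dimension). Flames are the elite of previous flames and current moths;
  the flame count shrinks as `round(M − k(M−1)/T)` (half away from zero),
  reaching 1 at the final iteration.
* **PSO** uses v' = I·v + c₁r(pbest−p) + c₂R(gbest−p) with c₁ = c₂ = 2,
  inertia annealed 0.9→0.4, velocities clamped to ±6 and positions to
  [0, 1].

Continuous positions are binarized by a strict 0.5 threshold (x = 0.5 maps
to 0; a stochastic rule `bit = [rand < x]` is available). All methods are
elitist: the best mask ever evaluated is retained, so the reported
best-fitness history never increases.

## Metrics and evaluation

Per-class one-vs-rest counts feed SEN, SPE, PRE, F1, ACC, MCC and Cohen's
κ ((p_o − p_e)/(1 − p_e), p_e from marginal products). Multiclass values
are macro-averaged (unweighted over classes); the averaging mode is
explicit in every report. Zero-denominator cells (e.g. precision with no
positive predictions) return 0 with a warning rather than raising, so fold
aggregation stays total. Cross-validation is stratified k-fold (default 5)
with a pooled confusion matrix that is exactly the sum of fold confusions;
the 70:30 stratified holdout is also provided, with per-class train shares
within one sample of the requested fraction.

The six classifier presets map MATLAB-style learner names onto
scikit-learn equivalents: fine/coarse trees (≤100 / ≤4 splits, i.e.
`max_leaf_nodes` 101 / 5), quadratic SVM (degree-2 polynomial kernel,
natively one-vs-one), fine Gaussian SVM (kernel scale √D/4, so
γ = 16/D — deliberately narrow, prone to overfitting high-dimensional
data, as the preset intends), coarse k-NN (k = min(100, ⌈N/10⌉)), and an
ensemble subspace discriminant (30 LDA learners on random ⌈D/2⌉-feature
subspaces). Exact MATLAB internals are not reproduced; the mapping is
documented here and fully determined by name + seed.

## Synthetic data

`make_images` produces red-dominant, smoothly textured backgrounds with
class-dependent soft-edged elliptical lesions — bleeding-like: saturated
red blobs; ulcer-like: pale bright blobs; healthy: none — plus exact lesion
masks and Gaussian pixel noise (SD 0.02). The palette imitates
capsule-endoscopy chroma loosely; there is no claim of clinical realism,
and specular highlights, motion blur and optical vignetting are absent.
Passing tests therefore demonstrate that the pipeline behaves correctly on
images with the assumed structure, not that it reaches any particular
accuracy on clinical data.

`make_table` draws every column as unit-variance Gaussian noise and adds
class-conditional mean shifts to `n_informative` randomly placed columns.
The `effect` parameter is the **overall** between-class separation: the
norm of the mean-shift vector across informative columns, so the
per-column shift is `effect/√k`. Under this convention no single column
separates the classes on its own (at the default effect = 3 and k = 10,
each column carries ≈0.95 SD), which is what makes planted-feature
recovery a meaningful test: the wrapper fitness rewards retaining the whole
planted set and dropping noise columns, and recovery increases with
`effect`. Block spans mirror the fused (deep_a, deep_b, lbp) layout
proportionally.

## Problem sizes and determinism

Defaults used by the test suite and the acceptance script: selector
recovery runs on 300×200 tables with 10 planted columns, five seeds per
method; optimizer-invariant checks use 60×30 tables with short runs (6
agents, 8 iterations) across 20 seeds; the demo uses 36 images at 64×64
with a 12-agent, 15-iteration selector. These sizes exercise every code
path at desk scale. Every random draw flows from a single
`numpy.random.Generator` seeded from the run seed, so identical seeds give
bit-identical masks, histories, folds and reports.

## Known limitations

* No CNN training or transfer learning: deep features are a contract plus a
  stub, by design.
* No lesion segmentation and no video handling.
* The chromatic weight map's functional form and the selector coefficient
  schedules are design choices where the underlying method descriptions are
  silent; both are parameterized and documented above.
* Headline accuracies reported for clinical WCE datasets elsewhere depend
  on those datasets and trained CNN extractors and are out of scope here;
  this package reproduces the structural and algorithmic behavior of the
  pipeline, not dataset-level scores.
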