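# Methods

## Problem

Regional tau PET quantification normally requires a paired structural MR:
the PET is coregistered to the MR, the MR is nonlinearly normalized to a
standard template, and ROI statistics are read out in template space.
`petnorm` implements an MR-free alternative: a small neural network predicts
the nonlinear deformation field directly from the PET volume, so a single
forward pass plus one resampling puts the PET into template space.  Regional
SUVR (ROI mean activity over cerebellar-gray mean) is then computed against
a label atlas on the template grid, and the statistics layer quantifies
agreement with ground truth and associations with cognition.

Everything is developed and validated on a built-in phantom cohort with
*known* deformations and *known* regional SUVR, so every stage of the
pipeline has an exact reference.

## Deformation-prediction model

The predictor is a two-stage coarse-to-fine cascade on the template grid
(each dimension must be divisible by 4):

* **Coarse stage.**  The input volume is average-pooled to quarter
  resolution.  A three-layer 3×3×3 convolutional network (8 channels, leaky
  ReLU) sees eight input channels: the RMS-normalized moving image, the
  template, the three components of the mismatch force
  `(moving − template) · ∇template` (the first-order intensity-matching
  force familiar from demons registration), and three normalized coordinate
  channels (convolutions are translation-equivariant; mapping to a *fixed*
  template requires absolute position).  Its output is (a) a low-resolution
  displacement grid, trilinearly upsampled to the full grid, and (b) a
  global affine field (3×3 linear + translation about the volume center)
  regressed from the zeroth and first spatial moments of its hidden
  features.  The affine head exists because the bulk of a typical
  inter-subject deformation is affine, and a local convolution kernel
  cannot express a coherent global rotation or scaling.
* **Fine stage.**  The coarse-warped volume at full resolution enters an
  identically shaped network (same eight input-channel layout); its residual
  displacement output passes through a fixed Gaussian smoothing (σ = 1.5
  voxels), a structural prior that restricts the stage to deformations at
  least as smooth as those being modeled.

Output layers are zero-initialized, so an untrained model predicts exactly
the zero field.  The composed field is
`φ(v) = φ_fine(v) + φ_coarse(v + φ_fine(v))`, stored template→native with
pull semantics (`warped[v] = input(v + φ(v))`, out-of-bounds = 0); a single
resampling through `φ` reproduces the cascade.

The network, its gradients, and the Adam optimizer are implemented directly
on numpy in `petnorm._nn` — a compact reverse-mode autodiff engine with
exactly the operations this architecture needs (conv3d via im2col,
differentiable trilinear warping and upsampling, NCC/MSE losses, diffusion
penalty).  Every gradient is verified against central finite differences in
the test suite's development harness; training is bit-reproducible under a
fixed seed on one platform.

## Training

Training is unsupervised in the registration sense — no ground-truth field
ever enters the objective:

    loss = similarity(warp(anatomy, φ), template)
         + 0.5 · similarity(warp(anatomy, φ_coarse), template)   # deep supervision
         + λ · (diffusion(φ_grid) + diffusion(φ_fine))

* The field is always predicted **from the PET**; when a paired MR is
  supplied (the normal training setup), the *MR* is the volume warped and
  scored against the template.  This matters: PET and anatomical templates
  have inverted gray/white contrast, and a similarity computed on the PET
  against an anatomical template has its optimum away from the true
  deformation.  With paired-anatomy supervision, the model remains MR-free
  at inference while training against a contrast-consistent target.
* Default similarity is global NCC (robust to the PET/template intensity
  scale mismatch); MSE is selectable.
* The diffusion penalty applies to the nonparametric parts of the field
  only (low-resolution grid + fine residual); the affine component is
  smooth by construction and is not shrunk.  Default λ = 1.0 (per-loss
  scale: the NCC loss of an unregistered phantom is ≈ 0.03–0.08 and the
  diffusion penalty of a typical true field ≈ 0.004).
* Optimization: Adam, lr 1e-3 by default (the acceptance experiment uses
  3e-3, which converges faster at 32³ without instability), one random
  subject per iteration, drawn with replacement.
* Augmentation (optional, off by default): random rigid jitter
  (translation/rotation, the same draw applied to both volumes of a pair)
  plus additive Gaussian noise, re-drawn every iteration.
* Fine-tuning restarts from a checkpoint with a 10× smaller default
  learning rate (1e-4), the standard transfer-learning recipe; zero
  iterations returns the pretrained weights unchanged.

Checkpoints are single-file `.npz` archives carrying an architecture hash;
loading refuses mismatched or corrupted files rather than silently
reinitializing.

## Classic MR-based comparator

`petnorm.baseline` is a functional stand-in for the conventional
MR-dependent route, *not* a reimplementation of any specific package's
pipeline: six-parameter rigid PET→MR registration (Powell search over NCC
from multiple starts) followed by multi-resolution demons-style MR→template
field optimization (SSD force with the classic
`diff·∇/(|∇|²+diff²)` update and Gaussian field smoothing).  The rigid and
nonlinear maps are concatenated in voxel space and the PET is resampled
exactly once through the composed map.

## Phantom generator

The phantom defines the study conditions; its defaults are fixed.

* **Template/atlas** (`make_template`): nested ellipsoids (gray shell,
  white core), an inferior-posterior cerebellum (the SUVR reference), and
  seven ROI blobs carrying the role taxonomy Braak12/Braak34/Braak56/
  metatemporal/EC/ITG (EC ⊂ Braak12, ITG ⊂ Braak34, metatemporal = the
  temporal-blob union).  A deterministic smooth intensity texture
  (σ ≈ 3 voxels, sd 10%) inside the head supplies the spatial asymmetry
  real anatomy has; without it the phantom is nearly rotation-symmetric and
  parts of the deformation are invisible to *any* intensity-driven method.
* **Deformations** (`sample_deformation`): Gaussian-smoothed white noise
  (smoothness in voxels) rescaled to a maximum magnitude of `amplitude`
  voxels, plus a small random affine jitter scaled with amplitude;
  rejection-and-rescale (×0.8, up to 10 times) until the minimum interior
  Jacobian determinant exceeds 0.1, guaranteeing invertibility.  Amplitude
  0 returns the exact zero field.
* **Subjects** (`synthesize_subject`): stage-dependent uptake is painted
  per ROI label (CN ≈ 1.0–1.15, MCI elevated in early Braak stages, AD
  elevated everywhere — magnitudes are schematic defaults, configurable per
  profile), multiplied by a per-label lognormal jitter (sd 0.10) for
  between-subject variability, textured, and lightly smoothed (σ 0.6).
  True SUVR is recorded from this painted map *before* warping and noise.
  The native-space volumes are produced by resampling through the numerical
  inverse of the subject's field, so warping them back through the true
  field recovers template space; a zero field with zero noise therefore
  round-trips SUVR exactly.  PET noise is absolute Gaussian (the validation
  condition is 5% of mean activity); MR noise defaults to 2% of the MR's
  RMS, reflecting the much higher SNR of structural MR.
* **Cohorts** (`make_cohort`): stage mix defaults to 59/33/8%
  CN/MCI/AD.  Cross-sectional scores follow
  `MMSE = 29 − effect·(metatemporal SUVR − 1) + N(0, noise)` (MoCA from
  28), clipped to [0, 30]; memory probabilities use a logistic link with
  the same sign convention, the nondurable-recall probability bounded by
  0.5.  Defaults `effect = 8`, `noise_sd_scores = 4` yield cross-sectional
  correlations around −0.5 at n ≈ 666-scale cohorts, the magnitude regime
  typical of tau–cognition associations.  Longitudinal visits decrement
  scores in proportion to the baseline EC/ITG SUVR excess
  (2.5 points/year/unit by default) with roughly annual scans and exam
  dates jittered ±20 days around scan dates.  A scores-only mode
  (`volumes=False`) skips image synthesis for statistics-scale cohorts.

What the phantom does **not** emulate: PET physics (PSF, scatter,
attenuation), MR tissue-contrast realism, anatomical shape realism, atrophy,
or any real parcellation geometry.  Passing tests therefore demonstrate the
pipeline's internal correctness and its behavior under controlled
deformation/noise/uptake conditions — not clinical performance on real
scans.

## Quantification

`compute_suvr` divides the ROI mean by the cerebellar-gray mean on the
template grid.  Composite ROIs pool voxels across member labels
(voxel-weighted, not a mean of sub-ROI means).  No partial-volume
correction.  Empty ROIs give NaN with a warning; a non-positive reference
mean is an error.  SUVR is exactly invariant to global intensity scaling.

## Statistics

* **ICC** (via `pingouin.intraclass_corr`): default is the single-measure
  absolute-agreement coefficient (McGraw & Wong A,1 — numerically the
  ICC(2,1) formula), which penalizes systematic offsets between pipelines;
  the consistency variant ICC(3,1) is also exposed.  95% CIs use the
  F-distribution method.  Both variants are reported because the choice is
  a genuine modeling decision: agreement answers "are the numbers
  interchangeable", consistency answers "do they rank subjects alike".
* **Correlations**: Pearson r with the t-transform p (n−2 df); one-sided
  negative tests halve the two-sided p when r < 0 (else 1 − p/2);
  Bonferroni `p_adj = min(1, m·p)` with the family size m explicit at every
  call (8 for the clinical-score family, 16 for the memory family, 6 for
  the longitudinal family).
* **Staging**: CN ⇔ CDR 0; CDR ≥ 1 ⇒ AD; CDR 0.5 is resolved by an explicit
  diagnosis column when present, else labeled `CDR0.5_unresolved` — the
  conventional CDR rule genuinely overlaps at 0.5 and the ambiguity is
  surfaced, not hidden.
* **Quintiles**: edges at the 20/40/60/80th percentiles
  (linear-interpolation definition), ties to the lower bin; a zero-spread
  score vector yields a single bin flagged `degenerate`.
* **Longitudinal analysis**: baseline = earliest scan; Pre/Post exams are
  matched to earliest/latest scans by minimum |date difference| with ties
  to the earlier exam; change ratio = `(post − pre)/(pre + 0.1)` (the 0.1
  is a zero-baseline guard, implemented verbatim); rows with any
  |ratio| > 0.5 are excluded as outliers; subjects with fewer than two
  scans or exams are dropped with a log entry.

## Numerical choices and degenerate inputs

* All resampling is trilinear with zero padding (nearest-neighbour for
  label maps); fields are in voxel units on the template grid, 0-based
  indices, pull semantics everywhere.
* NCC of a zero-variance image is undefined; the loss returns the guard
  value 1 with zero gradient.
* Field inversion (phantom synthesis) uses 20 fixed-point iterations
  `h ← −g(v + h)`; accurate for the Jacobian-positive fields the generator
  emits.
* Endpoint error is reported over a brain mask (template intensity > 5% of
  max); border voxels are excluded when no mask is given.

## Problem sizes used by the test suite and acceptance script

The validation experiment runs 40 subjects at 32³ (NCC, λ = 3, lr 3e-3;
1,200 training iterations inside the test suite, 1,500 in the standalone
acceptance script); the transfer-learning comparison runs at 24³ with a 250-
iteration pretrain and five paired 120-iteration runs; unit tests use 24³
phantoms and a 150-iteration model.  These sizes were chosen so the full
suite and the acceptance script each complete comfortably on a single CPU
while leaving the validation claims adequately powered.

## Known limitations

* Recovery of the *full* deformation field is bounded by identifiability:
  displacement components tangential to intensity isosurfaces and interior
  regions without texture are unconstrained by any similarity, so endpoint
  error cannot approach zero even at the similarity optimum.  On the
  phantom conditions used here the trained model recovers roughly a third
  of the zero-field error; SUVR quantification — means over extended ROIs —
  is far more forgiving, which is why ICC against truth exceeds 0.97 while
  voxel-level field error remains visible.
* The inverse transformation (template → native) is not provided; SUVR is
  always extracted in template space after one interpolation.
* The classic comparator approximates the conventional pipeline's *role*,
  not any specific software's numerics.
* Memory probabilities are consumed as given; the hierarchical cognitive
  model that produces them in real studies is out of scope.
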