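# Methods

This note documents the models, numerical choices, and open design decisions
behind `hippounet`. It is the companion to the README's user-level view.

## Problem setting

Lateral fluid-percussion injury in the rat produces a left-hemisphere cortical
lesion, progressive hippocampal atrophy and displacement, and ventricular
enlargement. Registration-based segmentation degrades near such pathology, so
the package implements a CNN that jointly skull-strips and segments both
hippocampi (ipsilateral = left, label 1; contralateral = right, label 2)
directly from T2*-weighted MR volumes, together with the cross-validation,
evaluation, and volumetric-statistics machinery needed to use and assess it.
Because the preclinical MRI cohorts themselves are not redistributable, a
synthetic phantom cohort generator stands in for them everywhere the pipeline
needs data.

## Network

U-Net-style encoder-decoder. Three encoder blocks (16, 32, 64 channels) are
joined by factor-2 max pooling with retained argmax indices; a 64-channel
bottleneck sits below; three decoder blocks are reached via index-based
unpooling and concatenation with the corresponding encoder output. Every
block is three iterations of *leaky ReLU (slope 0.01) → batch normalization →
same-padded convolution* in that order — the first block therefore normalizes
the raw (standardized) input before its first convolution. Kernels are 3×3×3
in the 3D variant (isotropic volumes) and 3×3 in the 2D variant, which
processes coronal slices independently; the slice axis is the
lowest-resolution axis by voxel spacing, with ties resolved to the last axis.
Two 1×1 heads decode the final 16-channel feature map: a 3-class softmax
(background / ipsilateral / contralateral hippocampus) and a single-channel
sigmoid brain-mask head.

**Decoder widths.** Index-based unpooling scatters values back to the argmax
positions recorded during encoder pooling, so the tensor being unpooled must
have exactly the channel count of the tensor that was pooled. With the
16/32/64 encoder plan this forces the decoder blocks to step down to
32/16/16 channels. The resulting trainable-parameter counts are **311,302
(2D)** and **929,062 (3D)**, counting convolution weights and biases plus the
batch-norm scale/shift pairs. Published totals for this architecture family
(428,436 / 1,125,716) are not reachable by any layer graph shared between the
2D and 3D variants: such a pair must differ by 18 weights (27−9) per
input-output channel product, and 1,125,716 − 428,436 = 697,280 ≡ 14 (mod 18).
The reconstruction here is faithful to the printed description instead; the
counts above are the package's reference values and are verified against a
closed-form count in the tests.

**Engine.** The network, backpropagation, batch normalization,
pooling/unpooling, and the RAdam optimizer are implemented in numpy (with two
numba-compiled memory kernels for the convolution column transforms). The
implementation is deterministic — identical seeds give bit-identical training
histories — and every layer's backward pass is verified against central
finite differences in float64 in the test suite.

**Batch-norm statistics at inference.** Training uses batch statistics per
update. At inference the default (`ModelConfig.eval_stats="input"`)
normalizes with the statistics of the volume being segmented rather than the
exponential running averages accumulated during training: with batch size one
(single slices), the running averages match the statistics of no actual
volume, and held-out Dice under running-average normalization oscillated
between ~0.0 and ~0.8 from epoch to epoch while input-statistics evaluation
was stable and accurate. Running-average mode remains available
(`eval_stats="running"`). Inference stays deterministic: the statistics
depend only on the input.

## Loss

`L = L_HC + L_Brain`.

The region term is the generalized Dice loss over the three classes with
size-based weights `w_l = (Σ_n y_ln)^-2` computed from the ground truth,
which raises the two small hippocampus classes against the large background.
The weight formula is also available computed from the prediction
(`weights_from="prediction"`); the ground-truth form follows the
generalized-Dice literature and is the default. Two stabilizations matter in
practice:

* ε = 1e-5 in the weight denominator guards near-empty classes, but a class
  **entirely absent** from the reference gets weight 0, not 1/ε². An absent
  class carries no overlap information; a ~1e10 weight on its denominator
  term otherwise dominates the loss on every hippocampus-free slice and
  prevents the region task from ever being learned in 2D slice-wise
  training. False positives of absent classes are still penalized through
  the softmax coupling with the present classes.
* The loss denominator is clamped below by ε only in the all-weights-zero
  corner; it is otherwise strictly positive, so perfect predictions score
  exactly 0.

The skull-stripping term is the raw Dice quotient `−Σ y p / Σ (y + p)`,
whose minimum is −0.5 at perfect overlap (no factor 2; the constant rescaling
moves no optimum). Slices with an empty brain mask (above/below the brain)
contribute nothing to this term, which is undefined there. The total loss
hence lives in [−0.5, 1].

## Training protocol

RAdam with learning rate 0.001, β₁ = 0.9, β₂ = 0.999, no weight decay;
batch size one; up to 250 epochs with early stopping when the mean validation
loss has not improved for 10 consecutive epochs; weights restored from the
best-validation epoch. For the 2D variant a "sample" is one coronal slice
(one update per slice, slices visited in random order within each volume);
the generalized-Dice class weights for a slice are those of its parent
volume, making the slice losses a stochastic approximation of the
volume-level objective — per-slice weights, recomputed on slices holding a
handful of hippocampus voxels, destabilized optimization. Validation loss is
computed volume-level in inference mode, so epoch selection optimizes exactly
the deployed behavior.

Online augmentation: with probability 0.5 per volume load, image and labels
are rescaled about the volume center by a single factor drawn uniformly from
[0.95, 1.05] (image trilinear, labels nearest-neighbour) via a center-fixed
affine map, so growth crops at the borders and shrinkage zero-pads. No
rotations. Each volume is standardized to zero mean and unit variance
after augmentation.

RAdam follows the published rectification: while the variance estimate is
intractable (ρ_t ≤ 4, the first four steps at β₂ = 0.999) the update is plain
bias-corrected momentum; afterwards the variance-rectified adaptive step. The
tests pin the full 25-step trajectory on a quadratic bowl against a scalar
reference recurrence.

## Cross-validation and ensembling

Folds are formed at the animal level so no animal contributes scans to more
than one fold. The outer split holds out test animals; the remaining pool is
randomly re-partitioned into six nested folds (as even as possible when the
pool is not divisible by six), and one network is trained per nested fold,
validating on it. The six members' hard labels are fused per voxel by
majority vote; exact ties break by the higher mean class probability when
probability maps are available, else by the lowest class index (six voters
admit 3–3 ties). The fused brain mask takes a voxel when at least half the
members vote for it.

The registration planner reproduces the bookkeeping of registration-based
baselines: within each timepoint, every annotated available target is paired
with every annotated available atlas outside the target's entire fold —
the reading under which a 12-animal, 6×2-fold, 4-timepoint design with one
animal unannotated at two timepoints yields 440 pairs, and a 6-animal,
6×1-fold, 3-timepoint design yields 90.

## Post-processing

Per region (brain mask, each hippocampus class independently): keep the
largest 26-connected component, fill its interior holes. Equal-size component
ties keep the component containing the smallest flat-index voxel. Overlaps
created by hole filling resolve in favour of the smaller region. Sparse
brain-mask completion (annotation on every second sagittal slice) uses binary
closing with a kernel spanning three voxels along the sparse axis — a 3-voxel
line dilated by a 3×3×3 cube — followed by volumetric hole filling; the exact
hand-crafted kernel of the original workflow is not published, so this
default is validated by the round-trip property (Dice > 0.98 against the
dense mask).

## Evaluation metrics

Dice, HD95, volume similarity, compactness score, precision, recall, per ROI,
with volumes in mm³. HD95 extracts surface voxels by XOR with a
connectivity-1 erosion and pools both directed surface-distance arrays before
taking the 95th percentile — the convention of the MedPy library, which the
original evaluation used (an alternative convention takes the max of the two
directed percentiles; the pooled form is implemented because it is what the
cited tool computes). Distances are voxel-center distances in mm with
anisotropy respected. Surface area for compactness is exposed-face counting
with per-face mm² areas — deterministic and exact on voxel sets — and
CS = 1 − 2|C − C_GT|/(C + C_GT), which is 1 iff the compactness values agree
(the absolute value makes the score symmetric, as its stated "identical
compactness" property requires). Every metric is checked against an
independent brute-force implementation on hundreds of random small mask
pairs.

## Volume statistics

Method comparisons use a two-sided paired permutation test on the mean of
paired differences (random sign flips; full enumeration when 2ⁿ does not
exceed the iteration budget, else 10,000 Monte-Carlo draws with an add-one
estimator), with Bonferroni correction. Inter-hemispheric contrasts report
mean (ipsi − contra) per metric with percentile-bootstrap 95% CIs (≥ 2000
resamples, seeded).

The hippocampal volume model is
`V = α + β_t t + β_R R + β_B B + β_tR tR + β_tB tB + β_RB RB + E` with t in
days (continuous), R = 1 for the ipsilateral hippocampus, B = 1 for TBI, and
a diagonal error covariance whose variance is indexed by timepoint. With only
fixed effects this model class is exactly heteroscedastic feasible
generalized least squares: iterated WLS with per-timepoint variances
estimated from residuals, iterated to coefficient convergence (tolerance
1e-8, ≤ 50 iterations), Wald tests per coefficient. When the estimated
per-timepoint variances are equal the fit coincides with OLS. Parameter
recovery (every coefficient within 3 estimated SEs in ≥ 95% of 200
simulated replications) and null p-value calibration are part of the test
suite.

## Phantom generator

Each phantom is a pure function of its spec and seed. Geometry, in mm
coordinates about the volume center: an ellipsoidal brain (semi-axes ~0.38 /
0.44 / 0.34 of the field of view, scaled by a per-animal size factor); two
mirrored hippocampi shaped as sectors of an elliptic-tube torus bent in the
axial plane (elongated rostro-caudally), sized to sit fully inside the brain
so that linear scaling translates exactly into volume scaling; two
midline-adjacent ventricles; for TBI animals a dorso-lateral left cortical
cavity whose size grows with lesion severity and which never overlaps the
hippocampi. Atrophy shrinks the left hippocampus linearly by
(1 − atrophy_fraction)^{1/3} about its center (volume ratio ≈
1 − atrophy_fraction, verified to ±0.05 at desk scale) and displaces it
toward the cavity; ventricles dilate with the enlargement parameter.

Intensities are stylized T2*-like tissue classes (CSF bright, parenchyma
mid, cortex rim slightly darker, extracranial near zero), modulated by a
smooth random bilinear bias field (amplitude 0.1 by default) and additive
Gaussian noise (σ = 0.05 against parenchyma 1.0, i.e. SNR ≈ 20, reflecting
high-SNR summed-echo magnitude data where a Gaussian approximation to Rician
noise is appropriate). Two dialects mirror the target cohorts: isotropic
0.16 mm voxels (desk grid 64×64×48) and anisotropic 0.15×0.15×0.5 mm
(desk grid 64×64×24).

Cohorts draw per-animal random effects once (size factor; for TBI: lesion
severity ~ U(0.4, 0.9), maximum atrophy ~ U(0.15, 0.35), maximum ventricle
enlargement ~ U(0.2, 0.6)) and hold them constant across timepoints; atrophy
and enlargement follow the saturating curve t/(t + 21 days), making the
ipsilateral volume non-increasing in time.

What the phantoms do **not** emulate: real rat neuroanatomy (no atlas
geometry), skull/scalp and extracranial tissue structure, multi-echo signal
formation, partial-volume gradients at tissue boundaries, motion or ghosting
artifacts, and inter-site contrast differences. Passing the end-to-end
pipeline on phantoms therefore demonstrates that the machinery (loss,
optimization, ensembling, fusion, post-processing, metrics) is correct and
learns geometry-defined structures at realistic contrast and noise — not
that the network reaches any particular accuracy on real MRI.

## Desk-scale end-to-end run

The self-contained pipeline check trains the full six-member ensemble on a
ten-animal isotropic phantom cohort (6 TBI / 4 sham, one timepoint at day
30, 64×64×48 grid) with two held-out animals, using the 2D variant and 8
epochs per member — sizes chosen so the whole run fits comfortably on one
CPU core while leaving the protocol (optimizer, loss, augmentation,
ensembling, post-processing) exactly as above. With the pinned seed the
held-out fused-ensemble Dice after post-processing is ~0.87–0.93
(ipsilateral) and ~0.98 (contralateral); the acceptance threshold is 0.85
for both hippocampi.

## Known limitations

* The 3D variant trains with one whole volume per update; at desk scale this
  is slower per unit of learning than the slice-wise 2D variant, and the
  end-to-end check exercises the 2D path.
* The printed-parameter-total discrepancy above means architecture-size
  comparisons against the published totals fail by construction; the
  closed-form count in the tests pins this package's own architecture
  instead.
* FGLS standard errors are conditional on the estimated variance structure
  (no small-sample correction), matching common mixed-model software
  behaviour but slightly optimistic for very small cohorts.
* The permutation test assumes exchangeability of paired differences under
  the null; scans are treated as independent pairs even when the same animal
  contributes several timepoints.
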