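# Methods

`fdgpet` implements a four-class differential-diagnosis pipeline for
dementia subtypes — Alzheimer's disease (AD), dementia with Lewy bodies
(DLB), mixed AD/DLB pathology (Mixed), and healthy controls (HC) — from
FDG-PET volumes on a common registered grid. This note records the model,
the choices made where the design was open, and what the synthetic
phantoms do and do not establish.

## Preprocessing

**SUVR.** Each PET volume is divided by its mean intensity over the
cerebellar gray-matter reference region and zeroed outside the subject's
brain mask. No smoothing is applied anywhere. SUVR is invariant to
per-subject global intensity scale by construction; the reference-region
mean of every SUVR volume is 1.

**Study-specific GM mask.** Per training subject, the GM probability map
is merged with a striatal indicator (putamen + caudate) by voxelwise
maximum; the merged maps are averaged across training subjects and voxels
below 30% of the averaged map's maximum are excluded
(`threshold_frac = 0.30`, configurable in (0, 1)).

**SRP (subject residual profile).** Log-SUVR is doubly centered:
subtract each subject's mean of log-SUVR over the brain mask (row
centering), then subtract the per-voxel mean of those subject-centered
fields over the *training* cohort, restricted to the GM mask (column
centering). Centering on the log scale follows the scaled-subprofile-model
convention; a `center_scale: linear` mode exists for comparison but
log/log is the canonical, tested path. Nonpositive SUVR values inside the
mask (possible after brain-masking) are floored at 1e-6 before the log,
with a counted warning.

Out-of-sample subjects are centered with the persisted training-set
voxel-mean profile. Centering test data with training statistics is an
acknowledged approximation — the class-conditional voxel means are
unavailable at test time — and is inherited as such, not corrected.
Both the GM mask and the profile are fit on training subjects only, so no
validation/test statistics leak into preprocessing.

## Networks

All models are small 3D CNNs implemented on a NumPy neural-network core
written for this package (strided/dilated 3D convolution via gathered
views and matrix products, instance normalization, explicit backward
passes, Adam, softmax cross-entropy). Every layer's backward pass is
finite-difference checked in the unit suite.

**Backbone (binary classifier).** Five sequential 3×3×3 convolution
stages with stride schedule (2, 2, 2, 2, 1), each followed by instance
normalization and ReLU; channel widths (16, 32, 64, 128, 128) ending at
128 (widths are configurable; the final 128 is the tested contract).
A context module follows: three parallel dilated 3×3×3 branches
(dilations 1, 2, 4, each to 64 channels, instance norm + ReLU) merged by
a 1×1×1 convolution back to 128 channels, preserving spatial shape. Then
global average pooling and a 128 → 2 linear layer. On the canonical
96×112×96 grid (2 mm, MNI-like) the pre-pooling feature map is
128×(6, 7, 6); on any grid divisible by 16 it is 128×(grid/16).
Instance normalization was chosen because it is batch-size independent —
inference at batch 1 matches training exactly. Initialization is He
throughout; a previously trained bundle can stand in for all layers
except the final linear, which is always He-initialized fresh.

**Feature extractor.** A trained backbone truncated after the context
module plus one fresh 3×3×3 stride-2 convolution to 128 channels and a
ReLU. Per-axis padding is 1 on even-sized axes and 0 on odd, giving
output ⌊n/2⌋ per axis — (1, 0, 1) and 6×7×6 → 3×3×3 on the canonical
grid, matching the printed 128×3×3×3 feature.

**Multiclass model.** Six extractors in fixed order (AD-HC, DLB-HC,
Mixed-HC on SUVR; the same three on SRP) produce a 768×3×3×3
concatenation, pooled to a 768-vector, then linear layers
768 → 384 → 50 → 3 with ReLU and dropout (rate 0.5 — unspecified
upstream, a conventional default) after the 384 and 50 layers. The three
logits are AD, DLB, Mixed. By default the extractor trunks are frozen
during multiclass training and only the added convolutions and the head
train (`freeze_extractors`, configurable); sequential pretraining of the
binary models before the multiclass head is the implemented order.

## Training

All models train independently with softmax cross-entropy under Adam.
Defaults: learning rate 1e-4, batch 8, up to 60 epochs, early stopping
with patience 10 on validation loss, checkpoint selection by best
validation loss. Each binary model sees only the two classes of its task
in every split. Augmentation applies to training samples only, each
technique independently with 10% probability per sample per epoch, in
the fixed order mix-up → flip → rotation: mix-up blends two same-class
images with a uniform weight (labels stay hard; the partner is drawn
uniformly from the same-class training pool, and for the multiclass
model the same partner/weight/flip/angle apply jointly to the SUVR and
SRP channels so they stay aligned); the flip mirrors the declared
left-right axis (voxel axis 0); rotations are uniform within ±10° about
a uniformly chosen grid axis with trilinear interpolation and zero fill.

Splits are 70/10/20 train/val/test per class with largest-remainder
rounding, deterministic under a seed. Manifest rows flagged `train_only`
(for appended external cohorts) are forced into training and never reach
validation or test. 5-fold cross-validation stratifies the non-test pool
by class, rotates validation folds, retrains the full ensemble per fold
(re-fitting preprocessing statistics on each fold's training portion when
asked), and evaluates every fold on the one fixed test set; across-fold
summaries are mean ± 1.96·sd/√5 (a normal-approximation 95% CI, chosen
in the absence of a specified interval method).

## Ensemble inference

Per subject: (1) the SUVR image goes to the AD-HC and Mixed-HC SUVR
models and the SRP image to the DLB-HC SRP model — a unanimous HC vote
ends inference at HC; (2) otherwise the multiclass model runs, and a DLB
argmax ends inference at DLB; (3) otherwise the dedicated AD-Mixed SUVR
model decides, regardless of the multiclass AD/Mixed preference. Binary
votes are softmax argmaxes (0.5 threshold, configurable). The three
binary models not used at inference (AD-HC SRP, DLB-HC SUVR, Mixed-HC
SRP) serve only as feature extractors.

The hard-gated rule defines no continuous score, so ROC analysis uses a
composed chain product constructed by this package and isolated in one
function (`class_scores`): HC = product of the three step-1 HC
probabilities; DLB = (1−HC)·P_mc(DLB); AD and Mixed =
(1−HC)·(1−P_mc(DLB))·P_am(·). Scores sum to 1 when each model's
probabilities do. One caveat is documented deliberately: the composed
score's argmax provably matches the hard decision when every model is
confident (max probability ≥ 0.8), but can disagree at low confidence —
e.g. step-1 HC probabilities (0.9, 0.9, 0.4) give an HC score of 0.324
that exceeds every dementia score although the hard gate routes the
subject past step 1. The property test asserts agreement only in the
confident regime.

Per-class metrics are one-vs-rest sensitivity/specificity/PPV/NPV from
final labels and AUROC from the composed scores; a class absent from the
test set yields NaN, never 0.

## Saliency

Grad-CAM on the binary models targets the last convolutional feature map
before pooling (the context-module output): channel weights are the
spatially averaged gradients of the target-class logit; the map is the
rectified weighted sum, trilinearly upsampled to the input grid and
zeroed outside the brain mask. Subject-level maps of correctly
classified test subjects are averaged per class, then min-max normalized
(a constant map normalizes to zero with a warning). Class-level maps are
normalized after averaging so that a single threshold applies to each
model/class map. Regions with any voxel above the threshold (default
0.7) are reported, sorted by peak, with laterality from the left-right
axis midline ("bilateral" when both sides exceed the threshold; the
voxel fraction is computed over the qualifying side(s)). The multiclass
model is excluded from saliency reporting — its concatenated
multi-extractor features make channel-weighted maps hard to attribute.
A model-level map (class-mean maps averaged with weights proportional to
correctly classified subjects) summarizes where a model attends
irrespective of class.

## Synthetic phantoms

Clinical FDG-PET cohorts for these four groups are not distributable, so
the package ships a generator whose defaults are the study conditions
used throughout the tests: a 32³ grid (2 mm spacing tag), per-subject
global scale uniform on [0.8, 1.2], additive Gaussian voxel noise with
sd 5 intensity units (5% of the gray-matter baseline of 100; white
matter 60, background 0), effect strength 0.7, and cohorts of 40/40/40/20
(AD/DLB/Mixed/HC) split 70/10/20.

The atlas places lobe-scale cortical regions as sectors of the shell
between the brain ellipsoid and an inner white-matter core, split at the
midline into left/right instances, plus mirrored subcortical spheres
(hippocampus, amygdala, putamen, pallidum, caudate), a posterior-inferior
cerebellar reference, and a background-GM fill. Lobar extents matter:
the class signal acts multiplicatively on whole regions, as lobar
hypometabolism does, and regions much smaller than the network's pooled
receptive fields would be undetectable in principle.

Class signatures are multiplicative regional factors (HC ≡ 1). At full
effect: all three dementia classes share motor cortex 1.15, pallidum
1.15, cerebellum 1.10, parietal 0.80, lateral temporal 0.82; AD and Mixed
add hippocampus 0.80; DLB adds occipital 0.78. Mixed composes the full
AD-specific deviation with a half-attenuated occipital deviation (0.89 at
full effect): coexisting pathologies interact and the DLB-typical pattern
is partially masked, which is what makes Mixed mimic AD and remain the
hardest class to call. Every Mixed factor therefore lies between (or
equals) the AD and DLB extremes. Deviations scale linearly with the
effect parameter. Because SUVR divides by the cerebellar mean, the
cerebellar factor itself expresses as a global rescaling of every other
region rather than a local signal — `suvr_signal_regions` accordingly
excludes the reference when listing informative regions.

What the phantoms do *not* emulate: anatomy beyond ellipsoids and
sectors, partial-volume effects, scanner point-spread functions,
registration error, spatially correlated noise, and site/cohort
heterogeneity. Passing recovery tests therefore show that the pipeline's
machinery — preprocessing identities, training, gating, scoring,
saliency — behaves correctly on data with known structure; they do not
certify clinical performance.

## Problem sizes and numerical choices

Recovery runs use the 32³ study cohort with learning rate 1e-3 and up to
60 epochs (patience 20); the saliency study uses 16 AD/12 HC phantoms at
effect 1.0 with the config-exposed stride schedule (2, 2, 2, 1, 1), whose
8³ CAM cells can resolve lobar structures (the default schedule's 16³
cells cannot at this grid). Cross-validation smoke runs use reduced
channel widths. Exact-arithmetic checks (SRP double-centering, the
decision table, tensor shapes) run at tolerance 1e-10 or exactly.
Determinism: every stochastic component (atlas jitter, subjects, splits,
initialization, augmentation, dropout) derives from explicit seeds;
volumes are written as 32-bit float NIfTI with deterministic gzip, so
re-running preprocessing reproduces artifacts byte-identically.

## Known limitations

- The composed ROC score is a construction of this package; the gated
  ensemble itself defines no continuous score (see the coherence caveat
  above).
- The context module's internal structure follows only the normative
  contract (128 channels in/out, shape preserved, multiple merged
  receptive-field branches); the specific dilations are this package's
  choice.
- Per-stage channel widths before the final 128 are unspecified upstream
  and config-exposed here.
- The pretrained-bundle initialization path loads weights from a
  previously trained bundle of this package; no external pretrained
  weights are shipped.
- Whether extractor trunks should stay frozen during multiclass training
  is genuinely open; frozen is the default and the alternative is one
  flag away.
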