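# Methods

`lobescore` implements automated lobe-level severity scoring of two cystic
fibrosis lung pathologies — bronchiectasis/wall thickening and mucus
plugging — on paired coronal/axial T2-weighted chest MRI, together with a
synthetic phantom framework that makes every stage testable without
clinical data. This note records the models, the parameters that matter,
and the design choices made where the design was genuinely open.

## Scoring model

Each of six lobar regions (left upper, lingula, left lower, right upper,
right middle, right lower) receives an ordinal severity score per
pathology: 0 = absent, 1 = under half the lobe affected, 2 = at least half
affected. The per-examination overall score is the sum over the six
regions, range 0–12. "Affected" is operationalised in the phantom as the
voxel coverage fraction f of the lobe: score = 0 iff f = 0, 1 iff
0 < f < 0.5, 2 iff f ≥ 0.5. A human reader's notion of "affected" is a
judgement, not a voxel count; the voxel fraction is the package's proxy,
chosen because it is exactly computable on synthetic ground truth.

## Classifier

The classifier is a dual-view multiple-instance model:

1. every 2D slice of a lobe's crop (repeated to 3 channels) passes through
   a 2D convolutional backbone, giving a C-channel feature map per slice;
2. adaptive average pooling reduces each map to a C-vector (one descriptor
   per slice);
3. max pooling over the slice dimension collapses the stack to a single
   C-vector per view — only the strongest slice evidence survives, which is
   what lets a lobe-level label supervise slice-level features without any
   slice annotations;
4. the coronal and axial descriptors are concatenated (late fusion) and a
   linear head produces three class logits; softmax gives probabilities and
   the predicted score is the argmax (ties broken toward the lower class).

Slice order is irrelevant by construction (the pooled descriptor is
permutation invariant), and appending a slice whose descriptor is
elementwise dominated by the current maxima cannot change the prediction.

The backbone is a contract — any callable mapping an (S, 3, H, W) slice
batch to (S, C, h, w) feature maps with a matching backward pass. The
shipped `TinyBackbone` is a three-block CNN (3×3 conv → ReLU → 2×2 max
pool, twice, then conv → ReLU) written in NumPy with explicit gradients;
it trains on one CPU at 32×32 slice resolution. Large ImageNet-pretrained
backbones operating at 256×256 fit the same contract but no weights are
shipped. Because published channel counts for such
networks differ from the 256-channel descriptor sometimes quoted for this
architecture family, the descriptor length is simply configurable
(`backbone_channels`, last entry = C).

Training is stochastic gradient descent with classical momentum 0.9, one
lobe sample per step, class-weighted cross-entropy, an initial learning
rate of 1e-5 decayed by γ = 0.4 every 15 epochs, at most 125 epochs, and
early stopping after 25 epochs without validation-loss improvement; the
best-validation state is restored. These defaults mirror the full-scale
protocol; the scaled-down phantom experiments (below) override them.

Class weights default to inverse class frequency normalised to mean 1
(rare classes weighted up) — the standard treatment of class imbalance. A
`proportional` mode implements the opposite direction (majority classes
penalised more) for comparison experiments, since descriptions of weighted
losses in the field are occasionally ambiguous on this point.

Online augmentation draws, per view and per epoch, a uniform rotation in
(−180°, 180°) applied to all slices of that view consistently, plus
horizontal/vertical flips with probability 0.5 each. Augmented stacks are
never stored.

## Preprocessing

Pipeline order is fixed: bias correction → z-score normalisation →
(coronal→axial mask resampling, morphological closing) → per-lobe crop →
rescale to [0, 1].

* **Bias correction.** The default corrector is homomorphic: the
  log-intensity is smoothed with a large Gaussian kernel (σ = 1/4 of the
  mask extent per axis, normalised convolution so the estimate extrapolates
  outside the mask), exponentiated, and divided out; the mask-mean
  intensity is preserved. Any external N4-style implementation can be
  plugged in behind the same `(volume, mask) -> volume` signature.
* **Cross-view transfer.** The coronal lung/lobe masks are carried into
  the axial grid by nearest-neighbour resampling through physical (mm)
  space using the acquisition geometry of both views — the two views of
  one examination are inherently co-registered, so no image registration
  is needed.
* **Closing** uses a ball structuring element, radius 1 voxel by default
  (no published value exists), applied per label; voxels are only added.
* **Cropping.** Per lobe, only slices intersecting the lobe are kept; the
  in-plane tight bounding box plus a 2-voxel margin is letterbox-padded to
  a square (aspect preserved; tubular structures must not be stretched)
  and resized to `out_side` (256 default, 32 in desk-scale experiments).
  By default the crop is **masked to the lobe**: voxels outside the lobe
  are set to the volume minimum. Without masking, a bounding-box crop of
  one lobe contains measurable pathology from neighbouring lobes (about 3%
  of crop voxels even for score-0 lobes on 32³ phantoms), which decouples
  the label from the crop content; masking makes the sample show exactly
  the region the label describes. A flag restores unmasked crops.
* **Rescaling** maps each stack affinely to [0, 1]; a constant stack maps
  to 0.5 with a logged warning.

## Lobe approximation

The six lobar regions are estimated on a patient's lung-half mask by
registering a labelled atlas lung per half (left and right independently)
and transferring the atlas lobe labels:

* **Rigid stage**: moments initialisation (centroid alignment), refined by
  gradient descent on the mean-squared difference of signed distance maps
  of the two binary masks — a smooth overlap surrogate. If refinement
  worsens mask Dice, the initialisation is returned (the stage can only
  help).
* **Elastic stage**: diffeomorphic demons on Gaussian-smoothed mask
  images, displacement field regularised with σ = 2 voxels, run in bursts
  of 5 iterations with mask Dice tracked after each burst; the best field
  is kept and the loop stops after 10 iterations without improvement.
* **Label transfer**: nearest-neighbour warping of the atlas labels
  through the chain, restricted per half (labels 1–3 left, 4–6 right).
* **Post-processing**: per-lobe hole filling, then every remaining
  unlabelled lung voxel takes the label of its nearest labelled voxel in
  the same half, so the output partitions the lung exactly.

The registration objective is mask overlap, not intensity similarity,
because the inputs are binary masks. The packaged default atlas is the
phantom anatomy at canonical pose — self-contained and synthetic by
construction; a real atlas can be supplied through the same two-NIfTI +
JSON file interface.

## Patient-level splitting

All examinations of a patient stay in one set. The 60/20/20
train/validation/test split is found by iterative random search (default
10,000 iterations): shuffle the patient list, assign contiguous blocks at
the target patient proportions (largest-remainder rounding), and score the
assignment by the sum over sets, pathologies and score classes of
|observed lobe-score count − set ratio × total count|. The minimum-cost
assignment wins; ties resolve to the first minimum under the seeded
stream, so results are reproducible. Both pathologies are pooled in the
cost by default (per-pathology tables can be passed instead). Grouped
k-fold construction shuffles patients and deals them round-robin, giving
patient-count-balanced, seed-deterministic folds.

## Grad-CAM

Relevance is computed from the last convolutional layer of each view
stream. For the chosen class logit, the channel weight of a slice's
feature map is the spatial mean of the logit's gradient with respect to
that map; with average pooling followed by slice max pooling this gradient
is constant over space and nonzero only for the slices that carry a
channel's maximum — precisely the slices the prediction relied on. The
relevance map is the rectified weighted channel sum, normalised to [0, 1]
jointly over all slices of the sample, and upsampled to slice resolution.
When the predicted and reference class differ, the predicted class's logit
is used for overlays (the map should explain the call actually made); the
localisation experiments instead probe the severe-class logit, because the
question there is where the model sees severity evidence, which is well
defined even when its final call underestimates the lobe. Maps can be reassembled into the source volume grid by inverting
the crop (using its recorded provenance) and thresholded (default 0.5) for
overlay export; per-view volumes are emitted separately rather than fused.

## Evaluation battery

Lobe-level (ordinal 0/1/2): one-vs-rest sensitivity, specificity and
accuracy; one-vs-rest AUROC (rank-based with midrank tie handling) and its
unweighted macro mean over defined classes; class-wise calibration error
(CWCE) — the one-vs-rest expected calibration error with 10 equal-width
bins, macro-averaged; quadratic weighted Cohen's κ (disagreement weights
(i−j)²/(K−1)²); and Gwet's AC2 with quadratic ordinal agreement weights,
chance agreement p_e = T_w/(K(K−1)) · Σ_k π_k(1−π_k) with π_k the mean
category prevalence. Exam-level (0–12): ICC(2,1) from the two-way ANOVA
decomposition (two-way random effects, absolute agreement, single rater),
Pearson's r with a Fisher-z interval, and Bland–Altman mean difference
with 95% limits of agreement (mean ± 1.96 sample SD of the differences).

Undefined quantities (a class absent from the reference, zero variance)
are reported as NaN and flagged, never silently zeroed. Degenerate perfect
agreement (both raters constant and identical) is defined as agreement 1
with a warning. Confidence intervals use a nonparametric percentile
bootstrap that resamples whole examinations, because the six lobes of one
exam are statistically dependent.

## Phantom generator

The phantom emulates what the pipeline consumes, not what a lung looks
like. One patient is two ellipsoid lung halves in millimetre space (sizes
and positions jittered per patient), each split into three lobar regions
by two oblique planes. Per examination the anatomy is shifted slightly
(repositioning between visits), per-lobe scores are sampled from
configurable marginals, and pathologies are planted to match: mucus
plugging as filled bright blobs (nearest-to-seed voxel growth, exact
target count), bronchiectasis/wall thickening as branching tubes with
bright wall rings (accumulated in addition order and cut at the exact
count). Severity bands are well separated by construction — moderate
lobes cover 15–40% of the lobe, severe lobes 55–75% — because fractions
abutting the 0 and 0.5 decision boundaries would make the ordinal classes
ambiguous by construction rather than by reader judgement.

The rendered T2-like contrast is: soft tissue 0.35, lung parenchyma 0.08,
vessels 0.45, bright wall rings 0.85, mucus 1.0 (arbitrary units). A thin
vascular tree (3–6% of lung volume) is planted in every lung half because
real T2 lungs always contain bright vasculature; without it a healthy lobe
is featureless, and the per-stack [0, 1] rescale then stretches pure noise
to full range, destroying the absence class in a way no real image
exhibits.

The coronal grid is the reference rendering; the axial volume is a genuine
geometric resampling of it at different spacing and orientation (each view
fine in-plane, coarse through-plane, in opposite directions), so the
cross-view mask transfer is exercised for real. Each view is then degraded
independently by a multiplicative exponentiated smooth Gaussian random
field (amplitude 0.3 by default — what an N4-style correction removes) and
Rician noise (σ = 0.05), the magnitude-MRI noise model.

Default score marginals per lobe are the reference cohort's observed
score distribution over 627 examinations (bronchiectasis/wall thickening
totals 563/2825/374 for scores 0/1/2; mucus 2251/1338/173), so synthetic
cohorts reproduce the real class imbalance. Patients contribute 1–4
repeated examinations by default. Randomness fans out from one master
seed through per-patient and per-exam substreams; identical configuration
gives byte-identical outputs.

What the phantom does **not** model: airway trees and fissure geometry,
k-space/acquisition physics, perfusion, and the remaining score items
(consolidation, sacculation/abscess, pleural lesions). Passing tests on
phantoms therefore demonstrate that the pipeline recovers planted,
well-separated severity signal under bias, noise, anisotropy and
cross-view geometry — not that clinical performance would match.

## Scaled-down experiment sizes

Desk-scale experiments (test suite and the acceptance script) use 32³
voxel grids, 32×32 crop resolution, the tiny backbone with channels
(12, 24, 48), 48 patients with 1–4 exams each, learning rate 7e-3 with
momentum 0.9 and no within-run LR decay, inverse-square-root class
weights (the tempered variant; plain inverse-frequency weights over-call
the rare severe class at this cohort size), no online augmentation, and
at most 20 epochs; the balanced split search uses 500 iterations. These sizes keep a full run on one CPU in minutes while
leaving the method itself unchanged. Full-protocol defaults (256×256
crops, LR 1e-5, 125 epochs, augmentation on) remain the package defaults.

## Known limitations

* The tiny backbone underfits subtle texture; at phantom scale the
  held-out quadratic-weighted κ is in the 0.55–0.7 range depending on the
  seed, with macro AUROC ≥ 0.8 — a stand-in for, not a reproduction of,
  clinical performance.
* The demons elastic stage is mask-driven; it cannot recover deformations
  invisible to the mask (internal fissure shifts).
* The homomorphic bias corrector assumes the bias field is smoother than
  the anatomy; fields with anatomy-scale structure are only partially
  removed.
* Lobe-expert training on small phantom cohorts is data-starved (a sixth
  of the samples per model) and correspondingly unstable, mirroring the
  instability reported for per-lobe experts at full scale.
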