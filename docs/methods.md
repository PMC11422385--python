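# Methods

This note records the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Bit-packed mask storage

Lesion annotation for one image is a stack of 32 aligned binary planes
(20 named anatomy/lesion classes, indices 20–31 reserved). Plane *i*
is stored in bit *(i mod 8)* — least-significant bit first — of 8-bit
channel ⌊i/8⌋, with channels ordered R, G, B, A, and the packed image
written as a standard non-interlaced 8-bit RGBA PNG at the default zlib
level. The alpha channel is data and is never premultiplied. Absent
classes are encoded as all-zero planes rather than omitted, keeping the
format fixed-width; reserved indices always decode to empty planes.
Bit order is normative here and is locked in by the round-trip property
test (decode∘encode = id on random stacks). PNG compression makes the
format's size proportional to mask entropy: an empty 512×512×32 stack
compresses to ~1.1 KB versus 32 MiB as raw float32.

The canonical channel registry fixes the class order (optic cup = 0 …
retinal detachment = 19). Clinical synonyms are accepted through an
alias table (e.g. *leopard fundus* → tessellated fundus, *macular
atrophy* → macular degeneration, *atrophic crescent* → atrophic arc).
*Preretinal fibrosis* has no channel of its own and is aliased to
retinal neovascularization, mirroring clinical staging, which groups
fibrovascular proliferation with new vessels.

## Lesion-focused compositing

The attention input is built from the original RGB image and a selected
subset of mask channels (default: 12 classes — cup, disc, macula,
hemorrhage, cotton wool spots, preretinal fibrosis, atrophic arc,
choroidal atrophy, choroidal neovascularization, exudation, macular
atrophy, leopard fundus). Selected planes are OR-combined (equivalent
to a fixed-weight 1×1 convolution with zero red/green kernels followed
by a threshold), gated by the field-of-view mask (any RGB channel
> `fov_threshold`, default 10 on the 8-bit scale, separating retina
from the black camera background), and composited into the blue plane
as B ← (B ∧ ¬L) ∨ L — i.e. blue saturates to 255 at lesion pixels and
is untouched elsewhere; red and green always pass through. Saturation
(rather than zeroing) was chosen so the attention signal is invariant
to the underlying blue value. The operation is idempotent and monotone
in the channel set, and with an empty mask stack it is the identity.

Composited outputs are memoised by a content-addressed cache keyed on
(image id, registry version, channel set, threshold): an in-memory LRU
front with an optional PNG-file backing directory; corrupted cache
entries are recomputed and overwritten with a logged warning.

## Segmentation (Retina-Unet)

One *binary* network per class — small lesions and large anatomy get
separate models rather than competing in one softmax head. The encoder
is a residual 18-layer design: 7×7 stride-2 stem (→128×128×64 at the
256-px reference resolution), 2×2 max-pool (→64×64×64), then four
two-block residual stages ending at 8×8×512. Five decoder stages
upsample (nearest-neighbour ×2), concatenate the matching encoder map,
and apply a 3×3 conv + batch-norm + ReLU, running 16×16×256 down to
256×256×16, followed by a 1×1 sigmoid head. A width multiplier
m ∈ (0, 1] scales every channel count (⌈c·m⌉) without touching spatial
sizes, and the input resolution is configurable in multiples of 32;
the printed shape contract refers to m = 1 at 256 px and is asserted by
a forward pass in the acceptance suite.

Inputs are normalized by dataset statistics: per-channel mean over all
pixels of all images, and spread = root mean square of mean-subtracted
values (the population standard deviation; dividing by the *variance*
would change units), held in float64 so ≥8 decimals are meaningful.
Constant datasets (zero spread) are rejected. Images resize bilinearly,
masks nearest-neighbour (label preservation). Predictions binarize at
0.5.

Training: pixel-wise binary cross-entropy plus a soft-Dice term with
equal weights (the standard pairing for class-imbalanced binary
segmentation), Adam at lr 1e-2 (batch 8), a patient-disjoint 4:1
train/validation split, early stopping on validation loss, and
restoration of the best-validation weights. A class with no positive
sample refuses to train. Runs are bit-reproducible per seed.

The report score for a class is 0.4·IoU_train + 0.6·IoU_val rounded to
six decimals — the validation-heavy convex combination used by the
reference report (the weights reproduce its printed score column).
IoU is |A∩B|/|A∪B|, defined as 1 when both masks are empty.

## Classification

The diagnosis network follows the nine-stage mobile-inverted-bottleneck
table: stride-2 3×3 stem (32ch); seven MBConv stages with expansion
factor 1 or 6, depthwise kernels 3×3 or 5×5, repeats (1,2,2,3,3,4,1)
and output channels (16,24,40,80,112,192,320); then a 1×1 conv to
1280ch, global average pooling and a softmax head. Batch normalization
and swish throughout; residual connections whenever stride 1 and equal
channel counts. Squeeze-excitation blocks are omitted — the stage
table specifies operator, kernel, expansion, repeats and width, and the
desk-scale experiments do not need them. A width multiplier and
configurable input resolution allow CPU-scale training of the same
topology. Pretrained initialization is supported in principle but
never required; all experiments here start from seeded random weights.

Training uses softmax cross-entropy, Adam (default lr 1e-3, patience 3;
the desk-scale experiments use lr 3e-3, batch 8, ≤16 epochs at width
0.25 and 64 px), a patient-disjoint 7:1:2 train/validation/test split
(overlapping patient IDs are a hard error), early stopping, and
best-weight restoration. Grading models replace the head with a 2-way
early/late softmax and inherit every feature weight from the trained
diagnosis model.

## Evaluation statistics

* ROC over all distinct-score operating points; trapezoidal AUC equals
  the Mann–Whitney concordance (ties ½), which the tests verify against
  exhaustive pair counting.
* Operating threshold maximizes Youden's J; ties break toward the
  higher-specificity point (hospital preference: fewer false
  positives). A "screening" policy shifts the threshold down, a
  "hospital" policy up. Degenerate score sets return the trivial
  threshold with a warning.
* Micro AUROC flattens all (class, image) one-vs-rest pairs; macro is
  the unweighted per-class mean, dropping classes absent from the
  labels with a warning.
* Risk stratification splits at the median score (ties to high risk)
  and reports, per group: n, positive events, within-group positive
  rate with a percentile bootstrap CI (1,000 resamples by default,
  seeded), the share of all positives captured by the group (both
  readings of "positive rate" are reported), and a Byar-approximation
  Poisson CI on the event count. The high-vs-low odds ratio uses the
  Woolf log-interval with the Haldane 0.5 correction iff any cell is
  zero, and the group×outcome table gets a Pearson χ² (no continuity
  correction, 1 df).
* Byar's interval: lower = x(1 − 1/9x − z/3√x)³,
  upper = (x+1)(1 − 1/9(x+1) + z/3√(x+1))³, z = 1.959964, lower 0 at
  x = 0. Its exact coverage at rate 20 is 95.7%; because a 10,000-draw
  Monte-Carlo estimate of that coverage carries a ±0.2% standard error,
  the coverage test asserts the exact pmf-weighted value against the
  94–96% band and requires the simulation to agree with it within
  3 standard errors.
* A reported calibration idea — rescaling outputs by the ratio of
  output variance to ground-truth variance — is not implemented: no
  concrete application of the ratio is specified, so it is recorded
  here as out of scope.

## Synthetic phantoms

`generate_fundus` renders, on a black canvas: a circular field of view
(radius 0.48 of the image side), a radially-shaded orange retina, a
bright optic disc ellipse (radius 0.11) containing a brighter cup at
the configured cup-to-disc ratio (default 0.4), a darker macula disk,
and tortuous vessels random-walking outward from the disc rim; mild
Gaussian noise (σ = 3) is added inside the field of view. Every
structure is simultaneously written into its mask channel, and masks
are clipped to the field of view.

Disease signatures (drawn into image *and* masks; a masks-only mode
supports ablation cohorts): GLAU re-renders the cup at ratio 0.82
(early) or 0.92 (late); AMD scatters drusen/exudate blobs within one
disc-diameter of the macula (4 early, 9 late); RVO draws flame
hemorrhages fanning along an occluded sector (7 early; 16 plus cotton
wool spots late); DR scatters microaneurysm dots (9 early; 26 plus
neovessel curls near the disc late); NORM adds nothing. For a fixed
seed the late rendering draws the early lesions first and then more,
so lesion burden is monotone in grade. Cohorts assign one disease per
patient (multinomial over the requested mix, every requested class
guaranteed present) and split 7:1:2 at the patient level.

What the phantoms deliberately lack: anatomical variation (geometry is
fixed by the config up to noise and vessel paths), photometric realism,
camera artefacts (blur, overexposure), and co-occurring pathologies.
Passing recovery tests therefore demonstrates that the pipeline's
machinery — masks → packing → fusion → training → statistics — is
correct and that the attention input carries class information end to
end; it does not predict clinical performance on real photographs, and
the reference cohort's real-data AUROCs are out of reach by design.

## Experiment scales

Chosen so the full suite runs on one CPU: recovery trains a width-0.25
classifier on 500 lesion-focused 64-px phantoms (125 patients × 4
images; held-out macro AUROC ≥ 0.95); the ablation repeats this on a
masks-only cohort and compares against raw-image training; the
transfer experiment fine-tunes grading heads for 3 epochs against
from-scratch baselines over 5 seeds (60 AMD patients), then runs one
12-epoch fine-tune (held-out early/late AUROC ≥ 0.9); segmentation
recovery trains a width-0.125 U-Net on 50 disc phantoms (validation
IoU ≥ 0.7) plus a shuffled-target null control whose IoU collapses
toward foreground prevalence. The full-width shape contract runs one
256-px forward pass.

## Known limitations

* The numpy training engine is single-threaded and desk-scale by
  design; it is not a general deep-learning framework (no autograd
  graph, no GPU).
* Max-pool backward distributes gradient equally across tied maxima.
* Batch-norm uses batch statistics in training and running averages at
  inference; very small batches make the two diverge.
* The RVO/DR confusion sentences of the reference report contain
  printing inconsistencies; the package stores the transposed DR
  reading (which reproduces every derived percentage) and excludes the
  RVO sentence from arithmetic checks, as documented in
  `clinical_reference.py`.
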