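# Methods

`scintigrade` implements an end-to-end pipeline for automated detection and
grading of cardiac tracer uptake on 2D bone scintigraphy: synthetic phantom
generation, anatomically informed preprocessing, two compact convolutional
network families, imbalance-aware cross-validated training, and
activation-map interpretability. This note documents the models, the
parameters that matter, and the numerical and design choices made where the
procedure was genuinely open.

## The clinical problem

Transthyretin amyloidosis (ATTR) binds bone-avid [99mTc] tracers, so it
shows up as myocardial uptake on ordinary bone scans. Uptake is graded
visually on the four-level Perugini scale relative to bone signal: 0 none,
1 less than bone, 2 similar to bone, 3 greater than bone; grade >= 2 is
considered positive. Because bone scans are acquired in volume for
oncologic indications, an automated screen for incidental cardiac uptake is
clinically valuable. The package frames this as image classification with
three tasks: the full four-class grading, positive-vs-negative detection
(grade >= 2), and high-grade detection (grade 3 vs the rest).

## Phantom generator

Clinical scintigraphy data are private, so the pipeline is exercised on
seeded synthetic phantoms that emulate the *count topology* of an anterior
[99mTc]-HMDP scan — not anatomy. The skeleton is a deterministic parametric
template (ellipses, rectangles, annuli: skull, spine, clavicles, sternum,
ribs, pelvis, femurs, humeri) inside a soft-tissue silhouette. Key
parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| `image_height x image_width` | 1024 x 256 (whole-body), 256 x 256 (planar) | acquisition matrix, pixels |
| `patient_height_fraction` | 0.9 (datasets draw U(0.8, 0.98)) | body rows / image rows |
| `bone_intensity` | 100 counts/px | mean skeletal count density |
| `background_intensity` | 15 counts/px | soft tissue, ~15% of bone (typical for bone scans) |
| `cardiac_ratio` | drawn per grade | mean cardiac / mean bone counts |
| `hotspot_rate` | 1.0 | expected focal spots (first = injection site, 5-20 x bone) |
| `metastasis_count` | 0 | focal bone lesions, 2-5 x bone |
| `noise_model` | `poisson` | per-pixel counting noise |

The grade is encoded by the cardiac-to-bone ratio drawn uniformly from
grade-specific intervals, by default 0: [0, 0.15], 1: [0.3, 0.8],
2: [0.9, 1.1], 3: [1.3, 2.5]. The defaults are deliberately disjoint so
phantom labels are unambiguous; overlapping intervals can be configured to
probe the hard grade-1/2 boundary. Inside the cardiac ellipse the template
value is `max(background, ratio x bone)`, so a grade-0 heart is
indistinguishable from soft tissue. The cardiac ellipse sits left of the
midline with its centre ~0.22 of body height below the crown (0.10 of body
height below the shoulder line) — the anatomical position that the
whole-body thoracic crop (below) is designed to capture. No published count
statistics exist for the source acquisitions; intensities are set at the
scale of a three-hour post-injection scan.

What the phantoms do **not** model: scanner/collimator response, scatter,
attenuation, 3D geometry, anatomical variation beyond height/position
jitter, or realistic lesion morphology. Tests passing on phantoms therefore
demonstrate that the pipeline's machinery is correct and can learn
intensity-ratio structure through Poisson noise and pose variation — not
that clinical-grade accuracy would be achieved on real scans.

## Preprocessing

Only anterior (AP) views are used. Whole-body images are cropped to a
128 x 128 thoracic window: the patient's row extent is found from the
y-direction line profile (rows with positive count sums); the window's top
edge is placed at `round(bottom_row - 0.85 x patient_height)` — i.e. 0.85
of the patient's height measured up from the lowest nonzero row, which
lands at ~0.15 of body height from the crown, over the thorax; the lower
edge is 128 rows down and the columns span +/-64 around the geometric image
centre. Fractional coordinates round half away from zero; windows are
clamped to the image, zero-padding only when the image itself is smaller
than the window. Planar thoracic images are block-average-downsampled to
256 x 256 when larger and centre-cropped to 128 x 128.

All counts then pass through `x -> ln(1 + x)`: zeros are preserved, order
is preserved, and focal hot spots are compressed (a spot 100x brighter than
bone at 10 counts retains only ~2.9x relative intensity), which stops the
injection site from dominating the dynamic range. Finally images are
z-scored pixel-wise against the *training fold only*: `(x - mean) /
max(std, 1e-7)`, the epsilon floor guarding never-illuminated pixels.
The patient-column centre (instead of the geometric centre) is available
behind a flag; base-e log on all pixels via `ln(1+x)` is the implemented
convention, chosen to remain defined for fractional counts produced by
resampling.

## Network architectures

Two compact families share one topology: a stem convolution followed by
four blocks of six 3x3, stride-1, ReLU convolutions, each block ending in a
2x2 average pool, then flatten -> dropout(0.2) -> softmax head (4-way or
2-way). The default filter plan is stem 16 and blocks 16/32/64/128.

* **Linear** — the plain stack.
* **Residual** — identical plus parameter-free skip connections every other
  convolution: within each block, the post-activation output from two
  convolutions back is added to the pre-activation of convolutions 2, 4 and
  6, with ReLU applied after the sum (three skips per block). Where the
  channel width doubles at block entry the skip passes through a zero-padded
  channel projection, so both families count exactly the same parameters:
  **1,112,644** under the default plan — the ~1-million budget these models
  are designed around (versus 138,357,544 for canonical VGG16).

Pooling uses stride 2. A stride-1 reading of the pool layer would make the
flattened feature dimension (and hence the head) explode far past the
1-million-parameter budget and contradict the 128 -> 64 -> 32 -> 16 -> 8
halving schedule, so stride 2 is the default and stride 1 remains available
via `ModelSpec.pool_stride`. Convolutions use 'same' padding (required for
the halving schedule and skip-shape compatibility) and carry biases.

Four standard backbones (VGG16, ResNet50, InceptionV3, MobileNetV1) can be
built with their classifier replaced by the same flatten/dropout/softmax
head and the single-channel input replicated to three channels. No
pretrained weights are bundled; initialisation is seeded-random, and the
backbones are fully trainable.

The networks run on a small NHWC NumPy engine written for this package
(layers with explicit forward/backward, a DAG container, Adam, a plateau
LR schedule). Convolutions are computed as sums of kernel-offset-shifted
batched matrix products; gradients are verified against finite differences
in the test suite.

## Training procedure

Training follows a fixed recipe: sparse categorical cross-entropy with
class weights, Adam at initial LR 1e-4, batch 128, 50 epochs; 10% of the
training data (stratified) is held out as validation, and the LR is
multiplied by 0.1 (configurable) whenever the validation loss fails to beat
its running best for 2 consecutive epochs, floored at 1e-7. Class weights
are inverse-frequency, `w_c = n / (n_classes x n_c)`, which satisfies
`sum_c w_c n_c = n`; on the reference cohort counts (991/296/23/24) this
up-weights the two positive grades by ~14x. Augmentation generates
`multiplier x n` randomized variants per fold (shift +/-10% of the image
size in each axis, rotation +/-20 degrees, zoom +/-20%, independent uniform
draws, bilinear resampling with zero fill, applied after the log transform
and before normalisation); with the default multiplier 5 a ~1066-image
training fold yields 5330 augmented images that supplement the originals.

Evaluation uses stratified 5-fold cross-validation (per-class fold counts
are seed-independent and match global proportions within one study).
Metrics are computed on the *pooled* out-of-fold predictions (per-fold
reports are retained): ROC-AUC on the positive-class probability for
binary tasks, macro-averaged one-vs-rest AUC for the four-class task,
total accuracy, and per-class precision/recall with undefined ratios
reported as NaN rather than silently zero. A binary-AUC brute-force
all-pairs concordance oracle backs the implementation in tests. Subgroup
reports split the pooled predictions by the bone-metastasis flag with
identical metric definitions.

### Conditioning options for short runs

At full scale (thousands of Adam steps) the plain recipe above trains both
families. At the small step budgets used for CPU-scale validation
(~100-200 steps), 25-conv-layer stacks started from He-uniform weights
collapse into emitting the class prior for every input: the plain stack's
deep activations die, while the residual stack's activation variance grows
until the softmax saturates. Three optional, architecture-preserving
switches in `TrainConfig` (all **off by default**) address this:

* `scaled_init` — layer-sequential unit-variance rescaling of the initial
  weights on a small data batch (deterministic; parameter count unchanged);
* `head_init_steps` — pre-fit the softmax head on the frozen random
  convolutional features (a weighted multinomial regression) before joint
  training, giving descent a direction out of the uniform-output saddle;
* `average_tail_fraction` / `snapshot_ensemble` — Polyak averaging of the
  weights visited in the last fraction of epochs, and probability averaging
  over the last epoch-end snapshots, reducing the variance of short noisy
  runs at negligible cost.

## CPU-scale validation study

A clinical-scale experiment (a ~1300-patient cohort, 50 epochs, GPU
training) is far beyond a single-CPU test budget, so the repository
validates learning end-to-end on a deliberately small study, returned by
`scintigrade.pipeline.small_study()`:
200 whole-body phantoms with a uniform grade design (the clinical
prevalence of ~2% positives is unrepresentable at n=200), metastasis flags
at rate 0.2 independent of grade, Poisson noise, default (disjoint) ratio
intervals and per-study height jitter; a reduced filter plan (stem 4,
blocks 4/8/12/16); stratified 5-fold cross-validation; batch 8, Adam 1e-3,
plateau factor 0.5; all three conditioning switches on; 7 epochs for the
Linear family and 5 for the Residual (the plain stack converges more
slowly — the same trainability gap that motivates skip connections). Under
these conditions both families reach pooled four-class macro-OVR AUC >= 0.95
with grade-3 recall >= 0.8 in at least two of three seeds, and the deepest
block-entry activation map of a trained model concentrates inside the
cardiac region of grade-3 phantoms (focus ratio > 1). These problem sizes
are the package's own validation choices; nothing about them is claimed to
transfer quantitatively to clinical data.

## Numerical choices and degenerate inputs

* float32 forward/backward; float64 preprocessing and metrics.
* Rounding of crop coordinates: half away from zero, then clamp.
* Division guards: z-score epsilon 1e-7; probability floor 1e-12 in the
  cross-entropy; cardiac-focus ratios capped (default 100) when the
  outside-mask mean is zero.
* Min-max rescaling maps constant activation maps to all-zero.
* All-zero images raise a "no patient" error in extent detection; empty
  classes raise in weight computation; single-class test sets yield NaN
  AUC with a logged warning.
* Every stochastic stage (phantom sampling, fold shuffling, augmentation,
  initialisation, dropout, batching) draws from named seeds; identical
  seeds give bit-identical phantoms and deterministic training on one CPU.

## Known limitations

* The phantom is a count-topology cartoon; it cannot probe robustness to
  anatomy, acquisition protocol, or scanner differences.
* The NumPy engine targets correctness and small models; it is not a
  general-purpose training framework (single device, no autograd graph
  optimisations), and the pretrained backbones, while buildable and
  trainable, are impractical to train at scale here and ship without
  ImageNet weights.
* Visual-grading reproducibility (reader agreement) requires human readers
  and is out of scope; so is any claim about clinical performance.
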