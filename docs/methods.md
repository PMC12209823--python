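# Methods

`wsimil` implements a slide-level classification and annotation pipeline for
nonmelanoma skin cancer (NMSC) histopathology: tiling and foreground
filtering of whole-slide images (WSIs), aggregation of per-tile embeddings
into slide embeddings, subtype classification with patient-stratified
cross-validated evaluation, and a training-free few-shot framework that
annotates individual tiles from a handful of expert-drawn regions of
interest.  Because the motivating cohort (H&E WSIs of skin biopsies from a
Bangladeshi arsenic-exposure study population) is private and its
foundation-model encoders are GPU-scale, the package ships a synthetic
cohort generator that reproduces the *statistical structure* the pipeline
assumes, so every stage is testable end to end on a laptop CPU.

## Tiling and foreground segmentation

A slide image is divided into non-overlapping square tiles (default
256 px).  Per-pixel luminance is the arithmetic mean of the three colour
channels; Otsu's method on the 256-bin luminance histogram chooses the
threshold maximizing between-class variance (ties resolved to the smallest
qualifying threshold), and tissue is taken to be *darker* than the bright
slide background, i.e. pixels strictly below the threshold.  Each tile's
occupancy is its foreground-pixel fraction; tiles with occupancy below the
threshold (default 0.1, inclusive comparison at the boundary: a tile is
kept iff occupancy ≥ 0.1) are flagged as discarded, not deleted, so grid
geometry survives for heatmaps.  Coordinates are 0-based (row, col), pixel
origin top-left, half-open footprints.  Otsu runs on the full-resolution
histogram by default; a thumbnail-downsampling option exists for large
inputs but is off, since desk-scale fixtures are small.

## Encoders

Foundation-model tile encoders are pluggable externals behind the
`EncoderSpec` contract (a callable mapping an RGB tile to a d-vector, plus
the transform contract: expected tile size, optional center crop, optional
per-channel normalization — the 224-px ImageNet-statistics path used by
convolutional baselines is provided as a tile transform).  Nothing in the
package updates encoder parameters.  The built-in **mock encoder** is a
deterministic stand-in: 30 Lipschitz summary features per tile (per-channel
mean, standard deviation, and spatial means of sin/cos harmonics of
intensity) expanded by a fixed seeded random projection to d dims.  It is
enough for the tiling → embedding plumbing and for linear-probe sanity
checks; it cannot, and is not meant to, carry diagnostic signal — class
structure for the learning experiments comes from the synthetic embedding
generator below.

## Aggregation

**GAP** is the coordinatewise mean of a slide's tile embeddings.

**ABMIL** computes softmax-normalized attention over tiles per branch,
with the standard score networks — ungated `e_k = w^T tanh(V h_k)`, gated
`e_k = w^T (tanh(V h_k) ⊙ σ(U h_k))` — with 1 or 8 parallel branches
(attention hidden dim 128 by default), branch outputs concatenated and
linearly projected back to the input dimension d.  Tile position is
injected by *adding* a 2D sinusoidal positional embedding (half the
dimensions encode the row, half the column, alternating sin/cos at
geometric frequencies with base 10,000; requires d divisible by 4).
Softmax uses max-subtraction; non-finite attention raises rather than
clamping.  The forward pass keeps an explicit cache so training
backpropagates exact gradients (verified against central finite
differences in the test suite).

Model-specific slide aggregators of external foundation models (dilated
transformers, latent cross-attention pooling) are out of scope; they enter
only as pluggable producers of slide embeddings.

## Classifiers and the training recipe

Three classifiers operate on fixed slide embeddings, used exactly as
given (no normalization): multinomial logistic regression (SAGA solver,
L2 penalty, 1,000 max iterations), gradient-boosted trees (library
defaults, softmax objective), and a three-hidden-layer MLP
(1024/512/256, ReLU, 4-way output, no dropout by default; the rate is
exposed).  The joint model trains the ABMIL aggregator end to end with
the MLP head: one slide per forward pass, gradients accumulated over 16
slides per optimizer step, AdamW at learning rate 1e-5 on cross-entropy,
at most 30 epochs.  Because neither PyTorch nor a GPU is assumed, the MLP
and the joint trainer are written directly in NumPy (explicit
forward/backward passes, hand-rolled AdamW with decoupled weight decay);
within an accumulation window the head runs as one batched pass, which is
gradient-identical to slide-at-a-time accumulation with the loss averaged
over the window.

Two deliberate initialization choices:

* the standalone MLP's output layer starts at zero (hidden layers use
  fan-in-scaled uniform), so an untrained model predicts exactly the
  uniform distribution and, under the small fixed learning rate, rankings
  reflect accumulated learning signal rather than initialization noise;
* the joint model's head is fan-in initialized throughout — a zero head
  passes no gradient to the attention module during early training, which
  measurably prevents attention from ever locking onto diagnostic tiles
  at this learning rate.

**Step-budget scaling.**  At full cohort scale (~1,700 training slides per
fold) the 30-epoch recipe performs ≈3,200 optimizer steps.  On a small
synthetic cohort, 30 epochs would mean ~10× fewer steps, and at a fixed
learning rate the step count — not the epoch count — governs convergence.
Training therefore runs for `max(30 epochs, enough epochs to reach a
3,200-step budget)`: at full scale the rule is inactive and the recipe is
exactly the 30-epoch one; at desk scale the epoch count extends to
preserve the recipe's optimization budget.  Learning rate, accumulation,
loss and optimizer are never altered.

## Evaluation

Folds are assigned at the patient level, k = 5, stratified by patient
label (per-fold class counts within one of perfect); all of a patient's
biopsies and slides share a fold, and the train/validation patient
intersection is asserted empty at runtime.  Slides inherit their biopsy's
label for training.  Slide-level class probabilities are averaged within
each biopsy; one-vs-rest AUROC (Mann–Whitney identity, ties one half) is
computed per class and fold — 4 × 5 = 20 values per experiment — at the
biopsy level by default (slide level behind a flag).  The summary is the
class-proportion-weighted mean AUROC over pooled validation predictions;
a per-fold-averaged variant is also reported since the pooled-vs-averaged
construction is a genuine ambiguity.  A fold missing a class records NaN
with a warning and drops out of the weighting (proportions renormalized).
Paired experiments are compared with a one-sided Wilcoxon signed-rank
test over the 20 paired values: zeros dropped, tied absolute differences
averaged-ranked, exact null distribution by dynamic programming over
signed ranks for n ≤ 25, normal approximation with tie and continuity
corrections beyond.  Confusion matrices use argmax with ties resolved to
the first class in the fixed order (Benign, Bowen, BCC, SCC).

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions of every statistical claim the tests make.

**Hierarchy.**  Patients → biopsies → slides with subtype labels at the
biopsy level; a patient's label is their most frequent biopsy label, ties
broken by clinical severity (SCC > BCC > Bowen > Benign).  In
published-count mode the generator reproduces the motivating cohort
exactly — 455 patients (210/140/85/20 per class), 553 biopsies
(229/171/116/37), 2,130 slides — distributing slides over biopsies by the
configured distribution with seeded adjustment to hit the exact total.
Defaults: biopsies per patient on {1, 2, 3} with mean ≈ 1.2; slides per
biopsy on {2..6} with mean ≈ 3.85 (the cohort averaged about four slides
per biopsy); per-slide tile counts log-uniform on [50, 2000], a desk-scale
nod to the enormous spread of real foreground tile counts (82–38,404).

**Embedding bags.**  Class prototypes sit at distance Δ
(`class_separation`, default 4) from the origin along mutually orthogonal
seeded directions; tile noise is isotropic with sd σ (default 1).  A
non-benign slide with n tiles carries max(1, round(diag_fraction · n))
diagnostic tiles (default fraction 0.3) drawn at its class prototype, in
a contiguous run of the row-major grid so heatmap and region checks have
coherent ground truth; a benign slide draws all tiles at a milder benign
shift (Δ/2), making Benign a learnable class.  Δ = 0 removes all signal.

**Background structure.**  Background tiles are *not* i.i.d. around one
mean: each slide mixes K = 64 shared background micro-environment
prototypes (norm 3σ, unconstrained random directions) in slide-specific
proportions drawn from a sparse Dirichlet (α = 0.2).  This choice is what
makes the bag structure genuinely multiple-instance.  With a purely
i.i.d. background the slide mean is a sufficient statistic — tile noise
averages out as σ/√n — and mean pooling with a linear model is essentially
perfect at any diagnostic dilution, so no attention mechanism could ever
beat it.  Two simpler alternatives fail in instructive ways: a per-slide
Gaussian nuisance shift does corrupt the mean, but hands the
high-capacity joint model a memorizable per-slide fingerprint; a low-rank
mixture (a handful of prototypes) is linearly removable in a
32-dimensional space.  The full-rank shared mixture is neither removable
nor memorizable: slide-composition variation confounds the mean (the
prototypes' incidental ~1/√d overlaps with class directions cannot be
projected out without destroying signal), while individual diagnostic
tiles stay cleanly separable — the regime where instance attention earns
its keep, and a reasonable cartoon of real slides, whose tissue
composition (epidermis, dermis, subcutis, artifacts) varies from section
to section.  `n_background_types = 0` recovers the plain isotropic
background.

**Determinism.**  A single root seed streams per-entity sub-seeds
(patients/biopsies/slides each draw from their own seed sequence), so
regenerating one slide never perturbs another, and identical
configurations are bitwise reproducible.

**Images.**  Tissue-like fixtures are bright backgrounds with darker
elliptical blobs (plus exact-rectangle placement for constructed-geometry
tests); the ground-truth mask is returned alongside.  They exercise
tiling and the mock encoder.  No attempt is made to simulate H&E texture,
stain variation, or scanner artifacts, and pixel fixtures carry no
subtype signal — so passing tests demonstrate the pipeline's mechanics and
its statistical behaviour on structured embeddings, not performance on
real histology.

## Few-shot annotation

Seven tissue classes by default (invasive SCC, Bowen, superficial BCC,
nodular BCC, epidermis, dermis/subcutis merged, artifact); the list is
configurable.  ROI boxes are half-open pixel rectangles; a kept tile
belongs to a box iff its footprint center lies inside (an
overlap-fraction rule is a configured alternative), a tile claimed by two
classes is an annotation conflict and raises.  One prototype per class is
the unweighted mean of all of that class's ROI tile embeddings pooled
across source slides (per-ROI pre-pooling behind a flag).  Inference is
training-free: each tile's similarity to each prototype is the **raw dot
product** — deliberately unnormalized, so prototype magnitude matters and
accidental cosine-normalization is caught by a dedicated test; exact
ties go to the first configured class and flag the tile ambiguous.
Prototype structure is visualized by PCA: the first two principal
components of the mean-centered prototypes, component signs fixed by
making the largest-magnitude loading positive.  Collinear prototypes get
an exactly-zero second component; only fully coincident prototypes raise.
The synthetic fixture emits slides whose grid is split into horizontal
per-class bands with one ROI box per band, five slides for prototype
building plus held-out slides for accuracy measurement.

## Orchestration

`run_pipeline` executes simulate → tile → embed → aggregate → train →
evaluate → annotate from one YAML config into a deterministic artifact
tree with a machine-readable run manifest (config hash, seed, package
version, per-stage timing); reruns with an unchanged config reuse cached
stages, and a missing upstream artifact names the stage to run.  The
default path is embedding-level — the simulate stage writes the manifest
and per-slide embedding bags directly, since subtype signal lives in
embedding space — while the tile and embed stages exercise the image path
(Otsu segmentation, occupancy filtering, mock encoding) on a generated
demo tissue image.

## Problem sizes and numerical choices

The acceptance experiments run on a 40-patient cohort (10 per class),
32-dimensional embeddings, and 50–500 tiles per slide (log-uniform,
mean ≈ 195) — the desk-scale problem size; the full generator default of
up to 2,000 tiles per slide is exercised by the library but not in the
cross-validated training loops.  Training arithmetic is float32; metrics
and aggregation arithmetic float64.  Attention softmax uses
max-subtraction; cross-entropy clips log arguments at 1e-12; AdamW uses
(β₁, β₂) = (0.9, 0.999), ε = 1e-8, decoupled weight decay 1e-2 (movement
from decay is negligible at lr 1e-5 over a 3,200-step budget, but the
optimizer is the stated one).  Embedding containers store row-major
float32 with a JSON header and a coordinate sidecar CSV; round trips are
bitwise.

## Known limitations

* The mock encoder cannot represent diagnostic morphology; image-level
  end-to-end classification is therefore meaningless by construction and
  deliberately absent.
* The synthetic embedding model is Gaussian with a linear class geometry;
  real foundation-model embeddings are neither, so absolute AUROCs here
  say nothing about clinical performance — only the *relative* behaviour
  of the pipeline's components under controlled structure.
* Attention-recovery and ordering results depend on the optimization
  budget; at the fixed learning rate the attention mechanism needs on the
  order of a thousand steps to lock onto diagnostic tiles, and a much
  smaller budget leaves it at chance.
* At the 40-patient desk scale the stochastic outcomes carry real
  cohort-draw variability: null weighted AUROCs scatter roughly ±0.1
  around chance and the attention-MIL vs. mean-pooling margin varies by a
  few hundredths across generator seeds.  The test suite therefore pins
  its seeds, as any fixed-seed stochastic check must; conclusions about
  tendencies across seeds would need replicated runs.
* Wilcoxon p-values for n > 25 use the normal approximation; AUROC
  confidence intervals and calibration metrics are out of scope.
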