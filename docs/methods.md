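# Methods

## The model and what it is for

`blurlab` studies how exposure to blurred images during training shapes
object recognition in a convolutional classifier. The experimental object is
a supervised image classifier f(x) → class trained by SGD under a *blur
policy*: a rule assigning each training sample a Gaussian blur width σ as a
function of epoch and batch. Four policies span the space between "never
blurred" and "always blurred": sharp-only (S), blur-only at fixed σ (B), a
per-batch half-and-half mixture (B+S), and a coarse-to-fine curriculum that
starts at σ = 4 px and anneals to sharp (B2S). The question each analysis
answers is not "how accurate is the network" but "what did the blur diet do"
— to blur robustness, to the spatial-frequency bands the network can use, to
its shape-versus-texture preference, to its sensitivity to global
configuration, and to how sharp and blurred inputs are represented across
layers.

## Stimulus construction

Gaussian low-pass filtering uses a sampled, renormalized Gaussian kernel
whose width is tied to σ by k = Round(8σ+1) (round-half-up), incremented by
one when even, so the kernel is always odd and spans ±4σ. σ = 0 is the exact
identity. Convolution is separable and per color channel, with reflect
padding at the borders (border handling is configurable; reflect avoids the
dark rims that zero padding would add to edge statistics). Band-pass images
are differences of two low-pass images, lowpass(σ1) − lowpass(σ2) with
σ1 < σ2; the signed band is kept exact for analysis, and a display variant
adds 0.5 and clips to [0, 1] before being shown to a network trained on
[0, 1] images (a zero band maps to mid-gray). Tile manipulations divide the
square image into n × n tiles (n ∈ {4, 8, 16, 32}; an indivisible side is an
error, never a silent crop): *jumble* permutes tile positions (uniformly
over all positions by default, with a rows-only option since horizontal-only
scrambling is also in use), *gray occluder* replaces the checkerboard tile
set — tile (0,0) retained, mid-gray 0.5 — and the combined mode jumbles
first, then occludes. Jumbling conserves the pixel multiset exactly; the
occluder touches exactly ⌈n²/2⌉ or ⌊n²/2⌋ tiles.

## The synthetic dataset

The generator renders a 16-class dataset in which every class is defined by
both a global shape and a local texture, so that shape-based and
texture-based recognition are separately possible and can be put in
conflict. Shapes are a fixed library of polygon prototypes (regular
polygons, stars, cross, arrow, T/L shapes, a blob, …) rasterized with 2×
supersampling; textures are plaids — two superposed sinusoidal gratings at
orientations ±θ — with θ ∈ linspace(0°, 90°, 8) and carrier frequency 8 or
14 cycles/image (8 × 2 = 16 unique textures). Plaids rather than single
gratings because training uses random horizontal flips, which map a single
grating of orientation θ onto −θ — another class's texture — whereas the
±θ plaid family is closed under flips. Per image, pose varies (rotation
±30°, scale 0.55–0.78 of the half-side, translation within the frame
margin, texture phase and small orientation/frequency jitter), and the
background is low-contrast smoothed noise (mean 0.42) — a uniform background
would make silhouettes trivially diagnostic. Object mean luminance (0.72)
differs from the background so the silhouette survives strong blur; at
σ = 4 px both carrier frequencies are essentially annihilated
(attenuation < 1%), so blurred recognition must rely on shape, and sharp
recognition can shortcut through texture. Cue-conflict images render the
shape of one class filled with the texture of another; the silhouette is
bit-identical to the pure shape-class render under the same scene seed.

Scene seeds derive from (master seed, split, class, index) via
`SeedSequence` spawn keys: splits are disjoint by construction and
generation is bit-reproducible. Default sizing is 128 train + 32 test per
class at 64×64 — large enough for the qualitative effects, small enough for
CPU minutes.

What the generator does *not* emulate: natural-image spectral statistics,
within-class texture variation, occlusion, color cues, or the weak
correlation between shape and texture found in natural categories. Passing
tests therefore demonstrate that the pipeline's logic and contrasts behave
as designed under a controlled shape/texture dissociation — not that the
same effect sizes would be measured on natural images.

## Training

The classifier is a compact NumPy CNN: four convolution blocks
(5×5 stride-2, then three 3×3 convolutions with 2×2 max pooling;
16/32/64/64 channels), a global-average-pool or flatten head, and two dense
layers (128 hidden units). Post-ReLU activities at conv1–conv4 and fc1, plus
the output logits, are named capture points. The optimizer is SGD with
momentum 0.9 and weight decay 5e-4; the learning rate is divided by ten at
each third of training (the torchvision-classification rule), and random
crop (reflect-pad 4) plus random horizontal flip are applied before the
policy blurs its chosen samples, so σ is in final-image pixel units. B+S
blurs exactly round(batch/2) samples per batch — deterministic count, random
membership — which makes the realized blur fraction auditable exactly; the
per-class blur audit is stored with every run. Divergence (non-finite loss)
raises with the epoch number. One seed expands through `SeedSequence` into
independent streams for initialization, shuffling, blur membership and
augmentation, so a run is reproducible to the last bit of its checkpoint;
ensembles refit across seeds and report t-distribution 95% confidence
intervals (the CI is reported absent for a single seed).

### Desk-scale configuration

The reference schedule — 60 epochs over ~40k images at 224×224 — is
expressible through `TrainConfig`, but the package's standard study runs at
desk scale (`blurlab.desk`): 2,048 training images at 64×64 for 10 epochs.
Two consequences of that reduction shaped the defaults. First, the update
budget shrinks from tens of thousands of SGD steps to a few hundred, so the
desk configuration uses batch 32 and lr0 = 0.02 (the reference grid spans
0.05–0.001) to recover adequate convergence within the short schedule; the
thirds-decay rule is kept. Second, σ = 4 px at a 64-px image is a much
stronger *relative* blur than the same σ at 224 px, which makes the blurred
branch of the task intrinsically harder; inputs are therefore per-image
standardized (zero mean, unit variance) rather than merely offset, removing
the systematic contrast difference between blurred and sharp images so that
neither domain is favored by input scale alone. Both choices are recorded in
every checkpoint's config. At this configuration the qualitative policy
contrasts of the full-scale experiments reproduce: sharp-only training
collapses under σ = 4 test blur, mixed training holds most of its sharp
accuracy, and blur-only training peaks at its training σ.

## Behavioral batteries

Evaluation applies no augmentation and is deterministic; exact logit ties
resolve to the lowest class index. Low-pass sweeps default to
σ ∈ {0, 1, 2, 4, 8, 16} (σ = 0 is the sharp baseline), band-pass conditions
to (1−2) and (4−8), tile tests to all grids × modes. Shape bias counts, over
cue-conflict images, decisions matching the shape label versus the texture
label: bias = shape/(shape+texture), flagged undefined (not NaN-propagated)
when no decision matches either label; the per-image decision log is kept so
counts can be replayed. A uniform-random reference classifier provides
chance calibration (1/C) through the same evaluation path.

## Representational analyses

For two stimulus conditions (sharp vs blurred σ = 4, or band-pass "high"
vs low-pass σ = 4), the per-layer profile is built from image pairs under
three cases: same image, different images of the same class, different
classes. Per pair, Pearson r is computed across units within a layer; the
profile reports the mean and the 25–75% interquartile range over pairs. The
alternative reading — correlating per unit across the pair set — is
available via the profile's ``axis`` option, but the per-pair-across-units
form is the default and the one used everywhere here. Zero-variance vectors
make r undefined; such pairs are skipped and counted (the skip fraction must
stay below 1% on the default data, which the tests enforce). Different-image
cases subsample pairs to a seeded budget (default 10,000; analyses here use
2,000) instead of enumerating all ~N² pairs. t-SNE embeddings use
perplexity 30 and 1,000 iterations by default and are seed-controlled;
degenerate (all-identical) inputs are an error, and fewer than 3× perplexity
points triggers a warning. First-layer filters are exported as a tile grid,
each filter normalized symmetrically about zero so a zero filter renders
mid-gray.

## Zero-shot class-exclusion transfer

During B+S training, an exclusion rule overrides the blur assignment for a
subset of classes: 'blurred'-excluded classes are never blurred,
'sharp'-excluded classes always are. The mixture fraction is applied among
the remaining samples only, so non-excluded classes still realize the
nominal half-and-half diet. Conditions follow the w/o n/CB / w/o n/CS
naming. After training, the excluded classes are evaluated on the withheld
image type (blurred at the training σ, or sharp); seen classes are evaluated
on the same type, and both-type accuracies plus the full confusion matrix
are reported, since the interesting failure mode is misclassification of an
unseen class into a representationally similar seen class. The default
single excluded class is the one whose shape prototype has the highest
silhouette IoU with another class — transfer is most informative where a
near neighbor exists in shape space. The audit must show zero rule
violations, exactly.

## Numerical and design choices

- Round(·) in the kernel-width rule is round-half-up; the tie rule is
  otherwise unstated in common usage.
- Blur is applied after crop/flip augmentation, keeping σ in final-image
  pixels.
- The gray level for occluders is 0.5 and the checkerboard phase retains
  tile (0,0), fixed for reproducibility.
- B+S uses a deterministic blur count per batch rather than per-sample coin
  flips: lower variance, exact audits.
- The B+S-random σ distribution is continuous uniform on [0, 4].
- Pearson profiles use per-pair-across-units correlation (see above).
- PNG I/O quantizes to 8 bits; in-memory pipelines stay float32.

## Known limitations

A structural difference from natural-image studies matters when reading the
correlation profiles: every synthetic render is a bright, roughly centered
object on a darker noise background, so even *different* images of
*different* classes share global spatial structure. Raw pixels of a sharp
image and a blurred different-class image already correlate at ~0.4, and an
untrained network's first layer inherits that (~0.4 as well). Consequently
the different-class correlation at conv1 sits far above zero here, where
natural-image studies find it near zero; on this dataset the interpretable
quantities are the *orderings* — same-image far above different-class, and
mixed-trained above sharp-trained in deep layers — not the absolute
different-class level.

The NumPy engine is single-threaded and desk-scale by design; the 60-epoch,
224×224 reference configuration is expressible in config but not practical
without substituting a GPU framework. The synthetic classes are perfectly
texture-separable and near-perfectly shape-separable, which inflates all
absolute accuracies relative to natural images; only directions and
contrasts between policies are interpretable. B2S at desk scale compresses
the σ ladder into few epochs, so its curriculum effect is weaker than in a
long schedule. The H-L analysis uses the display-remapped band image as
"high", matching what a model would actually see.
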