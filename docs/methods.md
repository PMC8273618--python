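# Methods

This note documents the models, conventions, and design choices behind
`ccmorph`, and what the synthetic validation does and does not show.

## Problem setting

Calcified cartilage (CC) is the thin mineralized band between the
tidemark and the cement line. In histology sections it is distinguishable
by staining; in micro-CT it is only subtly less mineralized than the
subchondral bone, which makes the CC/bone interface the hard part of the
segmentation. The pipeline segments the CC band, cleans the mask, and
reports CC thickness (CC.Th) statistics in micrometres.

Axis conventions: 2D images are `(row, column)` with depth along rows;
volumes are `(slice, row, column)` with depth along the slice axis.
Intensities are rescaled to [0, 1] by the on-disk bit-depth maximum at
read time; no attenuation windowing is applied (that belongs to scanner
reconstruction, which is out of scope). Pixel sizes default to 3.2 µm for
micro-CT and 2.56 µm for histology and are carried on every container.

## Segmentation models

Two encoder families and two decoders, combinable freely:

- encoders: a compact three-down-block double-convolution encoder
  (`small`, downsampling factor 8, default 16 base channels) for
  CPU-scale work, and 18-/34-layer residual encoders (factor 16) mirroring
  the architecture pairs used for the two modalities at full scale
  (34-layer + full-resolution skip decoder + batch norm for histology;
  18-layer + pyramid decoder + instance norm + spatial dropout for
  micro-CT, exposed as `HISTOLOGY_MODEL` / `MICROCT_MODEL` presets);
- decoders: a full-resolution skip decoder (upsample, concatenate skip,
  double conv per level — no final interpolation), and a feature-pyramid
  decoder (1×1 laterals, top-down additions, per-level heads merged at the
  finest pyramid level, one final 2× upsampling to input resolution).

The networks are implemented directly on numpy (`ccmorph.nn`): im2col
convolutions, exact manual backpropagation, Adam. Single-precision
activations; training is deterministic given a seed. A forward pass
requires tile sides divisible by the encoder's downsampling factor, and
the error message names the required multiple.

**Loss.** `w₁·BCE + w₂·(1 − soft Jaccard)`, both computed from
probabilities (sigmoid output). Weights default to 1:1 — no weighting is
prescribed for this combination, and equal weights keep both terms within
the same order of magnitude. The Jaccard smoothing ε defaults to 1e-7,
which also defines the empty-vs-empty convention (`J_soft = 1`).
Probabilities are clamped to [1e-7, 1−1e-7] inside the cross-entropy.

**Training protocol.** Folds split by *subject*, shuffled by seed and
dealt round-robin, so the leakage invariant (no subject on both sides of
any fold) is structural. Defaults: 4 folds; 100 epochs for histology and
60 for micro-CT (the published schedules); Adam at 1e-3 (the optimizer is
not named in the source protocol; an adaptive-moment method is the
field's default); random crops of the inference tile shape, several per
image per epoch. Out-of-fold Dice is evaluated at threshold 0.5 on raw
tiled predictions — distinct from the 0.8 deployment threshold, which
exists to exclude ambiguous regions, not to score training.

**Augmentation.** The exact published augmentation table is not available
in the source text; the defaults (flips, ±15° rotation, ±10% scale, ±20%
brightness/contrast, gamma 0.8–1.2, mild Gaussian noise) are a
conventional stand-in and are flagged as such. Geometric transforms hit
image and mask identically (nearest-neighbour for the mask; right-angle
rotations are handled losslessly); photometric transforms hit the image
only.

## Inference

Tiling uses a fixed window advancing by fixed steps; the final window in
each axis is shifted inward so windows never leave the image, and images
smaller than one window are reflect-padded then cropped after stitching.
Overlaps are averaged with uniform weights. Ensembling is one uniform
mean over all (fold × plane) members — equivalent to sequential
averaging because all the means are uniform. Plane names: coronal fixes
axis 1, sagittal fixes axis 2; the axial plane (perpendicular to depth)
is not used. Thresholding is inclusive (`p ≥ t` is foreground), so the
value printed as the threshold is itself accepted.

## Mask cleanup

- `remove_small_regions` (histology, 2D): components with *strictly
  fewer* than 500 pixels are removed; a 500-pixel component survives.
  Large disconnected CC pieces (e.g. split by a section fold) are kept.
- `keep_largest_component` (micro-CT, 3D): single sweep keeping the
  maximal component; ties resolve to the component first reached in
  raster order, which is deterministic.
- `median_filter_mask`: exact majority vote over a Euclidean disc/ball
  footprint (`‖d‖ ≤ r`, default r = 12 px; the footprint shape is not
  specified in the source text and a Euclidean footprint is the natural
  reading of "radius"), reflective boundaries, exact 50/50 ties resolve
  to foreground so thin structures are not eroded by ties. Note the
  odd-sized symmetric footprint makes true ties impossible in practice.
- Connectivity defaults to 8-neighbour (2D) / 26-neighbour (3D) so thin
  diagonal CC bridges stay connected; configurable.

## Local thickness

The discrete convention is fixed exactly:

- `EDT(c)` = Euclidean distance from foreground element `c` to the
  nearest *background element centre*, with everything outside the image
  treated as background (implemented by padding one background layer; the
  nearest outside centre always lies in that layer);
- `τ(p) = 2·max{ EDT(c) : c foreground, ‖p − c‖ < EDT(c) }` (strict
  inequality).

All comparisons run on squared integer distances, so the production path
and the brute-force oracle (`brute_force_thickness`, a literal evaluation
of the definition, guarded to 10⁴ foreground elements) agree **bitwise**
— the test suite asserts exact equality on hundreds of random masks. The
production path reduces candidates to a distance ridge: a ball is dropped
only when a neighbour's ball provably contains it (`‖c₁−c₂‖ + r₁ ≤ r₂`,
checked in exact integer arithmetic — containment is transitive, so the
reduction is conservative), then paints surviving balls largest-first.

Summaries (mean/median/max/SD CC.Th) are over foreground elements only,
converted to µm; SD is the population standard deviation. Multi-section
samples are aggregated as the unweighted mean of per-section means.

### Known numerical properties

- **Slab law**: an axis-aligned slab of even height `h` measures exactly
  `h` away from its lateral ends (by ≥ `h`). At ends and corners the
  inscribed disc is genuinely clipped — true of the continuous definition
  too — so whole-structure means include a small edge-depression.
- **Odd-height overshoot**: a slab of odd height `h` measures `h + 1`
  (the covering ball's integer radius is `⌈h/2⌉`). For a band of varying
  thickness this contributes roughly +0.5 px to the mean — ~3% at 16 px,
  ~5–7% at 10 px. Phantom-recovery checks therefore use bands ≥ 14 px,
  where recovery is within 5% of the prescription; thinner structures
  carry a proportionally larger positive bias.
- Balls clipped by the image boundary are limited by it (outside counts
  as background, no padding), a mild negative bias within ~τ/2 of lateral
  image edges — consistent with how a cropped volume of interest behaves.

## Agreement statistics

Dice `2|A∩B|/(|A|+|B|)` with empty-vs-empty defined as 1 (perfect
agreement on absence, flagged in reports). Pearson correlation is the
sample correlation with the two-tailed p-value from
`t = r·√((n−2)/(1−r²))` on `n−2` degrees of freedom (delegated to
`scipy.stats.pearsonr`, which implements exactly this transform; the
closed-form examples are frozen in the tests as an independent check).
Bland–Altman reports mean difference (bias), the *sample* SD of
differences (n−1 — the standard convention for limits of agreement), and
bias ± 1.96·SD. Mixed-effects modelling across anatomical regions is out
of scope; reports emit tidy per-sample tables consumable by external
statistics software.

## Synthetic phantoms

A phantom stacks three phases along depth: cartilage (intensity 0.25), a
CC band (0.55) whose thickness field is
`base + amplitude·sin(2πx/period)` (separable sinusoid in 3D) plus
optional smooth roughness, and bone (0.85) with multiplicative smoothed
speckle (±15%, clipped) that turns the CC/bone boundary into a gradient —
the hard interface of the real problem. Chondrocyte-like voids (dark
discs/balls, radius 2–4 px) are placed fully inside the band; they darken
the image but stay in the truth mask, matching the annotation convention
of including small intra-band cavities. Additive Gaussian noise
(σ = 0.03 by default) is applied last, then clipping. Everything is
deterministic in (spec, seed), and the truth mask's vertical extent
matches the rounded thickness field exactly, which makes the phantom an
analytic oracle for the whole pipeline.

The recovery study uses 12 phantoms of 128×192 px (one subject each,
8 train / 4 held-out), with per-subject base thickness drawn from
14–30 px (≈36–77 µm at histology scale) so that the prescribed-vs-
recovered correlation has real between-sample variance to explain — as
anatomical regions do. Training uses the `small` encoder, 20 epochs,
64×64 crops, six per image per epoch; inference uses a 64×64 window with
32×32 steps. These sizes were chosen as the smallest at which the full
protocol (grouped CV, ensembling, 0.8 threshold, cleanup, thickness) is
exercised meaningfully on a single CPU.

**What passing does and does not show.** The phantoms are intensity-
separable by construction: a well-trained network can segment them nearly
perfectly, so the study validates the *pipeline machinery* — that
training converges, that ensembling/thresholding/cleanup do not bias the
band geometry, and that morphometry recovers a known answer through the
whole chain. It does not emulate the genuinely ambiguous CC/bone
mineralization gradient of real micro-CT, stain variability, multiple
tidemarks, or pathology, and synthetic Dice scores should not be read as
expected performance on real tissue.

## Degenerate inputs and failure modes

Empty masks raise in `local_thickness`/`summarize`; the pipeline's
thickness stage records an empty segmentation as a NaN row instead of
aborting the run. All-background training sets warn and proceed. Every
run directory is self-describing (resolved config, seed, per-stage
timings, machine-readable `run.json`), and reruns with the same config
and seed are bit-identical.
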