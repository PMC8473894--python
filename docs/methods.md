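# Methods

`obseg` segments the paired olfactory bulbs (OB) — two small (~6–60 mm³ per
side) spindle-shaped structures at the base of the forebrain — in
high-resolution T2-weighted head MRI, and reports per-side volumes in mm³.
On T2-weighted contrast the OB appears as darker tissue demarcated by bright
surrounding cerebrospinal fluid (CSF), which is the appearance both the
pipeline and the synthetic test data rely on.

## Pipeline model

Segmenting a structure that occupies roughly one voxel in a million makes
direct whole-head segmentation hopeless, so inference is staged:

1. **Localization.** The head volume is conformed (reoriented to RAS+,
   resampled, intensity-normalised) to 1.6 mm isotropic and passed through
   three 2D fully convolutional networks operating on axial, coronal and
   sagittal slices. They are trained not on the OB itself but on a
   ball-shaped region of interest: a Gaussian (σ = 10 voxels on the 1.6 mm
   grid) centred on the OB-pair centroid, thresholded at 0.8 of its analytic
   maximum, i.e. the digital ball of radius σ·√(2 ln 1.25) ≈ 6.68 voxels.
   The three per-voxel probability volumes are averaged with equal weights;
   the argmax region's centroid, mapped through world coordinates, centres a
   96³ crop on the 0.8 mm working grid. If the predicted region is empty the
   pipeline falls back to an anterior-inferior midline centroid and flags
   the case instead of aborting, so cohort batch runs always complete.

2. **Segmentation.** Inside the crop, attention-augmented networks segment
   left+right OB as a single foreground class. Multiple independently
   trained models (4 at full scale) × 3 views give 12 networks whose
   post-softmax probability volumes are averaged without weights; the argmax
   of the mean is the mask. Averaging soft probabilities (not hard labels)
   means only voxels with high inter-model agreement survive. Probabilities
   are accumulated in double precision so the result is independent of
   checkpoint ordering.

3. **Reporting.** The mask is placed back on the exact input grid
   (nearest-neighbour resampling only if working and native grids differ),
   split into left/right by the mid-sagittal plane through its own centroid
   (left = smaller world x in RAS+), converted to mm³ via the voxel volume,
   and QC-flagged: `empty_ob` for a zero-volume result (a valid outcome —
   some subjects have no visually apparent OB), `low_volume` below 20 mm³
   (segmentations that small should be inspected visually),
   `localization_fallback` when stage 1 failed.

## Network architecture

Both network families share one encoder–decoder layout: four encoder
blocks, a bottleneck and four decoder blocks, joined by 2×2
index-preserving max-pooling/unpooling (unpooling restores each maximum to
its exact position, avoiding the blurring of plain upsampling). The unit
block is a *competitive dense block* (CDB): three sequences of
activation → convolution → batch-norm whose intermediate maps compete
through element-wise maxima (maxout) instead of being concatenated —
m1 = max(x1, x), m2 = max(x2, m1), output x3. In the very first encoder
block the leading activation is a batch-norm (raw intensities need
normalising before any competition), and because its input has 3 channels
against 64 filters the first maxout is skipped; competition starts at the
second sequence. Networks take stacks of three consecutive slices as input
channels (edge-replicated at volume faces) and classify only the middle
slice, a cheap way to give a 2D network out-of-plane context.

The localization network uses 5×5 kernels and maxout fusion of decoder
skip connections. The segmentation network shrinks kernels to 3×3, fuses
skips by element-wise sum (preserving the multi-scale attention output that
maxout would clip), and inserts a positional self-attention module after
every CDB — 4 encoder + bottleneck + 4 decoder = 9 modules. The module
projects block features F (C×H×W) to query/key maps with C/8 channels,
forms the N×N attention map (N = H·W)

    s_{j,i} = softmax_i( F_a(i) · F_b(j) ),

aggregates a C-channel projection F_c with it, and applies it residually,
F_att = α·(Σ_i s_{j,i} F_c(i)) + F, with the scalar α learned from an
initial value of exactly 0 — the layer starts as the identity and the
network introduces non-local context only as it helps. F_att is
batch-normalised before the next block (the implementation exposes an
identity-normalisation test mode so the α = 0 identity is assertable
bit-exactly). Internally the N×N map is stored transposed so that all
large arrays stay contiguous; the N² memory footprint is why attention
networks are restricted to crops ≤ 96².

## Loss, weighting, training

Per slice the networks minimise a composed loss: a weighted focal term
(γ = 2) plus a soft dice term summed over both classes,

    L = − Σ_x w(x)(1 − p_{l(x)}(x))^γ log p_{l(x)}(x)
        − Σ_l 2 Σ_x p_l g_l / (Σ_x p_l² + Σ_x g_l²),

whose minimum −n_classes is attained at a perfect prediction. Pixel
weights w(x) are median-frequency class weights (median of class
frequencies divided by the class's own frequency, computed per 2D slice to
match 2D training) plus an edge bonus — twice the largest class weight —
on every pixel whose 8-neighbourhood touches another label. Probabilities
are clamped to [1e−7, 1−1e−7] inside the log; the batch path adds 1e−6 to
the dice denominator against all-background slices. A class absent from
both maps contributes a perfect per-class score.

Optimisation is Adam (lr 0.01, weight decay 1e−4, betas (0.9, 0.999),
eps 1e−8) with the learning rate multiplied by 0.95 every 5 epochs; the
full-scale schedule is 40 epochs at batch 16. Augmentation is applied
online: random rigid+scaling transforms (±8 mm translation, ±10° rotation,
scale 0.9–1.1) on the *full* volume before cropping, so crops never contain
interpolation padding; and subject-level intensity transforms (smooth
multiplicative polynomial bias field of order 3, amplitude ≤ 0.3, and
Gaussian blur σ ≤ 1 voxel, each with probability 0.5, parameters drawn once
per subject so all slices and views see the same transform). Training
subjects are divided into four splits stratified by age-bin × sex
(round-robin after a seeded shuffle) and treated leave-one-split-out; the
checkpoint with the best held-out-split Dice is kept.

The networks and their training run on a compact reverse-mode automatic
differentiation engine written on numpy (convolution via im2col, batch
normalisation, PReLU, index-preserving pooling, batched matrix products for
attention), with every backward pass verified against central finite
differences in the test-suite. Training is deterministic given the seed.

## Evaluation

For binary masks G, P: Dice 2|G∩P|/(|G|+|P|); volume similarity
VS = 1 − ||G|−|P||/(|G|+|P|); average Hausdorff distance, the maximum of
the two directed mean nearest-neighbour Euclidean distances taken over
*all* foreground voxels (not boundary voxels only — the two differ for
thick masks), in mm; and the centroid (localization) distance R. Empty
against empty scores Dice = VS = 1, so correctly predicted absent-OB cases
count as perfect agreement; AVD is undefined for an empty mask and raises
with an infinity sentinel.

Model comparison ranks each metric ascendingly so the best model carries
the largest rank, with ties sharing the *largest* tied position (two equal
runner-ups both outrank the next model — this is the convention that
reproduces the published benchmark tables; mean-of-ties is available as an
option), and aggregates by the geometric mean of per-metric ranks, reported
to two decimals. Test–retest volume agreement uses ICC(A,1) — two-way,
absolute-agreement, single measures — computed from the two-way ANOVA mean
squares with the standard F-based 95% confidence interval; an independent
variance-components evaluation and `pingouin` serve as oracles in the
tests.

## Synthetic phantoms

Real study data is restricted, so the repository generates its own test
data: a head-sized ellipsoid of mid-grey tissue wrapped in a bright CSF
rim, with a bright CSF pocket at the anterior-inferior base holding a
mirrored pair of dark spindle-shaped ellipsoids (elongated along the
anterior-posterior axis) as stand-ins for the bulbs. Additive Gaussian
noise (σ = 0.03 of the intensity range) and a smooth multiplicative
modulation emulate acquisition effects. The bulbs sit at 88% of the
normalised head radius — adjacent to the head boundary — so localized crops
extend past the volume and exercise the zero-padding path. Phantoms are
deterministic given their seed; `present=(False, False)` yields absent-OB
cases whose ground-truth volume is exactly zero while the head and CSF
structures remain.

Cohorts programme a linear age model for total OB volume,
total = β₀ + β_age·age + ε, with defaults β₀ = 70.5 mm³,
β_age = −0.3 mm³/year over ages 30–85, mirroring the negative age
association reported for adult OB volumes and centring mid-cohort volumes
near 54 mm³; totals are clipped to [12, 120] mm³ and split over the two
sides with a small random asymmetry. The noise σ = 5 mm³ is deliberately
smaller than real inter-subject variability (residual spreads above
10 mm³ are typical) so that a 40-subject desk cohort remains informative
about the programmed slope; consequences for interpretation are noted
below.

What the phantoms do *not* emulate: cortical anatomy and any realistic
background structure, partial-volume fading of the OB boundary, Rician
noise statistics, motion/breathing artefacts, multi-site contrast
differences. Passing phantom tests therefore demonstrates that the
pipeline's machinery — localization geometry, training dynamics,
ensembling, volumetry, QC — works end to end, not that the reported
accuracy transfers to clinical scans.

## Desk-scale study configuration

The full-scale recipe (64-filter networks, 96³ crops, 40 epochs, hundreds
of subjects, GPU training) does not fit a single CPU, so the repository's
own experiments (`obseg.study`, `scripts/acceptance.py`, the acceptance
tests) run a reduced configuration chosen once: 64³ phantoms at 0.8 mm,
16-filter networks, 32³ crops, 12 training phantoms with the same
stratified 4-split leave-one-out validation, 4 epochs for localization and
12 for segmentation, batch size 4 with half the slice pool sampled per
epoch (tiny cohorts provide few slices, so smaller batches restore the
optimisation-step count that full-scale training gets from hundreds of
subjects), and a single segmentation model per view (the ensemble
reduction is explicit in the configuration; an ensemble of identical
checkpoints is verified to reproduce the single model). Held-out
evaluation uses a fresh 10-phantom cohort and 2 absent-OB phantoms.

## Numerical choices and edge cases

- Conforming preserves the world position of the volume centre; output
  dimensions are ⌈n·vox/target⌉, so world extent is kept within one voxel.
  Trilinear interpolation is used for intensities (the downsampling kernel
  is not otherwise constrained) and nearest-neighbour for labels, which
  therefore never invent label codes.
- Intensity normalisation is a robust percentile min–max to [0, 1] (0.1 and
  99.9 percentiles, taken inclusively so that re-normalising an already
  normalised volume is an exact no-op).
- Crop padding uses value 0, the post-normalisation background intensity.
- The ROI ball membership test is closed-form (distance against the
  analytic radius), normalising by the Gaussian's analytic maximum rather
  than the discrete grid maximum — for fractional centroids the two differ.
  δ is in voxel units of the 1.6 mm grid.
- Left/right splitting uses the mid-sagittal plane through the combined
  centroid rather than connected components, which stays robust when the
  two bulbs touch; voxels exactly on the plane go to the right.
- Maxout gradients route to the first operand on exact ties; pooling takes
  the first maximum. Both choices only matter on measure-zero ties.
- `float64` arrays are honoured by the autodiff engine (used by the
  finite-difference tests); everything else computes in float32.

## Known limitations

- No trained weights ship with the package; full-scale training requires
  annotated study data and is expressed by the same code path but has not
  been run here.
- The phantom realism limits noted above; in particular phantom Dice
  scores (~0.9 at desk scale) are not comparable to real-data accuracy.
- The 2D multi-view design bounds attention memory by N = H·W ≤ 96²; a 3D
  attention variant is deliberately out of scope.
- DICOM ingestion, de-facing and skull stripping are out of scope; whole
  head T2w NIfTI volumes are the expected input.
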