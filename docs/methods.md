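# Methods

This note documents the quantitative procedures implemented in
`spheroidquant`, the choices behind them, and what the built-in synthetic
data can and cannot establish.

## Coordinate conventions and preprocessing

All volumes are ordered (z, y, x) with physical voxel spacing in µm.
Analysis assumes an isotropic grid; `rescale_to_isotropic` resamples to the
finer of (dy, dx) — z is typically the coarse axis in confocal stacks, so z
is upsampled (linear interpolation for intensities, nearest neighbour for
label masks so no ids are invented) and lateral detail is never degraded.
Spacing priority is: explicit config override, then ImageJ-style TIFF
metadata, then an error — microscope TIFF metadata is too unreliable to
trust silently.

Nuclei with volume (voxel count × voxel volume) strictly below 300 µm³ or
strictly above 3000 µm³ are removed as debris or segmentation errors before
any feature extraction. The bounds are inclusive: exactly 300 and 3000 µm³
survive. The filter runs after isotropic rescaling, so borderline nuclei
are judged on the same grid as every downstream measurement.

## Per-nucleus features

Morphology comes from voxel-coordinate moments: volume is voxel count ×
voxel volume; axis lengths are the ellipsoid-equivalent values
2·√(5·λᵢ)·spacing from the eigenvalues λᵢ of the coordinate covariance (a
solid ellipsoid with semi-axis a has variance a²/5); elongation is the
major/minor axis ratio. Intensity statistics (mean, median, max, 95th
percentile with linear interpolation, population SD — the voxel set is the
entire region, not a sample) are computed per channel over the nucleus and
over its **outer region**: four binary dilations of the nucleus with the
6-connected (connectivity-1) structuring element, minus the nucleus itself
and every voxel of any other nucleus. The outer region may be empty under
extreme crowding; records carry an `outer_empty` flag and outer features
fall back to 0.

**Masked Gaussian smoothing** restricts smoothing to foreground by
normalized convolution: smooth(I·F)/smooth(F) with F = [I > threshold];
voxels with no foreground support map to 0. A constant foreground image is
a fixed point and an all-background image maps to zero. The per-channel
foreground threshold defaults to Otsu's method and can be overridden in the
config (`fg_threshold.<channel>`); the smoothing sigma defaults to 1 voxel.
Normalized convolution deliberately *extrapolates* foreground intensity
into nearby background — desirable for denoising a sparse signal, but it
also paints a bright neighbour's signal across an adjacent negative
nucleus. See the gating section for the consequence.

## Marker gating

Ki-67 positivity is classified from the 3-vector [nuclear-dye mean in the
nucleus, Ki-67 mean in the nucleus, Ki-67 mean in the outer region]; the
outer feature lets the gate reject elevated local background.
Live-or-Dye uses the 2-vector [nuclear-dye mean, Live-or-Dye mean], both
within the nucleus. All gates are support-vector classifiers with a linear
kernel and C = 1 on features standardized with the training mean/SD; the
fitted model is fully described by (mean, SD, weights, intercept) and
serializes to a YAML sidecar that reproduces training-time predictions
exactly. Positive fractions divide by the *total* surviving nucleus count,
not the gated subset.

Gate features use **raw** intensity means by default (`use_smoothed_features
= False`). In crowded spheroids the extrapolation of normalized convolution
can raise a marker-negative nucleus's smoothed nuclear mean to nearly the
positive level when it abuts positive neighbours (observed: 53.7 vs 55.0 in
a noise-free scene), destroying separability that plainly exists in the raw
data. Raw nuclear means aggregate hundreds of voxels, so per-voxel noise is
suppressed by averaging without any smoothing step. The CellTracker gate is
the exception: it is defined on σ = 1 Gaussian-smoothed nuclear means
(one feature), matching the staining protocol it belongs to, and is used
only to expand a small manual fibroblast annotation into a training set for
the cell-type classifier.

Cleaved Caspase-3 cannot be attributed per cell in dense apoptotic
clusters, so it is reported as an aggregate index: the sum of
above-threshold Cas3 voxel intensities divided by the nucleus count
(a.u./cell). The threshold reuses the channel's foreground threshold.

## Spheroid morphometry and shells

The whole-spheroid mask is fill_holes(erode⁴⁰(dilate⁴⁰(nuclei > 0))) with
the connectivity-1 element, keeping the largest connected component. The
dilation/erosion count (default 40) must exceed half the largest
inter-nuclear gap to be closed. Iterated connectivity-1 morphology is
computed exactly via taxicab distance transforms (dilateᵏ = L1-distance ≤ k),
which is orders of magnitude faster than k structuring-element passes and
bit-identical to them; the working array is padded by n_iter + 1 voxels so
dilation never clips at the boundary. On convex solids the closure is a
near-identity (volume change < 1 % on a radius-30 digital ball).

Derived quantities: void fraction = (|mask| − |nuclei ∩ mask|)/|mask|;
density = nuclei count / mask volume; largest equivalent xy diameter =
max over z-planes of 2·√(area/π). Per-nucleus distances use the mask's
center of mass and a Euclidean distance transform to the mask surface
(background-adjacent mask voxels), evaluated at the centroid's voxel — a
≤ 1 voxel discretization. "Hull" means the segmented surface, not a convex
hull: the closed mask is genuinely non-convex.

Shell analysis erodes the mask iteratively and takes the first eroded
state at or below 2/3 and 1/3 of the original volume; set differences give
outer/middle/inner shells that tile the mask exactly. The stop rule may
overshoot by one erosion ring, so achieved fractions are always reported
(within 5 % of a third on a radius-60 ball). Nuclei are assigned to shells
by centroid voxel; a centroid that lands outside every shell (possible
after aggressive filtering) is assigned to the outer shell and logged.
Shell marker distributions are percentages of the marker-positive cells per
shell, summing to 100. Densities use filtered nucleus counts throughout,
consistent with the cell table.

## Cell-type discrimination and corrected counts

Fibroblast nuclei are small (volume mode ≈ 500 µm³) and elongated; tumor
nuclei are large (mode ≈ 1200 µm³) and round — but late-mitotic tumor
nuclei can be small, so volume alone is biased. The classifier is a
standardized linear SVM on [volume, elongation, collagen-1 outer-region
mean, collagen-1 nuclear mean]: the collagen context rescues the
small-tumor confusers because only fibroblasts sit inside secreted
collagen-1. Training labels come from `expand_labels_with_celltracker`
(CellTracker⁺ → fibroblast). Corrected counts decompose co-culture totals:
tumor = total − predicted fibroblasts, so the two predicted counts always
sum to the total.

A volumetric CNN classifier over 48×64×64 (z, y, x) three-channel crops
(nuclei, collagen-1, focal-nucleus mask — `crop_for_cnn` builds these with
zero padding at volume borders) is a natural extension when a deep-learning
backend is available; the feature SVM is this package's default and only
built-in classifier, since it consumes the same information sources and is
trainable in seconds on a CPU.

## Segmentation metrics

SEG: each ground-truth object matches the (unique, if any) predicted object
covering strictly more than half of its voxels; SEG is the mean Jaccard
over ground-truth objects, 0 for unmatched. DET: with the same matching,
AOGM-D = 10·FN + 1·FP + 5·NS where NS counts split operations for predicted
objects matched to ≥ 2 ground-truth objects; DET = 1 − min(AOGM-D,
AOGM-D₀)/AOGM-D₀ with AOGM-D₀ = 10·|GT|. Both are verified against an
independent brute-force voxel-set implementation in the test suite.

## Condition tables

Replicate rows aggregate to per-condition mean ± SD (sample SD, ddof 1 —
the spreadsheet/statistics-package convention); z-scoring is
(x − mean)/SD per metric over all conditions, erroring on zero-variance
columns. Ratios to a named reference condition are available as a separate
view; z-scoring is not applied after reference division by default.
Hypothesis testing (ANOVA etc.) is deliberately out of scope: the exported
replicate tables feed any statistics tool.

## Synthetic scenes: what they emulate, and what they don't

The generator places non-overlapping ellipsoidal nuclei (rejection
sampling, uniform in the spheroid ball, random orientation) with lognormal
volumes parameterized by mode and geometric SD — strictly positive and
right-skewed, matching single-mode empirical histograms. Defaults are the
study conditions: radius 60 µm; 50 tumor + 150 fibroblast (the 1:3 seeding
ratio of the co-culture protocol); volume modes 1200/500 µm³, geometric SD
1.3; elongations 1.2 (tumor) vs 2.5 (fibroblast); 5 % of tumor nuclei
drawn small and round ("mitotic-like") to reproduce the volume-only
confusion case; Ki-67 fractions 0.5/0.05 (fibroblasts proliferate little),
Live-or-Dye 0.1, Cas3 0.05; collagen-1 as an additive Gaussian shell of
width 3 µm outside fibroblast nuclei only (collagen is extracellular, so it
must be caught by the outer-region feature, not the nuclear mask); nuclear
base intensity 100 with 10 % per-nucleus variation over background 5;
marker contrast 50 over Gaussian noise of SD 10 (5× the noise);
CellTracker rendered inside fibroblast nuclei. Blur and exponential depth
attenuation are off by default (whole-mount acquisition with
z-compensation) but available as robustness knobs. All randomness flows
from one seed; regeneration is byte-identical.

What the scenes do **not** emulate: a real PSF (anisotropic blur, spherical
aberration), chromatic shifts, cytoplasmic vs nuclear marker localization,
touching/overlapping nuclei or segmentation errors (labels are perfect by
construction), necrotic-core geometry, and intensity heterogeneity within a
nucleus. Passing recovery tests on these scenes therefore demonstrates that
the *analysis chain* is correct and unbiased when its inputs match its
assumptions — it does not certify performance on real microscope data,
where segmentation quality (measured separately via SEG/DET) dominates.

## Numerical choices

- Percentiles: linear interpolation; SD over a region: population (ddof 0);
  SD across replicates: sample (ddof 1).
- Structuring element: 6-connected (connectivity 1) everywhere in 3D.
- SVMs: `SVC(kernel="linear", C=1)` on standardized features — small, 1–4-D
  feature spaces need no kernel machinery, and the linear decision function
  serializes exactly.
- Erosion stop rule: first state at-or-below target (may overshoot by one
  ring); achieved fractions reported rather than hidden.
- Degenerate morphology: a single-voxel region has zero covariance and is
  defined to have elongation 1; zero-minor-axis planes map to elongation ∞.
- Problem sizes in tests and the acceptance script (radius-60 scenes with
  200 nuclei, 10 evaluation seeds, 16³ metric phantoms) were chosen so the
  full suite completes in about a minute on one CPU while keeping every
  statistical check comfortably powered.

## Known limitations

- Marker gates need user-supplied training annotations on real data; the
  package ships no pre-trained weights.
- Shell analysis assumes one connected spheroid; fragmented cultures reduce
  to the largest aggregate.
- The 300–3000 µm³ filter is tuned for human nuclei at the stated imaging
  scale; other cell types need config overrides.
- `MultiChannelVolume` holds everything in memory as float64; stacks beyond
  ~2 GB per channel warrant chunked processing that this package does not
  attempt.
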