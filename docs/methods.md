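# Methods

This note documents the models and numerical procedures implemented in
`neurofuse`, the parameter choices that matter, and what the synthetic
phantom does and does not demonstrate.

## Radiometric calibration

Hyperspectral cubes arrive as digital numbers and are converted to
reflectance fraction with white and dark reference acquisitions:
reflectance = (R − D) / (W − D), elementwise over pixels and bands.

Numerical choices:

- **Denominator guard.** Pixel-bands with W − D ≤ 1e-6 DN (dead or
  saturated sensor elements) are not divided; the pixel is flagged in a
  boolean validity mask carried on the cube, and classification labels such
  pixels background with confidence 1.
- **Negative reflectance** (R < D, possible under noise) is clipped to 0
  and counted in the log. **Reflectance above 1** (specular highlights) is
  passed through unclipped, also logged, because clipping would bias any
  downstream spectral statistics.
- **Band restriction.** The sensor records 51 bands over 450–850 nm, but
  the surgical light source emits nothing above 770 nm, so bands centred at
  or above 770 nm are noise. `restrict_bands` keeps bands strictly below
  the cutoff (default 770 nm → 40 bands ending at 762 nm for the factory
  8 nm spacing). Band centers are read from the ENVI header when present;
  the synthetic default is even spacing over the stated range.

pCLE frames are corrected by subtracting a fluorescence-free background
reference, floored at zero; a flag prevents double correction.

## Stereo geometry

The RGB camera (left) is the reference frame; the hyperspectral camera
(right) shares the microscope optics through a beam splitter. Calibration
consumes checkerboard **corner coordinates**, not images — corner detection
is a solved, library-dependent problem and keeping it out of the estimator
makes tests deterministic.

The estimator is two-stage:

1. **Closed-form initialisation** (plane-homography method): per-view
   homographies via the normalised DLT, intrinsics from the
   absolute-conic constraints with zero skew enforced, per-view poses by
   homography decomposition, and the relative pose as the quaternion mean
   of per-view left→right transforms. The microscope's telephoto optics
   (focal lengths of thousands of pixels, a few degrees of board tilt)
   leave the conic system poorly conditioned, so when it produces an
   invalid camera matrix the initialiser falls back to a focal-only
   estimate anchored at the observed corner centroid. Either way the
   result only seeds stage 2.
2. **Joint bundle refinement**: Levenberg–Marquardt over both intrinsics,
   all board poses, and the relative pose, minimising corner reprojection
   error in both cameras simultaneously. On noiseless synthetic views this
   converges to machine precision (corner RMS ~1e-13 px); tests assert
   T within 1e-3 mm and rotation within 1e-5 rad of truth from 30 views.

The reported RMS is pooled over both cameras and all corners. Distortion
is the standard 5-coefficient radial–tangential model, applied in
projection when coefficients are set and zero by default in synthetic
fixtures. Conventions: pixel (0,0) is the centre of the top-left pixel;
frames are right-handed, x right, y down, z forward; rotation recovery is
compared by axis-angle geodesic distance. Near-coplanar board motion
triggers a conditioning warning with the orientation-spread condition
number.

## Probe tracking

- **Marker pose.** The probe carries a planar square fiducial. Pose comes
  from RANSAC over 4-point homography decompositions followed by
  Levenberg–Marquardt refinement on the inlier set; a refined-pose
  re-classification pass recovers inliers the minimal sample missed.
  Default inlier gate: 2 px reprojection.
- **Pivot calibration.** Rotating the probe about its stationary tip gives
  one rigid constraint R_i·t_tip + t_i = p per pose; stacking them yields a
  linear system in (t_tip, p) solved by least squares. The RMS of the
  constraint violations is stored on the probe model. A stationary point
  target has no observable orientation, so the marker-to-tip rotation is
  fixed at identity and only the translational offset is estimated — the
  rotational part of the classic tool-tip transform is unobservable here.
  Rank < 5 (no rotational diversity) is an error; rank 5 or condition
  number > 1e6 (single-axis rotation) solves anyway with a warning, since
  one tip component is then weakly constrained.
- **Tip projection.** tip = R_m·T_probe + t_m in the left frame, then the
  stereo transform and right-camera pinhole projection give the HSI pixel.
  Out-of-bounds projections are flagged, never clamped.
- **Probe-tip error protocol.** For touch events on reference markers with
  known HSI pixel centres, the error is the Euclidean pixel distance
  between the projected tip and the known centre, reported mean ± sample
  sd. Conversion to millimetres multiplies by an explicit pixel footprint
  (0.12 mm/px RGB, 0.31 mm/px HSI at the 30 cm working distance) — the
  caller chooses the camera, since the error can be meaningfully expressed
  in either.
- **Site footprint.** The probe's 325 µm field of view spans about one HSI
  pixel (0.31 mm), so a site rasterises to its nearest pixel by default;
  a disc radius is configurable.

## Classification

- **Spectral (3-class, pixel-wise).** Two families: RBF-kernel SVM with
  C = 1 and pairwise-coupling probability estimates, and an MLP with
  hidden layers (128, 64), ReLU, softmax output, cross-entropy loss, Adam
  at learning rate 1e-3, batch size 256, 50 epochs, no weight decay
  (13,699 trainable parameters on 40-band input). The MLP uses the
  library's Glorot initialisation. Ties in SVM probabilities resolve by
  class order (BG < healthy < tumor).
- **Probe frames (binary).** `cnn_small`: three stride-2 convolutional
  blocks (16/32/64 channels, 3×3 seeded He-initialised filter banks, ReLU)
  with global average pooling, feeding a small dense softmax head trained
  with the same loss/optimizer/learning rate. The convolutional filters
  are fixed by seed and only the head is trained — at this data scale
  (tens of frames per class) a random convolutional feature bank with a
  trained head is both reproducible and sufficient, and the whole model is
  plain NumPy + scikit-learn. `mobilenet_v2`/`efficientnet` are accepted
  as configuration values but raise at training time: this package ships
  no pretrained backbone weights. Inputs are min-max scaled per image
  after background subtraction (scale-invariant default) and resized to
  64×64.
- **Imbalance and folding.** Undersampling reduces every class to the
  minority count, without replacement, deterministically per seed and
  independent of input order. Cross-validation is leave-one-specimen-out:
  each specimen is the held-out test set exactly once; fold train/test
  specimen sets are asserted disjoint. Probe scans from tumor-margin
  regions never enter training — attempting it raises a contamination
  error — because margins are the deployment condition being evaluated.

## Fusion

Inputs: the HSI tumor mask, its 3-class confidence maps, and the projected
biopsy sites with predicted labels.

1. **Logical OR**: union of the HSI tumor mask and the rasterised
   tumor-labelled sites. Healthy-labelled sites contribute nothing.
2. **Probe-informed largest component**: among connected components of the
   OR mask (8-connectivity by default — 4 splits diagonal structures), keep
   the largest that contains at least one tumor site. A switch can keep
   all qualifying components; default keeps only the largest.
3. **Runner-up replacement**: every discarded tumor pixel takes the larger
   of its BG/healthy confidences — a per-pixel confidence fallback, never a
   spatial fill — and is tagged `replaced` in the provenance map
   (`hsi` and `pcle` tag kept pixels by origin).

The OR runs before component filtering. If no component contains a site,
the configurable fallback applies (default: degrade to the HSI-only
largest-component baseline, with a warning). The HSI-LCC baseline keeps
the largest tumor component unconditionally; equal-sized components tie-
break on the smallest row-major pixel index.

Invariants enforced by tests: fusion never labels tumor outside the OR
mask; replaced pixels are never tumor; tumor pixel counts order as
HSI-LCC ≤ raw HSI ≤ OR output.

## Evaluation

Per-class Dice 2|A∩B|/(|A|+|B|) and recall |A∩B|/|B|, computed one-vs-rest
from the 3-class label maps with background participating as a class; the
average row is the unweighted 3-class mean. Both-empty masks score Dice 1;
empty ground truth scores recall 1 with a warning. Probe-only
"segmentation" is scored as the rasterised tumor-labelled sites against
the ground-truth tumor mask, tumor class only — a probe cannot score
pixels it never touched, and this is the minimal consistent spatial
reading of a point-sampling modality. Cross-fold aggregation reports
arithmetic mean ± sample (n−1) standard deviation. Frame-level probe
classification reports accuracy and macro F1.

## Synthetic phantom

The generator emulates a five-specimen bench study: a wobbly-ellipse
specimen body (healthy) on a dark background, one smooth tumor blob per
specimen with exposed size drawn from 5.0–17.6 mm (0.31 mm/px), 15–20
margin biopsy sites per specimen (at least one guaranteed on true tumor),
and per-specimen pools of labelled spectra at 50/25/25 BG/healthy/tumor
proportions (4000/specimen by default).

- **Spectra** are smooth per-class mean curves (sums of 2–3 Gaussians over
  wavelength) plus i.i.d. Gaussian noise, sd 0.02 by default; a
  `class_separation` scale collapses the class means to chance-level for
  control experiments. There is no spatial correlation — the classifiers
  under test are pixel-wise, so none is needed.
- **Reference cubes** are constructed so that white/dark calibration
  recovers the designed reflectance to numerical precision (the round-trip
  is asserted at 1e-6), with spatially varying dark level and illumination
  gain and a strictly positive denominator.
- **Satellite decoys**: small blobs (2 per specimen by default) carry
  tumor-like spectra but healthy ground truth, reproducing the
  over-prediction pattern that motivates component filtering.
- **Geometry**: biopsy-site pixels are chosen in a band around the tumor
  boundary, back-projected to 3-D at the working distance, and given a
  random marker pose consistent with the true probe offset; the stored
  pixel, tip and pose are mutually consistent to the last bit. Rendered
  checkerboard views and pivot sequences are exact pinhole/rigid forward
  models plus optional Gaussian noise.
- **Probe textures**: tumor frames are bright fluorescent blob fields on a
  dark ground, healthy frames low-intensity speckle, margin frames a
  smooth spatial mixture.
- **Randomness** flows from one root seed through named child streams
  (numpy `SeedSequence` spawn keys), one per content type per specimen, so
  datasets are byte-identical per seed and cube synthesis can be skipped
  without perturbing anything else.

**What passing on the phantom shows** — and does not. The default phantom
is separable by construction: spectral classes differ by ~10 noise sds, and
tumor/healthy probe textures differ strongly in intensity. Passing tests
therefore demonstrate that the calibration, geometry, training plumbing,
fusion logic and metrics are correct, and that probe-informed filtering
removes exactly the planted false positives; they say nothing about
classification difficulty on real tissue, where class overlap, spatial
correlation, illumination drift and annotation noise dominate. The
end-to-end assertions are deliberately directional (fused ≥ HSI-only Dice,
fused ≥ probe-only recall), not absolute.

## Problem sizes used

Unit tests run on reduced frames (60×64) with small sample pools; the
acceptance script and end-to-end acceptance test use the full study
conditions (5 specimens, 275×290×51 cubes, 30 calibration views, 20 pivot
poses, 4000 spectra/specimen, LOSO with the MLP and the compact conv-net).
The 20-seed directional check runs at the fusion stage on generator
outputs, taking the generator's spectral-identity map as the HSI mask —
equivalent to a well-trained spectral classifier under the phantom's
separable conditions — so that the repeated check isolates the fusion
logic.

## Known limitations

- Stereo calibration assumes zero skew and does not estimate distortion by
  default (synthetic fixtures are distortion-free); real lenses would need
  the distortion coefficients enabled and varied board tilts.
- The pivot model ignores marker pose noise correlation; residuals are
  interpreted as isotropic.
- The probe-frame classifier's convolutional features are fixed, not
  learned; with hundreds of training frames per class a fully trained
  network would be preferable.
- The probe-only Dice is tiny by construction (single-pixel footprints
  against blob-sized ground truth); it is reported for completeness, the
  meaningful probe-only quantity being recall at the sampled sites.
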