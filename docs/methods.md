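# Methods

## The standardized frame

Each bundle's frame is built from five landmarks.  The centre C solves the
2×2 linear system for the intersection of line(R3 heel, T3 centre) and
line(R4 heel, T3′ centre); bundles whose defining lines are near-parallel
(|sin| of the inter-line angle < 1e−6) are rejected with a
degenerate-geometry error and logged rather than silently skipped, since
only annotatable bundles enter any analysis.  Ellipse *centres*, never
boundary points, anchor all lengths and angles.

The radial unit is |C−T4|.  The angular map is piecewise linear: a physical
angle φ (measured from the C→T4 axis, chirality-signed so the T3 side is
positive) maps to θ = φ/∡(T3,C,T4) for φ ≥ 0 and θ = φ/∡(T4,C,T3′) for
φ < 0.  The two wedges genuinely differ (≈ 14.8° vs 13.3° in wild type), so
the map has a slope break at θ = 0; beyond ±1 each side's scale extends
linearly so the fixed grid's ±3 range is covered.  Chirality is resolved per
bundle from the sign of the cross product of C→T4 with C→T3, which makes
mirrored specimens need no preprocessing.  The construction is exactly
invariant under similarity transforms and mirror reflection of the raw
coordinates, and maps T3/T4/T3′ to θ = +1/0/−1 to 1e−9; these are tested
properties, not approximations.

Points exactly at C have undefined angle; they are returned as (r=0, θ=0).

## Density maps

The resampling grid is fixed: r from 0 to 3.8 in steps of 0.05, θ from −3
to +3 in steps of 0.05 (77 × 121 nodes), independent of image size.  Each
node maps through the inverse frame transform to pixel coordinates and is
sampled with bilinear interpolation (`scipy.ndimage.map_coordinates`,
order 1).  Bilinear sampling preserves constant images to machine precision
and is exact on affine intensity fields, which the tests exploit as an
oracle; nearest-neighbour and cubic schemes would break those properties.
Nodes outside the image get value 0 and a True entry in an out-of-bounds
mask, so downstream detection never reacts to border gradients.

Per-bundle maps average a 41-slice z-window centred on the reference slice.
The window *clips* at stack boundaries (no padding — padding invents data)
and the number of slices actually averaged is recorded.  The reference
slice is the one with the longest growth cone: per slice, the largest
radius among suprathreshold nodes, thresholded at 0.2 × the *stack-wide*
99.5th-percentile resampled intensity.  A stack-wide (not per-slice)
reference keeps dim slices from winning on noise, because a per-slice
relative threshold is scale-invariant.  Extent ties — extent is quantized
to one radial step — break by total suprathreshold intensity, then by
lowest index.

## Front detection

Front annotation was inherently manual in the original workflow; this
package's automated operator is its own definition, calibrated on synthetic
fixtures, and every constant is exposed as a parameter:

* binarize at `threshold_fraction` (default 0.2) × the map's
  99.5th-percentile intensity — a relative threshold, so detection is
  invariant to overall intensity scaling;
* per θ-column, the maximal suprathreshold radius forms the extent profile;
  `rel_length` is its maximum;
* local maxima of the extent profile separated by at least
  `min_peak_separation` (0.3 wedge units) and standing clear of their valley
  by ≥ 20% of their own extent are candidate filopodia; those reaching 90%
  of the maximal extent qualify.  Two or more qualifying peaks are split
  morphology, and the angle is the mean of the peak angles;
* otherwise the angle is the intensity-weighted mean over suprathreshold
  nodes with r ≥ 0.8 × `rel_length`, restricted to columns within
  `min_peak_separation` of the dominant peak.  The average is computed in
  *physical* angle with per-column angular widths as weights and converted
  back to wedge units at the end.  Both refinements remove systematic bias:
  wedge-unit averaging drags the estimate toward the narrow-wedge side
  whenever the two wedges differ, and the shaft of an oblique cone crosses
  the radial band at angles unrelated to the tip;
* a front is flagged ambiguous ("too dense to distinguish") when more than
  60% of the θ-columns in [−1.5, 1.5] have suprathreshold extent reaching
  half the growth-cone length.  The extent qualifier matters: every map has
  signal near the centre, where all angular columns converge on the heel
  region, so counting bare suprathreshold columns would flag everything.
  Ambiguous measurements are excluded from all downstream statistics.  At
  the earliest time point (22 hrs) short cones are frequently excluded by
  this rule — consistent with the original datasets, where early samples
  were also the hardest to annotate.

Cell types follow the reporter logic: a front whose GFP intensity is at
least `strong_gfp_ratio` (default 0.5) × the RFP intensity in the same node
neighbourhood is R4, otherwise R3.  R4 cells are measured from the GFP map
and R3 cells from the RFP map; an RFP front with strong GFP is the same R4
cell seen twice and is dropped.  In fate-transformed bundles both cells
live in one channel and appear as split morphology; each qualifying peak
is then measured separately.  Heel positions 3 and 4 are assigned by
descending front angle (the T3-side front is position 3); a lone cell takes
its wild-type position.

Final targeting classifies the front point against each target ellipse
mapped, via 64 boundary points, into the (r, θ) plane (shapely polygon
containment); fronts inside no ellipse are "other".  Bundle-level scoring
calls a bundle wild-type-like only when its two growth cones end on T3 and
T4.  In two-R4 bundles both cones converge on T4 and their fronts merge
into one detected front; a lone R4 front on T4 with a completely dark RFP
channel (no R3 exists to label) is therefore scored as the two-R4 pattern.
Channel darkness is itself a relative call — a channel whose intensity
scale is below 15% of its partner's carries only camera noise.

## The repulsion model

For R3 the repulsion vectors are v₁ = unit(R2→R3) and v₂ = unit(R4→R3);
for R4, v₁ = unit(R5→R4) and v₂ = unit(R3→R4).  Vectors are taken in the
rigidly aligned frame (C at origin, C→T4 along +x, chirality applied),
where unit vectors are comparable across bundles; unit vectors are not
meaningful after the non-conformal angular normalization, so the
standardized frame itself is not used for them.  The predicted direction is
that of αv₁ + βv₂, reported as a standardized angular coordinate; it is
invariant under positive rescaling of (α, β).

Weights are fitted per cell type by ordinary least squares without
intercept, stacking both Cartesian components of the measured extension
vector against those of (v₁, v₂), on data pooled from 22–26 hrs and
restricted to shape-symmetric bundles
(|∡(T3,C,T4) − ∡(T3′,C,T4)| / max ≤ 0.5).  One subtlety is documented on
the fitting routine: a pure direction (unit-vector target) determines the
α/β *ratio* but lets the normalization deflate or inflate the pair
jointly, so exact weight recovery requires the measured magnitude.  The
synthetic vector-sum generator therefore supplies |αv₁ + βv₂| with each
input; directions-only data fit with magnitude 1.

## Statistics

Two groups: two-sided Mann-Whitney U (exact for untied samples of size ≤ 8,
normal approximation with tie correction otherwise).  Three or more:
Kruskal-Wallis omnibus, then all pairwise Mann-Whitney with Holm-Bonferroni
step-down adjustment (statsmodels' implementation, tested against a
hand-coded step-down oracle).  Stars: ns for p ≥ 0.05, then */**/*** at
0.05/0.01/0.001.  Penetrance is 100 × altered/(altered + wild-type-like),
reported to one decimal.  Wedge-unit angles are treated as linear (not
circular) quantities for means and SDs — they occupy a narrow range around
zero; this is a documented limitation, not an oversight.

## The synthetic lamina

The generator emulates exactly the data the pipeline consumes.  Bundles sit
on a hexagonal lattice (pitch 10 µm).  Per bundle, |C−T4| ~ N(7.1, 1.5²) µm,
the T3-side wedge ~ N(14.8°, 4.0°²) and the T3′-side wedge ~ N(13.3°,
3.8°²) (draws truncated at 7° — bundles with near-collapsed wedges are not
annotatable and wedge-unit quantities diverge as 1/wedge), plus an
orientation jitter of SD 5°.  The landmark template places R3 on the line
through C and T3 and R4 on the line through C and T3′ — which is precisely
what makes C the intersection of those lines — with target radii 1.15,
1.0 and 1.10 |C−T4| for T3, T4, T3′ and heels at 0.28 |C−T4|.  A smooth
sinusoidal displacement field (amplitude 0.5 µm, wavelength 40 µm) warps
the whole lattice, emulating specimen-level distortion, and independent
Gaussian jitter (SD 0.1 µm) perturbs individual landmarks.  All draws are
deterministic given (config, seed); changing only the seed changes the
noise, never the template.

Kinetics: extension begins at 18 hrs APF and the front's radial coordinate
grows linearly at a cell-type-specific speed until it saturates at the
target radius.  Default speeds are r_target/10 per hour (R3 0.115, R4
0.10), so both cell types arrive exactly at 28 hrs and R3, whose target is
farther, is visibly faster — the published constraints; no absolute speeds
are published, so the defaults are the simplest values satisfying them.
Pre-arrival angles are symmetric (+0.5 wedge units for position 3, −0.5 for
position 4, the mid-wedge bearing) and snap to the target's angle at
arrival; noise is independent Gaussian per time point (length SD 0.05,
angle SD 0.08), with no within-cell temporal autocorrelation, because
fixed-specimen imaging carries no trajectories.  Fate modes reassign
identities and targets (two-R4: both to T4; two-R3: positions 3/4 to
T3/T3′), with alteration drawn per bundle as a Bernoulli at the configured
penetrance.

Rendering: growth cones are Gaussian ridges (cross-section SD =
filopodium_width/2 = 0.2 µm) from heel to front, brightest at the front,
with the tip capped three times harder axially so the detectable leading
edge of the rendered cone sits at the ground-truth front rather than a
PSF-halo beyond it.  Heels are blobs (24B10 channel), target ellipses are
rings (FasII), a Gaussian PSF (SD 0.12 µm) blurs every slice, and
Poisson-Gaussian noise (photon scale 200, read noise SD 0.01) is applied.
Across z only the *brightness* falls off (Gaussian profile, SD 2 slices,
peak at a selectable slice); against the stack-wide detection threshold
this makes the measured extent peak exactly at the bright slice, which is
what reference-slice selection keys on.

What the generator does not emulate: neighbouring-bundle clutter and
overlapping labels (each bundle renders in its own crop), filopodial
branching and dynamics, optical aberrations beyond a Gaussian PSF,
background staining, or annotation error in the landmark clicks beyond
isotropic jitter.  Passing tests therefore demonstrate that the pipeline's
geometry, resampling, detection and fitting are correct and unbiased at
realistic signal-to-noise — not that the detector would match a human
annotator on cluttered real images.

## Numerical choices and problem sizes

Degenerate inputs raise typed errors (never NaNs): near-parallel defining
lines, zero-length axes, targets on the same side of the axis, empty
channels, empty fronts, rank-deficient repulsion designs, zero-norm vector
sums.  The acceptance script runs a 500-bundle lattice for the frame
calibration, 200-input repulsion datasets at 5° angular noise for weight
recovery, 100-bundle desk studies (eight time points for the wild-type
pattern; two for the two-R4 targeting rate), and 5000 null replicates
(n = 25 per group) for the Mann-Whitney size check — sizes chosen so every
quantity's sampling error is well inside the precision at which it is
reported.  Angle-symmetry in the desk study is assessed per time point, the
unit at which the published polar summaries present it; pooling time points
would shrink the comparison band below the detector's sub-pixel systematics
(~0.01 wedge units ≈ tens of nanometres), which no image-based estimator
can beat.

## Known limitations

* The front-detection constants were calibrated on this generator's
  renderings; real confocal data will likely need `threshold_fraction` and
  the dense-region rule re-tuned, and the package exposes them for that.
* The angular mean treats wedge units linearly; far outside ±1 (never
  reached by real fronts) the slope break makes averages across the break
  scale-dependent.
* Repulsion weights from directions-only data inherit a joint scale
  distortion from target normalization (see above); ratios are reliable,
  absolute weights require magnitudes.
* The bundle-level two-R4 scoring rule assumes a dark RFP channel implies
  no R3; with very weak sparse labelling on real data that call should be
  reviewed.
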